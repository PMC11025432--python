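"""Between- vs within-cluster spread of adjusted odds ratios.

The cluster-level adjusted odds ratios come from the count-strategy
regression (one aOR per additional disease in the cluster); the
disease-level aORs come from the 212-indicator reference model.  Spread
is measured as the range (max - min) of log-aORs: per cluster over its
member diseases (within), and over the cluster-level estimates
(between).  The headline comparison asks whether the median within-
cluster range exceeds the between-cluster range.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .types import ClusterMap, DispersionSummary, ModelFit

logger = logging.getLogger(__name__)

Z95 = 1.959963984540054


def odds_ratio_table(
    cluster_fit: ModelFit,
    disease_fit: ModelFit,
    cluster_map: ClusterMap,
    outcome: str,
) -> pd.DataFrame:
    """Exposure-block aORs with 95% CIs from the two fits.

    One row per cluster (from the count-strategy model) and per disease
    (from the disease model), joined to its cluster.  Covariate terms are
    excluded.  Diseases whose column was dropped at the design stage get
    a row with missing estimates and ``estimated=False``.
    """
    rows = []
    for fit, level, prefix in (
        (cluster_fit, "cluster", "cluster_"),
        (disease_fit, "disease", "disease_"),
    ):
        ids = cluster_map.cluster_ids if level == "cluster" else cluster_map.disease_ids
        for unit in ids:
            col = prefix + unit
            if col in fit.coefficients.index:
                beta = float(fit.coefficients[col])
                se = float(fit.standard_errors[col])
                with np.errstate(over="ignore"):
                    lo, hi = np.exp(beta - Z95 * se), np.exp(beta + Z95 * se)
                rows.append(
                    {
                        "term_id": unit,
                        "level": level,
                        "outcome": outcome,
                        "log_aor": beta,
                        "aor": float(np.exp(beta)),
                        "ci_low": lo,
                        "ci_high": hi,
                        "significant": bool(lo > 1.0 or hi < 1.0),
                        "estimated": True,
                        "separated": bool(fit.separation_flags.get(col, False)),
                    }
                )
            else:
                rows.append(
                    {
                        "term_id": unit,
                        "level": level,
                        "outcome": outcome,
                        "log_aor": np.nan,
                        "aor": np.nan,
                        "ci_low": np.nan,
                        "ci_high": np.nan,
                        "significant": False,
                        "estimated": False,
                        "separated": False,
                    }
                )
    table = pd.DataFrame(rows)
    d2c = cluster_map.disease_to_cluster
    table["cluster_id"] = np.where(
        table["level"] == "cluster",
        table["term_id"],
        table["term_id"].map(d2c),
    )
    return table


def dispersion_summary(
    table: pd.DataFrame,
    cluster_map: ClusterMap,
    variant: str = "all_diseases",
) -> DispersionSummary:
    """Within- vs between-cluster log-aOR ranges.

    ``variant="significant_only"`` restricts the disease rows to those
    whose 95% CI excludes 1.  Separated coefficients (|log-aOR| beyond the
    separation threshold; their magnitude is an artefact of sparse cells,
    not an effect estimate) are excluded from ranges in both variants.
    Clusters with fewer than two usable disease rows are excluded from
    the median with a warning.
    """
    if variant not in ("all_diseases", "significant_only"):
        raise ValueError(f"unknown variant: {variant}")
    outcome = table["outcome"].iloc[0]

    diseases = table[
        (table["level"] == "disease") & table["estimated"] & ~table["separated"]
    ]
    if variant == "significant_only":
        diseases = diseases[diseases["significant"]]
    clusters = table[
        (table["level"] == "cluster") & table["estimated"] & ~table["separated"]
    ]

    within = {}
    excluded = []
    for cid in cluster_map.cluster_ids:
        vals = diseases.loc[diseases["cluster_id"] == cid, "log_aor"]
        if len(vals) < 2:
            excluded.append(cid)
            continue
        within[cid] = float(vals.max() - vals.min())
    if excluded:
        logger.warning(
            "clusters with <2 usable disease aORs excluded from the median: %s",
            excluded,
        )
    within_s = pd.Series(within, name="within_range", dtype=float)
    between = float(clusters["log_aor"].max() - clusters["log_aor"].min())
    median_within = float(within_s.median()) if len(within_s) else float("nan")
    return DispersionSummary(
        outcome=outcome,
        variant=variant,
        within_range=within_s,
        between_range=between,
        median_within_range=median_within,
        within_exceeds_between=bool(median_within > between),
        excluded_clusters=excluded,
    )
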