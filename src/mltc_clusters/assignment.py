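"""Cluster-to-person assignment strategies and their pattern summaries.

Seven strategies map a patient's set of LTCs to a per-cluster
representation:

* ``ge1`` / ``ge2`` / ``ge3`` — binary: cluster assigned if the patient
  has at least 1 / 2 / 3 diseases in it (any threshold m >= 1 works);
* ``modal`` — the single cluster holding the largest number of the
  patient's diseases, ties broken uniformly at random;
* ``majority`` — the cluster holding strictly more than half of the
  patient's diseases, if any;
* ``count`` — the number of the patient's diseases in each cluster;
* ``proportion`` — the proportion of the patient's diseases in each
  cluster (rows sum to 1).

All functions operate on a counts table (patients x clusters) produced by
:func:`cohort_cluster_counts`; rows are kept in patient_id order so the
modal tie-break consumes random draws reproducibly.
"""

from __future__ import annotations

import re

import numpy as np
import pandas as pd

from .types import (
    AssignmentResult,
    AssignmentSummary,
    ClusterMap,
    Cohort,
    ReferentialError,
)

_THRESHOLD_RE = re.compile(r"^ge(\d+)$")


def cluster_counts(diseases, cluster_map: ClusterMap) -> pd.Series:
    """Per-cluster disease counts for one patient's disease set.

    Returns a Series over all clusters (in map order); entries sum to the
    number of distinct diseases.
    """
    diseases = set(diseases)
    unknown = diseases - set(cluster_map.disease_ids)
    if unknown:
        raise ReferentialError(f"unknown diseases: {sorted(unknown)}")
    d2c = cluster_map.disease_to_cluster
    out = pd.Series(0, index=pd.Index(cluster_map.cluster_ids, name="cluster_id"))
    for d in diseases:
        out[d2c[d]] += 1
    return out


def cohort_cluster_counts(cohort: Cohort, cluster_map: ClusterMap) -> pd.DataFrame:
    """Patients x clusters table of disease counts, sorted by patient_id."""
    events = cohort.events
    unknown = set(events["disease_id"]) - set(cluster_map.disease_ids)
    if unknown:
        raise ReferentialError(f"unknown diseases in events: {sorted(unknown)[:5]}")
    cl = events["disease_id"].map(cluster_map.disease_to_cluster)
    counts = (
        pd.crosstab(events["patient_id"], cl)
        .reindex(columns=cluster_map.cluster_ids, fill_value=0)
        .sort_index()
    )
    counts.index.name = "patient_id"
    counts.columns.name = "cluster_id"
    return counts.astype(int)


def assign_threshold(counts: pd.DataFrame | pd.Series, m: int) -> pd.DataFrame | pd.Series:
    """Binary assignment: cluster c assigned iff the patient has >= m diseases in c."""
    if m < 1:
        raise ValueError("threshold m must be >= 1")
    return (counts >= m).astype(int)


def assign_majority(counts: pd.DataFrame | pd.Series) -> pd.DataFrame | pd.Series:
    """Cluster assigned iff it holds strictly more than 50% of the diseases.

    At most one cluster can qualify; a patient split exactly in half gets
    no assignment.
    """
    if isinstance(counts, pd.Series):
        return (counts / counts.sum() > 0.5).astype(int)
    total = counts.sum(axis=1)
    return counts.gt(total / 2.0, axis=0).astype(int)


def assign_proportion(counts: pd.DataFrame | pd.Series) -> pd.DataFrame | pd.Series:
    """Proportion of the patient's diseases in each cluster; rows sum to 1."""
    if isinstance(counts, pd.Series):
        return counts / counts.sum()
    return counts.div(counts.sum(axis=1), axis=0)


def assign_modal(
    counts: pd.DataFrame | pd.Series, rng: np.random.Generator
) -> tuple[pd.DataFrame | pd.Series, pd.Series | bool]:
    """One-hot assignment to a cluster holding the modal disease count.

    Ties (>= 2 clusters at the maximum) are broken uniformly at random;
    one draw is consumed per patient, in row (patient_id) order, so a
    fixed seed reproduces the assignment.  Returns (one_hot, tie_flag).
    """
    single = isinstance(counts, pd.Series)
    frame = counts.to_frame().T if single else counts
    arr = frame.to_numpy()
    max_val = arr.max(axis=1, keepdims=True)
    at_max = arr == max_val
    n_tied = at_max.sum(axis=1)
    r = rng.random(len(frame))
    pick = np.minimum((r * n_tied).astype(int), n_tied - 1)
    # column index of the (pick+1)-th cluster achieving the maximum
    winner = np.argmax(at_max.cumsum(axis=1) == (pick + 1)[:, None], axis=1)
    one_hot = np.zeros_like(arr, dtype=int)
    one_hot[np.arange(len(frame)), winner] = 1
    out = pd.DataFrame(one_hot, index=frame.index, columns=frame.columns)
    ties = pd.Series(n_tied >= 2, index=frame.index, name="modal_tie")
    if single:
        return out.iloc[0], bool(ties.iloc[0])
    return out, ties


def assign(
    counts: pd.DataFrame,
    strategy: str,
    rng: np.random.Generator | None = None,
) -> AssignmentResult:
    """Apply one named strategy to a counts table."""
    m = _THRESHOLD_RE.match(strategy)
    if m:
        return AssignmentResult(strategy, assign_threshold(counts, int(m.group(1))))
    if strategy == "majority":
        return AssignmentResult(strategy, assign_majority(counts))
    if strategy == "count":
        return AssignmentResult(strategy, counts.copy())
    if strategy == "proportion":
        return AssignmentResult(strategy, assign_proportion(counts))
    if strategy == "modal":
        if rng is None:
            raise ValueError("modal assignment needs a seeded rng for tie-breaks")
        values, ties = assign_modal(counts, rng)
        return AssignmentResult(strategy, values, ties)
    raise ValueError(f"unknown strategy: {strategy}")


def summarize_assignment(
    result: AssignmentResult, counts: pd.DataFrame
) -> AssignmentSummary:
    """Assignment-pattern metrics for one strategy.

    For ``count`` and ``proportion`` a cluster counts as assigned when its
    value is nonzero (which makes their pattern identical to ``ge1``).  A
    patient is *fully represented* when every one of their diseases lies
    in an assigned cluster; the unassigned-LTC count is the number of
    diseases left outside all assigned clusters.
    """
    if not result.values.index.equals(counts.index):
        raise ValueError("assignment and counts cover different patients")
    assigned = (result.values.to_numpy() != 0)
    n_assigned = assigned.sum(axis=1)
    total = counts.to_numpy().sum(axis=1)
    unassigned = total - np.where(assigned, counts.to_numpy(), 0).sum(axis=1)

    n = len(counts)
    pct = lambda mask: 100.0 * mask.sum() / n  # noqa: E731
    q25, q75 = np.percentile(unassigned, [25, 75])
    return AssignmentSummary(
        strategy=result.strategy,
        n_patients=n,
        pct_none=pct(n_assigned == 0),
        pct_one=pct(n_assigned == 1),
        pct_multi=pct(n_assigned > 1),
        pct_fully_represented=pct(unassigned == 0),
        median_unassigned_ltcs=float(np.median(unassigned)),
        iqr_unassigned_ltcs=(float(q25), float(q75)),
        pct_modal_ties=(
            pct(result.modal_tie.to_numpy()) if result.modal_tie is not None else None
        ),
    )


def summarize_all_strategies(
    counts: pd.DataFrame, seed: int, strategies=None
) -> pd.DataFrame:
    """One AssignmentSummary row per strategy (Table-2-style)."""
    from .types import STRATEGIES

    rows = []
    for strategy in strategies or STRATEGIES:
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 2]))
        res = assign(counts, strategy, rng=rng)
        rows.append(summarize_assignment(res, counts).to_dict())
    return pd.DataFrame(rows)
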