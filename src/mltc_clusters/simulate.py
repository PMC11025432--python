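"""Synthetic EHR-like cohort generator.

Emulates the statistical structure of a primary-care multimorbidity
cohort: adults (age ~ Normal(53, 18) truncated at 18) carrying two or
more of D=212 long-term conditions partitioned into K=15 clusters, a
right-skewed LTC count per patient (shifted negative binomial, median 8,
IQR 5-11), cluster-correlated disease co-occurrence driven by a
per-patient Dirichlet propensity over clusters, disease-specific onset-age
distributions, three binary 1-year outcomes (death, ED attendance,
emergency admission) generated from disease-level log-odds contributions
with controllable within-cluster heterogeneity, and ~4.9% censoring by
de-registration.

The generator keeps its ground truth (per-disease log-odds contributions
gamma_d = mu_c(d) + Normal(0, tau)) so that downstream model fits can be
checked against it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .types import OUTCOMES, ClusterMap, Cohort

logger = logging.getLogger(__name__)


def _default_baseline_logit() -> dict[str, float]:
    # logit(0.02), logit(0.18), logit(0.08): plausible 1-year risks for an
    # adult multimorbidity cohort before disease contributions.
    return {
        "death": -3.8918,
        "ed_attendance": -1.5163,
        "emergency_admission": -2.4423,
    }


def _default_covariate_effects() -> dict[str, dict]:
    # Log-odds per unit: age per year (centred at 53), female vs male,
    # IMD per decile (centred at 5.5), ethnicity vs white.
    return {
        "death": {
            "age": 0.08,
            "female": -0.15,
            "imd": 0.03,
            "ethnicity": {"south_asian": 0.05, "black": 0.05, "mixed": 0.0, "other": 0.0},
        },
        "ed_attendance": {
            "age": 0.005,
            "female": 0.05,
            "imd": 0.05,
            "ethnicity": {"south_asian": 0.1, "black": 0.1, "mixed": 0.05, "other": 0.0},
        },
        "emergency_admission": {
            "age": 0.02,
            "female": 0.0,
            "imd": 0.04,
            "ethnicity": {"south_asian": 0.05, "black": 0.05, "mixed": 0.0, "other": 0.0},
        },
    }


ETHNICITY_LEVELS = ("white", "south_asian", "black", "mixed", "other")
ETHNICITY_PROBS = (0.862, 0.060, 0.040, 0.020, 0.018)


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort generator.

    ``ltc_count_r``/``ltc_count_p`` parameterise the shifted negative
    binomial L = 2 + NB(r, p), calibrated to median 8 and IQR 5-11.
    ``dirichlet_alpha`` controls cluster co-occurrence: small alpha
    concentrates a patient's diseases in few clusters.
    ``heterogeneity_sd`` (tau) is the within-cluster SD of disease-level
    log-odds contributions around their cluster mean;
    ``cluster_effect_sd`` is the SD of the cluster means themselves.
    """

    n_patients: int = 20_000
    n_clusters: int = 15
    n_diseases: int = 212
    ltc_count_r: float = 3.0
    ltc_count_p: float = 0.3158
    dirichlet_alpha: float = 0.5
    dereg_prob: float = 0.049
    heterogeneity_sd: float = 0.5
    cluster_effect_sd: float = 0.3
    prevalence_log10_range: float = 2.0
    onset_median_range: tuple[float, float] = (25.0, 80.0)
    onset_spread_range: tuple[float, float] = (6.0, 14.0)
    age_mean: float = 53.0
    age_sd: float = 18.0
    female_prob: float = 0.531
    baseline_logit: dict[str, float] = field(default_factory=_default_baseline_logit)
    covariate_effects: dict[str, dict] = field(default_factory=_default_covariate_effects)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clusters < 1 or self.n_diseases < self.n_clusters:
            raise ValueError("need n_diseases >= n_clusters >= 1")
        if not 0.0 <= self.dereg_prob <= 1.0:
            raise ValueError("dereg_prob must lie in [0, 1]")
        if self.heterogeneity_sd < 0:
            raise ValueError("heterogeneity_sd must be nonnegative")


@dataclass
class DiseaseCatalog:
    """Ground-truth disease parameters behind a simulated cohort.

    ``diseases`` has one row per disease: cluster assignment, relative
    base prevalence weight, onset median/spread (years) and one
    ``gamma_<outcome>`` log-odds contribution per outcome.
    ``cluster_effects`` holds the per-cluster means mu_c those gammas were
    drawn around.
    """

    map: ClusterMap
    diseases: pd.DataFrame
    cluster_effects: pd.DataFrame
    heterogeneity_sd: float

    def gamma(self, outcome: str) -> pd.Series:
        return self.diseases.set_index("disease_id")[f"gamma_{outcome}"]


def make_catalog(config: SimConfig, seed: int | None = None) -> DiseaseCatalog:
    """Draw a disease catalog: partition, prevalence, onset and effects.

    Diseases are dealt round-robin over a randomly permuted order, so each
    cluster ends up with floor(D/K) or ceil(D/K) members and none is
    empty.  With ``heterogeneity_sd == 0`` every disease's gamma equals
    its cluster mean exactly.
    """
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0]))
    D, K = config.n_diseases, config.n_clusters

    disease_ids = [f"d{i + 1:03d}" for i in range(D)]
    cluster_ids = [f"c{j + 1:02d}" for j in range(K)]
    perm = rng.permutation(D)
    cluster_idx = np.empty(D, dtype=int)
    cluster_idx[perm] = np.arange(D) % K

    frame = pd.DataFrame(
        {
            "disease_id": disease_ids,
            "disease_name": [f"Disease {i + 1}" for i in range(D)],
            "cluster_id": [cluster_ids[c] for c in cluster_idx],
            "cluster_name": [f"Cluster {c + 1}" for c in cluster_idx],
        }
    )
    cmap = ClusterMap(frame)

    base_prevalence = 10.0 ** rng.uniform(0.0, config.prevalence_log10_range, D)
    onset_median = rng.uniform(*config.onset_median_range, D)
    onset_spread = rng.uniform(*config.onset_spread_range, D)

    diseases = frame[["disease_id", "cluster_id"]].copy()
    diseases["base_prevalence"] = base_prevalence
    diseases["onset_median"] = onset_median
    diseases["onset_spread"] = onset_spread

    mu = {}
    for outcome in OUTCOMES:
        mu_c = rng.normal(0.0, config.cluster_effect_sd, K)
        gamma = mu_c[cluster_idx] + rng.normal(0.0, config.heterogeneity_sd, D)
        diseases[f"gamma_{outcome}"] = gamma
        mu[outcome] = mu_c
    cluster_effects = pd.DataFrame(mu, index=pd.Index(cluster_ids, name="cluster_id"))

    return DiseaseCatalog(cmap, diseases, cluster_effects, config.heterogeneity_sd)


def _truncated_normal(
    rng: np.random.Generator,
    mean: np.ndarray,
    sd: np.ndarray,
    low,
    high,
    max_attempts: int = 1000,
) -> np.ndarray:
    """Elementwise Normal(mean, sd) truncated to (low, high].

    Rejection sampling, redrawing only the out-of-range entries; after
    ``max_attempts`` rounds any stragglers are clamped to the bounds.
    """
    x = rng.normal(mean, sd)
    low = np.broadcast_to(np.asarray(low, dtype=float), x.shape)
    high = np.broadcast_to(np.asarray(high, dtype=float), x.shape)
    bad = (x <= low) | (x > high)
    attempts = 0
    while bad.any() and attempts < max_attempts:
        idx = np.nonzero(bad)[0]
        x[idx] = rng.normal(np.asarray(mean)[idx] if np.ndim(mean) else mean,
                            np.asarray(sd)[idx] if np.ndim(sd) else sd)
        bad = (x <= low) | (x > high)
        attempts += 1
    if bad.any():
        span = np.where(np.isfinite(high), high - low, 1.0)
        x = np.clip(x, low + 1e-3 * np.maximum(span, 1e-3), high)
    return x


def simulate_cohort(catalog: DiseaseCatalog, config: SimConfig) -> Cohort:
    """Simulate a cohort of ``config.n_patients`` from the catalog.

    Per patient: demographics; an LTC count L >= 2; a Dirichlet(alpha)
    propensity over clusters; L distinct diseases sampled without
    replacement with weight base_prevalence(d) * pi(cluster(d)) (Gumbel
    top-k); an age at diagnosis per disease truncated to (0, age]; three
    Bernoulli outcomes from the logistic model; and a de-registration
    flag.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 1]))
    n, D, K = config.n_patients, config.n_diseases, config.n_clusters
    cat = catalog.diseases
    cluster_ids = catalog.map.cluster_ids
    cluster_pos = {c: j for j, c in enumerate(cluster_ids)}
    cluster_idx = cat["cluster_id"].map(cluster_pos).to_numpy()

    age = _truncated_normal(
        rng, np.full(n, config.age_mean), np.full(n, config.age_sd), 18.0, np.inf
    )
    age = np.round(age, 2)
    gender = np.where(rng.random(n) < config.female_prob, "female", "male")
    ethnicity = rng.choice(ETHNICITY_LEVELS, size=n, p=ETHNICITY_PROBS)
    # mild gradient towards less deprived areas (~52% in deciles 1-5)
    imd_probs = np.linspace(0.108, 0.092, 10)
    imd = rng.choice(np.arange(1, 11), size=n, p=imd_probs / imd_probs.sum())

    L = 2 + rng.negative_binomial(config.ltc_count_r, config.ltc_count_p, n)
    if (L > D).any():
        logger.warning("capping %d LTC counts at D=%d", int((L > D).sum()), D)
        L = np.minimum(L, D)

    pi = rng.dirichlet(np.full(K, config.dirichlet_alpha), n)
    log_w = np.log(cat["base_prevalence"].to_numpy())[None, :] + np.log(
        np.maximum(pi[:, cluster_idx], 1e-300)
    )
    # Gumbel top-k == weighted sampling without replacement
    keys = log_w + rng.gumbel(size=(n, D))
    order = np.argsort(-keys, axis=1)

    patient_idx = np.repeat(np.arange(n), L)
    disease_pos = np.concatenate([order[i, : L[i]] for i in range(n)])

    onset = _truncated_normal(
        rng,
        cat["onset_median"].to_numpy()[disease_pos],
        cat["onset_spread"].to_numpy()[disease_pos],
        0.0,
        age[patient_idx],
    )
    onset = np.minimum(np.maximum(np.round(onset, 2), 0.01), age[patient_idx])

    is_female = (gender == "female").astype(float)
    outcomes = {}
    for outcome in OUTCOMES:
        eff = config.covariate_effects[outcome]
        eth_eff = np.array([eff["ethnicity"].get(e, 0.0) for e in ethnicity])
        eta = (
            config.baseline_logit[outcome]
            + eff["age"] * (age - 53.0)
            + eff["female"] * is_female
            + eff["imd"] * (imd - 5.5)
            + eth_eff
        )
        gamma = cat[f"gamma_{outcome}"].to_numpy()
        np.add.at(eta, patient_idx, gamma[disease_pos])
        outcomes[outcome] = (rng.random(n) < expit(eta)).astype(int)

    deregistered = (rng.random(n) < config.dereg_prob).astype(int)

    patient_id = np.array([f"p{i + 1:07d}" for i in range(n)])
    patients = pd.DataFrame(
        {
            "patient_id": patient_id,
            "age_at_index": age,
            "gender": gender,
            "ethnicity": ethnicity,
            "imd_decile": imd,
            "deregistered": deregistered,
            **outcomes,
        }
    )
    events = pd.DataFrame(
        {
            "patient_id": patient_id[patient_idx],
            "disease_id": cat["disease_id"].to_numpy()[disease_pos],
            "age_at_diagnosis": onset,
        }
    )
    cohort = Cohort(patients, events)
    cohort.validate(catalog.map)
    return cohort


def simulate(config: SimConfig) -> tuple[DiseaseCatalog, Cohort]:
    """Draw a catalog and a cohort from one seed."""
    catalog = make_catalog(config)
    return catalog, simulate_cohort(catalog, config)


def apply_followup_exclusion(cohort: Cohort) -> Cohort:
    """Drop patients who de-registered during follow-up.

    Mirrors the equal-follow-up rule: outcomes are only comparable for
    patients observed for the whole year.
    """
    keep = cohort.patients["deregistered"] == 0
    n_excluded = int((~keep).sum())
    logger.info(
        "excluded %d (%.1f%%) de-registered patients",
        n_excluded,
        100.0 * n_excluded / max(len(keep), 1),
    )
    patients = cohort.patients[keep].reset_index(drop=True)
    events = cohort.events[
        cohort.events["patient_id"].isin(set(patients["patient_id"]))
    ].reset_index(drop=True)
    return Cohort(patients, events, cohort.index_date_label)


def write_simulation(
    catalog: DiseaseCatalog, cohort: Cohort, out_dir: str | Path
) -> dict[str, Path]:
    """Write cluster_map.csv, patients.csv, events.csv and catalog_truth.csv."""
    from .io import write_cluster_map, write_cohort

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = write_cohort(cohort, out_dir)
    paths["cluster_map"] = out_dir / "cluster_map.csv"
    write_cluster_map(catalog.map, paths["cluster_map"])
    paths["catalog_truth"] = out_dir / "catalog_truth.csv"
    catalog.diseases.to_csv(paths["catalog_truth"], index=False)
    return paths
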