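"""Logistic-regression fitting and AIC comparison of assignment strategies.

For each outcome, every assignment strategy supplies an exposure block
(15 per-cluster variables: binary for ge1/ge2/ge3/modal/majority,
continuous for count and proportion), and a disease-level reference model
uses the 212 individual diseases as binary predictors.  All models adjust
for age (linear), gender, ethnicity and IMD decile, are fitted on the
identical patient set, and are compared by AIC = 2k - 2*lnL.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .assignment import assign, cohort_cluster_counts
from .simulate import ETHNICITY_LEVELS
from .types import (
    OUTCOMES,
    STRATEGIES,
    AssignmentResult,
    ClusterMap,
    Cohort,
    DesignMatrix,
    ModelFit,
)

logger = logging.getLogger(__name__)

#: |coefficient| beyond which a column is flagged as (quasi-)separated.
SEPARATION_BETA = 15.0


def disease_indicators(cohort: Cohort, cluster_map: ClusterMap) -> pd.DataFrame:
    """Patients x diseases 0/1 indicator table, sorted by patient_id."""
    ind = (
        pd.crosstab(cohort.events["patient_id"], cohort.events["disease_id"])
        .clip(upper=1)
        .reindex(columns=cluster_map.disease_ids, fill_value=0)
        .sort_index()
    )
    ind.index.name = "patient_id"
    return ind.astype(int)


def _covariate_block(patients: pd.DataFrame, imd_categorical: bool = True) -> pd.DataFrame:
    """Age, gender, ethnicity and IMD covariates, indexed by patient_id.

    References: gender = male, ethnicity = most frequent level, IMD =
    decile 1 (when categorical).
    """
    p = patients.set_index("patient_id").sort_index()
    cov = pd.DataFrame(index=p.index)
    cov["age"] = p["age_at_index"].astype(float)
    cov["gender_female"] = (p["gender"] == "female").astype(float)
    ref = p["ethnicity"].value_counts().idxmax()
    levels = [e for e in ETHNICITY_LEVELS if e != ref]
    levels += sorted(set(p["ethnicity"].unique()) - set(ETHNICITY_LEVELS) - {ref})
    for lev in levels:
        col = (p["ethnicity"] == lev).astype(float)
        cov[f"ethnicity_{lev}"] = col
    if imd_categorical:
        for dec in range(2, 11):
            cov[f"imd_{dec}"] = (p["imd_decile"] == dec).astype(float)
    else:
        cov["imd_decile"] = p["imd_decile"].astype(float)
    return cov


def build_design(
    cohort: Cohort,
    representation: AssignmentResult | str,
    cluster_map: ClusterMap,
    imd_categorical: bool = True,
    counts: pd.DataFrame | None = None,
) -> DesignMatrix:
    """Assemble intercept + exposure block + covariates for one model.

    ``representation`` is an AssignmentResult, or the string ``"diseases"``
    for the 212-indicator reference model.  Zero-variance columns are
    dropped and recorded; patient ordering (sorted patient_id) is
    identical across representations.
    """
    if isinstance(representation, str):
        if representation != "diseases":
            raise ValueError(f"unknown representation: {representation}")
        exposure = disease_indicators(cohort, cluster_map).astype(float)
        exposure.columns = [f"disease_{c}" for c in exposure.columns]
    else:
        exposure = representation.values.sort_index().astype(float)
        exposure.columns = [f"cluster_{c}" for c in exposure.columns]

    cov = _covariate_block(cohort.patients, imd_categorical)
    if not exposure.index.equals(cov.index):
        raise ValueError("exposure and covariate tables cover different patients")

    X = pd.concat([exposure, cov], axis=1)
    X.insert(0, "intercept", 1.0)
    variances = X.to_numpy().var(axis=0)
    keep = (variances > 0) | (np.arange(X.shape[1]) == 0)
    dropped = [c for c, k in zip(X.columns, keep) if not k]
    if dropped:
        logger.info("dropping %d zero-variance columns: %s", len(dropped), dropped[:5])
    X = X.loc[:, keep]
    exposure_cols = [c for c in exposure.columns if c in X.columns]
    return DesignMatrix(X=X, exposure_columns=exposure_cols, dropped_columns=dropped)


def fit_logistic(design: DesignMatrix, outcome: pd.Series | np.ndarray) -> ModelFit:
    """Maximum-likelihood logistic fit (IRLS/Newton, BFGS fallback).

    Standard errors come from the inverse observed information.
    Non-convergence is reported, not raised; coefficients with
    |beta| > 15 are flagged as separated.
    """
    y = np.asarray(outcome, dtype=float)
    if y.shape[0] != len(design.X):
        raise ValueError("outcome length does not match design rows")
    if y.min() == y.max():
        raise ValueError("outcome has a single class; model is undefined")

    model = sm.Logit(y, design.X.to_numpy())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(method="newton", maxiter=100, disp=0, tol=1e-8)
        except Exception:  # singular Hessian / separation: quasi-Newton fallback
            res = model.fit(method="bfgs", maxiter=500, disp=0)

    converged = bool(res.mle_retvals.get("converged", False))
    if not converged:
        logger.warning("logistic fit did not converge after %s iterations",
                       res.mle_retvals.get("iterations"))
    params = pd.Series(res.params, index=design.column_names)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        bse = pd.Series(np.asarray(res.bse), index=design.column_names)
    k = design.k
    llf = float(res.llf)
    return ModelFit(
        coefficients=params,
        standard_errors=bse,
        loglik=llf,
        k=k,
        aic=aic_from(llf, k),
        converged=converged,
        n_iterations=int(res.mle_retvals.get("iterations", -1)),
        n_obs=len(y),
        separation_flags=params.abs() > SEPARATION_BETA,
        exposure_columns=design.exposure_columns,
        dropped_columns=design.dropped_columns,
    )


def aic_from(loglik: float, k: int) -> float:
    """Akaike information criterion, 2k - 2*lnL."""
    return 2.0 * k - 2.0 * loglik


def aic(fit: ModelFit) -> float:
    return aic_from(fit.loglik, fit.k)


REPRESENTATIONS = STRATEGIES + ("diseases",)


def compare_strategies(
    cohort: Cohort,
    cluster_map: ClusterMap,
    seed: int = 0,
    outcomes=OUTCOMES,
    representations=REPRESENTATIONS,
    imd_categorical: bool = True,
) -> tuple[pd.DataFrame, dict[tuple[str, str], ModelFit]]:
    """Fit every representation x outcome on one patient set; compare AIC.

    The cohort must already have follow-up exclusion applied.  Returns
    (table, fits): the table has one row per (outcome, representation)
    with n, k, aic, convergence, plus per-outcome flags for the
    best cluster strategy and whether the disease model beats all of
    them.
    """
    counts = cohort_cluster_counts(cohort, cluster_map)
    y_all = cohort.patients.set_index("patient_id").sort_index()

    designs: dict[str, DesignMatrix] = {}
    for rep in representations:
        if rep == "diseases":
            designs[rep] = build_design(cohort, "diseases", cluster_map, imd_categorical)
        else:
            rng = np.random.default_rng(np.random.SeedSequence([int(seed), 2]))
            res = assign(counts, rep, rng=rng)
            designs[rep] = build_design(cohort, res, cluster_map, imd_categorical)

    rows = []
    fits: dict[tuple[str, str], ModelFit] = {}
    for outcome in outcomes:
        y = y_all[outcome]
        for rep in representations:
            fit = fit_logistic(designs[rep], y)
            fits[(outcome, rep)] = fit
            rows.append(
                {
                    "outcome": outcome,
                    "representation": rep,
                    "n": fit.n_obs,
                    "k": fit.k,
                    "loglik": fit.loglik,
                    "aic": fit.aic,
                    "converged": fit.converged,
                }
            )
    table = pd.DataFrame(rows)

    cluster_reps = [r for r in representations if r != "diseases"]
    best, beats = {}, {}
    for outcome in outcomes:
        sub = table[table["outcome"] == outcome].set_index("representation")
        if cluster_reps:
            best[outcome] = sub.loc[cluster_reps, "aic"].idxmin()
        if "diseases" in sub.index and cluster_reps:
            beats[outcome] = bool(
                sub.loc["diseases", "aic"] < sub.loc[cluster_reps, "aic"].min()
            )
    table["best_cluster_strategy"] = table["outcome"].map(best)
    table["diseases_beats_all"] = table["outcome"].map(beats)
    return table, fits


def coefficient_table(fit: ModelFit) -> pd.DataFrame:
    """Per-term estimates with Wald 95% CIs on the odds-ratio scale."""
    z = 1.959963984540054
    beta, se = fit.coefficients, fit.standard_errors
    from scipy.stats import norm

    pvals = 2 * norm.sf(np.abs(beta / se))
    with np.errstate(over="ignore"):
        return pd.DataFrame(
            {
                "term": beta.index,
                "beta": beta.to_numpy(),
                "se": se.to_numpy(),
                "odds_ratio": np.exp(beta.to_numpy()),
                "ci_low": np.exp(beta.to_numpy() - z * se.to_numpy()),
                "ci_high": np.exp(beta.to_numpy() + z * se.to_numpy()),
                "p_value": pvals,
            }
        )
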