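"""Logistic fits: closed-form oracles, AIC identity, design building."""

import numpy as np
import pandas as pd
import pytest

import mltc_clusters as m
from mltc_clusters.types import DesignMatrix


def design_from(X: pd.DataFrame, exposure_columns=None) -> DesignMatrix:
    return DesignMatrix(X=X, exposure_columns=exposure_columns or [])


def intercept_design(n: int) -> DesignMatrix:
    X = pd.DataFrame({"intercept": np.ones(n)})
    return design_from(X)


class TestFitLogistic:
    def test_intercept_only_equals_logit_of_prevalence(self):
        y = np.r_[np.ones(25), np.zeros(75)]
        fit = m.fit_logistic(intercept_design(100), y)
        assert fit.coefficients["intercept"] == pytest.approx(np.log(25 / 75), abs=1e-4)
        assert fit.converged

    def test_binary_exposure_recovers_2x2_log_odds_ratio(self):
        # exposed: 30 events / 70 non-events; unexposed: 10 / 90
        y = np.r_[np.ones(30), np.zeros(70), np.ones(10), np.zeros(90)]
        x = np.r_[np.ones(100), np.zeros(100)]
        X = pd.DataFrame({"intercept": 1.0, "exposed": x})
        fit = m.fit_logistic(design_from(X, ["exposed"]), y)
        expected = np.log((30 * 90) / (70 * 10))
        assert fit.coefficients["exposed"] == pytest.approx(expected, abs=1e-4)
        assert fit.coefficients["intercept"] == pytest.approx(np.log(10 / 90), abs=1e-4)

    def test_matches_brute_force_loglik_grid(self):
        """One-parameter model vs a grid search over beta in [-5, 5]."""
        rng = np.random.default_rng(4)
        x = rng.normal(size=400)
        y = (rng.random(400) < 1 / (1 + np.exp(-(0.7 * x)))).astype(float)
        X = pd.DataFrame({"x": x})
        fit = m.fit_logistic(design_from(X, ["x"]), y)
        grid = np.arange(-5, 5, 1e-3)
        eta = np.outer(grid, x)
        lnl = (y * eta - np.log1p(np.exp(eta))).sum(axis=1)
        beta_grid = grid[np.argmax(lnl)]
        assert fit.coefficients["x"] == pytest.approx(beta_grid, abs=2e-3)
        # the true MLE can only beat the grid argmax, and only just
        assert lnl.max() - 1e-9 <= fit.loglik <= lnl.max() + 1e-4

    def test_loglik_nonpositive_and_aic_identity(self, small_sim):
        _, catalog, cohort = small_sim
        counts = m.cohort_cluster_counts(cohort, catalog.map)
        design = m.build_design(cohort, m.assign(counts, "count"), catalog.map)
        fit = m.fit_logistic(design, cohort.patients.set_index("patient_id").sort_index()["death"])
        assert fit.loglik <= 0
        assert fit.aic == 2 * fit.k - 2 * fit.loglik
        assert fit.k == design.X.shape[1]

    def test_single_class_outcome_rejected(self):
        with pytest.raises(ValueError):
            m.fit_logistic(intercept_design(10), np.zeros(10))

    def test_separation_flagged_not_fatal(self):
        y = np.r_[np.ones(20), np.zeros(20)]
        x = y.copy()  # perfectly separating covariate
        X = pd.DataFrame({"intercept": 1.0, "x": x})
        fit = m.fit_logistic(design_from(X, ["x"]), y)
        assert fit.separation_flags["x"]


class TestAic:
    def test_formula(self):
        assert m.aic_from(-10.0, 1) == 22.0

    def test_intercept_only_closed_form(self):
        y = np.r_[np.ones(50), np.zeros(50)]
        fit = m.fit_logistic(intercept_design(100), y)
        assert fit.loglik == pytest.approx(100 * np.log(0.5), abs=1e-6)
        assert fit.aic == pytest.approx(2 - 200 * np.log(0.5), abs=1e-3)

    def test_fewer_parameters_win_at_equal_loglik(self):
        assert m.aic_from(-100.0, 4) < m.aic_from(-100.0, 5)


class TestBuildDesign:
    def test_count_exposures_pass_through(self, small_sim, small_counts):
        _, catalog, cohort = small_sim
        design = m.build_design(cohort, m.assign(small_counts, "count"), catalog.map)
        for c in small_counts.columns:
            if f"cluster_{c}" in design.X:
                assert (design.X[f"cluster_{c}"].to_numpy() == small_counts[c].to_numpy()).all()

    def test_zero_variance_exposure_dropped(self, toy_map):
        patients = pd.DataFrame(
            {
                "patient_id": ["p1", "p2", "p3", "p4"],
                "age_at_index": [50.0, 60.0, 70.0, 55.0],
                "gender": ["female", "male", "female", "male"],
                "ethnicity": ["white", "white", "black", "white"],
                "imd_decile": [1, 2, 3, 4],
                "deregistered": [0, 0, 0, 0],
                "death": [0, 1, 0, 1],
                "ed_attendance": [0, 0, 1, 1],
                "emergency_admission": [0, 0, 0, 1],
            }
        )
        events = pd.DataFrame(
            {
                "patient_id": ["p1", "p1", "p2", "p2", "p3", "p3", "p4", "p4"],
                "disease_id": ["d1", "d2", "d1", "d3", "d2", "d3", "d1", "d4"],
                "age_at_diagnosis": [30] * 8,
            }
        )
        cohort = m.Cohort(patients, events)
        counts = m.cohort_cluster_counts(cohort, toy_map)
        # nobody has any alcohol_liver disease -> majority column is constant 0
        design = m.build_design(cohort, m.assign(counts, "majority"), toy_map)
        assert "cluster_alcohol_liver" in design.dropped_columns
        assert "cluster_alcohol_liver" not in design.X.columns

    def test_ge1_and_count_share_nonzero_pattern(self, small_sim, small_counts):
        _, catalog, cohort = small_sim
        d1 = m.build_design(cohort, m.assign(small_counts, "ge1"), catalog.map)
        d2 = m.build_design(cohort, m.assign(small_counts, "count"), catalog.map)
        a = d1.X[d1.exposure_columns].to_numpy() != 0
        b = d2.X[d2.exposure_columns].to_numpy() != 0
        assert (a == b).all()

    def test_disease_indicators_binary(self, small_sim):
        _, catalog, cohort = small_sim
        ind = m.disease_indicators(cohort, catalog.map)
        assert set(np.unique(ind.to_numpy())) <= {0, 1}
        assert ind.shape[1] == catalog.map.n_diseases


@pytest.fixture(scope="module")
def comparison(small_sim):
    _, catalog, cohort = small_sim
    cohort = m.apply_followup_exclusion(cohort)
    return m.compare_strategies(cohort, catalog.map, seed=7)


class TestCompareStrategies:
    def test_all_cells_share_one_patient_set(self, comparison):
        table, _ = comparison
        assert table["n"].nunique() == 1
        assert len(table) == 3 * 8

    def test_aic_identity_every_fit(self, comparison):
        table, fits = comparison
        for fit in fits.values():
            assert fit.aic == 2 * fit.k - 2 * fit.loglik

    def test_adding_a_column_never_hurts_loglik(self, small_sim):
        _, catalog, cohort = small_sim
        counts = m.cohort_cluster_counts(cohort, catalog.map)
        y = cohort.patients.set_index("patient_id").sort_index()["death"]
        full = m.build_design(cohort, m.assign(counts, "count"), catalog.map)
        reduced = DesignMatrix(
            X=full.X.drop(columns=full.exposure_columns[:1]),
            exposure_columns=full.exposure_columns[1:],
        )
        assert (
            m.fit_logistic(full, y).loglik
            >= m.fit_logistic(reduced, y).loglik - 1e-6
        )

    def test_identical_designs_give_identical_aic(self, toy_map):
        """If no patient has 2+ diseases in any one cluster, ge1 and count
        designs coincide, and so must their AICs."""
        rng = np.random.default_rng(0)
        n = 60
        patients = pd.DataFrame(
            {
                "patient_id": [f"p{i:02d}" for i in range(n)],
                "age_at_index": rng.uniform(40, 80, n).round(1),
                "gender": rng.choice(["female", "male"], n),
                "ethnicity": rng.choice(["white", "black"], n),
                "imd_decile": rng.integers(1, 11, n),
                "deregistered": 0,
                "death": rng.integers(0, 2, n),
                "ed_attendance": rng.integers(0, 2, n),
                "emergency_admission": rng.integers(0, 2, n),
            }
        )
        # exactly one disease from each of two different clusters
        ev = []
        for i in range(n):
            ev.append((f"p{i:02d}", "d1", 30.0))  # metabolic
            ev.append((f"p{i:02d}", rng.choice(["d5", "d7"]), 35.0))  # varies by cluster
        events = pd.DataFrame(ev, columns=["patient_id", "disease_id", "age_at_diagnosis"])
        cohort = m.Cohort(patients, events)
        table, _ = m.compare_strategies(
            cohort, toy_map, seed=1, outcomes=("death",),
            representations=("ge1", "count"),
        )
        aics = table.set_index("representation")["aic"]
        assert aics["ge1"] == pytest.approx(aics["count"], abs=1e-6)

    def test_best_strategy_flags_consistent(self, comparison):
        table, _ = comparison
        for outcome, sub in table.groupby("outcome"):
            sub = sub.set_index("representation")
            clusters = sub.drop(index="diseases")
            assert sub["best_cluster_strategy"].iloc[0] == clusters["aic"].idxmin()
            assert sub["diseases_beats_all"].iloc[0] == (
                sub.loc["diseases", "aic"] < clusters["aic"].min()
            )


class TestCoefficientTable:
    def test_or_and_ci_arithmetic(self, small_sim, small_counts):
        _, catalog, cohort = small_sim
        design = m.build_design(cohort, m.assign(small_counts, "count"), catalog.map)
        y = cohort.patients.set_index("patient_id").sort_index()["ed_attendance"]
        fit = m.fit_logistic(design, y)
        tab = m.coefficient_table(fit).set_index("term")
        row = tab.loc[fit.exposure_columns[0]]
        beta = fit.coefficients[fit.exposure_columns[0]]
        se = fit.standard_errors[fit.exposure_columns[0]]
        assert row["odds_ratio"] == pytest.approx(np.exp(beta), rel=1e-9)
        assert row["ci_low"] == pytest.approx(np.exp(beta - 1.96 * se), rel=1e-3)
        assert row["ci_high"] == pytest.approx(np.exp(beta + 1.96 * se), rel=1e-3)
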