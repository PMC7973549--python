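"""Exposure derivation and the adverse-event association analysis."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from oxcpk.estimate import FitConfig, fit
from oxcpk.exposure import (
    derive_exposure,
    fisher_exact_2x2,
    group_compare,
    logistic_adjusted,
    mann_whitney,
    roc_youden,
)
from oxcpk.model import (
    PopulationParameters,
    Regimen,
    conc_steady_state,
    individual_params,
)
from oxcpk.simulate import CohortConfig, generate

from conftest import make_dataset
from oracles import logistic_mle_direct, roc_youden_bruteforce


class TestGroupCompare:
    # printed 2x2 tables of the study cohort (EIASM/sex vs DRAE/dizziness)
    @pytest.mark.parametrize("table, expected", [
        ([[2, 26], [21, 398]], 0.648),
        ([[0, 18], [23, 406]], 0.614),
        ([[14, 14], [250, 169]], 0.327),
        ([[10, 8], [254, 175]], 0.809),
    ])
    def test_fisher_exact_reproduces_published_p_values(self, table, expected):
        assert fisher_exact_2x2(table) == pytest.approx(expected, abs=5e-4)

    def test_degenerate_margin_gives_p_one(self):
        with pytest.warns(UserWarning, match="degenerate"):
            assert fisher_exact_2x2([[0, 0], [10, 20]]) == 1.0

    def test_identical_groups_mann_whitney_p_near_one(self):
        x = np.arange(30.0)
        assert mann_whitney(x, x) > 0.9

    def test_dispatcher_routes_binary_to_fisher(self):
        values = np.array([1, 0, 1, 0, 0, 0, 1, 0])
        groups = np.array([1, 1, 1, 1, 0, 0, 0, 0], dtype=bool)
        want = fisher_exact_2x2([[2, 2], [1, 3]])
        assert group_compare(values, groups) == pytest.approx(want)

    def test_dispatcher_routes_continuous_to_mannwhitney(self):
        rng = np.random.default_rng(0)
        values = rng.normal(size=40)
        groups = np.arange(40) < 20
        want = mann_whitney(values[groups], values[~groups])
        assert group_compare(values, groups) == pytest.approx(want)


class TestROC:
    def test_perfect_separation(self):
        res = roc_youden([1.0, 2.0, 3.0, 10.0, 11.0, 12.0],
                         [0, 0, 0, 1, 1, 1])
        assert res.sens_at_cutoff == 1.0 and res.spec_at_cutoff == 1.0
        assert res.auc_roc == pytest.approx(1.0)
        assert 3.0 < res.cutoff < 10.0

    def test_matches_bruteforce_oracle_on_random_instances(self):
        rng = np.random.default_rng(12)
        for _ in range(200):
            n = rng.integers(8, 40)
            labels = rng.integers(0, 2, size=n)
            if labels.sum() in (0, n):
                continue
            values = np.round(rng.normal(size=n) + labels * rng.uniform(0, 2), 2)
            res = roc_youden(values, labels)
            thr, j, (sens, spec) = roc_youden_bruteforce(values, labels)
            assert res.youden.max() == pytest.approx(j, abs=1e-12)
            assert res.cutoff == thr
            assert res.sens_at_cutoff == pytest.approx(sens)
            assert res.spec_at_cutoff == pytest.approx(spec)

    def test_label_inversion_mirrors_roc_area(self):
        rng = np.random.default_rng(5)
        values = rng.normal(size=60)
        labels = rng.integers(0, 2, size=60)
        a = roc_youden(values, labels).auc_roc
        b = roc_youden(values, 1 - labels).auc_roc
        assert a + b == pytest.approx(1.0, abs=1e-12)

    def test_single_class_is_an_error(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_youden([1.0, 2.0], [1, 1])


class TestLogistic:
    def test_coefficients_match_direct_likelihood_maximization(self):
        rng = np.random.default_rng(3)
        n = 400
        x = rng.normal(10.0, 4.0, n)
        sex = rng.integers(0, 2, n)
        age = rng.normal(40.0, 10.0, n)
        gfr = rng.normal(100.0, 15.0, n)
        p = expit(-3.0 + 0.15 * x + 0.3 * sex)
        y = rng.random(n) < p
        res = logistic_adjusted(y, x, sex, age, gfr, exposure_name="x")
        X = np.column_stack([np.ones(n), x, sex, age, gfr])
        beta = logistic_mle_direct(X, y.astype(float))
        assert np.log(res.odds_ratio("x")) == pytest.approx(beta[1], abs=1e-6)
        assert np.log(res.odds_ratio("sex")) == pytest.approx(beta[2], abs=1e-6)

    def test_simulation_recovery_of_exposure_slope(self):
        # logit p = -3 + 0.08 x, OR per unit ~ e^0.08 ~ 1.083
        rng = np.random.default_rng(8)
        n = 2000
        x = rng.normal(15.0, 8.0, n)
        y = rng.random(n) < expit(-3.0 + 0.08 * x)
        res = logistic_adjusted(y, x, rng.integers(0, 2, n),
                                rng.normal(40, 10, n), rng.normal(100, 15, n),
                                exposure_name="trough")
        beta = np.log(res.odds_ratio("trough"))
        row = res.table.set_index("covariate").loc["trough"]
        se = (np.log(row["hi"]) - np.log(row["lo"])) / (2 * 1.96)
        assert abs(beta - 0.08) < 2 * se
        assert res.odds_ratio("trough") == pytest.approx(1.083, abs=0.05)

    def test_wald_ci_coverage_near_nominal(self):
        rng = np.random.default_rng(21)
        n, hits, reps = 400, 0, 200
        for _ in range(reps):
            x = rng.normal(0.0, 1.0, n)
            y = rng.random(n) < expit(-1.0 + 0.5 * x)
            res = logistic_adjusted(y, x, rng.integers(0, 2, n),
                                    rng.normal(0, 1, n), rng.normal(0, 1, n),
                                    exposure_name="x")
            row = res.table.set_index("covariate").loc["x"]
            hits += row["lo"] <= np.exp(0.5) <= row["hi"]
        assert 0.90 <= hits / reps <= 0.99

    def test_constant_exposure_dropped_with_warning(self):
        rng = np.random.default_rng(2)
        n = 100
        y = rng.integers(0, 2, n)
        with pytest.warns(UserWarning, match="constant"):
            res = logistic_adjusted(y, np.full(n, 3.0), rng.integers(0, 2, n),
                                    rng.normal(40, 10, n), rng.normal(100, 15, n))
        assert "exposure" not in set(res.table["covariate"])

    def test_all_event_outcome_is_an_error(self):
        with pytest.raises(ValueError):
            logistic_adjusted(np.ones(10), np.arange(10), np.zeros(10),
                              np.arange(10), np.arange(10))


@pytest.fixture(scope="module")
def fitted_cohort():
    cohort = generate(CohortConfig(n_sparse=30, n_rich=4, seed=29))
    init = PopulationParameters(theta1_cl=2.0, theta3_v=45.0, ka=0.45,
                                omega2_cl=0.06, omega2_v=0.1,
                                sigma_prop=0.18)
    res = fit(cohort.dataset, FitConfig(init=init, n_starts=1))
    return cohort, res


class TestDeriveExposure:
    def test_auc_is_daily_dose_over_individual_clearance(self, fitted_cohort):
        cohort, res = fitted_cohort
        with pytest.warns(UserWarning, match="skipped"):
            table = derive_exposure(cohort.dataset, res)
        np.testing.assert_allclose(table["auc"],
                                   table["daily_dose"] / table["cl_i"],
                                   rtol=1e-12)
        # only steady-state subjects exposed; the rich arm is skipped
        assert len(table) == 30

    def test_typical_subject_auc(self, ref_pop):
        # eta=0 subject at reference weight on 999 mg/day: AUC = 999/1.65
        ds = make_dataset([
            {"id": 1, "dose": 499.5, "tau": 12.0, "times": [6.0], "dvs": [25.0]},
        ])
        from oxcpk.estimate import FitResult
        res = FitResult(
            estimates=ref_pop, ofv=0.0, se={}, rse={},
            ebes=pd.DataFrame({"ID": [1], "ETA_CL": [0.0], "ETA_V": [0.0]}),
            converged=True, n_subjects=1, n_obs=1,
        )
        table = derive_exposure(ds, res)
        assert table["auc"].iloc[0] == pytest.approx(999.0 / 1.65, rel=1e-12)
        assert table["auc"].iloc[0] == pytest.approx(605.5, abs=0.1)

    def test_trough_equals_steady_state_at_interval(self, ref_pop):
        ds = make_dataset([
            {"id": 1, "dose": 500.0, "tau": 12.0, "times": [6.0], "dvs": [25.0]},
        ])
        from oxcpk.estimate import FitResult
        eta_cl, eta_v = 0.2, -0.1
        res = FitResult(
            estimates=ref_pop, ofv=0.0, se={}, rse={},
            ebes=pd.DataFrame({"ID": [1], "ETA_CL": [eta_cl], "ETA_V": [eta_v]}),
            converged=True, n_subjects=1, n_obs=1,
        )
        table = derive_exposure(ds, res)
        ind = individual_params(ref_pop, eta_cl, eta_v, wt=66.0)
        want = conc_steady_state(ind, Regimen(500.0, 12.0), 12.0)
        assert table["trough"].iloc[0] == pytest.approx(want, rel=1e-12)

    def test_doubling_clearance_halves_auc(self, ref_pop):
        ds = make_dataset([
            {"id": 1, "dose": 500.0, "tau": 12.0, "times": [6.0], "dvs": [25.0]},
            {"id": 2, "dose": 500.0, "tau": 12.0, "times": [6.0], "dvs": [25.0]},
        ])
        from oxcpk.estimate import FitResult
        res = FitResult(
            estimates=ref_pop, ofv=0.0, se={}, rse={},
            ebes=pd.DataFrame({"ID": [1, 2], "ETA_CL": [0.0, np.log(2.0)],
                               "ETA_V": [0.0, 0.0]}),
            converged=True, n_subjects=2, n_obs=2,
        )
        table = derive_exposure(ds, res)
        assert table["auc"].iloc[1] == pytest.approx(table["auc"].iloc[0] / 2,
                                                     rel=1e-12)
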