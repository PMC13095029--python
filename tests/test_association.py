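"""Mixed-model fitting: design construction, estimation, inference."""

import warnings

import numpy as np
import pandas as pd
import pytest

from kirhla import (MODELS, SimulationConfig, build_design, derive_pairs,
                    fit_mixed_model, inject_imputation_error, run_all_models,
                    simulate_cohort)
from kirhla.association import model_spec
from kirhla.errors import DegenerateDesignError, FitError
from kirhla.lmm import fit_random_intercept
from kirhla.power import _SIM_COVARIATES, simulate_and_fit


def _derived(cfg):
    pairs, truth = simulate_cohort(cfg)
    hla, kir = inject_imputation_error(truth, 1.0, 1.0, seed=cfg.seed + 1)
    derived, _ = derive_pairs(pairs, hla, kir)
    return pairs, derived


class TestRandomInterceptSolver:
    def test_matches_statsmodels_mixedlm(self):
        """The profiled-REML solver agrees with statsmodels MixedLM."""
        from statsmodels.regression.mixed_linear_model import MixedLM

        rng = np.random.default_rng(3)
        n = 600
        gid = np.repeat(np.arange(450), rng.permutation([1] * 300 + [2] * 150))[:n]
        X = np.column_stack([np.ones(n), rng.standard_normal((n, 3)),
                             rng.integers(0, 2, n)])
        u = rng.standard_normal(gid.max() + 1) * 150
        y = X @ rng.uniform(-50, 50, 5) + u[gid] + rng.standard_normal(n) * 400
        ours = fit_random_intercept(y, X, gid)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ref = MixedLM(y, X, groups=gid).fit(reml=True)
        np.testing.assert_allclose(ours.params, ref.fe_params, rtol=5e-4)
        np.testing.assert_allclose(ours.bse, ref.bse_fe, rtol=5e-3)
        assert ours.tau2 == pytest.approx(float(np.asarray(ref.cov_re)[0, 0]), rel=0.02)
        assert ours.sigma2 == pytest.approx(float(ref.scale), rel=0.01)

    def test_singleton_groups_reduce_to_ols(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(4)
        n = 200
        X = np.column_stack([np.ones(n), rng.standard_normal((n, 2))])
        y = X @ np.array([3.0, -1.0, 0.5]) + rng.standard_normal(n)
        ours = fit_random_intercept(y, X, np.arange(n))
        ols = sm.OLS(y, X).fit()
        np.testing.assert_allclose(ours.params, ols.params, rtol=1e-10)
        np.testing.assert_allclose(ours.bse, ols.bse, rtol=1e-10)

    def test_zero_variance_boundary_allowed(self):
        rng = np.random.default_rng(5)
        n = 300
        gid = np.repeat(np.arange(150), 2)
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        y = X @ np.array([1.0, 2.0]) + rng.standard_normal(n)  # no group effect
        fit = fit_random_intercept(y, X, gid)
        assert fit.tau2 >= 0.0 and fit.tau2 < 0.5


class TestBuildDesign:
    def test_ambiguous_pairs_dropped_from_paternal_models(self):
        pairs, derived = _derived(SimulationConfig(n_pairs=800, seed=21))
        n_amb = int(derived["po_ambiguous"].sum())
        assert n_amb > 0
        design, audit = build_design(derived, pairs, model_spec(5, _SIM_COVARIATES))
        assert (audit["reason"] == "PO_AMBIGUOUS").sum() == n_amb
        assert len(design) == len(derived) - n_amb
        # models 1-4 keep those pairs
        design2, audit2 = build_design(derived, pairs, model_spec(1, _SIM_COVARIATES))
        assert len(design2) == len(derived) and len(audit2) == 0

    def test_constant_maternal_term_is_degenerate(self):
        pairs, derived = _derived(SimulationConfig(n_pairs=300, seed=22))
        derived = derived.assign(kir_b_dosage=0.0)  # every mother KIR AA
        with pytest.raises(DegenerateDesignError, match="maternal"):
            build_design(derived, pairs, model_spec(1, _SIM_COVARIATES))

    def test_constant_covariate_pruned_not_fatal(self):
        pairs, derived = _derived(SimulationConfig(n_pairs=300, seed=23))
        pairs = pairs.assign(batch="batch1")
        design, _ = build_design(derived, pairs, model_spec(2, _SIM_COVARIATES))
        assert not any(c.startswith("batch") for c in design.attrs["covariates"])


class TestFitModels:
    def test_lmm_equals_ols_when_no_sibships(self):
        cfg = SimulationConfig(n_pairs=500, sibship_rate=0.0, beta3=100.0, seed=24)
        pairs, derived = _derived(cfg)
        spec = model_spec(2, _SIM_COVARIATES)
        design, _ = build_design(derived, pairs, spec)
        fit = fit_mixed_model(design, spec)
        # closed-form OLS oracle via the normal equations
        cols = ["fetal", "maternal", "interaction"] + list(design.attrs["covariates"])
        X = np.column_stack([np.ones(len(design))] + [design[c] for c in cols])
        beta = np.linalg.solve(X.T @ X, X.T @ design["birth_weight"].to_numpy())
        assert fit.interaction_est == pytest.approx(beta[3], rel=1e-6)

    def test_null_interaction_within_three_se(self):
        fit = simulate_and_fit(SimulationConfig(n_pairs=4000, seed=25), 1.0, 26)
        assert abs(fit.interaction_est) < 3 * fit.interaction_se
        assert fit.interaction_ci[0] < fit.interaction_est < fit.interaction_ci[1]

    def test_interaction_invariant_to_pc_recentering(self):
        cfg = SimulationConfig(n_pairs=1000, beta3=150.0, pc_effect=20.0, seed=27)
        pairs, derived = _derived(cfg)
        spec = model_spec(4, _SIM_COVARIATES)
        design, _ = build_design(derived, pairs, spec)
        fit1 = fit_mixed_model(design, spec)
        shifted = pairs.copy()
        for c in [f"mother_pc{i}" for i in range(1, 6)] + [f"child_pc{i}" for i in range(1, 6)]:
            shifted[c] = shifted[c] - shifted[c].mean()
        design2, _ = build_design(derived, shifted, spec)
        fit2 = fit_mixed_model(design2, spec)
        assert fit1.interaction_est == pytest.approx(fit2.interaction_est, abs=1e-8)

    def test_engines_agree(self):
        cfg = SimulationConfig(n_pairs=400, beta3=200.0, seed=28)
        pairs, derived = _derived(cfg)
        spec = model_spec(2, _SIM_COVARIATES)
        design, _ = build_design(derived, pairs, spec)
        a = fit_mixed_model(design, spec, engine="closed_form")
        b = fit_mixed_model(design, spec, engine="statsmodels")
        assert a.interaction_est == pytest.approx(b.interaction_est, rel=1e-3, abs=0.01)
        assert a.interaction_se == pytest.approx(b.interaction_se, rel=1e-2)


class TestRunAllModels:
    def test_six_models_and_determinism(self):
        cfg = SimulationConfig(n_pairs=600, seed=29)
        pairs, derived = _derived(cfg)
        res1, fits = run_all_models(derived, pairs, covariates=_SIM_COVARIATES)
        assert sorted(fits) == [1, 2, 3, 4, 5, 6]
        assert set(res1["term"]) == {"fetal", "maternal", "interaction"}
        res2, _ = run_all_models(derived, pairs, covariates=_SIM_COVARIATES)
        pd.testing.assert_frame_equal(res1, res2)

    def test_cohort_without_gestational_age(self):
        cfg = SimulationConfig(n_pairs=600, seed=30)
        pairs, derived = _derived(cfg)
        pairs = pairs.drop(columns=["gestational_age"])
        res, fits = run_all_models(derived, pairs, covariates=_SIM_COVARIATES)
        assert "gestational_age" in fits[1].notes
        assert "gestational_age" not in fits[1].coefficients

    def test_failed_model_recorded_run_continues(self):
        cfg = SimulationConfig(n_pairs=600, seed=31)
        pairs, derived = _derived(cfg)
        derived = derived.assign(kir_b_dosage=0.0)  # kills models 1, 3, 5
        res, fits = run_all_models(derived, pairs, covariates=_SIM_COVARIATES)
        assert sorted(fits) == [2, 4, 6]
        failed = res[res["note"].str.startswith("failed")]
        assert sorted(failed["model_id"]) == [1, 3, 5]
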