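"""Behavioral estimation: design construction, GLM fits, LR tests,
truncated Rescorla-Wagner inversion, reward-history slope test."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import expit, logit

from rewardsurprise.analysis import (FitResult, build_behavior_design,
                                     estimate_learning_rate, fit_lapse_model,
                                     fit_rt_model, fit_truncated_rw, lr_test,
                                     reward_history_slope_test, rw_lag_weights)
from rewardsurprise.behavior import AgentParams, compute_sre, simulate_behavior
from rewardsurprise.pipeline import CohortConfig, simulate_cohort
from rewardsurprise.schedules import ScheduleSpec, generate_session

from conftest import perturbed_lapse_agent


def _zscore(v):
    return (v - v.mean()) / v.std(ddof=0)


class TestDesign:
    def test_sre_column_matches_recursion_oracle(self, small_session):
        # error-free agent so attempts coincide with rewarded trials
        agent = perturbed_lapse_agent(Intercept=-np.inf, VS=0, sRE=0, RRE=0,
                                      Position=0, TrialNumber=0)
        trials = simulate_behavior(small_session, agent, 2)
        design = build_behavior_design(trials, alpha=0.257)
        # oracle: plain RW recursion on the outcome sequence, pre-outcome
        trace = compute_sre(small_session.drops, 0.257, 2.0)[:20]
        expected = _zscore(np.asarray(trace[5:]))
        assert design.X["sRE"].to_numpy() == pytest.approx(expected, abs=1e-9)

    def test_lag_history_rows_dropped(self, stable_trials):
        design = build_behavior_design(stable_trials, alpha=None)
        first_kept = design.X.index[0]
        assert design.n_dropped >= 5
        assert design.X.loc[first_kept, "RewardLag5"] is not None
        assert not design.X[[f"RewardLag{k}" for k in range(1, 6)]].isna().any().any()

    def test_columns_standardized_per_session(self, cohort_trials):
        design = build_behavior_design(cohort_trials, alpha=0.257)
        for c in design.predictors:
            assert design.X[c].mean() == pytest.approx(0.0, abs=0.05)
            assert design.X[c].std(ddof=0) == pytest.approx(1.0, abs=0.05)

    def test_vs_zero_after_error(self, stable_trials):
        design = build_behavior_design(stable_trials, alpha=0.257)
        repeats = design.is_repeat.to_numpy()
        raw_vs = design.X["VS"].to_numpy()
        # z-scored zeros all share the minimum column value on repeats
        assert len(np.unique(np.round(raw_vs[repeats], 9))) <= 1

    def test_constant_predictor_flagged(self, default_agent):
        spec = ScheduleSpec.for_type("stable", p_offside=0.0,
                                     run_length_range=(200, 200),
                                     n_rewarded_trials=50)
        sess = generate_session(spec, 1)
        agent = perturbed_lapse_agent(Intercept=-np.inf, VS=0, sRE=0, RRE=0,
                                      Position=0, TrialNumber=0)
        trials = simulate_behavior(sess, agent, 1)
        with pytest.warns(UserWarning, match="zero-variance"):
            design = build_behavior_design(trials, alpha=0.257)
        assert "VS" in design.dropped_columns
        assert "VS" not in design.predictors


class TestLapseModel:
    def test_intercept_recovers_base_rate(self):
        rng = np.random.default_rng(0)
        n = 20000
        X = pd.DataFrame({"subject": np.repeat([0, 1], n // 2),
                          "session": 0, "trial": np.tile(np.arange(n // 2), 2),
                          "attempt": 1, "side": "left", "rt_ms": 300.0,
                          "is_error": False, "is_outlier": False,
                          "vs_raw": 0.0, "vs_zeroed": rng.normal(size=n),
                          "rre_prev": rng.normal(size=n),
                          "drops": rng.choice([1, 2, 3], size=n)})
        X["is_lapse"] = rng.random(n) < 0.1
        design = build_behavior_design(X, alpha=0.257)
        fit = fit_lapse_model(design, predictors=[])
        assert fit.params["const"] == pytest.approx(logit(0.1), abs=0.1)

    @pytest.mark.parametrize("method", ["two-stage", "pooled"])
    def test_sign_recovery_of_vs_coefficient(self, method):
        """Simulated b_VS > 0 yields a fitted b_VS > 0 across cohorts."""
        hits = 0
        n_cohorts = 6
        for k in range(n_cohorts):
            cfg = CohortConfig(n_subjects=3, session_counts={"stable": 3},
                               seed=100 + k,
                               agent=perturbed_lapse_agent(VS=0.6))
            _, trials = simulate_cohort(cfg)
            design = build_behavior_design(trials, alpha=0.257)
            fit = fit_lapse_model(design, method=method)
            hits += fit.params["VS"] > 0
        assert hits == n_cohorts

    def test_null_coefficients_are_calibrated(self):
        """With all slopes zero, |z| stays below 1.96 in about 95% of fits."""
        agent = perturbed_lapse_agent(VS=0, sRE=0, RRE=0, Position=0,
                                      TrialNumber=0)
        zs = []
        for k in range(25):
            cfg = CohortConfig(n_subjects=2, session_counts={"stable": 2},
                               seed=300 + k, agent=agent)
            _, trials = simulate_cohort(cfg)
            design = build_behavior_design(trials, alpha=0.257)
            fit = fit_lapse_model(design, method="pooled")
            zs.extend(fit.zvalues.drop("const").tolist())
        frac = np.mean(np.abs(zs) < 1.96)
        lo = stats.binom.ppf(0.0005, len(zs), 0.95) / len(zs)
        assert frac >= lo


class TestLRTest:
    def _fake(self, llf, terms):
        s = pd.Series(0.0, index=terms)
        return FitResult(params=s, bse=s + 1.0, llf=llf,
                         per_subject=pd.DataFrame(), converged=True,
                         method="x", family="binomial-logit")

    def test_identical_models_give_null_result(self):
        full = self._fake(-100.0, ["const", "VS"])
        chi2, p = lr_test(full, full, df=1)
        assert chi2 == 0.0
        assert p == 1.0

    def test_chi2_critical_value(self):
        full = self._fake(-100.0, ["const", "VS"])
        red = self._fake(-100.0 - 3.84 / 2, ["const"])
        chi2, p = lr_test(full, red, df=1)
        assert p == pytest.approx(0.05, abs=0.002)

    def test_two_df_statistic_matches_reference_p(self):
        # chi2(2) = 6.918 -> p ~ 0.031, the scale of the sRE term's test
        full = self._fake(-50.0, ["const", "sRE"])
        red = self._fake(-50.0 - 6.918 / 2, ["const"])
        _, p = lr_test(full, red, df=2)
        assert p == pytest.approx(0.0314, abs=0.001)

    def test_non_nested_rejected(self):
        full = self._fake(-10.0, ["const", "VS"])
        other = self._fake(-11.0, ["const", "RRE"])
        with pytest.raises(ValueError, match="nested"):
            lr_test(full, other, df=1)

    def test_pvalues_uniform_under_null(self):
        """LR p-values on pooled null fits pass a KS uniformity check."""
        agent = perturbed_lapse_agent(VS=0, sRE=0, RRE=0, Position=0,
                                      TrialNumber=0)
        pvals = []
        for k in range(60):
            cfg = CohortConfig(n_subjects=2, session_counts={"stable": 1},
                               seed=500 + k, agent=agent)
            _, trials = simulate_cohort(cfg)
            design = build_behavior_design(trials, alpha=0.257)
            full = fit_lapse_model(design, method="pooled")
            red = fit_lapse_model(
                design, method="pooled",
                predictors=[c for c in design.predictors if c != "VS"])
            _, p = lr_test(full, red, df=1)
            pvals.append(p)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestTruncatedRW:
    def test_noiseless_inversion_is_exact(self):
        b = 0.6 * rw_lag_weights(0.257)
        fit = fit_truncated_rw(b)
        assert fit.alpha_hat == pytest.approx(0.257, abs=1e-6)
        assert fit.scale_hat == pytest.approx(0.6, abs=1e-6)
        assert fit.residual_norm == pytest.approx(0.0, abs=1e-12)

    def test_one_trial_memory(self):
        fit = fit_truncated_rw([0.8, 0.0, 0.0, 0.0, 0.0])
        assert fit.alpha_hat == pytest.approx(1.0, abs=1e-6)

    def test_negative_scale_supported(self):
        b = -0.3 * rw_lag_weights(0.4)
        fit = fit_truncated_rw(b)
        assert fit.alpha_hat == pytest.approx(0.4, abs=1e-6)
        assert fit.scale_hat == pytest.approx(-0.3, abs=1e-6)

    def test_noisy_recovery_matches_brute_force_oracle(self, rng):
        """Median recovery error < 0.05 and agreement with a dense 2-D grid."""
        def oracle(b):
            alphas = np.linspace(0.0, 1.0, 2001)
            scales = np.linspace(-1.0, 1.0, 8001)
            best = (np.inf, np.nan)
            for a in alphas:
                w = rw_lag_weights(a)
                r = np.linalg.norm(b[None, :] - scales[:, None] * w[None, :],
                                   axis=1)
                i = np.argmin(r)
                if r[i] < best[0]:
                    best = (r[i], a)
            return best[1]

        errs, agree = [], []
        for _ in range(50):
            b = -0.3 * rw_lag_weights(0.4) + rng.normal(0, 0.01, 5)
            fit = fit_truncated_rw(b)
            errs.append(abs(fit.alpha_hat - 0.4))
        assert np.median(errs) < 0.05
        # spot-check the optimizer against the brute-force grid
        for _ in range(5):
            b = -0.3 * rw_lag_weights(0.4) + rng.normal(0, 0.01, 5)
            assert fit_truncated_rw(b).alpha_hat == pytest.approx(
                oracle(b), abs=1e-3)

    def test_all_zero_betas_flagged(self):
        fit = fit_truncated_rw(np.zeros(5))
        assert not fit.ok
        assert np.isnan(fit.alpha_hat)


class TestSlopeTest:
    def test_constant_betas_give_zero_t(self):
        B = np.tile([0.2, 0.2, 0.2, 0.2, 0.2], (4, 1))
        with pytest.warns(UserWarning, match="zero variance"):
            t, df, p = reward_history_slope_test(B)
        assert t == 0.0
        assert df == 3

    def test_exact_linear_decay_is_detected(self, rng):
        lags = np.arange(1, 6)
        B = np.stack([0.5 - 0.1 * lags + rng.normal(0, 1e-4, 5)
                      for _ in range(6)])
        t, df, p = reward_history_slope_test(B)
        assert df == 5  # six subjects, as in the reported t(5)
        assert abs(t) > 100
        assert p < 0.001

    def test_missing_subject_excluded(self, rng):
        B = np.vstack([0.5 - 0.1 * np.arange(1, 6) + rng.normal(0, 0.01, (3, 5)),
                       np.full((1, 5), np.nan)])
        with pytest.warns(UserWarning, match="excluding"):
            t, df, p = reward_history_slope_test(B)
        assert df == 2


class TestRTModel:
    def test_intercept_only_matches_log_mean(self, cohort_trials):
        design = build_behavior_design(cohort_trials, alpha=0.257)
        fit = fit_rt_model(design, predictors=[], method="pooled")
        kept = design.rt_ms[~design.is_outlier.to_numpy()]
        assert fit.params["const"] == pytest.approx(np.log(kept.mean()),
                                                    abs=0.01)

    def test_vs_slows_reaction_times(self):
        """Positive generative VS weight on log-RT is recovered."""
        agent = AgentParams(rt_coefs={"Intercept": 5.99, "VS": 0.15,
                                      "sRE": 0.0, "RRE": 0.0, "Position": 0.0,
                                      "TrialNumber": 0.0})
        cfg = CohortConfig(n_subjects=3, session_counts={"stable": 3},
                           seed=7, agent=agent)
        _, trials = simulate_cohort(cfg)
        design = build_behavior_design(trials, alpha=0.257)
        fit = fit_rt_model(design)
        assert fit.params["VS"] > 0
        assert fit.zvalues["VS"] > 2

    def test_exclusion_variants_nest(self, cohort_trials):
        design = build_behavior_design(cohort_trials, alpha=0.257)
        strict = ~(design.is_outlier | design.is_error | design.is_repeat)
        assert strict.sum() < (~design.is_outlier).sum()
        fit = fit_rt_model(design, exclude="outliers_errors_repeats")
        assert np.isfinite(fit.llf)
        with pytest.raises(ValueError, match="exclusion"):
            fit_rt_model(design, exclude="nope")


class TestTwoStageConsistency:
    def test_learning_rate_recovered_from_cohort(self, cohort_trials):
        """The full build -> fit -> invert chain recovers the generative
        learning rate to within 0.1 on one cohort."""
        rw, fit, _ = estimate_learning_rate(cohort_trials)
        assert rw.ok
        assert abs(rw.alpha_hat - 0.257) < 0.1
        # lapse-model lag weights are negative (reward protects performance)
        lag1 = fit.params["RewardLag1"]
        assert lag1 < 0
        assert rw.scale_hat < 0
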