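"""Random-intercept linear mixed model: oracles, collapse cases, Wald tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from advicetrial import SimConfig, analysis_records, build_woa_table, simulate_trial
from advicetrial.models import ModelSpec, arm_difference, fit_random_intercept, wald_test
from advicetrial.models.spec import RankDeficientError
from tests.conftest import noise_free_config


def _toy_balanced(J=20, m=5, mu=0.4, diff=-0.12, s_u=0.15, s_e=0.1, seed=5):
    """Balanced two-arm data: J participants (J/2 per arm), m records each."""
    rng = np.random.default_rng(seed)
    arms = np.repeat(["ALGORITHM", "CLINICIAN"], J // 2)
    u = rng.normal(0, s_u, J)
    rows = []
    for j in range(J):
        base = mu + (diff if arms[j] == "CLINICIAN" else 0.0) + u[j]
        y = base + rng.normal(0, s_e, m)
        for k in range(m):
            rows.append({"participant_id": f"p{j}", "arm": arms[j], "woa": y[k]})
    return pd.DataFrame(rows)


class TestClosedFormOracles:
    def test_matches_balanced_anova_estimator(self):
        """In a balanced design REML equals the closed-form ANOVA estimator."""
        df = _toy_balanced()
        J, m = 20, 5
        fit = fit_random_intercept(df, ModelSpec(fixed_effects=["arm"]))

        means = df.groupby(["participant_id", "arm"])["woa"].mean().reset_index()
        arm_means = means.groupby("arm")["woa"].mean()
        # within-participant mean square
        sse = ((df["woa"] - df.groupby("participant_id")["woa"].transform("mean")) ** 2).sum()
        s2e = sse / (J * (m - 1))
        # between-participant (within-arm) mean square of participant means
        ssb = ((means["woa"] - means.groupby("arm")["woa"].transform("mean")) ** 2).sum()
        s2b = ssb / (J - 2)
        s2u = s2b - s2e / m

        assert fit.beta["Intercept"] == pytest.approx(arm_means["ALGORITHM"], abs=1e-6)
        assert fit.beta["arm[CLINICIAN]"] == pytest.approx(
            arm_means["CLINICIAN"] - arm_means["ALGORITHM"], abs=1e-6
        )
        assert fit.sigma_e2 == pytest.approx(s2e, abs=1e-6)
        assert fit.sigma_u2 == pytest.approx(s2u, abs=1e-6)

    def test_gls_equals_ols_in_balanced_design(self):
        df = _toy_balanced(seed=8)
        fit = fit_random_intercept(df, ModelSpec(fixed_effects=["arm"]))
        X = np.column_stack(
            [np.ones(len(df)), (df["arm"] == "CLINICIAN").to_numpy(float)]
        )
        ols = np.linalg.lstsq(X, df["woa"].to_numpy(), rcond=None)[0]
        np.testing.assert_allclose(fit.beta.to_numpy(), ols, atol=1e-8)

    def test_independent_errors_collapse_to_ols(self):
        # sigma_u^2 = 0 truth: fitted beta equals OLS beta within 1e-6
        rng = np.random.default_rng(3)
        n = 400
        df = pd.DataFrame(
            {
                "participant_id": np.repeat([f"p{j}" for j in range(80)], 5),
                "arm": np.repeat(
                    np.tile(["ALGORITHM", "CLINICIAN"], 40), 5
                ),
                "woa": rng.normal(0.4, 0.1, n),
            }
        )
        fit = fit_random_intercept(df, ModelSpec(fixed_effects=["arm"]))
        X = np.column_stack(
            [np.ones(n), (df["arm"] == "CLINICIAN").to_numpy(float)]
        )
        ols = np.linalg.lstsq(X, df["woa"].to_numpy(), rcond=None)[0]
        np.testing.assert_allclose(fit.beta.to_numpy(), ols, atol=1e-6)
        assert fit.boundary or fit.sigma_u2 < 1e-3

    def test_brute_force_mvn_likelihood(self):
        """Woodbury likelihood equals per-cluster multivariate-normal density."""
        rng = np.random.default_rng(9)
        sizes = [2, 3, 5, 4, 1]
        rows = []
        for j, m in enumerate(sizes):
            for _ in range(m):
                rows.append(
                    {
                        "participant_id": f"p{j}",
                        "arm": "ALGORITHM" if j % 2 else "CLINICIAN",
                        "woa": rng.normal(0.4, 0.2),
                    }
                )
        df = pd.DataFrame(rows)
        fit = fit_random_intercept(df, ModelSpec(fixed_effects=["arm"]))
        beta = np.array([0.35, -0.1])
        s2u, s2e = 0.02, 0.015
        own = fit.loglik_at(beta, s2u, s2e)

        X = np.column_stack(
            [np.ones(len(df)), (df["arm"] == "CLINICIAN").to_numpy(float)]
        )
        resid = df["woa"].to_numpy() - X @ beta
        brute = 0.0
        start = 0
        for m in sizes:
            r = resid[start : start + m]
            cov = s2u * np.ones((m, m)) + s2e * np.eye(m)
            brute += stats.multivariate_normal.logpdf(r, mean=np.zeros(m), cov=cov)
            start += m
        assert own == pytest.approx(brute, abs=1e-10)


class TestAgainstStatsmodels:
    def test_reml_matches_mixedlm(self, default_records):
        import statsmodels.formula.api as smf

        own = fit_random_intercept(default_records, ModelSpec(fixed_effects=["arm"]))
        sm = smf.mixedlm(
            "woa ~ C(arm)", default_records, groups=default_records["participant_id"]
        ).fit(reml=True)
        assert own.beta["Intercept"] == pytest.approx(sm.params["Intercept"], abs=1e-5)
        assert own.beta["arm[CLINICIAN]"] == pytest.approx(
            sm.params["C(arm)[T.CLINICIAN]"], abs=1e-5
        )
        assert own.sigma_u2 == pytest.approx(float(sm.cov_re.iloc[0, 0]), abs=1e-5)
        assert own.sigma_e2 == pytest.approx(sm.scale, abs=1e-5)
        assert own.loglik == pytest.approx(sm.llf, abs=1e-5)


class TestOptimum:
    def test_profiled_criterion_is_maximal_at_solution(self, default_records):
        fit = fit_random_intercept(default_records, ModelSpec(fixed_effects=["arm"]))
        assert fit.converged
        best = max(fit.criterion_trace)
        assert fit.criterion_trace[-1] <= best + 1e-12
        assert best - np.max(fit.criterion_trace[: len(fit.criterion_trace) // 2]) > -1e-9

    def test_variance_components_nonnegative(self, default_records):
        fit = fit_random_intercept(default_records, ModelSpec(fixed_effects=["arm"]))
        assert fit.sigma_u2 >= 0
        assert fit.sigma_e2 > 0

    def test_rank_deficient_design_names_columns(self, default_records):
        df = default_records.copy()
        df["arm_copy"] = df["arm"]
        with pytest.raises(RankDeficientError, match="arm_copy"):
            fit_random_intercept(df, ModelSpec(fixed_effects=["arm", "arm_copy"]))

    def test_single_participant_rejected(self):
        df = pd.DataFrame(
            {"participant_id": ["a"] * 5, "arm": ["ALGORITHM"] * 5, "woa": [0.4] * 5}
        )
        with pytest.raises(ValueError):
            fit_random_intercept(df)


class TestWaldTest:
    def test_single_term_is_squared_z(self, default_records):
        fit = fit_random_intercept(default_records, ModelSpec(fixed_effects=["arm"]))
        stat, df_, p = wald_test(fit, ["arm[CLINICIAN]"])
        z = fit.beta["arm[CLINICIAN]"] / fit.se["arm[CLINICIAN]"]
        assert stat == pytest.approx(z**2)
        assert df_ == 1
        assert p == pytest.approx(stats.chi2.sf(z**2, 1))

    def test_interaction_term_expands_to_contrasts(self, default_records):
        spec = ModelSpec(fixed_effects=["arm", "strength", "arm:strength"])
        fit = fit_random_intercept(default_records, spec)
        stat, df_, p = wald_test(fit, ["arm:strength"])
        assert df_ == 2  # two non-reference strengths
        assert stat >= 0 and 0 <= p <= 1

    def test_empty_term_set_rejected(self, default_records):
        fit = fit_random_intercept(default_records, ModelSpec(fixed_effects=["arm"]))
        with pytest.raises(ValueError):
            wald_test(fit, [])

    def test_interaction_pvalues_uniform_under_null(self):
        """With no true arm x experience interaction, Wald p-values are
        uniform across replicates (Kolmogorov-Smirnov)."""
        pvals = []
        for seed in range(120):
            df = simulate_trial(
                SimConfig(n_participants=60, dropout_probability=0.0, seed=9000 + seed)
            )
            rec = analysis_records(build_woa_table(df))
            spec = ModelSpec(
                fixed_effects=["arm", "total_experience", "arm:total_experience"]
            )
            fit = fit_random_intercept(rec, spec)
            pvals.append(wald_test(fit, ["arm:total_experience"])[2])
        _, ks_p = stats.kstest(pvals, "uniform")
        assert ks_p > 0.01


class TestArmDifference:
    def test_identical_arms_give_zero(self):
        df = _toy_balanced(diff=0.0, s_u=0.0, s_e=0.0)
        est, ci, p = arm_difference(df)
        assert est == pytest.approx(0.0, abs=1e-12)

    def test_noise_free_identifiability(self):
        df = simulate_trial(noise_free_config(n_participants=120))
        rec = analysis_records(build_woa_table(df))
        est, ci, p = arm_difference(rec)
        assert est == pytest.approx(0.31 - 0.44, abs=0.01)
        assert ci[0] < est < ci[1]

    def test_single_arm_rejected(self):
        df = _toy_balanced()
        with pytest.raises(ValueError):
            arm_difference(df[df["arm"] == "ALGORITHM"])
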