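import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, gammaln
from scipy.stats import norm

from jointglmm import (
    DegenerateDataError,
    ModelSpec,
    SingularDesignError,
    build_design,
    default_truth,
    fit_glmm,
    fit_separate,
    fit_statistics,
    marginal_loglik,
    simulate_cohort,
    stack_bivariate,
)
from jointglmm.glmm import _start_values, layout_for

from conftest import make_cohort


# ---------------------------------------------------------------------------
# independent oracle: dense-grid integration of the per-subject integral

def brute_force_joint_loglik(cohort, beta_c, beta_b, sigma, lam,
                             n_grid=40001, span=8.0):
    """Direct trapezoid integration over b of the joint subject likelihood.

    The linear predictors are computed directly from the cohort columns
    (intercept + visit), fully independent of the engine's design/quadrature
    code path.
    """
    total = 0.0
    for _, grp in cohort.groupby("patient_id"):
        b = np.linspace(-span * sigma, span * sigma, n_grid)
        log_int = norm.logpdf(b, 0.0, sigma)
        for _, row in grp.iterrows():
            eta_c = beta_c[0] + beta_c[1] * row["visit"]
            y = row["cd4_count"]
            log_int = log_int + y * (eta_c + b) - np.exp(eta_c + b) - gammaln(y + 1)
            eta_b = beta_b[0] + beta_b[1] * row["visit"]
            lin = eta_b + lam * b
            log_int = log_int + row["tb_status"] * lin - np.logaddexp(0.0, lin)
        m = log_int.max()
        total += m + np.log(np.trapezoid(np.exp(log_int - m), b))
    return total


@pytest.fixture
def three_subject_cohort():
    rows = []
    cd4 = {(1, 1): 9, (1, 2): 14, (2, 1): 11, (2, 2): 8, (3, 1): 13, (3, 2): 10}
    tb = {(1, 1): 1, (1, 2): 0, (2, 1): 1, (2, 2): 1, (3, 1): 0, (3, 2): 1}
    for p in (1, 2, 3):
        for v in (1, 2):
            rows.append({
                "patient_id": f"S{p}", "visit": v,
                "cd4_count": cd4[(p, v)], "tb_status": tb[(p, v)],
            })
    return make_cohort(rows)


SMALL_SPEC = ModelSpec(count_terms=("visit",), binary_terms=("visit",),
                       lambda_binary="free")


def pack_small(beta_c, beta_b, sigma, lam):
    return np.array([*beta_c, *beta_b, np.log(sigma), lam])


class TestMarginalLoglik:
    def test_agq_matches_brute_force_integration(self, three_subject_cohort):
        stacked = stack_bivariate(three_subject_cohort)
        spec = ModelSpec(count_terms=("visit",), binary_terms=("visit",),
                         lambda_binary="free", method="agq", n_nodes=51)
        bundle = build_design(stacked, spec)
        beta_c, beta_b, sigma, lam = (2.0, 0.1), (-0.3, 0.2), 0.4, 0.7
        mine = marginal_loglik(pack_small(beta_c, beta_b, sigma, lam), bundle)
        oracle = brute_force_joint_loglik(three_subject_cohort, beta_c, beta_b, sigma, lam)
        assert mine == pytest.approx(oracle, abs=1e-6)

    def test_laplace_close_to_exact_on_count_dominated_data(self, three_subject_cohort):
        stacked = stack_bivariate(three_subject_cohort)
        theta = pack_small((2.0, 0.1), (-0.3, 0.2), 0.3, 1.0)
        ll_lap = marginal_loglik(theta, build_design(stacked, SMALL_SPEC))
        spec51 = ModelSpec(count_terms=("visit",), binary_terms=("visit",),
                          lambda_binary="free", method="agq", n_nodes=51)
        ll_agq = marginal_loglik(theta, build_design(stacked, spec51))
        assert ll_lap == pytest.approx(ll_agq, abs=0.05)

    def test_agq_node_refinement_converges(self, three_subject_cohort):
        stacked = stack_bivariate(three_subject_cohort)
        theta = pack_small((2.0, 0.1), (-0.3, 0.2), 0.4, 0.7)
        lls = {}
        for n in (5, 11, 21, 51):
            spec = ModelSpec(count_terms=("visit",), binary_terms=("visit",),
                             lambda_binary="free", method="agq", n_nodes=n)
            lls[n] = marginal_loglik(theta, build_design(stacked, spec))
        assert abs(lls[21] - lls[51]) < 1e-6
        errs = [abs(lls[n] - lls[51]) for n in (5, 11, 21)]
        assert errs[0] >= errs[1] >= errs[2]

    def test_no_random_effect_equals_sum_of_glm_logliks(self, three_subject_cohort):
        # with sigma_b = 0 the integral collapses to independent GLMs;
        # oracle computed directly from the density formulas
        stacked = stack_bivariate(three_subject_cohort)
        spec = ModelSpec(count_terms=("visit",), binary_terms=("visit",),
                         random_effects="none")
        bundle = build_design(stacked, spec)
        beta_c, beta_b = np.array([2.0, 0.1]), np.array([-0.3, 0.2])
        mine = marginal_loglik(np.r_[beta_c, beta_b], bundle)
        df = three_subject_cohort
        eta_c = beta_c[0] + beta_c[1] * df["visit"]
        eta_b = beta_b[0] + beta_b[1] * df["visit"]
        y1, y2 = df["cd4_count"], df["tb_status"]
        oracle = float(
            np.sum(y1 * eta_c - np.exp(eta_c) - gammaln(y1 + 1))
            + np.sum(y2 * eta_b - np.logaddexp(0.0, eta_b))
        )
        assert mine == pytest.approx(oracle, abs=1e-10)

    def test_correlated_intercepts_match_2d_grid_oracle(self, three_subject_cohort):
        stacked = stack_bivariate(three_subject_cohort)
        spec = ModelSpec(count_terms=("visit",), binary_terms=("visit",),
                         random_effects="correlated_intercepts",
                         method="agq", n_nodes=31)
        bundle = build_design(stacked, spec)
        beta_c, beta_b = (2.0, 0.1), (-0.3, 0.2)
        s1, s2, rho = 0.4, 0.6, 0.5
        theta = np.array([*beta_c, *beta_b, np.log(s1), np.log(s2), np.arctanh(rho)])
        mine = marginal_loglik(theta, bundle)

        # independent 2-D trapezoid integration
        from scipy.stats import multivariate_normal
        cov = np.array([[s1**2, rho * s1 * s2], [rho * s1 * s2, s2**2]])
        g1 = np.linspace(-6 * s1, 6 * s1, 601)
        g2 = np.linspace(-6 * s2, 6 * s2, 601)
        B1, B2 = np.meshgrid(g1, g2, indexing="ij")
        total = 0.0
        for _, grp in three_subject_cohort.groupby("patient_id"):
            log_int = multivariate_normal.logpdf(
                np.dstack([B1, B2]), mean=[0, 0], cov=cov)
            for _, row in grp.iterrows():
                eta_c = beta_c[0] + beta_c[1] * row["visit"] + B1
                log_int += row["cd4_count"] * eta_c - np.exp(eta_c) - gammaln(row["cd4_count"] + 1)
                eta_b = beta_b[0] + beta_b[1] * row["visit"] + B2
                log_int += row["tb_status"] * eta_b - np.logaddexp(0.0, eta_b)
            m = log_int.max()
            inner = np.trapezoid(np.exp(log_int - m), g2, axis=1)
            total += m + np.log(np.trapezoid(inner, g1))
        assert mine == pytest.approx(total, abs=1e-5)

    def test_nonfinite_linear_predictor_names_subject(self, three_subject_cohort):
        bad = three_subject_cohort.copy()
        bad.loc[bad["patient_id"] == "S2", "weight"] = np.inf
        stacked = stack_bivariate(bad)
        spec = ModelSpec(count_terms=("weight",), binary_terms=("visit",))
        bundle = build_design(stacked, spec)
        theta = np.array([2.0, 0.01, -0.3, 0.2, np.log(0.3)])
        with pytest.raises(FloatingPointError, match="S2"):
            marginal_loglik(theta, bundle)


class TestBuildDesign:
    def test_intercept_only(self):
        cohort = make_cohort(
            [{"patient_id": f"P{p}", "visit": v} for p in (1, 2) for v in (1, 2)]
        )
        spec = ModelSpec(count_terms=(), binary_terms=())
        bundle = build_design(stack_bivariate(cohort), spec)
        assert bundle.X_count.shape == (4, 1) and (bundle.X_count == 1).all()
        assert bundle.X_binary.shape == (4, 1) and (bundle.X_binary == 1).all()

    def test_categorical_drops_last_level(self):
        cohort = make_cohort(
            [{"patient_id": f"P{i}", "visit": 1, "adherence": 1 + i % 3}
             for i in range(9)]
        )
        spec = ModelSpec(count_terms=("adherence",), binary_terms=())
        bundle = build_design(stack_bivariate(cohort), spec)
        assert bundle.count_names == ["intercept", "adherence[1]", "adherence[2]"]

    def test_constant_covariate_raises_singularity(self):
        cohort = make_cohort(
            [{"patient_id": f"P{i}", "visit": 1, "gender": 1} for i in range(6)]
        )
        spec = ModelSpec(count_terms=("gender",), binary_terms=())
        with pytest.raises(SingularDesignError, match="gender"):
            build_design(stack_bivariate(cohort), spec)


class TestFitClosedForms:
    def test_bernoulli_intercept_is_logit_prevalence(self):
        rows = [{"patient_id": f"P{i}", "visit": 1, "tb_status": int(i < 50)}
                for i in range(100)]
        stacked = stack_bivariate(make_cohort(rows))
        spec = ModelSpec(count_terms=(), binary_terms=(), random_effects="none")
        fit = fit_glmm(stacked.loc[stacked["channel"] == "binary"], spec)
        assert fit.coef.loc[0, "estimate"] == pytest.approx(0.0, abs=1e-6)

    def test_poisson_intercept_is_log_sample_mean(self):
        rng = np.random.default_rng(4)
        ys = rng.poisson(100, size=80)
        rows = [{"patient_id": f"P{i}", "visit": 1, "cd4_count": int(y)}
                for i, y in enumerate(ys)]
        stacked = stack_bivariate(make_cohort(rows))
        spec = ModelSpec(count_terms=(), binary_terms=(), random_effects="none")
        fit = fit_glmm(stacked.loc[stacked["channel"] == "count"], spec)
        assert fit.coef.loc[0, "estimate"] == pytest.approx(np.log(ys.mean()), abs=1e-6)

    def test_degenerate_binary_channel_rejected(self):
        rows = [{"patient_id": f"P{i}", "visit": 1, "tb_status": 1} for i in range(10)]
        stacked = stack_bivariate(make_cohort(rows))
        spec = ModelSpec(count_terms=(), binary_terms=())
        with pytest.raises(DegenerateDataError):
            fit_glmm(stacked, spec)


@pytest.fixture(scope="module")
def joint_fixture():
    truth = default_truth(
        n_patients=200, max_visits=5, seed=101, sigma_b=0.4,
        beta_count={"intercept": 5.3, "visit": 0.02, "weight": 0.003},
        beta_binary={"intercept": 1.0, "oi_status": 1.798},
    )
    truth.categorical_probs["oi_status"] = {1: 40, 0: 60}
    cohort, truth = simulate_cohort(truth)
    stacked = stack_bivariate(cohort)
    spec = ModelSpec(count_terms=("visit", "weight"), binary_terms=("oi_status",))
    return cohort, stacked, spec, truth


class TestFitGlmm:
    def test_laplace_and_agq_agree(self, joint_fixture):
        _, stacked, spec, _ = joint_fixture
        from dataclasses import replace
        fit_lap = fit_glmm(stacked, spec)
        fit_agq = fit_glmm(stacked, replace(spec, method="agq", n_nodes=21))
        lap = fit_lap.coef.set_index(["channel", "term"])["estimate"]
        agq = fit_agq.coef.set_index(["channel", "term"])["estimate"]
        # count channel: the high Poisson information makes the integrand
        # near-Gaussian, so Laplace is accurate to well under 3 decimals
        np.testing.assert_allclose(lap["count"], agq["count"], atol=1e-3)
        # binary channel: Laplace carries a small but real bias for
        # Bernoulli data; agreement is relative, not absolute
        np.testing.assert_allclose(lap["binary"], agq["binary"], rtol=5e-3)
        assert fit_lap.random_effects["sigma_b2"] == pytest.approx(
            fit_agq.random_effects["sigma_b2"], rel=0.01
        )

    def test_recovers_truth_roughly(self, joint_fixture):
        _, stacked, spec, truth = joint_fixture
        fit = fit_glmm(stacked, spec)
        est = dict(zip(zip(fit.coef["channel"], fit.coef["term"]), fit.coef["estimate"]))
        se = dict(zip(zip(fit.coef["channel"], fit.coef["term"]), fit.coef["se"]))
        for ch, term, true_val in [
            ("count", "visit", 0.02),
            ("count", "weight", 0.003),
            ("binary", "oi_status[1]", 1.798),
        ]:
            assert abs(est[(ch, term)] - true_val) < 4 * se[(ch, term)]
        assert fit.converged

    def test_weight_rescaling_equivariance(self, joint_fixture):
        cohort, _, spec, _ = joint_fixture
        fit1 = fit_glmm(stack_bivariate(cohort), spec)
        scaled = cohort.copy()
        scaled["weight"] = scaled["weight"] * 10.0
        fit2 = fit_glmm(stack_bivariate(scaled), spec)
        w1 = fit1.coef.set_index(["channel", "term"]).loc[("count", "weight"), "estimate"]
        w2 = fit2.coef.set_index(["channel", "term"]).loc[("count", "weight"), "estimate"]
        assert w2 == pytest.approx(w1 / 10.0, rel=1e-3)

    def test_posterior_modes_track_random_effects(self, joint_fixture):
        # with counts near exp(5.3) per visit the modes almost equal the
        # simulated b_i
        cohort, stacked, spec, truth = joint_fixture
        fit = fit_glmm(stacked, spec)
        truth2 = default_truth(
            n_patients=200, max_visits=5, seed=101, sigma_b=0.4,
            beta_count=truth.beta_count, beta_binary=truth.beta_binary,
        )
        truth2.categorical_probs["oi_status"] = {1: 40, 0: 60}
        _, _, latent = simulate_cohort(truth2, return_latent=True)
        b_true = latent.groupby("patient_id")["b"].first()
        b_hat = pd.Series(fit.posterior_modes, index=fit.subjects)
        r = np.corrcoef(b_true.loc[b_hat.index], b_hat)[0, 1]
        assert r > 0.95


class TestFitSeparate:
    def test_count_fit_ignores_binary_channel(self, joint_fixture):
        _, stacked, spec, _ = joint_fixture
        flipped = stacked.copy()
        mask = flipped["channel"] == "binary"
        flipped.loc[mask, "response"] = 1.0 - flipped.loc[mask, "response"]
        c1, _ = fit_separate(stacked, spec)
        c2, _ = fit_separate(flipped, spec)
        np.testing.assert_allclose(c1.coef["estimate"], c2.coef["estimate"], atol=1e-8)

    def test_sigma_zero_data_matches_plain_glm(self):
        import statsmodels.api as sm

        truth = default_truth(
            n_patients=400, max_visits=4, seed=55, sigma_b=0.0,
            beta_count={"intercept": 5.0, "visit": 0.02},
            beta_binary={"intercept": 0.5, "visit": 0.05},
        )
        cohort, _ = simulate_cohort(truth)
        stacked = stack_bivariate(cohort)
        spec = ModelSpec(count_terms=("visit",), binary_terms=("visit",))
        count_fit, binary_fit = fit_separate(stacked, spec)
        X = sm.add_constant(cohort["visit"].to_numpy())
        glm_c = sm.GLM(cohort["cd4_count"], X, family=sm.families.Poisson()).fit()
        glm_b = sm.GLM(cohort["tb_status"], X, family=sm.families.Binomial()).fit()
        np.testing.assert_allclose(
            count_fit.coef["estimate"], glm_c.params, atol=5e-3)
        np.testing.assert_allclose(
            binary_fit.coef["estimate"], glm_b.params, atol=5e-2)


class TestAgainstLme4:
    def test_binary_random_intercept_matches_glmer(self, tmp_path):
        truth = default_truth(
            n_patients=150, max_visits=6, seed=11, sigma_b=0.5,
            beta_count={"intercept": 5.0},
            beta_binary={"intercept": -0.3, "visit": 0.15},
        )
        cohort, _ = simulate_cohort(truth)
        csv = tmp_path / "bin.csv"
        cohort[["patient_id", "visit", "tb_status"]].rename(
            columns={"tb_status": "y"}
        ).to_csv(csv, index=False)
        spec = ModelSpec(count_terms=(), binary_terms=("visit",),
                         method="agq", n_nodes=25, lambda_binary=1.0)
        stacked = stack_bivariate(cohort)
        fit = fit_glmm(stacked.loc[stacked["channel"] == "binary"], spec)

        rcode = f"""
        suppressMessages(library(lme4))
        d <- read.csv("{csv}")
        m <- glmer(y ~ visit + (1|patient_id), data=d, family=binomial, nAGQ=25)
        cat(fixef(m), as.data.frame(VarCorr(m))$sdcor, sqrt(diag(vcov(m))), "\\n")
        """
        out = subprocess.run(["Rscript", "-e", rcode], capture_output=True,
                             text=True, check=True)
        vals = np.array([float(v) for v in out.stdout.split()])
        np.testing.assert_allclose(fit.coef["estimate"], vals[:2], atol=1e-4)
        assert np.sqrt(fit.random_effects["sigma_b2"]) == pytest.approx(vals[2], abs=1e-3)
        np.testing.assert_allclose(fit.coef["se"], vals[3:5], atol=1e-3)


class TestFitStatistics:
    def test_perfect_fit_gives_zero_chi_square(self):
        # constant counts: the intercept-only Poisson fit reproduces y exactly
        rows = [{"patient_id": f"P{i}", "visit": 1, "cd4_count": 70} for i in range(10)]
        stacked = stack_bivariate(make_cohort(rows)).query("channel == 'count'")
        spec = ModelSpec(count_terms=(), binary_terms=(), random_effects="none")
        fit = fit_glmm(stacked, spec)
        stats = fit_statistics(fit, stacked, spec)
        assert stats["pearson_chi2"] == pytest.approx(0.0, abs=1e-8)

    def test_well_specified_model_has_unit_dispersion(self, joint_fixture):
        _, stacked, spec, _ = joint_fixture
        fit = fit_glmm(stacked, spec)
        stats = fit_statistics(fit, stacked, spec)
        assert 0.8 < stats["chi2_per_df"] < 1.2
        assert stats["minus2_loglik"] == pytest.approx(-2 * fit.loglik)

    def test_overdispersed_counts_inflate_chi_square(self):
        truth = default_truth(
            n_patients=200, max_visits=5, seed=77, count_dispersion=2.0,
            beta_count={"intercept": 5.3, "visit": 0.02},
            beta_binary={"intercept": 1.0, "oi_status": 1.798},
        )
        truth.categorical_probs["oi_status"] = {1: 40, 0: 60}
        cohort, _ = simulate_cohort(truth)
        stacked = stack_bivariate(cohort)
        spec = ModelSpec(count_terms=("visit",), binary_terms=("oi_status",))
        fit = fit_glmm(stacked, spec)
        stats = fit_statistics(fit, stacked, spec)
        assert stats["chi2_per_df"] > 1.5


class TestSpecValidation:
    @pytest.mark.parametrize("kwargs", [
        {"method": "agq", "n_nodes": 4},
        {"method": "mcmc"},
        {"count_family": "gamma"},
        {"random_effects": "slopes"},
        {"lambda_binary": "maybe"},
    ])
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ModelSpec(**kwargs)


class TestGaussianLogChannel:
    def test_fit_recovers_log_scale_parameters(self):
        truth = default_truth(
            n_patients=300, max_visits=4, seed=21, sigma_b=0.3,
            count_family="gaussian-log", sigma_e=0.3,
            beta_count={"intercept": 5.5, "visit": 0.05},
            beta_binary={"intercept": 1.0, "oi_status": 1.798},
        )
        truth.categorical_probs["oi_status"] = {1: 40, 0: 60}
        cohort, _ = simulate_cohort(truth)
        stacked = stack_bivariate(cohort)
        spec = ModelSpec(count_terms=("visit",), binary_terms=("oi_status",),
                         count_family="gaussian-log")
        fit = fit_glmm(stacked, spec)
        est = fit.coef.set_index(["channel", "term"])["estimate"]
        assert est[("count", "visit")] == pytest.approx(0.05, abs=0.02)
        assert fit.random_effects["sigma_e"] == pytest.approx(0.3, abs=0.05)
        assert fit.random_effects["sigma_b2"] == pytest.approx(0.09, rel=0.5)
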