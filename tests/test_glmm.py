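import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import norm, poisson

from astrobiodose import glmm
from astrobiodose.preflight import PRE_FIXED, PRE_RANDOM, _pre_frame


def _pre_spec(cohort):
    df = _pre_frame(cohort, include_baseline=True, dose_cap=0.5)
    return glmm.ModelSpec.from_frame(df, PRE_FIXED, PRE_RANDOM)


def _subject_loglik_on_grid(spec, k, beta, sigma0, u):
    """Dense-grid log-integrand per subject for the 1-D intercept model."""
    out = []
    for g in range(spec.n_groups):
        m = spec.groups == g
        eta0 = spec.X[m] @ beta + spec.offset[m]
        ll = (
            k[m][:, None] * (eta0[:, None] + u[None, :])
            - np.exp(eta0[:, None] + u[None, :])
        ).sum(axis=0) - sum(math.lgamma(x + 1) for x in k[m])
        out.append(ll)
    return out


class TestMarginalLoglik:
    def test_zero_variance_equals_poisson_pmf_sum(self, tiny_intercept_model):
        spec, k, beta, _ = tiny_intercept_model
        params = glmm.pack_params(beta, [0.0])
        mu = np.exp(spec.X @ beta + spec.offset)
        expected = poisson.logpmf(k.astype(int), mu).sum()
        assert glmm.marginal_loglik(params, spec, k) == pytest.approx(
            expected, abs=1e-10
        )

    def test_matches_dense_grid_oracle(self, tiny_intercept_model):
        spec, k, beta, sigma0 = tiny_intercept_model
        u = np.linspace(-8 * sigma0, 8 * sigma0, 100001)
        total = 0.0
        for ll in _subject_loglik_on_grid(spec, k, beta, sigma0, u):
            total += np.log(np.trapezoid(np.exp(ll) * norm.pdf(u, 0, sigma0), u))
        ours = glmm.marginal_loglik(glmm.pack_params(beta, [sigma0]), spec, k)
        assert abs(ours - total) / abs(total) < 1e-6

    def test_matches_monte_carlo_oracle(self, tiny_intercept_model):
        spec, k, beta, sigma0 = tiny_intercept_model
        rng = np.random.default_rng(42)
        draws = rng.normal(0, sigma0, 10**6)
        params = glmm.pack_params(beta, [sigma0])
        # compare per-subject integrals on the natural scale, 3 MC SEs
        grid = _subject_loglik_on_grid(spec, k, beta, sigma0, draws)
        grp = glmm._Grouped(spec, k)
        logI, _ = glmm._group_logliks(
            grp, grp.eta0(beta), np.array([sigma0]), 0.0, 7
        )
        for g, ll in enumerate(grid):
            I = np.exp(ll)
            const = sum(math.lgamma(x + 1) for x in k[spec.groups == g])
            ours = np.exp(logI[g] - const)
            assert abs(ours - I.mean()) < 3 * I.std() / np.sqrt(len(I))

    def test_quadrature_order_converged_by_default(self, default_cohort):
        cohort, _ = default_cohort
        spec, k = _pre_spec(cohort)
        beta0, _, _ = glmm.poisson_glm_irls(spec.X, k, spec.offset)
        params = glmm.pack_params(beta0, [0.4, 0.8], 0.3)
        a = glmm.marginal_loglik(params, spec, k, quad_order=7)
        b = glmm.marginal_loglik(params, spec, k, quad_order=25)
        assert abs(a - b) < 1e-4

    def test_subject_relabeling_invariance(self, default_cohort):
        cohort, _ = default_cohort
        spec, k = _pre_spec(cohort)
        params = glmm.pack_params(np.array([-5.7, 4.1, 0.03, 0.17]), [0.4, 0.8], 0.3)
        a = glmm.marginal_loglik(params, spec, k)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(k))
        spec2 = glmm.ModelSpec(
            spec.X[perm], spec.x_names, spec.Z[perm], spec.z_names,
            spec.groups[perm], spec.group_labels, spec.offset[perm],
        )
        assert glmm.marginal_loglik(params, spec2, k[perm]) == pytest.approx(
            a, abs=1e-8
        )


class TestFit:
    def test_zero_variance_fit_matches_statsmodels_glm(self, default_cohort):
        import statsmodels.api as sm

        cohort, _ = default_cohort
        spec, k = _pre_spec(cohort)
        fixed_only = glmm.ModelSpec(
            spec.X, spec.x_names, np.empty((len(k), 0)), [], spec.groups,
            spec.group_labels, spec.offset,
        )
        ours = glmm.fit(fixed_only, k)
        ref = sm.GLM(
            k, spec.X, family=sm.families.Poisson(), offset=spec.offset
        ).fit()
        np.testing.assert_allclose(ours.beta, ref.params, atol=1e-6)
        np.testing.assert_allclose(ours.se_beta, ref.bse, atol=1e-5)
        assert ours.loglik == pytest.approx(ref.llf, abs=1e-6)

    def test_loglik_not_worse_than_start(self, pre_fit_full, default_cohort):
        cohort, _ = default_cohort
        spec, k = _pre_spec(cohort)
        beta0, _, _ = glmm.poisson_glm_irls(spec.X, k, spec.offset)
        start = glmm.pack_params(beta0, [0.3, 0.3], 0.0)
        ll_start = glmm.marginal_loglik(start, spec, k)
        assert pre_fit_full.fit.loglik >= ll_start

    def test_refit_from_optimum_is_fixed_point(self, pre_fit_full, default_cohort):
        cohort, _ = default_cohort
        spec, k = _pre_spec(cohort)
        again = glmm.fit(spec, k, start=pre_fit_full.fit.params, compute_se=False)
        np.testing.assert_allclose(
            again.params, pre_fit_full.fit.params, atol=1e-6
        )

    def test_vcov_symmetric_psd_and_sigma_bounds(self, pre_fit_full):
        f = pre_fit_full.fit
        V = np.asarray(f.vcov_beta)
        np.testing.assert_allclose(V, V.T, atol=1e-12)
        assert np.all(np.linalg.eigvalsh(V) > -1e-10)
        assert np.all(f.sigmas >= 0) and abs(f.rho) <= 1

    def test_single_row_subjects_allowed(self):
        # intercept-only random effect, one observation per subject
        rng = np.random.default_rng(2)
        m = 30
        X = np.ones((m, 1))
        off = np.log(np.full(m, 4000.0))
        u = rng.normal(0, 0.5, m)
        k = rng.poisson(np.exp(-5.5 + u + off))
        spec = glmm.ModelSpec(
            X, ["const"], np.ones((m, 1)), ["const"], np.arange(m),
            [f"S{i}" for i in range(m)], off,
        )
        f = glmm.fit(spec, k)
        assert f.converged and -6.5 < f.beta[0] < -4.5


class TestEmpiricalBayes:
    def test_posterior_mean_matches_grid_oracle_single_subject(self):
        X = np.array([[1.0]])
        off = np.log(np.array([3000.0]))
        spec = glmm.ModelSpec(
            X, ["const"], np.ones((1, 1)), ["const"], np.array([0]), ["a"], off
        )
        k = np.array([9.0])
        beta = np.array([-5.6])
        sigma0 = 0.6
        fitlike = glmm.MixedPoissonFit(
            spec=spec, counts=k, params=glmm.pack_params(beta, [sigma0]),
            beta=beta, se_beta=np.array([np.nan]),
            vcov_beta=np.full((1, 1), np.nan), sigmas=np.array([sigma0]),
            se_sigmas=np.array([np.nan]), rho=0.0, se_rho=np.nan,
            loglik=np.nan, quad_order=15, converged=True, n_iter=0,
        )
        eb = glmm.empirical_bayes(fitlike, quad_order=25)
        u = np.linspace(-6 * sigma0, 6 * sigma0, 200001)
        eta = beta[0] + off[0] + u
        w = np.exp(k[0] * eta - np.exp(eta)) * norm.pdf(u, 0, sigma0)
        oracle = np.trapezoid(u * w, u) / np.trapezoid(w, u)
        assert eb.mean[0, 0] == pytest.approx(oracle, abs=1e-6)

    def test_shrinkage_to_zero_with_vanishing_prior(self, default_cohort):
        cohort, _ = default_cohort
        spec, k = _pre_spec(cohort)
        params = glmm.pack_params(
            np.array([-5.7, 4.1, 0.03, 0.17]), [1e-4, 1e-4], 0.0
        )
        fitlike = glmm.MixedPoissonFit(
            spec=spec, counts=k, params=params, beta=params[:4],
            se_beta=np.full(4, np.nan), vcov_beta=np.full((4, 4), np.nan),
            sigmas=np.array([1e-4, 1e-4]), se_sigmas=np.full(2, np.nan),
            rho=0.0, se_rho=np.nan, loglik=np.nan, quad_order=7,
            converged=True, n_iter=0,
        )
        eb = glmm.empirical_bayes(fitlike)
        assert np.max(np.abs(eb.mean)) < 1e-3

    def test_subject_with_no_data_gets_prior_mean(self):
        X = np.ones((2, 1))
        off = np.zeros(2)
        spec = glmm.ModelSpec(
            X, ["const"], np.ones((2, 1)), ["const"], np.array([0, 0]),
            ["a", "b"], off,  # subject "b" contributes no rows
        )
        k = np.array([3.0, 4.0])
        f = glmm.fit(spec, k, compute_se=False)
        eb = glmm.empirical_bayes(f)
        assert eb.mean[1, 0] == pytest.approx(0.0, abs=1e-10)

    def test_eb_means_center_near_zero(self, pre_fit_full):
        eb = pre_fit_full.eb
        assert abs(eb.mean[:, 0].mean()) < 0.05
        assert abs(eb.mean[:, 1].mean()) < 0.05


class TestPredictRate:
    def test_zero_coefficients_give_unit_rate(self):
        f = glmm.MixedPoissonFit.from_coefficients(
            ["const", "dose"], [0.0, 0.0], vcov=np.zeros((2, 2))
        )
        rate, lo, hi = glmm.predict_rate(f, {"dose": 0.3})
        assert rate == 1.0 and lo == 1.0 and hi == 1.0

    def test_missing_covariate_raises(self):
        f = glmm.MixedPoissonFit.from_coefficients(["const", "dose"], [0.0, 1.0])
        with pytest.raises(ValueError, match="dose"):
            glmm.predict_rate(f, {})

    def test_ci_uses_fixed_effect_covariance(self):
        V = np.array([[0.04, 0.0], [0.0, 0.0]])
        f = glmm.MixedPoissonFit.from_coefficients(["const", "dose"], [-5.0, 2.0], vcov=V)
        rate, lo, hi = glmm.predict_rate(f, {"dose": 0.0})
        assert rate == pytest.approx(np.exp(-5.0))
        assert lo == pytest.approx(np.exp(-5.0 - 1.96 * 0.2), rel=1e-3)
        assert hi == pytest.approx(np.exp(-5.0 + 1.96 * 0.2), rel=1e-3)


@settings(derandomize=True, max_examples=60, deadline=None)
@given(
    beta=st.lists(st.floats(-6, 6), min_size=1, max_size=4),
    s0=st.floats(0.01, 3.0),
    s1=st.floats(0.01, 3.0),
    rho=st.floats(-0.95, 0.95),
)
def test_pack_unpack_round_trip(beta, s0, s1, rho):
    params = glmm.pack_params(np.array(beta), [s0, s1], rho)
    b, s, r, Sigma = glmm.unpack_params(params, len(beta), 2)
    np.testing.assert_allclose(b, beta)
    np.testing.assert_allclose(s, [s0, s1], rtol=1e-12)
    assert r == pytest.approx(rho, abs=1e-12)
    assert np.linalg.det(Sigma) > 0
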