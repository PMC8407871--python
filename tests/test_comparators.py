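"""LMM (ML) and GEE comparator fits, likelihood values, information criteria."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal

import spmlong as sl
from spmlong.comparators import (chol_params_to_tau, information_criteria,
                                 lmm_loglik, lmm_subject_loglik,
                                 tau_to_chol_params)
from spmlong.data_model import ConfigurationError, build_designs


@pytest.mark.parametrize("loglik,p,n,aic,bic", [
    (-100.0, 5, 50, 210.0, 200.0 + 5 * np.log(50)),
    (-42.0, 0, 10, 84.0, 84.0),
    (-1.0, 1, int(round(np.e ** 2)), 4.0, 2.0 + np.log(round(np.e ** 2))),
])
def test_information_criteria_closed_form(loglik, p, n, aic, bic):
    a, b = information_criteria(loglik, p, n)
    assert a == pytest.approx(aic)
    assert b == pytest.approx(bic, abs=1e-9)


def test_tau_cholesky_parameterization_roundtrip():
    tau = np.array([[0.81, 0.0416], [0.0416, 0.0237]])
    np.testing.assert_allclose(chol_params_to_tau(tau_to_chol_params(tau), 2),
                               tau, atol=1e-10)


class TestLMMLoglik:
    def test_single_obs_standard_normal_density(self):
        ll = lmm_subject_loglik(np.array([0.0]), 1.0, np.array([[1e-300]]),
                                np.ones((1, 1)), np.ones((1, 1)),
                                np.array([0.0]))
        assert ll == pytest.approx(np.log(1.0 / np.sqrt(2 * np.pi)))

    def test_matches_bivariate_normal_closed_form(self):
        X = np.array([[1.0, 0.0], [1.0, 6.0]])
        Z = X.copy()
        y = np.array([0.3, -0.5])
        beta = np.array([0.1, -0.05])
        tau = np.array([[0.5, 0.05], [0.05, 0.02]])
        V = Z @ tau @ Z.T + 0.35 ** 2 * np.eye(2)
        expected = multivariate_normal(X @ beta, V).logpdf(y)
        assert lmm_subject_loglik(beta, 0.35, tau, X, Z, y) == \
            pytest.approx(expected, rel=1e-12)

    def test_vectorized_total_matches_per_subject_sum(self, xmar_small, spec):
        data, _ = xmar_small
        b = build_designs(data, spec)
        beta = np.array([-0.1, -0.05, -0.3, -0.007, -0.02])
        tau = np.array([[0.8, 0.04], [0.04, 0.02]])
        total = lmm_loglik(beta, 0.35, tau, b)
        direct = 0.0
        for i in range(b.n_subjects):
            m = b.subject_index == i
            direct += lmm_subject_loglik(beta, 0.35, tau, b.X[m], b.Z[m], b.y[m])
        assert total == pytest.approx(direct, rel=1e-12)

    def test_invariant_to_subject_ordering(self, xmar_small, spec):
        data, _ = xmar_small
        rev = sl.PanelDataset(tuple(reversed(data.subjects)),
                              data.covariate_names, allow_empty_subjects=True)
        beta = np.array([-0.1, -0.05, -0.3, -0.007, -0.02])
        tau = np.array([[0.8, 0.04], [0.04, 0.02]])
        assert lmm_loglik(beta, 0.35, tau, build_designs(data, spec)) == \
            pytest.approx(lmm_loglik(beta, 0.35, tau, build_designs(rev, spec)),
                          rel=1e-12)


class TestFitLMM:
    def test_noise_free_data_recovered_exactly(self):
        rng = np.random.default_rng(0)
        subs = []
        for i in range(30):
            ts = np.array([0.0, 5.0, 10.0])
            subs.append(sl.SubjectRecord(f"s{i}", np.array([float(i % 2)]),
                                         ts, 2.0 + 3.0 * ts, None))
        data = sl.PanelDataset(tuple(subs), ("x1",))
        fit = sl.fit_lmm(data, sl.ModelSpec(exposure="x1"))
        assert fit.params["intercept"] == pytest.approx(2.0, abs=1e-5)
        assert fit.params["time"] == pytest.approx(3.0, abs=1e-5)
        assert fit.params["sigma"] < 1e-4
        assert fit.params["tau_00"] < 1e-4

    def test_loglik_beats_brute_force_grid(self):
        """ML optimum dominates a dense grid over (beta, sigma, tau)."""
        rng = np.random.default_rng(3)
        subs = []
        for i in range(3):
            ts = np.array([0.0, 8.0])
            y = 1.0 - 0.1 * ts + rng.normal(0, 0.5, 2) + rng.normal(0, 0.5)
            subs.append(sl.SubjectRecord(f"s{i}", np.array([0.5 * i]), ts, y, None))
        data = sl.PanelDataset(tuple(subs), ("x1",))
        spec = sl.ModelSpec(exposure="x1", random_effects="intercept")
        fit = sl.fit_lmm(data, spec)
        bundle = build_designs(data, spec)
        best_grid = -np.inf
        b0 = fit.extras["beta"]
        for d0 in np.linspace(-0.5, 0.5, 7):
            for d1 in np.linspace(-0.05, 0.05, 7):
                for s in np.linspace(0.1, 1.2, 10):
                    for t in np.linspace(0.01, 1.5, 10):
                        beta = b0 + np.array([d0, d1, 0, 0])
                        best_grid = max(best_grid, lmm_loglik(
                            beta, s, np.array([[t]]), bundle))
        assert fit.loglik >= best_grid - 1e-9

    def test_parameter_recovery_without_dropout(self, truth, spec):
        data, _ = sl.simulate_cohort(
            sl.SimConfig(n=500, mechanism="none", seed=21), truth)
        fit = sl.fit_lmm(data, spec)
        tv = sl.truth_values(truth)
        for name in ("time", "atrophy:time"):
            assert abs(fit.params[name] - tv[name]) < 3 * fit.se(name)
        assert fit.params["sigma"] == pytest.approx(truth.params.sigma, abs=0.02)
        assert fit.params["tau_00"] == pytest.approx(truth.params.tau[0, 0],
                                                     abs=0.15)

    def test_total_loglik_consistent_with_subject_sum_at_optimum(
            self, lmm_fit_small, xmar_small, spec):
        data, _ = xmar_small
        fit = lmm_fit_small
        bundle = build_designs(data, spec)
        assert fit.loglik == pytest.approx(
            lmm_loglik(fit.extras["beta"], fit.extras["sigma"],
                       fit.extras["tau"], bundle), rel=1e-10)

    def test_matches_statsmodels_mixedlm(self, truth, spec):
        import statsmodels.formula.api as smf
        data, _ = sl.simulate_cohort(
            sl.SimConfig(n=300, mechanism="none", seed=17), truth)
        fit = sl.fit_lmm(data, spec)
        panel, _ = data.to_frames()
        panel["at_t"] = panel["atrophy"] * panel["time"]
        sm_fit = smf.mixedlm("y ~ time + atrophy + at_t + age_c", panel,
                             groups=panel["id"], re_formula="~time"
                             ).fit(reml=False)
        assert fit.loglik >= sm_fit.llf - 1e-6
        np.testing.assert_allclose(fit.extras["beta"],
                                   sm_fit.fe_params.values, atol=2e-4)

    def test_single_visit_slope_design_is_estimation_error(self):
        subs = [sl.SubjectRecord(f"s{i}", np.array([float(i % 2)]),
                                 np.array([float(i % 3)]), np.array([0.1 * i]),
                                 None) for i in range(12)]
        data = sl.PanelDataset(tuple(subs), ("x1",))
        with pytest.raises(sl.DataError, match="intercept"):
            sl.fit_lmm(data, sl.ModelSpec(exposure="x1"))


class TestFitGEE:
    @staticmethod
    def _single_visit_data(n=60, seed=5):
        rng = np.random.default_rng(seed)
        subs = []
        for i in range(n):
            t = float(rng.integers(0, 4))
            x = float(rng.random() < 0.4)
            y = 0.5 - 0.1 * t - 0.2 * x + rng.normal(0, 0.7)
            subs.append(sl.SubjectRecord(f"s{i}", np.array([x]),
                                         np.array([t]), np.array([y]), None))
        return sl.PanelDataset(tuple(subs), ("x1",))

    def test_independent_single_visit_reduces_to_ols(self):
        data = self._single_visit_data()
        spec = sl.ModelSpec(exposure="x1", random_effects="intercept")
        fit = sl.fit_gee(data, spec, "independent")
        bundle = build_designs(data, spec)
        ols = np.linalg.lstsq(bundle.X, bundle.y, rcond=None)[0]
        np.testing.assert_allclose(fit.extras["beta"], ols, atol=1e-8)

    def test_sandwich_matches_robust_ols_covariance(self):
        import statsmodels.api as sm
        data = self._single_visit_data()
        spec = sl.ModelSpec(exposure="x1", random_effects="intercept")
        fit = sl.fit_gee(data, spec, "independent")
        bundle = build_designs(data, spec)
        ols = sm.OLS(bundle.y, bundle.X).fit(cov_type="HC0")
        np.testing.assert_allclose(fit.cov, ols.cov_params(), rtol=1e-6)
        assert np.allclose(fit.cov, fit.cov.T)
        assert np.all(np.linalg.eigvalsh(fit.cov) > -1e-12)

    def test_exchangeable_correlation_matches_moment_formula(self, truth):
        data, _ = sl.simulate_cohort(
            sl.SimConfig(n=300, mechanism="none", jitter=0.0, seed=9), truth)
        spec = sl.default_spec()
        fit = sl.fit_gee(data, spec, "exchangeable")
        bundle = build_designs(data, spec)
        r = (bundle.y - bundle.X @ fit.extras["beta"]) / np.sqrt(fit.extras["scale"])
        num = den = 0.0
        for i in range(bundle.n_subjects):
            ri = r[bundle.subject_index == i]
            n = len(ri)
            num += (ri.sum() ** 2 - ri @ ri) / 2.0
            den += n * (n - 1) / 2.0
        hand = num / den
        assert fit.extras["dep_params"] == pytest.approx(hand, rel=0.05)

    def test_agrees_with_lmm_on_complete_data(self, truth, spec):
        data, _ = sl.simulate_cohort(
            sl.SimConfig(n=400, mechanism="none", seed=13), truth)
        lmm = sl.fit_lmm(data, spec)
        for corr in ("independent", "exchangeable", "ar1"):
            gee = sl.fit_gee(data, spec, corr)
            assert gee.params["atrophy:time"] == pytest.approx(
                lmm.params["atrophy:time"], abs=1e-3)

    def test_unstructured_without_schedule_is_configuration_error(
            self, xmar_small, spec):
        data, _ = xmar_small
        with pytest.raises(ConfigurationError, match="schedule"):
            sl.fit_gee(data, spec, "unstructured", waves=None)

    def test_no_likelihood_criteria_reported(self, xmar_small, spec):
        data, _ = xmar_small
        fit = sl.fit_gee(data, spec)
        assert fit.loglik is None and fit.aic is None and fit.bic is None
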