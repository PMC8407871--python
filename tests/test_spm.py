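"""Joint shared-parameter likelihood, adaptive quadrature, and ML fitting."""

import numpy as np
import pytest

import spmlong as sl
from spmlong.comparators import lmm_subject_loglik
from spmlong.data_model import build_designs
from spmlong.hazard import BaselineHazard, HazardParams, cumulative_hazard, \
    event_loglik
from spmlong.mc import mc_marginal_logliks
from spmlong.spm import (CauseParams, QuadratureRule, SPMParams,
                         subject_conditional_loglik, subject_marginal_logliks)


def _params(rho=(-0.9, -0.5), log_rate=np.log(0.012), causes=1):
    cs = [CauseParams(np.array([0.588, 0.05]),
                      BaselineHazard("exponential", (log_rate,)),
                      np.asarray(rho, dtype=float))]
    if causes == 2:
        cs.append(CauseParams(np.array([0.3, 0.07]),
                              BaselineHazard("exponential", (np.log(0.015),)),
                              np.array([-0.3, -0.2])))
    return SPMParams(np.array([-0.129, -0.0476, -0.30, -0.0067, -0.02]),
                     0.35, np.array([[0.81, 0.0416], [0.0416, 0.0237]]),
                     tuple(cs))


@pytest.fixture(scope="module")
def bundle(xmar_small, spec):
    data, _ = xmar_small
    return build_designs(data, spec)


class TestConditionalLoglik:
    def test_no_event_equals_gaussian_density(self, bundle):
        p = SPMParams(_params().beta, 0.35, _params().tau, ())
        b = np.array([0.4, -0.05])
        i = 3
        m = bundle.subject_index == i
        direct = 0.0
        mu = bundle.X[m] @ p.beta + bundle.Z[m] @ b
        direct = float(np.sum(-0.5 * np.log(2 * np.pi * 0.35 ** 2)
                              - 0.5 * ((bundle.y[m] - mu) / 0.35) ** 2))
        assert subject_conditional_loglik(p, bundle, i, b) == \
            pytest.approx(direct, abs=1e-12)

    def test_zero_visit_subject_reduces_to_event_term(self):
        subs = (sl.SubjectRecord("a", np.array([1.0, 0.3]), np.empty(0),
                                 np.empty(0), sl.EventRecord(12.0, (0,))),)
        data = sl.PanelDataset(subs, ("atrophy", "age_c"),
                               allow_empty_subjects=True)
        b = build_designs(data, sl.default_spec())
        p = _params()
        bval = np.array([0.2, 0.1])
        cp = p.causes[0]
        eta = np.array([1.0, 0.3]) @ cp.alpha + cp.rho @ bval
        expected = -float(cumulative_hazard(cp.baseline, 12.0)) * np.exp(eta)
        assert subject_conditional_loglik(p, b, 0, bval) == \
            pytest.approx(expected, rel=1e-12)

    def test_single_visit_subject_hand_computation(self):
        subs = (sl.SubjectRecord("a", np.array([1.0, 0.5]), np.array([6.0]),
                                 np.array([-0.7]), sl.EventRecord(9.0, (1,))),)
        data = sl.PanelDataset(subs, ("atrophy", "age_c"))
        b = build_designs(data, sl.default_spec())
        p = _params()
        bval = np.array([-0.3, 0.02])
        mu = (p.beta[0] + p.beta[1] * 6 + p.beta[2] * 1 + p.beta[3] * 6 * 1
              + p.beta[4] * 0.5) + bval[0] + 6 * bval[1]
        hand = -0.5 * np.log(2 * np.pi * 0.35 ** 2) - (-0.7 - mu) ** 2 / (2 * 0.35 ** 2)
        eta = 0.588 * 1 + 0.05 * 0.5 + (-0.9) * bval[0] + (-0.5) * bval[1]
        hand += np.log(0.012) + eta - 0.012 * 9.0 * np.exp(eta)
        assert subject_conditional_loglik(p, b, 0, bval) == \
            pytest.approx(hand, abs=1e-12)


class TestMarginalLoglik:
    def test_quadrature_weights_integrate_the_prior_to_one(self):
        """A subject with no data has marginal likelihood exactly 1."""
        subs = (sl.SubjectRecord("a", np.array([0.0, 0.0]), np.empty(0),
                                 np.empty(0), None),)
        data = sl.PanelDataset(subs, ("atrophy", "age_c"),
                               allow_empty_subjects=True)
        b = build_designs(data, sl.default_spec())
        ll = subject_marginal_logliks(_params(), b, rule=QuadratureRule(9, 2),
                                      adaptive=False)
        assert abs(ll[0]) < 1e-10

    def test_zero_loading_factorizes(self, bundle):
        """rho = 0: joint marginal = LMM marginal x event likelihood, per subject."""
        p0 = _params(rho=(0.0, 0.0))
        lm = subject_marginal_logliks(p0, bundle, rule=QuadratureRule(15, 2))
        cp = p0.causes[0]
        hp = HazardParams(cp.alpha, cp.baseline)
        for i in range(15):
            m = bundle.subject_index == i
            ll_long = lmm_subject_loglik(p0.beta, p0.sigma, p0.tau,
                                         bundle.X[m], bundle.Z[m], bundle.y[m])
            eta = float(bundle.X_haz[i] @ cp.alpha)
            ll_ev = float(event_loglik(hp, eta, bundle.event_time[i],
                                       bundle.status[i, 0]))
            assert lm[i] == pytest.approx(ll_long + ll_ev, abs=1e-8)

    def test_vanishing_tau_collapses_to_conditional_at_zero(self, bundle):
        # the exact marginal is cond(0) + g' tau g / 2 + O(tau^2); the slope
        # score can reach ~2.5e3 here, so tau = 1e-13 keeps the analytic
        # correction below the 1e-6 comparison tolerance
        p = SPMParams(_params().beta, 0.35, np.eye(2) * 1e-13, _params().causes)
        lm = subject_marginal_logliks(p, bundle, rule=QuadratureRule(9, 2))
        for i in range(10):
            cond0 = subject_conditional_loglik(p, bundle, i, np.zeros(2))
            assert lm[i] == pytest.approx(cond0, abs=1e-6)

    def test_matches_monte_carlo_oracle(self, bundle):
        p = _params()
        idx = np.arange(10)
        gh = subject_marginal_logliks(p, bundle, rule=QuadratureRule(15, 2))[idx]
        mc = mc_marginal_logliks(p, bundle, idx, n_draws=200_000, seed=3)
        rel_err = np.abs(np.exp(gh - mc) - 1.0)
        assert np.max(rel_err) < 3e-3

    def test_matches_dense_grid_integration(self, bundle):
        """Trapezoid integration over a 2-D grid agrees to 4 significant digits."""
        p = _params()
        gh = subject_marginal_logliks(p, bundle, rule=QuadratureRule(15, 2))
        g0 = np.linspace(-4.5, 4.5, 401)
        g1 = np.linspace(-0.8, 0.8, 401)
        B = np.array(np.meshgrid(g0, g1, indexing="ij")).reshape(2, -1).T
        from scipy.stats import multivariate_normal
        log_prior = multivariate_normal(np.zeros(2), p.tau).logpdf(B)
        for i in range(5):
            m = bundle.subject_index == i
            mu = bundle.X[m] @ p.beta
            resid = bundle.y[m][None, :] - mu[None, :] - B @ bundle.Z[m].T
            lc = (-0.5 * len(mu) * np.log(2 * np.pi * p.sigma ** 2)
                  - 0.5 * np.sum(resid ** 2, axis=1) / p.sigma ** 2)
            cp = p.causes[0]
            eta = bundle.X_haz[i] @ cp.alpha + B @ cp.rho
            H = float(cumulative_hazard(cp.baseline, bundle.event_time[i]))
            d = bundle.status[i, 0]
            lc += d * (np.log(0.012) + eta) - H * np.exp(eta)
            integrand = np.exp(lc + log_prior).reshape(len(g0), len(g1))
            val = np.trapezoid(np.trapezoid(integrand, g1, axis=1), g0)
            assert gh[i] == pytest.approx(np.log(val), abs=5e-5)

    def test_additivity_under_dataset_duplication(self, xmar_small, spec):
        data, _ = xmar_small
        p = _params()
        single = sl.spm_loglik(p, data, spec, QuadratureRule(9, 2))
        doubled = sl.PanelDataset(
            tuple(list(data.subjects) +
                  [sl.SubjectRecord(s.id + "_dup", s.x_base, s.times, s.y,
                                    s.event) for s in data.subjects]),
            data.covariate_names, allow_empty_subjects=True)
        assert sl.spm_loglik(p, doubled, spec, QuadratureRule(9, 2)) == \
            pytest.approx(2 * single, rel=1e-12)

    @pytest.mark.parametrize("Q", [9, 13])
    def test_quadrature_converged_by_order_nine(self, bundle, Q):
        p = _params()
        a = subject_marginal_logliks(p, bundle, rule=QuadratureRule(Q, 2))
        b = subject_marginal_logliks(p, bundle, rule=QuadratureRule(Q + 4, 2))
        assert np.max(np.abs(a - b)) < 1e-4

    def test_outcome_rescaling_is_exact_reparameterization(self, xmar_small, spec):
        """y -> c y with (beta, sigma) -> c(beta, sigma), rho -> rho/c shifts
        the log-likelihood by exactly -n_obs log c (change of variables)."""
        data, _ = xmar_small
        c = 2.5
        p = _params()
        scaled = sl.PanelDataset(
            tuple(sl.SubjectRecord(s.id, s.x_base, s.times, c * s.y, s.event)
                  for s in data.subjects),
            data.covariate_names, allow_empty_subjects=True)
        # beta scales by c except covariate columns stay in original units:
        # the whole linear predictor scales, so every beta entry scales by c
        p_scaled = SPMParams(c * p.beta, c * p.sigma, c ** 2 * p.tau,
                             tuple(CauseParams(cp.alpha, cp.baseline, cp.rho / c)
                                   for cp in p.causes))
        ll = sl.spm_loglik(p, data, spec, QuadratureRule(11, 2))
        ll_scaled = sl.spm_loglik(p_scaled, scaled, spec, QuadratureRule(11, 2))
        n_obs = sum(s.n_visits for s in data.subjects)
        assert ll_scaled == pytest.approx(ll - n_obs * np.log(c), abs=1e-7)


class TestFitSPM:
    def test_zero_coupling_fit_separates(self, truth, spec):
        """All rho fixed at 0: joint fit reproduces separate LMM + PH fits."""
        data, _ = sl.simulate_cohort(
            sl.SimConfig(n=150, mechanism="xmar", seed=31), truth)
        spm0 = sl.fit_spm(data, spec, sl.SPMOptions(
            baseline="exponential", fix_rho="zero", compute_se=False))
        lmm = sl.fit_lmm(data, spec)
        ph = sl.fit_ph(data, spec, baseline="exponential")
        np.testing.assert_allclose(spm0.extras["beta"], lmm.extras["beta"],
                                   atol=1e-4)
        assert spm0.extras["sigma"] == pytest.approx(lmm.extras["sigma"],
                                                     abs=1e-4)
        np.testing.assert_allclose(spm0.extras["tau"], lmm.extras["tau"],
                                   atol=1e-4)
        np.testing.assert_allclose(
            [spm0.params["alpha_atrophy"], spm0.params["alpha_age_c"]],
            ph.extras["alpha"], atol=1e-4)
        assert spm0.loglik == pytest.approx(lmm.loglik + ph.loglik, abs=1e-6)

    def test_fit_reports_loading_hazard_ratios(self, spm_fit_small):
        fit = spm_fit_small
        assert fit.converged
        assert len(fit.loading_hr) == 2
        hr0 = fit.loading_hr[0]
        assert hr0.hr_adverse == pytest.approx(
            np.exp(abs(fit.params["rho_0"]) * np.sqrt(fit.params["tau_00"])),
            rel=1e-10)
        assert hr0.ci[0] < hr0.hr_adverse < hr0.ci[1]

    def test_competing_likelihood_reduces_when_second_cause_vanishes(
            self, xmar_small, spec):
        data, _ = xmar_small
        b = build_designs(data, spec)
        p1 = _params()
        p2 = SPMParams(p1.beta, p1.sigma, p1.tau, (
            p1.causes[0],
            CauseParams(np.zeros(2), BaselineHazard("exponential", (-600.0,)),
                        np.zeros(2))))
        l1 = subject_marginal_logliks(p1, b, rule=QuadratureRule(9, 2))
        l2 = subject_marginal_logliks(p2, b, rule=QuadratureRule(9, 2))
        np.testing.assert_allclose(l1, l2, atol=1e-8)

    def test_competing_cause_without_events_is_estimation_error(
            self, xmar_small, spec):
        data, _ = xmar_small
        with pytest.raises(sl.DataError, match="cause"):
            sl.fit_spm(data, spec, sl.SPMOptions(causes=2))

    def test_competing_risks_recovery_single_cohort(self, spec):
        truth2 = sl.default_true_params(competing=True)
        data, _ = sl.simulate_cohort(
            sl.SimConfig(n=800, mechanism="xmar_competing", seed=41), truth2)
        fit = sl.fit_spm_competing(data, spec,
                                   sl.SPMOptions(baseline="exponential"))
        assert fit.converged
        for name, tv in [("rho_0_c1", -0.9), ("rho_0_c2", -0.3),
                         ("atrophy:time", -0.0067)]:
            est = fit.free_values[list(fit.free_names).index(name)]
            assert abs(est - tv) < 3 * fit.se(name), name
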