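"""MCAR and MAR comparator fits: GEE (marginal, sandwich SEs) and ML linear mixed model.

The mixed model is fitted by maximum likelihood (not REML) so its
log-likelihood, AIC and BIC are directly comparable with the joint
shared-parameter model's.  The GEE comparator wraps statsmodels' GEE with a
selectable working correlation and robust (sandwich) covariance; being
quasi-likelihood based it reports no likelihood criteria.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve

from . import _numdiff
from .data_model import (ConfigurationError, DataError, DesignBundle, ModelSpec,
                         PanelDataset, assign_waves, build_designs, DEFAULT_WAVES)
from .results import FitResult, information_criteria

__all__ = [
    "fit_lmm", "fit_gee", "lmm_subject_loglik", "information_criteria",
    "FitResult", "lmm_loglik", "tau_to_chol_params", "chol_params_to_tau",
]

_LOG_SD_MIN, _LOG_SD_MAX = -9.5, 8.0   # SD-scale parameters bounded in (7.5e-5, e^8)


# ------------------------------------------------------------- tau parameterization

def chol_params_to_tau(params: np.ndarray, q: int) -> np.ndarray:
    """Unconstrained vector -> PSD random-effect covariance (via Cholesky).

    q=1: [log L00]; q=2: [log L00, L10, log L11] with tau = L L'.
    """
    L = np.zeros((q, q))
    if q == 1:
        L[0, 0] = np.exp(params[0])
    else:
        L[0, 0] = np.exp(params[0])
        L[1, 0] = params[1]
        L[1, 1] = np.exp(params[2])
    return L @ L.T


def tau_to_chol_params(tau: np.ndarray) -> np.ndarray:
    tau = np.atleast_2d(np.asarray(tau, dtype=float))
    q = tau.shape[0]
    L = np.linalg.cholesky(tau + 1e-12 * np.eye(q))
    if q == 1:
        return np.array([np.log(L[0, 0])])
    return np.array([np.log(L[0, 0]), L[1, 0], np.log(L[1, 1])])


def n_chol_params(q: int) -> int:
    return q * (q + 1) // 2


# ------------------------------------------------------------------ LMM likelihood

def lmm_subject_loglik(beta: np.ndarray, sigma: float, tau: np.ndarray,
                       X: np.ndarray, Z: np.ndarray, y: np.ndarray) -> float:
    """Marginal Gaussian log-density of one subject's outcome vector.

    Mean X beta, covariance Z tau Z' + sigma^2 I.  A subject with zero visits
    contributes 0.
    """
    n = y.size
    if n == 0:
        return 0.0
    r = y - X @ beta
    V = Z @ np.atleast_2d(tau) @ Z.T + sigma ** 2 * np.eye(n)
    try:
        c, low = cho_factor(V, lower=True)
    except np.linalg.LinAlgError as exc:
        cond = np.linalg.cond(V)
        raise np.linalg.LinAlgError(
            f"singular marginal covariance (cond={cond:.3g})") from exc
    logdet = 2.0 * np.sum(np.log(np.diag(c)))
    quad = r @ cho_solve((c, low), r)
    return float(-0.5 * (n * np.log(2.0 * np.pi) + logdet + quad))


def _per_subject_arrays(bundle: DesignBundle):
    out = []
    for i in range(bundle.n_subjects):
        m = bundle.subject_index == i
        out.append((bundle.X[m], bundle.Z[m], bundle.y[m]))
    return out


class _LMMStats:
    """Parameter-free per-subject sufficient statistics for the marginal likelihood.

    With V_i = sigma^2 I + Z tau Z', Woodbury reduces every likelihood and GLS
    quantity to the blocks X'X, X'Z, X'y, Z'Z, Z'y, y'y per subject, so
    repeated evaluation is a batched small-matrix computation.
    """

    def __init__(self, bundle: DesignBundle):
        X, Z, y, g = bundle.X, bundle.Z, bundle.y, bundle.subject_index
        N = bundle.n_subjects
        p, q = X.shape[1], Z.shape[1]
        self.N, self.p, self.q = N, p, q
        self.n_i = bundle.n_visits.astype(float)

        def blk(Acols, Bcols):
            out = np.empty((N, Acols.shape[1], Bcols.shape[1]))
            for a in range(Acols.shape[1]):
                for b in range(Bcols.shape[1]):
                    out[:, a, b] = np.bincount(g, weights=Acols[:, a] * Bcols[:, b],
                                               minlength=N) if len(g) else 0.0
            return out

        self.XtX = blk(X, X)
        self.XtZ = blk(X, Z)
        self.ZtZ = blk(Z, Z)
        self.Xty = blk(X, y[:, None])[:, :, 0]
        self.Zty = blk(Z, y[:, None])[:, :, 0]
        self.yty = np.bincount(g, weights=y * y, minlength=N) if len(g) else \
            np.zeros(N)

    def _M_inv(self, sigma: float, tau: np.ndarray):
        """Batched inverse of M_i = sigma^2 tau^{-1} + Z'Z and log|I + tau Z'Z / s^2|."""
        q = self.q
        s2 = sigma ** 2
        tinv = np.linalg.inv(tau)
        M = s2 * tinv[None, :, :] + self.ZtZ
        if q == 1:
            Minv = 1.0 / M
            logdet_corr = np.log(M[:, 0, 0] * tau[0, 0] / s2)
        else:
            a, b, c = M[:, 0, 0], M[:, 0, 1], M[:, 1, 1]
            det = a * c - b * b
            Minv = np.empty_like(M)
            Minv[:, 0, 0] = c / det
            Minv[:, 0, 1] = Minv[:, 1, 0] = -b / det
            Minv[:, 1, 1] = a / det
            # |V| = s^(2 n_i) |M tau| / s^(2q)
            sign, logdet_tau = np.linalg.slogdet(tau)
            logdet_corr = np.log(det) + logdet_tau - q * np.log(s2)
        return Minv, logdet_corr

    def profiled_beta(self, sigma: float, tau: np.ndarray) -> np.ndarray:
        Minv, _ = self._M_inv(sigma, tau)
        XZM = np.einsum("npq,nqr->npr", self.XtZ, Minv)
        A = np.sum(self.XtX - np.einsum("npq,nrq->npr", XZM, self.XtZ), axis=0)
        b = np.sum(self.Xty - np.einsum("npq,nq->np", XZM, self.Zty), axis=0)
        return np.linalg.solve(A, b)

    def loglik(self, beta: np.ndarray, sigma: float, tau: np.ndarray) -> float:
        s2 = sigma ** 2
        Minv, logdet_corr = self._M_inv(sigma, tau)
        Srr = self.yty - 2.0 * self.Xty @ beta + \
            np.einsum("p,npq,q->n", beta, self.XtX, beta)
        Szr = self.Zty - np.einsum("npq,p->nq", self.XtZ, beta)
        quad = (Srr - np.einsum("nq,nqr,nr->n", Szr, Minv, Szr)) / s2
        logdet = self.n_i * np.log(s2) + logdet_corr
        return float(np.sum(-0.5 * (self.n_i * np.log(2 * np.pi) + logdet + quad)))


def lmm_loglik(beta: np.ndarray, sigma: float, tau: np.ndarray,
               bundle: DesignBundle) -> float:
    """Total ML log-likelihood: sum of subject marginal log-densities."""
    return _LMMStats(bundle).loglik(np.asarray(beta, float), float(sigma),
                                    np.atleast_2d(tau))


def fit_lmm(data: PanelDataset, spec: ModelSpec, *, gtol: float = 1e-6,
            maxiter: int = 500) -> FitResult:
    """ML fit of the linear mixed longitudinal sub-model.

    Random intercept or intercept+slope per ``spec``; beta is profiled out by
    GLS and the variance parameters (log sigma, Cholesky of tau) maximized by
    quasi-Newton.  SEs come from the numerically differentiated observed
    information over the full free-parameter vector.
    """
    bundle = build_designs(data, spec)
    if bundle.n_subjects < 2 or bundle.n_obs < bundle.X.shape[1]:
        raise DataError("need at least 2 subjects with visits to fit the LMM")
    q = spec.n_random
    if q == 2 and int(np.max(bundle.n_visits)) < 2:
        raise DataError(
            "random slope requested but every subject has a single visit; "
            "use random_effects='intercept'")
    stats = _LMMStats(bundle)

    # variance-parameter start: residual SD split between sigma and tau
    beta0 = np.linalg.lstsq(bundle.X, bundle.y, rcond=None)[0]
    resid = bundle.y - bundle.X @ beta0
    s0 = max(float(np.std(resid)), 1e-3)
    if q == 1:
        th0 = np.array([np.log(s0 / np.sqrt(2)), np.log(s0 / np.sqrt(2))])
    else:
        th0 = np.array([np.log(s0 / np.sqrt(2)), np.log(s0 / np.sqrt(2)),
                        0.0, np.log(max(s0 / 20.0, 1e-3))])

    def negll_profiled(th):
        sigma = np.exp(th[0])
        tau = chol_params_to_tau(th[1:], q)
        try:
            beta = stats.profiled_beta(sigma, tau)
            return -stats.loglik(beta, sigma, tau)
        except np.linalg.LinAlgError:
            return 1e12

    bounds = [(_LOG_SD_MIN, _LOG_SD_MAX)] + \
        ([( _LOG_SD_MIN, _LOG_SD_MAX)] if q == 1 else
         [(_LOG_SD_MIN, _LOG_SD_MAX), (-50.0, 50.0), (_LOG_SD_MIN, _LOG_SD_MAX)])
    res = optimize.minimize(negll_profiled, th0, method="L-BFGS-B", jac="3-point",
                            bounds=bounds,
                            options={"maxiter": maxiter, "ftol": 1e-12, "gtol": gtol})
    th = res.x
    sigma = float(np.exp(th[0]))
    tau = chol_params_to_tau(th[1:], q)
    beta = stats.profiled_beta(sigma, tau)
    loglik = float(-res.fun)

    messages = []
    if np.exp(min(th[0], th[1])) < 1e-5:
        messages.append("variance component estimated near zero (boundary)")
    converged = bool(res.success) or float(np.max(np.abs(res.jac))) < 1e-3

    free_names = tuple(bundle.fixed_names) + ("log_sigma",) + tuple(
        f"ltau_{i}" for i in range(n_chol_params(q)))
    free = np.concatenate([beta, th])

    def full_negll(v):
        b = v[: beta.size]
        s = np.exp(v[beta.size])
        t = chol_params_to_tau(v[beta.size + 1:], q)
        return -stats.loglik(b, s, t)

    H = _numdiff.hessian(lambda v: -full_negll(v), free)
    cov, pd_ok = _numdiff.covariance_from_neg_hessian(H)
    if not pd_ok:
        messages.append("observed information not positive definite; SEs unreliable")

    p_free = free.size
    params = {**dict(zip(bundle.fixed_names, beta)), "sigma": sigma}
    for i in range(q):
        for j in range(i + 1):
            params[f"tau_{i}{j}"] = float(np.atleast_2d(tau)[i, j])
    return FitResult(model="lmm", params=params, free_names=free_names,
                     free_values=free, cov=cov, loglik=loglik, n_params=p_free,
                     n_subjects=bundle.n_subjects, n_obs=bundle.n_obs,
                     converged=converged, n_iter=int(res.nit),
                     grad_norm=float(np.max(np.abs(res.jac))), messages=messages,
                     extras={"tau": tau, "sigma": sigma, "beta": beta,
                             "spec": spec, "bundle": bundle})


# ------------------------------------------------------------------------- GEE

_CORR_FAMILIES = ("independent", "exchangeable", "ar1", "unstructured")


def fit_gee(data: PanelDataset, spec: ModelSpec, corr: str = "exchangeable", *,
            waves=DEFAULT_WAVES) -> FitResult:
    """Marginal (population-average) fit via GEE with robust sandwich SEs.

    ``corr`` selects the working correlation.  AR1 and unstructured
    correlations index occasions by scheduled wave number, so they need a
    declared ``waves`` schedule; passing ``waves=None`` for those families is a
    configuration error.
    """
    import statsmodels.api as sm
    from statsmodels.genmod.cov_struct import (Autoregressive, Exchangeable,
                                               Independence, Unstructured)

    if corr not in _CORR_FAMILIES:
        raise ConfigurationError(f"unknown working correlation {corr!r}; "
                                 f"choose from {_CORR_FAMILIES}")
    bundle = build_designs(data, spec)
    if bundle.n_obs == 0:
        raise DataError("no observed visits")

    time_arg = None
    if corr in ("ar1", "unstructured"):
        if waves is None:
            raise ConfigurationError(
                f"{corr} working correlation needs a declared wave schedule")
        w = assign_waves(bundle.t, waves)
        if np.any(w < 0):
            raise DataError("visits could not be matched to the wave schedule")
        time_arg = w[:, None]

    cov_struct = {"independent": Independence,
                  "exchangeable": Exchangeable,
                  "ar1": lambda: Autoregressive(grid=True),
                  "unstructured": Unstructured}[corr]()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GEE(bundle.y, bundle.X, groups=bundle.subject_index,
                       time=time_arg, family=sm.families.Gaussian(),
                       cov_struct=cov_struct)
        res = model.fit(maxiter=200)
    beta = np.asarray(res.params)
    cov = np.asarray(res.cov_params())
    params = dict(zip(bundle.fixed_names, beta))
    params["scale"] = float(res.scale)
    return FitResult(model=f"gee-{corr}", params=params,
                     free_names=tuple(bundle.fixed_names), free_values=beta,
                     cov=cov, loglik=None, n_params=beta.size,
                     n_subjects=bundle.n_subjects, n_obs=bundle.n_obs,
                     converged=bool(getattr(res, "converged", True)),
                     extras={"dep_params": getattr(res.cov_struct, "dep_params", None),
                             "scale": float(res.scale), "spec": spec,
                             "bundle": bundle, "beta": beta})
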