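"""Shared-parameter joint model: likelihood, adaptive quadrature, ML fitting.

The model couples a Gaussian linear mixed longitudinal sub-model

    y_ij = x_ij' beta + z_ij' b_i + e_ij,     e_ij ~ N(0, sigma^2)

with one or two cause-specific parametric proportional-hazards sub-models for
the censoring event(s)

    h_ik(t) = h_0k(t) exp(x*_i' alpha_k + rho_k' b_i)

through shared subject random effects b_i ~ MVN(0, tau).  The loading vector
rho_k multiplies the random effects directly, so given b_i the hazard's linear
predictor is time-fixed and the cumulative hazard is closed form.  Conditional
on b_i the longitudinal outcomes and event times are independent; dropout
driven by the event process is therefore ignorable given b_i ("extended MAR").

Each subject's marginal likelihood integrates the conditional likelihood over
b_i by adaptive Gauss-Hermite quadrature: nodes are recentered at the
subject's conditional posterior mode and rescaled by the local curvature,
which keeps a modest node count accurate even for subjects with many visits.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize

from . import _numdiff
from .comparators import (chol_params_to_tau, fit_lmm, n_chol_params,
                          tau_to_chol_params)
from .data_model import (DataError, DesignBundle, ModelSpec, PanelDataset,
                         build_designs)
from .hazard import (BaselineHazard, HazardParams, cumulative_hazard,
                     event_loglik, fit_ph, log_hazard)
from .results import FitResult

__all__ = ["CauseParams", "SPMParams", "QuadratureRule", "SPMOptions", "SPMFit",
           "subject_conditional_loglik", "subject_marginal_logliks", "spm_loglik",
           "fit_spm", "fit_spm_competing", "posterior_modes"]

_EXP_CLIP = 700.0


# ------------------------------------------------------------------- parameters

@dataclass(frozen=True)
class CauseParams:
    """Event sub-model parameters for one cause."""
    alpha: np.ndarray
    baseline: BaselineHazard
    rho: np.ndarray            # one loading per shared random effect

    def __post_init__(self):
        object.__setattr__(self, "alpha", np.asarray(self.alpha, dtype=float))
        object.__setattr__(self, "rho", np.asarray(self.rho, dtype=float))


@dataclass(frozen=True)
class SPMParams:
    """Full joint-model parameter vector."""
    beta: np.ndarray
    sigma: float
    tau: np.ndarray
    causes: tuple[CauseParams, ...]

    def __post_init__(self):
        object.__setattr__(self, "beta", np.asarray(self.beta, dtype=float))
        object.__setattr__(self, "tau", np.atleast_2d(np.asarray(self.tau, float)))
        object.__setattr__(self, "causes", tuple(self.causes))
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        q = self.tau.shape[0]
        for c in self.causes:
            if c.rho.size != q:
                raise ValueError("loading vector length must equal the "
                                 "random-effect dimension")

    @property
    def q(self) -> int:
        return self.tau.shape[0]


# ------------------------------------------------------------------- quadrature

@dataclass(frozen=True)
class QuadratureRule:
    """Tensor-product Gauss-Hermite rule used with adaptive recentering.

    ``z`` are the standard (physicists') nodes on a full d-dimensional grid;
    the adaptive transform evaluated per subject is b = mode + sqrt(2) L z
    with L the Cholesky factor of the inverse curvature at the mode.
    """
    order: int
    dim: int
    z: np.ndarray = field(init=False, repr=False)          # (M, dim)
    log_w: np.ndarray = field(init=False, repr=False)      # (M,) sum of log weights
    z_sq: np.ndarray = field(init=False, repr=False)       # (M,) |z|^2

    def __post_init__(self):
        if self.order < 1:
            raise ValueError("quadrature order must be >= 1")
        x, w = np.polynomial.hermite.hermgauss(self.order)
        grids = np.meshgrid(*([x] * self.dim), indexing="ij")
        z = np.column_stack([g.ravel() for g in grids])
        wgrids = np.meshgrid(*([np.log(w)] * self.dim), indexing="ij")
        lw = np.sum(np.column_stack([g.ravel() for g in wgrids]), axis=1)
        object.__setattr__(self, "z", z)
        object.__setattr__(self, "log_w", lw)
        object.__setattr__(self, "z_sq", np.sum(z * z, axis=1))

    @property
    def n_nodes(self) -> int:
        return len(self.z)


# --------------------------------------------------------------- prepared arrays

class _Prepared:
    """Per-dataset sufficient statistics for fast repeated likelihood evaluation."""

    def __init__(self, bundle: DesignBundle, n_causes: int):
        self.bundle = bundle
        self.N = bundle.n_subjects
        self.q = bundle.q
        self.K = n_causes
        self.subj = bundle.subject_index
        self.n_i = bundle.n_visits.astype(float)
        self.X, self.y, self.t = bundle.X, bundle.y, bundle.t
        # Z'Z entries per subject (Z = (1,) or (1, t))
        self.St = np.bincount(self.subj, weights=self.t, minlength=self.N) \
            if len(self.t) else np.zeros(self.N)
        self.Stt = np.bincount(self.subj, weights=self.t * self.t, minlength=self.N) \
            if len(self.t) else np.zeros(self.N)
        has_event = np.isfinite(bundle.event_time)
        self.has_event = has_event
        self.T = np.where(has_event, bundle.event_time, 0.0)
        self.delta = bundle.status.astype(float) * has_event[:, None]
        self.Xh = bundle.X_haz

    def resid_stats(self, beta: np.ndarray):
        r = self.y - self.X @ beta
        if len(r) == 0:
            z = np.zeros(self.N)
            return (z.copy(), z.copy(), z.copy())
        Srr = np.bincount(self.subj, weights=r * r, minlength=self.N)
        Sr = np.bincount(self.subj, weights=r, minlength=self.N)
        if self.q == 2:
            Str = np.bincount(self.subj, weights=self.t * r, minlength=self.N)
        else:
            Str = np.zeros(self.N)
        return Srr, Sr, Str


def _tau_inverse(tau: np.ndarray):
    q = tau.shape[0]
    tinv = np.linalg.inv(tau)
    sign, logdet = np.linalg.slogdet(tau)
    if sign <= 0:
        raise np.linalg.LinAlgError("tau not positive definite")
    return tinv, float(logdet)


def _solve_spd(A: np.ndarray, rhs: np.ndarray) -> np.ndarray:
    """Batched solve of (N,q,q) SPD systems against (N,q) right-hand sides."""
    q = A.shape[-1]
    if q == 1:
        return rhs / A[:, :, 0]
    a, b, c = A[:, 0, 0], A[:, 0, 1], A[:, 1, 1]
    det = a * c - b * b
    x0 = (c * rhs[:, 0] - b * rhs[:, 1]) / det
    x1 = (-b * rhs[:, 0] + a * rhs[:, 1]) / det
    return np.column_stack([x0, x1])


def _chol_of_inverse(A: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """For batched SPD A, return L with L L' = A^{-1} and log|L|."""
    q = A.shape[-1]
    if q == 1:
        L = (1.0 / np.sqrt(A))
        return L, np.log(L[:, 0, 0])
    a, b, c = A[:, 0, 0], A[:, 0, 1], A[:, 1, 1]
    det = a * c - b * b
    ia, ib, ic = c / det, -b / det, a / det
    l11 = np.sqrt(ia)
    l21 = ib / l11
    l22 = np.sqrt(np.maximum(ic - l21 * l21, 1e-300))
    L = np.zeros(A.shape)
    L[:, 0, 0], L[:, 1, 0], L[:, 1, 1] = l11, l21, l22
    return L, np.log(l11) + np.log(l22)


def _event_pieces(params: SPMParams, prep: _Prepared):
    """Per cause: H0(T), delta, delta*log h0(T), eta_fix = Xh alpha (all (N,))."""
    out = []
    for k, cp in enumerate(params.causes):
        H = cumulative_hazard(cp.baseline, prep.T) * prep.has_event
        eta_fix = prep.Xh @ cp.alpha if prep.Xh.size else np.zeros(prep.N)
        d = prep.delta[:, k] if prep.delta.shape[1] > k else np.zeros(prep.N)
        dlh = np.zeros(prep.N)
        m = d > 0
        if m.any():
            dlh[m] = log_hazard(cp.baseline, prep.T[m])
        out.append((H, d, dlh, eta_fix))
    return out


def _modes(params: SPMParams, prep: _Prepared, *, include_event: bool = True,
           tol: float = 1e-10, max_iter: int = 60):
    """Newton argmax of each subject's conditional log-posterior over b.

    The objective is concave (Gaussian quadratic plus -H e^{rho'b} terms), so
    damped Newton converges; returns modes (N,q) and the negative Hessian
    A_post (N,q,q) at the mode.
    """
    N, q = prep.N, prep.q
    sigma2 = params.sigma ** 2
    tinv, _ = _tau_inverse(params.tau)
    Srr, Sr, Str = prep.resid_stats(params.beta)
    A = np.empty((N, q, q))
    A[:, 0, 0] = prep.n_i / sigma2 + tinv[0, 0]
    if q == 2:
        A[:, 0, 1] = A[:, 1, 0] = prep.St / sigma2 + tinv[0, 1]
        A[:, 1, 1] = prep.Stt / sigma2 + tinv[1, 1]
    c = np.column_stack([Sr] + ([Str] if q == 2 else [])) / sigma2

    pieces = _event_pieces(params, prep) if include_event else []
    rhos = [cp.rho for cp in params.causes] if include_event else []
    for (H, d, dlh, eta_fix), rho in zip(pieces, rhos):
        c = c + d[:, None] * rho[None, :]

    b = _solve_spd(A, c)                      # Gaussian-only mode as start
    Hess = A.copy()
    rho_outer = [np.outer(r, r)[None, :, :] for r in rhos]
    for _ in range(max_iter):
        if q == 1:
            Ab = A[:, 0, :] * b
        else:
            Ab = np.column_stack([A[:, 0, 0] * b[:, 0] + A[:, 0, 1] * b[:, 1],
                                  A[:, 1, 0] * b[:, 0] + A[:, 1, 1] * b[:, 1]])
        g = c - Ab
        Hess = A.copy()
        for (H, d, dlh, eta_fix), rho, ro in zip(pieces, rhos, rho_outer):
            E = H * np.exp(np.clip(eta_fix + b @ rho, -_EXP_CLIP, _EXP_CLIP))
            g -= E[:, None] * rho[None, :]
            Hess += E[:, None, None] * ro
        step = _solve_spd(Hess, g)
        nrm = np.max(np.abs(step), axis=1, keepdims=True)
        step = step * np.minimum(1.0, 4.0 / np.maximum(nrm, 1e-300))  # damping
        b = b + step
        if np.max(np.abs(g)) < tol:
            break
    return b, Hess


def _adaptive_nodes(mode: np.ndarray, L: np.ndarray, z: np.ndarray) -> np.ndarray:
    """b = mode + sqrt(2) L z for batched lower-triangular L: (N, M, q)."""
    N, q = mode.shape
    M = len(z)
    out = np.empty((N, M, q))
    s2 = np.sqrt(2.0)
    out[:, :, 0] = mode[:, 0, None] + s2 * L[:, 0, 0, None] * z[None, :, 0]
    if q == 2:
        out[:, :, 1] = mode[:, 1, None] + s2 * (
            L[:, 1, 0, None] * z[None, :, 0] + L[:, 1, 1, None] * z[None, :, 1])
    return out


def _conditional_at_nodes(params: SPMParams, prep: _Prepared,
                          b_nodes: np.ndarray) -> np.ndarray:
    """f(b) = data log-likelihood + log prior at (N, M, q) node array."""
    N, M, q = b_nodes.shape
    sigma2 = params.sigma ** 2
    Srr, Sr, Str = prep.resid_stats(params.beta)
    const = -0.5 * prep.n_i * np.log(2.0 * np.pi * sigma2) - Srr / (2.0 * sigma2)
    b0 = b_nodes[:, :, 0]
    b1 = b_nodes[:, :, 1] if q == 2 else None
    lin = b0 * Sr[:, None]
    quad = b0 * b0 * prep.n_i[:, None]
    if q == 2:
        lin += b1 * Str[:, None]
        quad += 2.0 * b0 * b1 * prep.St[:, None] + b1 * b1 * prep.Stt[:, None]
    f = const[:, None] + lin / sigma2 - quad / (2.0 * sigma2)

    for cp, (H, d, dlh, eta_fix) in zip(params.causes, _event_pieces(params, prep)):
        eta = eta_fix[:, None] + b0 * cp.rho[0]
        if q == 2:
            eta += b1 * cp.rho[1]
        f += d[:, None] * (dlh[:, None] + eta)
        f -= H[:, None] * np.exp(np.clip(eta, -_EXP_CLIP, _EXP_CLIP))

    tinv, logdet = _tau_inverse(params.tau)
    pq = tinv[0, 0] * b0 * b0
    if q == 2:
        pq += 2.0 * tinv[0, 1] * b0 * b1 + tinv[1, 1] * b1 * b1
    f += -0.5 * q * np.log(2.0 * np.pi) - 0.5 * logdet - 0.5 * pq
    return f


def subject_conditional_loglik(params: SPMParams, bundle: DesignBundle, i: int,
                               b: np.ndarray) -> float:
    """Conditional (given b) log-likelihood of subject i: Gaussian visits + events.

    The prior density of b is *not* included.  With zero visits the
    longitudinal product is empty and only event terms remain.
    """
    b = np.asarray(b, dtype=float)
    m = bundle.subject_index == i
    X, Z, y = bundle.X[m], bundle.Z[m], bundle.y[m]
    mu = X @ params.beta + Z @ b if len(y) else np.empty(0)
    ll = float(np.sum(-0.5 * np.log(2 * np.pi * params.sigma ** 2)
                      - 0.5 * ((y - mu) / params.sigma) ** 2))
    if np.isfinite(bundle.event_time[i]):
        T = bundle.event_time[i]
        xh = bundle.X_haz[i]
        for k, cp in enumerate(params.causes):
            eta = float(xh @ cp.alpha + cp.rho @ b)
            d = float(bundle.status[i, k]) if bundle.status.shape[1] > k else 0.0
            ll += float(event_loglik(HazardParams(cp.alpha, cp.baseline),
                                     eta, T, d))
    return ll


def subject_marginal_logliks(params: SPMParams, data_or_bundle, spec: ModelSpec | None = None,
                             rule: QuadratureRule | None = None, *,
                             adaptive: bool = True) -> np.ndarray:
    """Adaptive Gauss-Hermite marginal log-likelihood per subject.

    log integral of exp(conditional) * MVN(b; 0, tau) db, stabilized by
    log-sum-exp.  With ``adaptive=False`` nodes are centered at 0 and scaled
    by the prior covariance.
    """
    bundle = data_or_bundle if isinstance(data_or_bundle, DesignBundle) else \
        build_designs(data_or_bundle, spec)
    prep = _Prepared(bundle, len(params.causes))
    if rule is None:
        rule = QuadratureRule(9, prep.q)
    if rule.dim != prep.q:
        raise ValueError("quadrature rule dimension does not match random effects")

    if adaptive:
        mode, A_post = _modes(params, prep)
        bad = ~np.all(np.isfinite(mode), axis=1)
        if bad.any():
            # fall back to prior-centered nodes for the offending subjects
            import warnings
            warnings.warn(f"mode finding failed for {int(bad.sum())} "
                          "subject(s); using non-adaptive nodes there")
            tinv, _ = _tau_inverse(params.tau)
            mode[bad] = 0.0
            A_post[bad] = tinv
        L, logdetL = _chol_of_inverse(A_post)
    else:
        mode = np.zeros((prep.N, prep.q))
        Lt = np.linalg.cholesky(params.tau)
        L = np.broadcast_to(Lt, (prep.N, prep.q, prep.q)).copy()
        logdetL = np.full(prep.N, np.sum(np.log(np.diag(Lt))))

    b_nodes = _adaptive_nodes(mode, L, rule.z)
    f = _conditional_at_nodes(params, prep, b_nodes)
    arg = rule.log_w[None, :] + rule.z_sq[None, :] + f
    amax = np.max(arg, axis=1)
    lse = amax + np.log(np.sum(np.exp(arg - amax[:, None]), axis=1))
    return 0.5 * prep.q * np.log(2.0) + logdetL + lse


def spm_loglik(params: SPMParams, data_or_bundle, spec: ModelSpec | None = None,
               rule: QuadratureRule | None = None, **kw) -> float:
    """Total joint log-likelihood: sum of subject marginals (order-invariant)."""
    return float(np.sum(subject_marginal_logliks(params, data_or_bundle, spec,
                                                 rule, **kw)))


def posterior_modes(params: SPMParams, bundle: DesignBundle, *,
                    include_event: bool = True) -> np.ndarray:
    """Empirical-Bayes modes of b_i given each subject's data at ``params``."""
    prep = _Prepared(bundle, len(params.causes))
    mode, _ = _modes(params, prep, include_event=include_event)
    return mode


# --------------------------------------------------------------------- fitting

@dataclass(frozen=True)
class SPMOptions:
    quad_order: int = 9
    baseline: str = "piecewise"
    n_intervals: int = 5
    causes: int = 1
    fix_rho: dict | str | None = None   # {(cause, effect): value} or "zero"
    maxiter: int = 500
    gtol: float = 1e-5
    restarts: int = 3
    seed: int = 0
    compute_se: bool = True


@dataclass
class SPMFit(FitResult):
    spm_params: SPMParams | None = None
    loading_hr: list = field(default_factory=list)

    def rho(self, cause: int = 0) -> np.ndarray:
        return self.spm_params.causes[cause].rho


class _Packer:
    """Maps SPMParams <-> unconstrained optimization vector, honoring fixed rho."""

    def __init__(self, p: int, q: int, h: int, baselines: tuple[BaselineHazard, ...],
                 fix_rho: dict):
        self.p, self.q, self.h = p, q, h
        self.baselines = baselines
        self.K = len(baselines)
        self.fix_rho = fix_rho
        self.names: list[str] = []
        self.free_rho: list[tuple[int, int]] = []
        for k in range(self.K):
            for e in range(q):
                if (k, e) not in fix_rho:
                    self.free_rho.append((k, e))

    def pack(self, params: SPMParams) -> np.ndarray:
        v = [params.beta, [np.log(params.sigma)], tau_to_chol_params(params.tau)]
        for k, cp in enumerate(params.causes):
            v.append(cp.alpha)
            v.append(np.asarray(cp.baseline.params))
        v.append([params.causes[k].rho[e] for (k, e) in self.free_rho])
        return np.concatenate([np.atleast_1d(np.asarray(x, float)) for x in v])

    def unpack(self, v: np.ndarray) -> SPMParams:
        p, q, h = self.p, self.q, self.h
        i = 0
        beta = v[i:i + p]; i += p
        sigma = float(np.exp(v[i])); i += 1
        nt = n_chol_params(q)
        tau = chol_params_to_tau(v[i:i + nt], q); i += nt
        causes = []
        for k in range(self.K):
            alpha = v[i:i + h]; i += h
            nb = self.baselines[k].n_params
            base = self.baselines[k].with_params(v[i:i + nb]); i += nb
            causes.append([alpha, base, np.zeros(q)])
        for (k, e) in self.free_rho:
            causes[k][2][e] = v[i]; i += 1
        for (k, e), val in self.fix_rho.items():
            causes[k][2][e] = val
        return SPMParams(beta, sigma, tau,
                         tuple(CauseParams(a, b_, r) for a, b_, r in causes))

    def free_names(self, fixed_names, hazard_names) -> tuple[str, ...]:
        names = list(fixed_names) + ["log_sigma"] + \
            [f"ltau_{i}" for i in range(n_chol_params(self.q))]
        for k in range(self.K):
            suf = "" if self.K == 1 else f"_c{k + 1}"
            names += [f"alpha_{n}{suf}" for n in hazard_names]
            names += [f"log_h0_{i}{suf}" for i in range(self.baselines[k].n_params)]
        for (k, e) in self.free_rho:
            suf = "" if self.K == 1 else f"_c{k + 1}"
            names.append(f"rho_{e}{suf}")
        return tuple(names)


def _normalize_fix_rho(fix_rho, K: int, q: int) -> dict:
    if fix_rho is None:
        return {}
    if fix_rho == "zero":
        return {(k, e): 0.0 for k in range(K) for e in range(q)}
    return {tuple(k): float(v) for k, v in dict(fix_rho).items()}


def fit_spm(data: PanelDataset, spec: ModelSpec,
            options: SPMOptions | None = None) -> SPMFit:
    """Maximum-likelihood fit of the joint shared-parameter model.

    Two-stage initialization (separate LMM and PH fits, loadings started at 0)
    followed by joint quasi-Newton maximization of the adaptive-quadrature
    log-likelihood in an unconstrained parameterization.  SEs come from the
    numerically differentiated observed information (central differences,
    relative step 1e-4); any loading can be held fixed (e.g. all zero for the
    MAR-constrained joint model).
    """
    options = options or SPMOptions()
    K = options.causes
    if data.n_causes < K:
        raise DataError(f"data provide {data.n_causes} cause column(s), "
                        f"options request {K}")
    bundle = build_designs(data, spec)
    for k in range(K):
        if bundle.status[:, k].sum() < 1:
            raise DataError(f"no events observed for cause {k}")
    prep = _Prepared(bundle, K)
    q = spec.n_random
    rule = QuadratureRule(options.quad_order, q)

    # --- two-stage initialization
    lmm = fit_lmm(data, spec)
    ph_fits = [fit_ph(data, spec, cause=k, baseline=options.baseline,
                      n_intervals=options.n_intervals) for k in range(K)]
    baselines = tuple(f.extras["baseline"] for f in ph_fits)
    fix_rho = _normalize_fix_rho(options.fix_rho, K, q)
    packer = _Packer(len(bundle.fixed_names), q, bundle.X_haz.shape[1],
                     baselines, fix_rho)
    start = SPMParams(lmm.extras["beta"], lmm.extras["sigma"], lmm.extras["tau"],
                      tuple(CauseParams(f.extras["alpha"], b, np.zeros(q))
                            for f, b in zip(ph_fits, baselines)))
    x0 = packer.pack(start)

    def negll(v):
        try:
            params = packer.unpack(v)
            return -float(np.sum(_marginal(params)))
        except (np.linalg.LinAlgError, FloatingPointError):
            return 1e12

    def _marginal(params):
        mode, A_post = _modes(params, prep)
        L, logdetL = _chol_of_inverse(A_post)
        b_nodes = _adaptive_nodes(mode, L, rule.z)
        f = _conditional_at_nodes(params, prep, b_nodes)
        arg = rule.log_w[None, :] + rule.z_sq[None, :] + f
        amax = np.max(arg, axis=1)
        return 0.5 * q * np.log(2.0) + logdetL + amax + \
            np.log(np.sum(np.exp(arg - amax[:, None]), axis=1))

    rng = np.random.default_rng(options.seed)
    best = None
    messages = []
    x_start = x0.copy()
    for attempt in range(1 + options.restarts):
        res = optimize.minimize(negll, x_start, method="L-BFGS-B", jac="2-point",
                                options={"maxiter": options.maxiter,
                                         "ftol": 1e-11, "gtol": options.gtol})
        # polish with more accurate gradients
        res2 = optimize.minimize(negll, res.x, method="L-BFGS-B", jac="3-point",
                                 options={"maxiter": 100, "ftol": 1e-13,
                                          "gtol": options.gtol})
        if res2.fun <= res.fun:
            res = res2
        ok = bool(res.success) or float(np.max(np.abs(res.jac))) < 1e-2
        if best is None or res.fun < best[0].fun:
            best = (res, ok)
        if ok:
            break
        # jitter free loadings (seeded) and retry
        x_start = x0.copy()
        nrho = len(packer.free_rho)
        if nrho:
            x_start[-nrho:] += rng.normal(0.0, 0.3, size=nrho)
        messages.append(f"restart {attempt + 1}: jittered loading starts")
    res, converged = best
    if not converged:
        messages.append("joint optimization did not meet convergence criteria")

    params = packer.unpack(res.x)
    loglik = -float(res.fun)
    free_names = packer.free_names(bundle.fixed_names, bundle.hazard_names)

    cov = None
    if options.compute_se:
        H = _numdiff.hessian(lambda v: -negll(v), res.x, rel_step=1e-4)
        cov, pd_ok = _numdiff.covariance_from_neg_hessian(H)
        if not pd_ok:
            messages.append("observed information not PD at optimum; "
                            "SEs flagged unreliable")

    pdict = {**dict(zip(bundle.fixed_names, params.beta)), "sigma": params.sigma}
    for i in range(q):
        for j in range(i + 1):
            pdict[f"tau_{i}{j}"] = float(params.tau[i, j])
    for k, cp in enumerate(params.causes):
        suf = "" if K == 1 else f"_c{k + 1}"
        for n, a in zip(bundle.hazard_names, cp.alpha):
            pdict[f"alpha_{n}{suf}"] = float(a)
        for e in range(q):
            pdict[f"rho_{e}{suf}"] = float(cp.rho[e])

    fit = SPMFit(model="spm" if K == 1 else "spm-competing", params=pdict,
                 free_names=free_names, free_values=res.x.copy(), cov=cov,
                 loglik=loglik, n_params=res.x.size,
                 n_subjects=bundle.n_subjects, n_obs=bundle.n_obs,
                 converged=converged, n_iter=int(res.nit),
                 grad_norm=float(np.max(np.abs(res.jac))), messages=messages,
                 extras={"spec": spec, "options": options, "packer": packer,
                         "bundle": bundle, "beta": params.beta,
                         "sigma": params.sigma, "tau": params.tau,
                         "init_lmm": lmm, "init_ph": ph_fits},
                 spm_params=params)
    if cov is not None:
        from .prediction import loading_hr_per_sd
        fit.loading_hr = [
            loading_hr_per_sd(fit, cause=k, effect=e)
            for k in range(K) for e in range(q)
        ]
    return fit


def fit_spm_competing(data: PanelDataset, spec: ModelSpec,
                      options: SPMOptions | None = None) -> SPMFit:
    """Joint fit with two cause-specific event sub-models sharing one b_i."""
    options = options or SPMOptions()
    return fit_spm(data, spec, replace(options, causes=2))
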