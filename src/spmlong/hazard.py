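"""Parametric proportional-hazards machinery.

Baseline hazard families (piecewise-constant, Weibull, exponential) with exact
closed-form cumulative hazards, a standalone maximum-likelihood PH fitter used
both as the separate event model and to initialize the joint fit, and
inverse-transform event-time sampling for the cohort simulator.

The hazard design is baseline-only (time-fixed covariates); for a subject with
linear predictor eta the survival function is S(t | eta) = exp(-H0(t) e^eta).
The last piecewise interval is open-ended so sampled times beyond the data
range remain well defined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from . import _numdiff
from .data_model import DataError, ModelSpec, PanelDataset, build_designs
from .results import FitResult

__all__ = ["BaselineHazard", "HazardParams", "cumulative_hazard", "log_hazard",
           "event_loglik", "fit_ph", "sample_event_time", "default_cuts"]

_FAMILIES = ("piecewise", "weibull", "exponential")


@dataclass(frozen=True)
class BaselineHazard:
    """Baseline hazard h0(t).

    piecewise: ``cuts`` are the interior cut points (first interval starts at
    0, last is open-ended) and ``params`` the log-rates, one per interval.
    weibull: params = (log scale lambda, log shape k), h0(t) = lambda k t^(k-1).
    exponential: params = (log rate,).
    """

    family: str
    params: tuple[float, ...]
    cuts: tuple[float, ...] = ()

    def __post_init__(self):
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown baseline family {self.family!r}")
        object.__setattr__(self, "params", tuple(float(p) for p in self.params))
        object.__setattr__(self, "cuts", tuple(float(c) for c in self.cuts))
        if self.family == "piecewise":
            if len(self.params) != len(self.cuts) + 1:
                raise ValueError("piecewise needs one log-rate per interval "
                                 "(len(cuts) + 1)")
            if len(self.cuts) and (np.any(np.diff(self.cuts) <= 0) or self.cuts[0] <= 0):
                raise ValueError("cut points must be positive and strictly increasing")
        elif self.family == "weibull" and len(self.params) != 2:
            raise ValueError("weibull takes (log scale, log shape)")
        elif self.family == "exponential" and len(self.params) != 1:
            raise ValueError("exponential takes a single log rate")

    @property
    def n_params(self) -> int:
        return len(self.params)

    def with_params(self, params) -> "BaselineHazard":
        return BaselineHazard(self.family, tuple(params), self.cuts)


@dataclass(frozen=True)
class HazardParams:
    alpha: np.ndarray
    baseline: BaselineHazard

    def __post_init__(self):
        object.__setattr__(self, "alpha", np.asarray(self.alpha, dtype=float))
        if not np.all(np.isfinite(self.alpha)):
            raise ValueError("non-finite hazard coefficients")


def _edges(b: BaselineHazard) -> np.ndarray:
    return np.concatenate([[0.0], np.asarray(b.cuts, dtype=float)])


def log_hazard(baseline: BaselineHazard, t) -> np.ndarray:
    """log h0(t), vectorized; t >= 0 (t = 0 allowed only where finite)."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("negative time")
    if baseline.family == "exponential":
        return np.full(t.shape, baseline.params[0])
    if baseline.family == "piecewise":
        idx = np.searchsorted(_edges(baseline), t, side="right") - 1
        return np.asarray(baseline.params, dtype=float)[idx]
    log_lam, log_k = baseline.params
    k = np.exp(log_k)
    with np.errstate(divide="ignore"):
        return log_lam + log_k + (k - 1.0) * np.log(t)


def cumulative_hazard(baseline: BaselineHazard, t) -> np.ndarray:
    """H0(t) = integral of h0 over [0, t], exact per family."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("negative time")
    if baseline.family == "exponential":
        return np.exp(baseline.params[0]) * t
    if baseline.family == "weibull":
        log_lam, log_k = baseline.params
        return np.exp(log_lam) * t ** np.exp(log_k)
    edges = _edges(baseline)
    rates = np.exp(np.asarray(baseline.params, dtype=float))
    # cumulative hazard at the left edge of each interval
    widths = np.diff(edges)
    H_edges = np.concatenate([[0.0], np.cumsum(rates[:-1] * widths)])
    idx = np.searchsorted(edges, t, side="right") - 1
    return H_edges[idx] + rates[idx] * (t - edges[idx])


def event_loglik(params: HazardParams, eta, T, delta) -> np.ndarray:
    """Per-subject log-likelihood contribution delta*(log h0(T)+eta) - H0(T)e^eta."""
    T = np.asarray(T, dtype=float)
    eta = np.asarray(eta, dtype=float)
    delta = np.asarray(delta, dtype=float)
    H = cumulative_hazard(params.baseline, T)
    out = -H * np.exp(eta)
    lh = log_hazard(params.baseline, np.maximum(T, 1e-300))
    return np.where(delta > 0, out + lh + eta, out)


def default_cuts(event_times: np.ndarray, n_intervals: int = 5) -> tuple[float, ...]:
    """Interior cut points at the quantiles of the observed event times."""
    event_times = np.asarray(event_times, dtype=float)
    if event_times.size == 0:
        raise DataError("no events to place piecewise cut points")
    qs = np.linspace(0, 1, n_intervals + 1)[1:-1]
    cuts = np.quantile(event_times, qs)
    cuts = np.unique(cuts[cuts > 0])
    return tuple(cuts)


def fit_ph(data: PanelDataset, spec: ModelSpec, *, cause: int = 0,
           baseline: str = "piecewise", n_intervals: int = 5,
           cuts: tuple[float, ...] | None = None) -> FitResult:
    """ML fit of the parametric PH model with no random effects.

    Used standalone as the MAR-separate event model and as the joint fit's
    initializer.  ``cause`` selects which status column counts as the event;
    other causes censor.
    """
    bundle = build_designs(data, spec)
    ok = np.isfinite(bundle.event_time)
    T = bundle.event_time[ok]
    delta = bundle.status[ok, cause].astype(float)
    Xh = bundle.X_haz[ok]
    if delta.sum() < 1:
        raise DataError(f"no events observed for cause {cause}")

    if baseline == "piecewise":
        cuts = default_cuts(T[delta > 0], n_intervals) if cuts is None else tuple(cuts)
        nb = len(cuts) + 1
        base0 = BaselineHazard("piecewise",
                               (np.log(max(delta.sum() / max(T.sum(), 1e-12), 1e-8)),) * nb,
                               cuts)
    elif baseline == "exponential":
        base0 = BaselineHazard("exponential",
                               (np.log(max(delta.sum() / max(T.sum(), 1e-12), 1e-8)),))
    elif baseline == "weibull":
        base0 = BaselineHazard("weibull",
                               (np.log(max(delta.sum() / max(T.sum(), 1e-12), 1e-8)), 0.0))
    else:
        raise ValueError(f"unknown baseline family {baseline!r}")

    h = Xh.shape[1]
    x0 = np.concatenate([np.zeros(h), base0.params])

    def negll(v):
        hp = HazardParams(v[:h], base0.with_params(v[h:]))
        eta = Xh @ hp.alpha
        with np.errstate(over="ignore"):
            ll = event_loglik(hp, eta, T, delta)
        return -float(np.sum(ll))

    res = optimize.minimize(negll, x0, method="L-BFGS-B", jac="3-point",
                            options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-7})
    alpha = res.x[:h]
    base = base0.with_params(res.x[h:])
    loglik = -float(res.fun)

    free_names = tuple(f"alpha_{n}" for n in bundle.hazard_names) + tuple(
        f"log_h0_{i}" for i in range(base.n_params))
    H = _numdiff.hessian(lambda v: -negll(v), res.x)
    cov, pd_ok = _numdiff.covariance_from_neg_hessian(H)
    messages = [] if pd_ok else ["observed information not PD; SEs unreliable"]
    params = {**{f"alpha_{n}": float(a) for n, a in zip(bundle.hazard_names, alpha)},
              **{f"log_h0_{i}": float(p) for i, p in enumerate(base.params)}}
    return FitResult(model=f"ph-{baseline}", params=params, free_names=free_names,
                     free_values=res.x.copy(), cov=cov, loglik=loglik,
                     n_params=res.x.size, n_subjects=int(ok.sum()),
                     n_obs=int(ok.sum()), converged=bool(res.success),
                     n_iter=int(res.nit), grad_norm=float(np.max(np.abs(res.jac))),
                     messages=messages,
                     extras={"alpha": alpha, "baseline": base, "cause": cause,
                             "n_events": int(delta.sum()), "spec": spec})


def sample_event_time(params: HazardParams, eta, u) -> np.ndarray:
    """Inverse-transform sample: solve S(t | eta) = u, i.e. H0(t) e^eta = -log u.

    Closed form per family; the piecewise family walks intervals.  Where the
    target cumulative hazard is unreachable (numerically zero hazard) returns
    +inf, to be administratively censored by the caller.
    """
    eta = np.asarray(eta, dtype=float)
    u = np.asarray(u, dtype=float)
    if np.any((u <= 0) | (u >= 1)):
        raise ValueError("u must lie in (0, 1)")
    target = -np.log(u) * np.exp(-eta)          # required H0(t)
    b = params.baseline
    if b.family == "exponential":
        return target / np.exp(b.params[0])
    if b.family == "weibull":
        log_lam, log_k = b.params
        return (target / np.exp(log_lam)) ** (1.0 / np.exp(log_k))
    edges = _edges(b)
    rates = np.exp(np.asarray(b.params, dtype=float))
    widths = np.diff(edges)
    H_edges = np.concatenate([[0.0], np.cumsum(rates[:-1] * widths)])
    idx = np.searchsorted(H_edges, target, side="right") - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        t = edges[idx] + (target - H_edges[idx]) / rates[idx]
    t = np.where(np.isfinite(t), t, np.inf)
    return t
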