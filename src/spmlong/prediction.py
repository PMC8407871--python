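"""Subject-level empirical-Bayes predictions and derived summary quantities.

Covers the post-fit quantities an analyst reports from the joint model:
posterior modes of the random effects and fitted trajectories, marginalized
declines over a horizon (with delta-method CIs), loading-factor hazard ratios
per SD of random effect, and percent attenuation between model estimates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from . import _numdiff
from .data_model import (ConfigurationError, DesignBundle, PanelDataset,
                         build_designs)
from .results import FitResult

__all__ = ["empirical_bayes", "predict_trajectory", "predict_panel",
           "marginalized_decline", "loading_hr_per_sd", "attenuation",
           "DeclineContrast", "LoadingHR", "Attenuation"]


def _fit_spm_params(fit: FitResult):
    """SPMParams view of any fit (LMM fits get an empty cause tuple)."""
    from .spm import SPMParams
    sp = getattr(fit, "spm_params", None)
    if sp is not None:
        return sp
    return SPMParams(fit.extras["beta"], fit.extras["sigma"],
                     np.atleast_2d(fit.extras["tau"]), ())


def empirical_bayes(fit: FitResult, data: PanelDataset | None = None) -> pd.DataFrame:
    """Posterior modes b_i of each subject's random effects at the estimates.

    For the SPM the conditional posterior includes the event contribution; for
    the LMM it is the Gaussian closed form.  Subjects carrying no information
    sit at the prior mode 0.
    """
    from .spm import posterior_modes
    params = _fit_spm_params(fit)
    bundle = fit.extras.get("bundle")
    if data is not None:
        bundle = build_designs(data, fit.extras["spec"])
    if bundle is None:
        raise ConfigurationError("no dataset available; pass `data`")
    modes = posterior_modes(params, bundle)
    cols = [f"b{i}" for i in range(modes.shape[1])]
    return pd.DataFrame(modes, columns=cols, index=pd.Index(bundle.ids, name="id"))


def predict_trajectory(fit: FitResult, x_base: np.ndarray, b: np.ndarray,
                       times) -> np.ndarray:
    """Pointwise predictions yhat(t) = x(t)' beta + z(t)' b for one profile."""
    times = np.asarray(times, dtype=float)
    if np.any(times < 0):
        raise ValueError("prediction times must be >= 0")
    bundle: DesignBundle = fit.extras["bundle"]
    beta = fit.extras["beta"]
    b = np.atleast_1d(np.asarray(b, dtype=float))
    out = np.empty_like(times)
    for i, t in enumerate(times):
        xrow = bundle.fixed_row(np.asarray(x_base, float), float(t))
        z = np.array([1.0, t])[: b.size]
        out[i] = xrow @ beta + z @ b
    return out


def predict_panel(fit: FitResult, data: PanelDataset | None = None) -> pd.DataFrame:
    """Long-format observed vs predicted values at every observed visit."""
    bundle = fit.extras["bundle"] if data is None else \
        build_designs(data, fit.extras["spec"])
    eb = empirical_bayes(fit, data)
    beta = fit.extras["beta"]
    b_obs = eb.to_numpy()[bundle.subject_index]
    pred = bundle.X @ beta + np.sum(bundle.Z * b_obs, axis=1)
    ids = np.asarray(bundle.ids)[bundle.subject_index]
    return pd.DataFrame({"id": ids, "time": bundle.t, "observed": bundle.y,
                         "predicted": pred, "model": fit.model})


@dataclass(frozen=True)
class _Estimate:
    est: float
    se: float
    ci: tuple[float, float]
    p: float


@dataclass(frozen=True)
class DeclineContrast:
    """Absolute outcome change over a horizon at two exposure levels."""
    without: _Estimate
    with_: _Estimate
    additional: _Estimate
    horizon: float


def _linear_estimate(fit: FitResult, c: np.ndarray) -> _Estimate:
    est = float(c @ fit.free_values)
    if fit.cov is not None:
        se = float(np.sqrt(max(c @ fit.cov @ c, 0.0)))
    else:
        se = float("nan")
    z = norm.ppf(0.975)
    p = 2.0 * norm.sf(abs(est) / se) if se > 0 else float("nan")
    return _Estimate(est, se, (est - z * se, est + z * se), float(p))


def marginalized_decline(fit: FitResult, horizon: float = 20.0,
                         exposure_levels=(0.0, 1.0)) -> DeclineContrast:
    """Outcome change over ``horizon`` years at each exposure level.

    decline(a) = horizon * (beta_time + a * beta_interaction), with any
    adjustor-by-time terms averaged over the empirical adjustor distribution
    (marginalization over adjustors).  SEs/CIs by the delta method, exact here
    since the contrast is linear in the fixed effects.
    """
    spec = fit.extras["spec"]
    names = list(fit.free_names)
    tname, iname = "time", f"{spec.exposure}:time"
    if iname not in names or tname not in names:
        raise ConfigurationError(
            f"fit lacks '{tname}' and/or '{iname}' fixed effects")
    c_base = np.zeros(len(names))
    c_base[names.index(tname)] = horizon
    if spec.adjustor_time_interactions:
        bundle = fit.extras["bundle"]
        for a in spec.adjustor_time_interactions:
            j = list(bundle.fixed_names).index(a)
            per_sub = np.full(bundle.n_subjects, np.nan)
            for i in range(bundle.n_subjects):
                m = bundle.subject_index == i
                if m.any():
                    per_sub[i] = bundle.X[m][0, j]
            c_base[names.index(f"{a}:time")] = horizon * np.nanmean(per_sub)
    a0, a1 = exposure_levels
    c0 = c_base.copy(); c0[names.index(iname)] = horizon * a0
    c1 = c_base.copy(); c1[names.index(iname)] = horizon * a1
    cdiff = c1 - c0
    return DeclineContrast(without=_linear_estimate(fit, c0),
                           with_=_linear_estimate(fit, c1),
                           additional=_linear_estimate(fit, cdiff),
                           horizon=float(horizon))


@dataclass(frozen=True)
class LoadingHR:
    """Hazard ratio per SD of a shared random effect, on the adverse scale."""
    cause: int
    effect: int
    rho: float
    sd: float
    hr: float                      # exp(rho * sd), signed convention
    hr_adverse: float              # exp(|rho| * sd): per SD in the risk-raising direction
    direction: str                 # which SD shift raises the hazard
    ci: tuple[float, float]        # 95% CI for hr_adverse (delta method, log scale)
    degenerate: bool = False


def loading_hr_per_sd(fit, cause: int = 0, effect: int = 0) -> LoadingHR:
    """HR per SD of random effect ``effect`` in the hazard of ``cause``.

    The SD basis is the estimated random-effect SD from the same fit
    (sqrt of the corresponding diagonal of tau-hat).  The CI comes from the
    delta method on log HR over the free-parameter covariance; fixed loadings
    get a point-mass CI.
    """
    packer = fit.extras["packer"]

    def log_hr(v):
        params = packer.unpack(np.asarray(v, dtype=float))
        sd = float(np.sqrt(params.tau[effect, effect]))
        return float(params.causes[cause].rho[effect] * sd)

    val = log_hr(fit.free_values)
    params = packer.unpack(np.asarray(fit.free_values, dtype=float))
    sd = float(np.sqrt(params.tau[effect, effect]))
    rho = float(params.causes[cause].rho[effect])
    if sd < 1e-8:
        return LoadingHR(cause, effect, rho, sd, 1.0, 1.0, "degenerate",
                         (1.0, 1.0), degenerate=True)
    if fit.cov is not None:
        se = _numdiff.delta_method_se(log_hr, fit.free_values, fit.cov)
    else:
        se = float("nan")
    z = norm.ppf(0.975)
    lo, hi = np.exp(abs(val) - z * se), np.exp(abs(val) + z * se)
    direction = "per SD lower" if rho < 0 else "per SD higher"
    return LoadingHR(cause, effect, rho, sd, float(np.exp(val)),
                     float(np.exp(abs(val))), direction, (float(lo), float(hi)))


@dataclass(frozen=True)
class Attenuation:
    percent: float                 # 100 (ref - comp) / ref, unrounded
    rounded: int | None            # nearest integer percent, None when undefined

    def __str__(self):
        return "NA" if self.rounded is None else f"{self.rounded}%"


def attenuation(reference: float, comparator: float) -> Attenuation:
    """Percent reduction of ``comparator`` relative to ``reference``.

    Positive means the comparator sits closer to zero than the reference.
    A zero reference leaves the quantity undefined (reported as NA).
    """
    if reference == 0:
        return Attenuation(float("nan"), None)
    pct = 100.0 * (reference - comparator) / reference
    return Attenuation(float(pct), int(round(pct)))
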