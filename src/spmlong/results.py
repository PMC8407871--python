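"""Common fit-result container shared by the LMM, GEE, PH and SPM fitters."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


def information_criteria(loglik: float, p: int, n_subjects: int) -> tuple[float, float]:
    """AIC = -2l + 2p, BIC = -2l + p log N with N the number of subjects."""
    if p < 0 or n_subjects < 1:
        raise ValueError("need p >= 0 and n_subjects >= 1")
    aic = -2.0 * loglik + 2.0 * p
    bic = -2.0 * loglik + p * np.log(n_subjects)
    return float(aic), float(bic)


@dataclass
class FitResult:
    """Estimates, uncertainty and diagnostics from a single model fit.

    ``params`` maps parameter names to estimates in their *reporting* scale;
    ``free_names``/``cov`` live in the (possibly transformed) free-parameter
    space actually optimized, so delta-method transports are done against it.
    For GEE fits ``loglik``/``aic``/``bic`` are None (quasi-likelihood).
    """

    model: str
    params: dict
    free_names: tuple
    free_values: np.ndarray
    cov: np.ndarray | None
    loglik: float | None
    n_params: int
    n_subjects: int
    n_obs: int
    converged: bool = True
    n_iter: int = 0
    grad_norm: float = float("nan")
    messages: list = field(default_factory=list)
    aic: float | None = None
    bic: float | None = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.loglik is not None and self.aic is None:
            self.aic, self.bic = information_criteria(
                self.loglik, self.n_params, self.n_subjects)

    def se(self, name: str) -> float:
        """Standard error of a free parameter (natural names only)."""
        i = self.free_names.index(name)
        if self.cov is None:
            return float("nan")
        return float(np.sqrt(self.cov[i, i]))

    def wald_ci(self, name: str, level: float = 0.95) -> tuple[float, float]:
        from scipy.stats import norm
        z = norm.ppf(0.5 + level / 2.0)
        i = self.free_names.index(name)
        est = float(self.free_values[i])
        se = self.se(name)
        return est - z * se, est + z * se

    def wald_p(self, name: str) -> float:
        from scipy.stats import norm
        i = self.free_names.index(name)
        est = float(self.free_values[i])
        se = self.se(name)
        if not np.isfinite(se) or se == 0:
            return float("nan")
        return float(2.0 * norm.sf(abs(est) / se))

    def to_dict(self) -> dict:
        out = {
            "model": self.model,
            "params": {k: float(v) for k, v in self.params.items()},
            "loglik": self.loglik,
            "aic": self.aic,
            "bic": self.bic,
            "n_params": self.n_params,
            "n_subjects": self.n_subjects,
            "n_obs": self.n_obs,
            "converged": bool(self.converged),
            "n_iter": int(self.n_iter),
            "grad_norm": float(self.grad_norm),
            "messages": list(self.messages),
        }
        if self.cov is not None:
            out["se"] = {n: float(np.sqrt(self.cov[i, i]))
                         for i, n in enumerate(self.free_names)}
        return out
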