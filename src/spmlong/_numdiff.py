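"""Central-difference gradients and Hessians for observed-information SEs."""

from __future__ import annotations

import numpy as np


def _steps(x: np.ndarray, rel_step: float) -> np.ndarray:
    return rel_step * np.maximum(1.0, np.abs(x))


def gradient(f, x: np.ndarray, rel_step: float = 1e-6) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    h = _steps(x, rel_step)
    g = np.empty_like(x)
    for i in range(x.size):
        e = np.zeros_like(x)
        e[i] = h[i]
        g[i] = (f(x + e) - f(x - e)) / (2.0 * h[i])
    return g


def hessian(f, x: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    """Symmetric central-difference Hessian; step is relative (1e-4 default)."""
    x = np.asarray(x, dtype=float)
    n = x.size
    h = _steps(x, rel_step)
    H = np.empty((n, n))
    f0 = f(x)
    fp = np.empty(n)
    fm = np.empty(n)
    for i in range(n):
        e = np.zeros(n)
        e[i] = h[i]
        fp[i] = f(x + e)
        fm[i] = f(x - e)
        H[i, i] = (fp[i] - 2.0 * f0 + fm[i]) / h[i] ** 2
    for i in range(n):
        for j in range(i + 1, n):
            ei = np.zeros(n); ei[i] = h[i]
            ej = np.zeros(n); ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4.0 * h[i] * h[j])
    return H


def covariance_from_neg_hessian(H: np.ndarray) -> tuple[np.ndarray | None, bool]:
    """Invert the observed information -H of a log-likelihood; None if not PD."""
    info = -H
    try:
        L = np.linalg.cholesky(info)
        inv = np.linalg.inv(info)
        inv = 0.5 * (inv + inv.T)
        return inv, True
    except np.linalg.LinAlgError:
        # pseudo-inverse fallback, flagged unreliable by the caller
        try:
            return np.linalg.pinv(info), False
        except np.linalg.LinAlgError:
            return None, False


def delta_method_se(g, free_values: np.ndarray, cov: np.ndarray,
                    rel_step: float = 1e-6) -> float:
    """SE of a scalar function g(theta) of the free parameters."""
    grad = gradient(g, free_values, rel_step)
    return float(np.sqrt(max(grad @ cov @ grad, 0.0)))
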