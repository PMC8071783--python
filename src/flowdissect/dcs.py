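"""Toy intensity-autocorrelation model for the diffuse flow channel.

The diffuse correlation measurement infers flow from the decay of the
normalized intensity autocorrelation g2(tau).  This module provides a
deliberately minimal stand-in — a single-exponential decay

    g2(tau) = 1 + beta * exp(-2 * gamma * tau),   gamma = flow_index / tau_scale

with coherence factor ``beta`` in (0, 1] — so that a flow index can be
round-tripped through a curve for testing.  It is not a physical
correlation-diffusion model; downstream analysis treats the diffuse channel
simply as a relative-flow time series.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize

__all__ = ["simulate_g2", "extract_flow_index", "G2FitError"]

DEFAULT_TAU_SCALE = 1e-3  # s of decay time per unit flow index


class G2FitError(RuntimeError):
    """Raised when an autocorrelation curve does not show a usable decay."""


def simulate_g2(flow_index: float, beta: float, tau_grid: np.ndarray,
                tau_scale: float = DEFAULT_TAU_SCALE) -> np.ndarray:
    """Single-exponential g2 curve for a given flow index."""
    if flow_index <= 0:
        raise ValueError("flow_index must be > 0")
    if not 0 < beta <= 1:
        raise ValueError("beta must be in (0, 1]")
    tau = np.asarray(tau_grid, dtype=float)
    gamma = flow_index / tau_scale
    return 1.0 + beta * np.exp(-2.0 * gamma * tau)


def extract_flow_index(curve: np.ndarray, tau_grid: np.ndarray,
                       tau_scale: float = DEFAULT_TAU_SCALE) -> float:
    """Invert :func:`simulate_g2` by least squares; returns the flow index.

    Raises :class:`G2FitError` when the curve does not decay.
    """
    tau = np.asarray(tau_grid, dtype=float)
    g2 = np.asarray(curve, dtype=float)
    if g2.size != tau.size or g2.size < 3:
        raise ValueError("curve and tau_grid must match with >= 3 samples")
    beta0 = g2[np.argmin(tau)] - 1.0
    if beta0 <= 0 or g2[np.argmax(tau)] >= g2[np.argmin(tau)]:
        raise G2FitError("curve does not decay from a positive intercept")

    def model(tau, beta, gamma):
        return 1.0 + beta * np.exp(-2.0 * gamma * tau)

    gamma0 = 1.0 / (2.0 * max(float(np.mean(tau)), 1e-12))
    try:
        popt, _ = optimize.curve_fit(model, tau, g2, p0=[min(beta0, 1.0), gamma0],
                                     maxfev=10000)
    except RuntimeError as exc:
        raise G2FitError(f"autocorrelation fit failed: {exc}") from exc
    beta, gamma = popt
    if gamma <= 0:
        raise G2FitError("fitted decay rate is not positive")
    return float(gamma * tau_scale)
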