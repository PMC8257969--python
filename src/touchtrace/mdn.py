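"""Gaussian mixture output head math: likelihood and point estimates.

The model's output for each target channel is a 3-component Gaussian
mixture (means, standard deviations, mixing weights).  Training
minimizes the negative log-likelihood of the observed z-scored count
under that mixture; the scalar prediction for evaluation is the
mixture mode (maximum-likelihood point), found by dense grid search
over the support followed by local refinement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = ["MixtureParams", "mixture_nll", "mixture_logpdf", "point_estimate"]

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass
class MixtureParams:
    """Per-channel mixture parameters, arrays of shape (..., 3)."""

    means: np.ndarray
    stds: np.ndarray
    weights: np.ndarray

    def __post_init__(self):
        self.means = np.asarray(self.means, dtype=np.float64)
        self.stds = np.asarray(self.stds, dtype=np.float64)
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if not (self.means.shape == self.stds.shape == self.weights.shape):
            raise ValueError("means, stds, weights must share a shape")
        if np.any(self.stds <= 0):
            raise ValueError("standard deviations must be positive")
        if np.any(self.weights < 0) or not np.allclose(
            self.weights.sum(axis=-1), 1.0, atol=1e-6
        ):
            raise ValueError("weights must be nonnegative and sum to 1")


def mixture_logpdf(params: MixtureParams, x) -> np.ndarray:
    """log density of the mixture at ``x`` (broadcast against leading dims)."""
    x = np.asarray(x, dtype=np.float64)[..., None]
    z = (x - params.means) / params.stds
    log_comp = (
        np.log(params.weights + 1e-300)
        - np.log(params.stds)
        - 0.5 * (z**2 + _LOG_2PI)
    )
    m = log_comp.max(axis=-1, keepdims=True)
    return (m + np.log(np.exp(log_comp - m).sum(axis=-1, keepdims=True)))[..., 0]


def mixture_nll(params: MixtureParams, target) -> np.ndarray:
    """Negative log-likelihood of ``target`` under the mixture."""
    return -mixture_logpdf(params, target)


def point_estimate(params: MixtureParams, grid_points: int = 1024) -> np.ndarray:
    """Mode of each mixture: dense grid search over
    [min mu - 3 sigma, max mu + 3 sigma], refined locally.

    Accepts arbitrary leading dimensions; returns that shape.
    """
    means = np.atleast_2d(params.means.reshape(-1, params.means.shape[-1]))
    stds = np.atleast_2d(params.stds.reshape(-1, params.stds.shape[-1]))
    weights = np.atleast_2d(params.weights.reshape(-1, params.weights.shape[-1]))
    out = np.empty(means.shape[0])
    for i in range(means.shape[0]):
        p = MixtureParams(means[i], stds[i], weights[i])
        lo = float((p.means - 3 * p.stds).min())
        hi = float((p.means + 3 * p.stds).max())
        grid = np.linspace(lo, hi, grid_points)
        dens = mixture_logpdf(p, grid)
        k = int(np.argmax(dens))
        step = (hi - lo) / (grid_points - 1) if grid_points > 1 else 0.0
        if step > 0:
            res = minimize_scalar(
                lambda x: -mixture_logpdf(p, np.array(x)),
                bounds=(grid[k] - step, grid[k] + step),
                method="bounded",
                options={"xatol": 1e-10},
            )
            out[i] = float(res.x)
        else:
            out[i] = float(grid[k])
    return out.reshape(params.means.shape[:-1])
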