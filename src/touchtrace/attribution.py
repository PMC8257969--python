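"""Gradient x input attribution over the behavioral feature space.

Which regions of the JID drive a channel's predicted discharge count
up or down?  For each evaluated window the gradient of a scalar model
output — the mean of the mixture component carrying the largest weight,
the differentiable stand-in for the mixture mode — is taken with
respect to the 9x2x50x50 input window and multiplied elementwise by
the input.  Averaging over the 9 context bins and over windows yields
one signed 50x50 map per feature space (all-ITI and Social): positive
values mark behavior that raises the predicted count, negative values
behavior that lowers it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .features import HourlyFeatureSeries
from .model import ContextWindowSet, MDNModel
from .nn.autodiff import Tensor

__all__ = ["AttributionMap", "gradient_times_input"]


@dataclass
class AttributionMap:
    """Signed 50x50 contribution maps, one per input feature space."""

    all_iti: np.ndarray      # (50, 50)
    social: np.ndarray       # (50, 50)
    channel: int
    n_windows: int

    def by_space(self, space: int) -> np.ndarray:
        return self.all_iti if space == 0 else self.social


def _dominant_mean_scalar(model: MDNModel, raws: list[Tensor], channel: int) -> Tensor:
    """Sum over windows of the dominant-component mean for one channel.

    The component choice (argmax weight) is a constant w.r.t. the
    differentiation, making the scalar piecewise-linear in the head
    output.
    """
    raw = raws[channel]
    K = model.config.n_mixture
    logits = raw.data[:, 2 * K :]
    onehot = np.zeros((raw.shape[0], K), dtype=np.float32)
    onehot[np.arange(raw.shape[0]), np.argmax(logits, axis=1)] = 1.0
    mu = raw[:, :K]
    return (mu * Tensor(onehot)).sum()


def gradient_times_input(
    model,
    windows: ContextWindowSet,
    features: HourlyFeatureSeries,
    channel: int = 0,
    window_indices: np.ndarray | None = None,
    batch_size: int = 64,
    scalar_fn=None,
) -> AttributionMap:
    """Average gradient x input map for one output channel.

    By default averages over windows with at least one present context
    bin (mirroring the evaluation mask).  ``scalar_fn(model, raws,
    channel) -> Tensor`` may override the differentiated scalar; the
    default is the dominant-component mean.
    """
    if hasattr(model, "trained") and not model.trained:
        raise ValueError("model has not been trained")
    if scalar_fn is None:
        scalar_fn = _dominant_mean_scalar
    if window_indices is None:
        window_indices = np.where(windows.any_present)[0]
    window_indices = np.asarray(window_indices)
    if len(window_indices) == 0:
        raise ValueError("no windows to attribute")
    frames_all = features.frames()
    model.set_training(False)
    acc = np.zeros((2, 50, 50), dtype=np.float64)
    for b0 in range(0, len(window_indices), batch_size):
        batch = window_indices[b0 : b0 + batch_size]
        x = frames_all[windows.frame_idx[batch]]      # (B, 9, 2, 50, 50)
        xt = Tensor(x, requires_grad=True)
        raws = model.forward_windows(xt)
        scalar = scalar_fn(model, raws, channel)
        scalar.backward()
        gxi = xt.grad * x                             # zero input => zero attribution
        acc += gxi.mean(axis=1).sum(axis=0)           # mean over 9 bins, sum windows
    acc /= len(window_indices)
    return AttributionMap(
        all_iti=acc[0], social=acc[1], channel=channel, n_windows=len(window_indices)
    )


def plot_attribution(map_: AttributionMap, path=None):
    """Render the two maps with a signed colormap; returns the figure."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .features import bin_centers

    fig, axes = plt.subplots(1, 2, figsize=(9, 4), constrained_layout=True)
    c = bin_centers()
    vmax = max(np.abs(map_.all_iti).max(), np.abs(map_.social).max()) or 1.0
    for ax, data, title in zip(
        axes, [map_.all_iti, map_.social], ["all ITIs", "Social-app ITIs"]
    ):
        im = ax.pcolormesh(c, c, data.T, cmap="RdBu_r", vmin=-vmax, vmax=vmax)
        ax.set_xlabel("log10 ITI k (ms)")
        ax.set_ylabel("log10 ITI k+1 (ms)")
        ax.set_title(title)
    fig.colorbar(im, ax=axes, shrink=0.8, label="gradient x input")
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig
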