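"""Wavelet periodograms of hourly series with shuffle-bootstrap significance.

Cyclicity in hourly discharge counts and in each pixel of the hourly
JID is characterized with a complex Morlet continuous wavelet
transform (center frequency omega0 = 6).  The periodogram value at a
scale is ``sqrt(mean_t |W(scale, t)|)``, the square root of the
time-averaged coefficient modulus; significance comes from uniformly
permuting the series (which preserves the marginal distribution and
destroys all temporal structure) and taking a per-scale upper quantile
of the shuffled powers.

Time averages exclude a cone of influence of ``sqrt(2) * scale``
samples at each edge (capped so that at least the central tenth of the
series, and never fewer than 8 samples, always contributes); the
series mean is removed before transforming so that power is exactly
invariant to additive constants.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
from scipy import ndimage

from .features import GRID_BINS, HourlyFeatureSeries

__all__ = [
    "Periodogram",
    "CyclePowerMap",
    "default_periods",
    "wavelet_periodogram",
    "bootstrap_periodogram",
    "analyze_series",
    "pixelwise_cycle_map",
]

# complex Morlet, omega0 = 6 convention: psi(t) ~ exp(i*omega0*t) exp(-t^2/2)
_CENTER_FREQ = 6.0 / (2.0 * np.pi)
_WAVELET = pywt.ContinuousWavelet(f"cmor2.0-{_CENTER_FREQ!r}")
VOICES_PER_OCTAVE = 24


@dataclass
class Periodogram:
    periods: np.ndarray          # hours, strictly increasing
    power: np.ndarray            # sqrt(mean_t |W|) per period
    ci_upper: np.ndarray | None = None
    significant: np.ndarray | None = None

    def peak_period(self) -> float:
        return float(self.periods[int(np.argmax(self.power))])


@dataclass
class CyclePowerMap:
    period: float
    power: np.ndarray            # (50, 50)
    significant: np.ndarray      # (50, 50) pre-mask bootstrap outcome
    mask: np.ndarray             # (50, 50) True = shown (survives 2x2 rule)


def default_periods(n_hours: int, min_period: float = 2.0,
                    max_period_days: float = 35.0) -> np.ndarray:
    """Log-spaced periods from 2 h to min(35 days, span/2), 24 voices/octave."""
    max_period = min(max_period_days * 24.0, n_hours / 2.0)
    if max_period <= min_period:
        raise ValueError("series too short for any requested period")
    n_octaves = np.log2(max_period / min_period)
    n = max(2, int(np.ceil(n_octaves * VOICES_PER_OCTAVE)) + 1)
    return np.geomspace(min_period, max_period, n)


def _coi_slice(n: int, scale: float) -> slice:
    coi = int(np.ceil(np.sqrt(2.0) * scale))
    keep_min = max(8, n // 10)
    coi = min(coi, (n - keep_min) // 2)
    coi = max(coi, 0)
    return slice(coi, n - coi)


def _power_matrix(data: np.ndarray, periods: np.ndarray) -> np.ndarray:
    """Powers for (possibly batched) series: (..., N) -> (..., n_periods)."""
    data = np.asarray(data, dtype=np.float64)
    n = data.shape[-1]
    data = data - data.mean(axis=-1, keepdims=True)
    scales = _CENTER_FREQ * np.asarray(periods, dtype=np.float64)
    out = np.empty(data.shape[:-1] + (len(periods),))
    # chunk over scales to bound the complex coefficient array at ~256 MB
    batch = int(np.prod(data.shape[:-1]))
    chunk = max(1, int(256e6 / (batch * n * 16)))
    for start in range(0, len(scales), chunk):
        sub = scales[start : start + chunk]
        coef, _ = pywt.cwt(data, sub, _WAVELET, method="fft", axis=-1)
        # coef shape: (n_sub_scales, ..., N)
        for k, s in enumerate(sub):
            sl = _coi_slice(n, s)
            out[..., start + k] = np.sqrt(np.abs(coef[k])[..., sl].mean(axis=-1))
    return out


def wavelet_periodogram(series: np.ndarray,
                        periods: np.ndarray | None = None) -> Periodogram:
    """Morlet-CWT periodogram of an hourly series.

    Requires the series to span at least twice the longest requested
    period; raises otherwise, naming the maximum analyzable period.
    """
    series = np.asarray(series, dtype=np.float64)
    if series.ndim != 1:
        raise ValueError("series must be 1-dimensional")
    n = len(series)
    if periods is None:
        periods = default_periods(n)
    periods = np.asarray(periods, dtype=np.float64)
    if np.any(np.diff(periods) <= 0):
        raise ValueError("periods must be strictly increasing")
    if n < 2 * periods.max():
        raise ValueError(
            f"series of {n} h supports periods up to {n / 2:.1f} h; "
            f"requested {periods.max():.1f} h"
        )
    return Periodogram(periods=periods, power=_power_matrix(series, periods))


def bootstrap_periodogram(series: np.ndarray, periods: np.ndarray,
                          n_shuffles: int = 1000, level: float = 95.0,
                          seed: int | None = None) -> np.ndarray:
    """Per-period upper ``level``-percentile of power over shuffled copies.

    The permutation null: the series values are uniformly permuted
    ``n_shuffles`` times (>= 100) and the periodogram recomputed for
    each; exceeding the returned threshold is the significance call.
    """
    if n_shuffles < 100:
        raise ValueError("n_shuffles must be >= 100")
    series = np.asarray(series, dtype=np.float64)
    rng = np.random.default_rng(seed)
    shuffled = np.tile(series, (n_shuffles, 1))
    shuffled = rng.permuted(shuffled, axis=1)
    powers = _power_matrix(shuffled, periods)   # (n_shuffles, n_periods)
    return np.percentile(powers, level, axis=0)


def analyze_series(series: np.ndarray, periods: np.ndarray | None = None,
                   n_shuffles: int = 1000, level: float = 95.0,
                   seed: int | None = None) -> Periodogram:
    """Periodogram plus bootstrap threshold and significance flags."""
    pg = wavelet_periodogram(series, periods)
    pg.ci_upper = bootstrap_periodogram(series, pg.periods, n_shuffles, level, seed)
    pg.significant = pg.power > pg.ci_upper
    return pg


def _clusters_with_2x2(sig: np.ndarray) -> np.ndarray:
    """Mask keeping 4-connected significant clusters containing a full
    2x2 significant square; everything else is masked out."""
    labels, n = ndimage.label(sig, structure=[[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    if n == 0:
        return np.zeros_like(sig, dtype=bool)
    sq = sig[:-1, :-1] & sig[1:, :-1] & sig[:-1, 1:] & sig[1:, 1:]
    keep_ids = np.unique(labels[:-1, :-1][sq])
    keep_ids = keep_ids[keep_ids > 0]
    return np.isin(labels, keep_ids)


def pixelwise_cycle_map(features: HourlyFeatureSeries, period: float = 24.0,
                        n_shuffles: int = 100, level: float = 95.0,
                        seed: int | None = None, space: int = 0) -> CyclePowerMap:
    """Per-pixel cycle power of the hourly JID at one period, with
    per-pixel shuffle bootstrap and the 2x2-cluster mask.

    Absent hours enter as the stored all-zero grids.  Each pixel's
    series is shuffled independently; significant 4-connected clusters
    that contain no 2x2 all-significant square are masked out.
    """
    grids = features.jid_all if space == 0 else features.jid_social
    H = grids.shape[0]
    if H < 14 * 24 and period >= 24.0:
        raise ValueError("need >= 14 days of features for a 24 h cycle map")
    if H < 2 * period:
        raise ValueError(
            f"series of {H} h supports periods up to {H / 2:.1f} h"
        )
    X = grids.reshape(H, -1).T.astype(np.float64)   # (2500, H)
    periods = np.array([period])
    power = _power_matrix(X, periods)[:, 0]
    rng = np.random.default_rng(seed)
    boot = np.empty((n_shuffles, X.shape[0]))
    for b in range(n_shuffles):
        perm = rng.permuted(X, axis=1)
        boot[b] = _power_matrix(perm, periods)[:, 0]
    thr = np.percentile(boot, level, axis=0)
    sig = (power > thr).reshape(GRID_BINS, GRID_BINS)
    mask = _clusters_with_2x2(sig)
    return CyclePowerMap(
        period=float(period),
        power=power.reshape(GRID_BINS, GRID_BINS),
        significant=sig,
        mask=mask,
    )
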