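"""Shared toy fixtures: decodable hourly grids and paired count series."""

import numpy as np

from touchtrace.detrend import DetectorSeries, DetrendedSeries
from touchtrace.features import GRID_BINS, HourlyFeatureSeries


def toy_features(H, seed=0, signal=None):
    """Random hourly grids; optional per-hour scalar 'signal' written into
    the fast corner so the target is decodable from the frames."""
    rng = np.random.default_rng(seed)
    grids = rng.random((H, GRID_BINS, GRID_BINS)).astype(np.float32) * 0.002
    if signal is not None:
        grids[:, :10, :10] += (0.02 * signal[:, None, None]).astype(np.float32)
    grids /= grids.sum(axis=(1, 2), keepdims=True)
    return HourlyFeatureSeries(
        hours=np.arange(H, dtype=np.int64),
        jid_all=grids,
        jid_social=grids.copy(),
        present=np.ones((H, 2), dtype=bool),
        n_pairs=np.full((H, 2), 20, dtype=np.int64),
    )


def simple_detrend(det):
    """Mean-removal stand-in for the 24-h detrend (toy series are short)."""
    fitted = np.tile(det.counts.mean(axis=0), (len(det.hours), 1))
    return DetrendedSeries(det.hours, det.counts - fitted, fitted, "polynomial")


def toy_dataset(H=240, seed=0, coupled=True):
    rng = np.random.default_rng(seed + 50)
    signal = rng.random(H)
    feats = toy_features(H, seed=seed, signal=signal if coupled else None)
    lam = 5 + 40 * signal if coupled else np.full(H, 20.0)
    counts = rng.poisson(lam).astype(np.int64).reshape(-1, 1)
    det = DetectorSeries(hours=np.arange(H, dtype=np.int64), counts=counts)
    return feats, det, simple_detrend(det)
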