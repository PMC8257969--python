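"""Wavelet periodograms of detector counts and behavioral pixels.

Simulates 40 days with a diurnal discharge-rate cycle, estimates the
Morlet periodogram with a shuffle-bootstrap threshold, and maps which
JID pixels carry a significant 24-h cycle.
"""

import numpy as np

from touchtrace import (
    SimulationConfig,
    analyze_series,
    build_hourly_features,
    make_paired_dataset,
    pixelwise_cycle_map,
)

cfg = SimulationConfig(duration_days=40, diurnal_amplitude=0.6, n_detectors=1,
                       seed=7)
log, det, truth = make_paired_dataset(cfg)

pg = analyze_series(det.counts[:, 0].astype(float), n_shuffles=200, level=99.0,
                    seed=1)
peak = pg.peak_period()
sig = pg.significant[np.argmax(pg.power)]
print(f"detector periodogram peak: {peak:.1f} h "
      f"({'significant' if sig else 'not significant'} at the 99% shuffle "
      f"threshold; planted period 24 h)")

feats = build_hourly_features(log, hour_range=(0, cfg.n_hours))
cmap = pixelwise_cycle_map(feats, period=24.0, n_shuffles=100, seed=2)
print(f"pixels with significant 24-h power: {cmap.significant.mean():.1%} "
      f"pre-mask, {cmap.mask.mean():.1%} after the 2x2-cluster rule")
print("(behavioral 24-h cyclicity comes from the diurnal session profile and "
      "the diurnal modulation of fast-ITI mixture weight)")
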