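"""Synthetic paired touch logs and detector counts with known ground truth.

The study's patient data are private, so every downstream stage is
exercised on simulated data whose statistical structure mirrors the
real recordings:

* **Sessions** arise from an inhomogeneous Poisson process over hours
  (a 24-value diurnal intensity profile); each session's tap count is
  geometric with configurable mean, its app is Social with probability
  ``social_fraction``, and its inter-touch intervals are drawn from a
  log10-normal mixture spanning roughly 30 ms - 100 s.  Touch
  timestamps carry independent Gaussian jitter (default sd 15 ms,
  matching the logger's timestamp precision).
* **JID variability**: the weight of the fastest mixture component is
  modulated on the logit scale by a diurnal sinusoid plus hourly noise,
  so the shape of the hourly JID genuinely varies (real behavior is
  nonstationary; a frozen mixture would make the feature space
  informationless beyond presence).
* **Detector counts** are hourly Poisson draws with rate
  ``baseline x diurnal x multidien x exp(coupling_strength * z)``
  where ``z`` is the standardized hourly value of a named JID
  sub-region integral (default: the fast-ITI corner mass) computed
  with the same feature pipeline used downstream — the planted signal
  lives exactly in the model's input space.  Counts continue through
  behavioral gaps (the implanted device records regardless of phone
  use).

Identical config + seed gives bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .detrend import DetectorSeries
from .features import (
    HourlyFeatureSeries,
    MS_PER_HOUR,
    TouchEventLog,
    build_hourly_features,
    region_mass,
)

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_touch_log",
    "simulate_detector_counts",
    "make_paired_dataset",
]

# daytime-heavy session intensity (sessions/hour) over the 24 clock hours
_DEFAULT_PROFILE = np.array(
    [0.10, 0.05, 0.05, 0.05, 0.10, 0.30, 0.80, 1.20,
     1.50, 1.50, 1.40, 1.40, 1.50, 1.40, 1.30, 1.30,
     1.40, 1.60, 1.80, 1.80, 1.60, 1.20, 0.70, 0.30]
)


@dataclass
class SimulationConfig:
    duration_days: int = 30
    session_rate_per_hour: np.ndarray = field(
        default_factory=lambda: _DEFAULT_PROFILE.copy()
    )
    taps_per_session_mean: float = 40.0
    # (log10-mean of ms, log10-sd, weight); components span ~30 ms - 100 s
    iti_mixture: list[tuple[float, float, float]] = field(
        default_factory=lambda: [(2.45, 0.22, 0.55), (3.15, 0.28, 0.33), (4.05, 0.30, 0.12)]
    )
    social_fraction: float = 0.4
    timestamp_jitter_sd_ms: float = 15.0
    # hourly modulation of the fast component's mixture weight (logit scale)
    iti_weight_diurnal_amplitude: float = 0.8
    iti_weight_noise_sd: float = 0.5
    n_detectors: int = 2
    baseline_rate: float = 20.0          # counts/hour for the first detector
    diurnal_amplitude: float = 0.5
    multidien_period_days: float | None = None
    multidien_amplitude: float = 0.4
    coupling_strength: float = 0.0
    coupling_feature: str = "fast_iti_mass"
    gap_schedule: list[tuple[int, int]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self):
        self.session_rate_per_hour = np.asarray(self.session_rate_per_hour, dtype=float)
        if self.session_rate_per_hour.shape != (24,):
            raise ValueError("session_rate_per_hour must have 24 values")
        if np.any(self.session_rate_per_hour < 0):
            raise ValueError("session rates must be nonnegative")
        w = np.array([c[2] for c in self.iti_mixture], dtype=float)
        if np.any(w < 0) or not np.isclose(w.sum(), 1.0, atol=1e-9):
            raise ValueError("iti_mixture weights must be nonnegative and sum to 1")
        if not 0 <= self.social_fraction <= 1:
            raise ValueError("social_fraction must lie in [0, 1]")
        if self.timestamp_jitter_sd_ms < 0 or self.baseline_rate <= 0:
            raise ValueError("jitter must be >= 0 and baseline_rate > 0")
        if not 1 <= self.n_detectors <= 4:
            raise ValueError("n_detectors must be in [1, 4]")
        if self.duration_days <= 0 or self.diurnal_amplitude < 0:
            raise ValueError("duration and amplitudes must be nonnegative")

    @property
    def n_hours(self) -> int:
        return self.duration_days * 24


@dataclass
class GroundTruth:
    hourly_rate: np.ndarray          # (H, D) latent Poisson intensity
    coupling_series: np.ndarray      # (H,) standardized coupled feature
    cycle_components: dict


def _in_gap(hour: float, gaps: list[tuple[int, int]]) -> bool:
    return any(lo <= hour < hi for lo, hi in gaps)


def simulate_touch_log(config: SimulationConfig) -> TouchEventLog:
    """Draw a touch log from the configured session process.

    Events are returned sorted; every touch lies within its session's
    [screen-on, screen-off] span; sessions intersecting gap-schedule
    intervals are dropped entirely.
    """
    rng = np.random.default_rng(config.seed)
    mix = np.array(config.iti_mixture, dtype=float)  # (K, 3)
    base_logit = np.log(mix[:, 2] + 1e-12)
    rows = []
    prev_end = -np.inf
    for h in range(config.n_hours):
        lam = config.session_rate_per_hour[h % 24]
        n_sessions = rng.poisson(lam) if lam > 0 else 0
        # hourly mixture-weight modulation: shared by all sessions this hour
        delta = config.iti_weight_diurnal_amplitude * np.cos(
            2 * np.pi * (h % 24 - 14) / 24.0
        ) + config.iti_weight_noise_sd * rng.standard_normal()
        logits = base_logit.copy()
        logits[0] += delta
        weights = np.exp(logits - logits.max())
        weights /= weights.sum()
        starts = np.sort(rng.uniform(0, MS_PER_HOUR, size=n_sessions))
        for s in starts:
            start_ms = h * MS_PER_HOUR + s
            if _in_gap(start_ms / MS_PER_HOUR, config.gap_schedule):
                continue
            if start_ms < prev_end + 1000:
                continue  # sessions do not overlap
            n_taps = int(rng.geometric(1.0 / config.taps_per_session_mean))
            comp = rng.choice(len(mix), size=max(n_taps - 1, 0), p=weights)
            itis = 10 ** rng.normal(mix[comp, 0], mix[comp, 1])
            touches = start_ms + 200 + np.concatenate([[0.0], np.cumsum(itis)])
            touches = touches + rng.normal(0, config.timestamp_jitter_sd_ms, n_taps)
            touches = np.sort(touches)
            end_ms = touches[-1] + 500
            if _in_gap(end_ms / MS_PER_HOUR, config.gap_schedule):
                continue
            social = rng.random() < config.social_fraction
            app = "app.social" if social else "app.other"
            rows.append((int(start_ms - 300), "screen_on", ""))
            rows.extend((int(t), "touch", app) for t in touches)
            rows.append((int(end_ms), "screen_off", ""))
            prev_end = end_ms
    df = pd.DataFrame(rows, columns=["timestamp_ms", "kind", "app_id"])
    if len(df):
        df = df.sort_values("timestamp_ms", kind="stable").reset_index(drop=True)
    return TouchEventLog(df, {"app.social": "Social", "app.other": "NonSocial"})


def _coupling_series(features: HourlyFeatureSeries, name: str) -> np.ndarray:
    if name == "fast_iti_mass":
        raw = region_mass(features.jid_all)
    elif name == "slow_iti_mass":
        raw = region_mass(features.jid_all, lo=3.5, hi=5.0)
    else:
        raise ValueError(f"unknown coupling feature {name!r}")
    raw = np.asarray(raw, dtype=float)
    sd = raw.std()
    z = (raw - raw.mean()) / sd if sd > 0 else np.zeros_like(raw)
    # winsorize: the hourly sub-region mass is strongly right-skewed (absent
    # hours pin it at its floor), and exp(coupling * z) with unbounded z
    # would produce physiologically absurd count excursions
    return np.clip(z, -2.5, 2.5)


def simulate_detector_counts(
    log: TouchEventLog, config: SimulationConfig
) -> tuple[DetectorSeries, GroundTruth]:
    """Hourly Poisson counts whose latent rate couples to a JID sub-region.

    Per detector ``d``, rate = baseline * 0.6^d * diurnal * multidien *
    exp(coupling_strength * z_h); detector baselines decay so channels
    differ in sparsity, as real detector-channel pairs do.
    """
    H = config.n_hours
    features = build_hourly_features(log, hour_range=(0, H))
    z = _coupling_series(features, config.coupling_feature)
    hours = np.arange(H, dtype=np.int64)
    diurnal = 1.0 + config.diurnal_amplitude * np.cos(2 * np.pi * (hours % 24 - 3) / 24.0)
    diurnal = np.clip(diurnal, 0.0, None)
    cycles = {"diurnal": {"period_h": 24.0, "amplitude": config.diurnal_amplitude}}
    multidien = np.ones(H)
    if config.multidien_period_days is not None:
        period_h = 24.0 * config.multidien_period_days
        multidien = 1.0 + config.multidien_amplitude * np.cos(2 * np.pi * hours / period_h)
        multidien = np.clip(multidien, 0.0, None)
        cycles["multidien"] = {
            "period_h": period_h,
            "amplitude": config.multidien_amplitude,
        }
    modulation = diurnal * multidien * np.exp(config.coupling_strength * z)
    rng = np.random.default_rng(config.seed + 1)
    rates = np.empty((H, config.n_detectors))
    counts = np.empty((H, config.n_detectors), dtype=np.int64)
    for d in range(config.n_detectors):
        rates[:, d] = config.baseline_rate * (0.6**d) * modulation
        counts[:, d] = rng.poisson(rates[:, d])
    labels = [f"L{1 + d // 2}D{1 + d % 2}" for d in range(config.n_detectors)]
    series = DetectorSeries(hours=hours, counts=counts, detector_labels=labels)
    truth = GroundTruth(hourly_rate=rates, coupling_series=z, cycle_components=cycles)
    return series, truth


def make_paired_dataset(
    config: SimulationConfig,
) -> tuple[TouchEventLog, DetectorSeries, GroundTruth]:
    """Convenience composition: one seed drives both generators."""
    log = simulate_touch_log(config)
    series, truth = simulate_detector_counts(log, config)
    return log, series, truth
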