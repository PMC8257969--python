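"""File formats: touch-log CSV, detector-count CSV, category maps,
feature archives, and run configuration.

Hour bins are half-open ``[h, h+1)`` on the local clock everywhere;
detector CSV hours are ISO timestamps on exact hour boundaries.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .detrend import DetectorSeries
from .features import MS_PER_HOUR, HourlyFeatureSeries, TouchEventLog

__all__ = [
    "read_touch_log",
    "write_touch_log",
    "read_category_map",
    "write_category_map",
    "read_detector_csv",
    "write_detector_csv",
    "save_features",
    "load_features",
    "RunConfig",
]

log = logging.getLogger("touchtrace")

_KINDS = {"touch", "screen_on", "screen_off"}


def read_touch_log(path, category_map: dict | str | Path | None = None) -> TouchEventLog:
    """Read ``timestamp_ms,kind,app_id`` CSV; rows are sorted on read
    (with a warning when reordering occurred); malformed rows raise
    with their line number."""
    df = pd.read_csv(path, dtype={"app_id": str}, keep_default_na=False)
    expected = ["timestamp_ms", "kind", "app_id"]
    if list(df.columns) != expected:
        raise ValueError(f"{path}: expected header {','.join(expected)}")
    ts = pd.to_numeric(df["timestamp_ms"], errors="coerce")
    bad = np.where(ts.isna())[0]
    if len(bad):
        raise ValueError(f"{path}: non-numeric timestamp at line {bad[0] + 2}")
    df["timestamp_ms"] = ts.astype(np.int64)
    bad_kind = ~df["kind"].isin(_KINDS)
    if bad_kind.any():
        line = int(np.where(bad_kind)[0][0]) + 2
        raise ValueError(f"{path}: unknown kind {df['kind'][line - 2]!r} at line {line}")
    if not df["timestamp_ms"].is_monotonic_increasing:
        log.warning("%s: events were not sorted; sorting on read", path)
        df = df.sort_values("timestamp_ms", kind="stable").reset_index(drop=True)
    if isinstance(category_map, (str, Path)):
        category_map = read_category_map(category_map)
    return TouchEventLog(df, category_map or {})


def write_touch_log(tlog: TouchEventLog, path):
    tlog.events.to_csv(path, index=False)


def read_category_map(path) -> dict[str, str]:
    """Two-column CSV ``app_id,category`` with category Social|NonSocial."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if list(df.columns) != ["app_id", "category"]:
        raise ValueError(f"{path}: expected header app_id,category")
    bad = ~df["category"].isin(["Social", "NonSocial"])
    if bad.any():
        line = int(np.where(bad)[0][0]) + 2
        raise ValueError(f"{path}: category must be Social|NonSocial (line {line})")
    return dict(zip(df["app_id"], df["category"]))


def write_category_map(cmap: dict[str, str], path):
    pd.DataFrame(
        {"app_id": list(cmap.keys()), "category": list(cmap.values())}
    ).to_csv(path, index=False)


def _hour_to_iso(hour: int) -> str:
    return pd.Timestamp(int(hour) * 3600, unit="s").isoformat()


def write_detector_csv(series: DetectorSeries, path):
    rows = []
    for c, label in enumerate(series.detector_labels):
        for i, h in enumerate(series.hours):
            if series.observed[i, c]:
                rows.append((_hour_to_iso(h), label, int(series.counts[i, c])))
    pd.DataFrame(rows, columns=["hour_start_iso", "detector_id", "count"]).to_csv(
        path, index=False
    )


def read_detector_csv(path) -> DetectorSeries:
    """Read ``hour_start_iso,detector_id,count`` into a dense hourly grid.

    Hours absent from the file are flagged unobserved (distinct from a
    recorded zero); duplicate (hour, detector) rows and negative counts
    raise.
    """
    df = pd.read_csv(path)
    expected = ["hour_start_iso", "detector_id", "count"]
    if list(df.columns) != expected:
        raise ValueError(f"{path}: expected header {','.join(expected)}")
    stamps = pd.to_datetime(df["hour_start_iso"])
    secs = stamps.astype("int64") // 10**9
    if np.any(secs % 3600 != 0):
        raise ValueError(f"{path}: hours must lie on local-clock hour boundaries")
    hours = (secs // 3600).to_numpy()
    if np.any(df["count"] < 0):
        raise ValueError(f"{path}: negative count")
    labels = list(dict.fromkeys(df["detector_id"]))
    if df.duplicated(subset=["hour_start_iso", "detector_id"]).any():
        raise ValueError(f"{path}: duplicate (hour, detector) rows")
    h0, h1 = hours.min(), hours.max() + 1
    H = int(h1 - h0)
    counts = np.zeros((H, len(labels)), dtype=np.int64)
    observed = np.zeros((H, len(labels)), dtype=bool)
    lab_idx = {lab: i for i, lab in enumerate(labels)}
    for h, lab, cnt in zip(hours, df["detector_id"], df["count"]):
        i, c = int(h - h0), lab_idx[lab]
        counts[i, c] = cnt
        observed[i, c] = True
    return DetectorSeries(
        hours=np.arange(h0, h1, dtype=np.int64),
        counts=counts,
        detector_labels=labels,
        observed=observed,
    )


def save_features(features: HourlyFeatureSeries, path):
    """Compressed array archive with a JSON header."""
    header = {
        "hours": [int(features.hours[0]), int(features.hours[-1]) + 1],
        "grid": {"bins": 50, "lo": 1.5, "hi": 5.0},
        "spaces": ["all", "social"],
    }
    np.savez_compressed(
        path,
        header=np.frombuffer(json.dumps(header).encode(), dtype=np.uint8),
        hours=features.hours,
        jid_all=features.jid_all,
        jid_social=features.jid_social,
        present=features.present,
        n_pairs=features.n_pairs,
    )


def load_features(path) -> HourlyFeatureSeries:
    with np.load(path) as data:
        return HourlyFeatureSeries(
            hours=data["hours"],
            jid_all=data["jid_all"],
            jid_social=data["jid_social"],
            present=data["present"],
            n_pairs=data["n_pairs"],
        )


@dataclass
class RunConfig:
    """Everything needed to reproduce a run: inputs, parameters, seed."""

    touch_log: str = ""
    detector_csv: str = ""
    category_map: str = ""
    output_dir: str = "out"
    bandwidth: float = 0.1
    alignment: str = "centered"
    extractor: str = "small"
    epochs: int = 20
    learning_rate: float = 1e-3
    batch_size: int = 64
    detrend_method: str = "polynomial"
    detrend_degree: int = 5
    alpha: float = 0.05
    seed: int = 0
    extra: dict = field(default_factory=dict)

    def save(self, path):
        Path(path).write_text(json.dumps(self.__dict__, indent=2))

    @classmethod
    def load(cls, path) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text()))
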