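"""Joint interval distributions (JIDs) from smartphone touch logs.

A usage *session* is the span between a screen-on and the next
screen-off event.  Within a session, consecutive inter-touch intervals
(ITIs) form pairs ``(x_k, x_{k+1})``; their joint distribution in
``log10`` space — the JID — is the behavioral feature space.  The JID is
estimated hourly by 2D Gaussian kernel density estimation (bandwidth
0.1 in log10 units) and discretized on a fixed 50x50 grid spanning
log10-ITI in [1.5, 5] (30 ms to 100 s), then renormalized to sum to 1.

Two feature spaces are maintained per hour: all sessions, and sessions
on Social-category apps only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GRID_BINS",
    "GRID_LO",
    "GRID_HI",
    "BIN_WIDTH",
    "bin_centers",
    "TouchEventLog",
    "Session",
    "JIDGrid",
    "HourlyFeatureSeries",
    "sessionize",
    "estimate_jid",
    "build_hourly_features",
    "jid_entropy",
    "mean_entropy",
    "region_mass",
]

GRID_BINS = 50
GRID_LO = 1.5
GRID_HI = 5.0
BIN_WIDTH = (GRID_HI - GRID_LO) / GRID_BINS  # 0.07 log10 units
CELL_AREA = BIN_WIDTH**2

MS_PER_HOUR = 3_600_000

KINDS = ("touch", "screen_on", "screen_off")


def bin_centers() -> np.ndarray:
    """Centers of the 50 equal bins over [1.5, 5]: 1.535, 1.605, ..., 4.965."""
    return GRID_LO + BIN_WIDTH * (np.arange(GRID_BINS) + 0.5)


@dataclass
class TouchEventLog:
    """Ordered touch / screen events plus the app -> Social/NonSocial map.

    ``events`` columns: ``timestamp_ms`` (int64), ``kind`` (one of
    touch/screen_on/screen_off), ``app_id`` (string, empty for screen
    events).
    """

    events: pd.DataFrame
    category_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        ts = self.events["timestamp_ms"].to_numpy()
        if len(ts) > 1 and np.any(np.diff(ts) < 0):
            raise ValueError("event timestamps must be non-decreasing")
        bad = set(self.events["kind"].unique()) - set(KINDS)
        if bad:
            raise ValueError(f"unknown event kinds: {sorted(bad)}")

    def is_social(self, app_id: str) -> bool:
        return self.category_map.get(app_id, "NonSocial") == "Social"


@dataclass
class Session:
    start: int
    end: int
    touch_timestamps: np.ndarray
    app_id: str = ""

    @property
    def n_touches(self) -> int:
        return len(self.touch_timestamps)


@dataclass
class JIDGrid:
    """50x50 probability surface over consecutive log10-ITI pairs.

    ``values[i, j]`` is the probability mass at (log10 x_k = axis[i],
    log10 x_{k+1} = axis[j]); values sum to 1 whenever ``n_pairs >= 1``
    and any kernel mass falls on the support.
    """

    values: np.ndarray
    n_pairs: int

    @property
    def axis(self) -> np.ndarray:
        return bin_centers()


@dataclass
class HourlyFeatureSeries:
    """Hourly JID grids for the all-app and Social feature spaces.

    ``hours`` are integer epoch-hour bins (half-open [h, h+1) clock
    hours); absent hours carry an all-zero grid and ``present`` false.
    ``present[:, 0]`` refers to the all-app space, ``present[:, 1]`` to
    the Social space.
    """

    hours: np.ndarray          # (H,) int64
    jid_all: np.ndarray        # (H, 50, 50) float32
    jid_social: np.ndarray     # (H, 50, 50) float32
    present: np.ndarray        # (H, 2) bool
    n_pairs: np.ndarray        # (H, 2) int64

    def __len__(self) -> int:
        return len(self.hours)

    def frames(self) -> np.ndarray:
        """Stacked (H, 2, 50, 50) float32 model-input frames."""
        return np.stack([self.jid_all, self.jid_social], axis=1).astype(np.float32)


def sessionize(log: TouchEventLog) -> list[Session]:
    """Split a log into usage sessions (screen-on to screen-off).

    Touches outside any session are discarded.  A screen-on that is
    never matched closes at the final event of the log; a screen-on
    arriving while a session is open implicitly closes the previous
    session at that instant.  A session's ``app_id`` is the app of its
    first touch.
    """
    sessions: list[Session] = []
    open_start: int | None = None
    touches: list[int] = []
    app_id = ""

    def close(end: int):
        nonlocal open_start, touches, app_id
        if open_start is not None:
            kept = np.array([t for t in touches if open_start <= t <= end], dtype=np.int64)
            sessions.append(Session(open_start, end, kept, app_id))
        open_start, touches, app_id = None, [], ""

    last_ts = None
    for ts, kind, app in log.events[["timestamp_ms", "kind", "app_id"]].itertuples(
        index=False
    ):
        last_ts = ts
        if kind == "screen_on":
            if open_start is not None:
                close(ts)
            open_start = ts
        elif kind == "screen_off":
            close(ts)
        elif kind == "touch" and open_start is not None:
            if not touches:
                app_id = app if isinstance(app, str) else ""
            touches.append(ts)
    if open_start is not None and last_ts is not None:
        close(last_ts)
    return sessions


def _session_iti_pairs(session: Session) -> tuple[np.ndarray, np.ndarray]:
    """Return (pairs, pair_hour_ms): consecutive ITI pairs and, per pair,
    the timestamp of the touch terminating the first interval.

    A session with n touches yields n-1 intervals and n-2 pairs.
    Nonpositive intervals (possible under timestamp jitter) invalidate
    the pairs they participate in.
    """
    t = session.touch_timestamps
    if len(t) < 3:
        return np.empty((0, 2)), np.empty(0, dtype=np.int64)
    iti = np.diff(t).astype(np.float64)
    pairs = np.stack([iti[:-1], iti[1:]], axis=1)
    anchor = t[1:-1]  # touch terminating interval k
    ok = (pairs > 0).all(axis=1)
    return pairs[ok], anchor[ok]


def estimate_jid(
    iti_pairs: np.ndarray, bandwidth: float = 0.1
) -> JIDGrid:
    """2D Gaussian KDE of log10-ITI pairs on the 50x50 grid.

    The isotropic Gaussian product kernel is evaluated exactly at the
    bin centers (two 50xN factor matrices and one matrix product), and
    the grid renormalized to sum to 1.  Kernel mass outside the
    [1.5, 5]^2 support is lost to the renormalization.
    """
    pairs = np.asarray(iti_pairs, dtype=np.float64)
    if pairs.ndim != 2 or pairs.shape[1] != 2 or len(pairs) == 0:
        raise ValueError("estimate_jid requires a nonempty (n, 2) array of ITIs")
    if np.any(pairs <= 0):
        raise ValueError("ITIs must be positive")
    lx = np.log10(pairs[:, 0])
    ly = np.log10(pairs[:, 1])
    c = bin_centers()
    inv2h2 = 1.0 / (2.0 * bandwidth**2)
    kx = np.exp(-((c[:, None] - lx[None, :]) ** 2) * inv2h2)  # (50, n)
    ky = np.exp(-((c[:, None] - ly[None, :]) ** 2) * inv2h2)
    grid = kx @ ky.T  # (50, 50): rows = x_k, cols = x_{k+1}
    total = grid.sum()
    if total > 0:
        grid = grid / total
    return JIDGrid(values=grid, n_pairs=len(pairs))


def build_hourly_features(
    log: TouchEventLog,
    bandwidth: float = 0.1,
    hour_range: tuple[int, int] | None = None,
) -> HourlyFeatureSeries:
    """Hourly JIDs for the all-app and Social feature spaces.

    A pair is assigned to the clock hour containing the touch that
    terminates its first interval.  Social grids use only pairs from
    sessions whose app is in the Social category.
    """
    sessions = sessionize(log)
    all_pairs, all_hours = [], []
    soc_flags = []
    for s in sessions:
        pairs, anchors = _session_iti_pairs(s)
        if len(pairs) == 0:
            continue
        all_pairs.append(pairs)
        all_hours.append(anchors // MS_PER_HOUR)
        soc_flags.append(np.full(len(pairs), log.is_social(s.app_id)))
    if all_pairs:
        pairs = np.concatenate(all_pairs)
        pair_hours = np.concatenate(all_hours).astype(np.int64)
        social = np.concatenate(soc_flags)
    else:
        pairs = np.empty((0, 2))
        pair_hours = np.empty(0, dtype=np.int64)
        social = np.empty(0, dtype=bool)

    if hour_range is None:
        if len(log.events) == 0:
            raise ValueError("empty log and no hour_range given")
        ts = log.events["timestamp_ms"].to_numpy()
        hour_range = (int(ts.min() // MS_PER_HOUR), int(ts.max() // MS_PER_HOUR) + 1)
    h0, h1 = hour_range
    hours = np.arange(h0, h1, dtype=np.int64)
    H = len(hours)
    jid_all = np.zeros((H, GRID_BINS, GRID_BINS), dtype=np.float32)
    jid_social = np.zeros_like(jid_all)
    present = np.zeros((H, 2), dtype=bool)
    n_pairs = np.zeros((H, 2), dtype=np.int64)

    order = np.argsort(pair_hours, kind="stable")
    pairs, pair_hours, social = pairs[order], pair_hours[order], social[order]
    keep = (pair_hours >= h0) & (pair_hours < h1)
    pairs, pair_hours, social = pairs[keep], pair_hours[keep], social[keep]
    for h in np.unique(pair_hours):
        sel = pair_hours == h
        i = int(h - h0)
        g = estimate_jid(pairs[sel], bandwidth)
        jid_all[i] = g.values
        present[i, 0] = True
        n_pairs[i, 0] = g.n_pairs
        sel_s = sel & social
        if sel_s.any():
            gs = estimate_jid(pairs[sel_s], bandwidth)
            jid_social[i] = gs.values
            present[i, 1] = True
            n_pairs[i, 1] = gs.n_pairs
    return HourlyFeatureSeries(hours, jid_all, jid_social, present, n_pairs)


def align_features(
    features: HourlyFeatureSeries, hours: np.ndarray
) -> HourlyFeatureSeries:
    """Re-grid a feature series onto another hour grid (pad absent hours
    with zero grids; drop hours outside the target range)."""
    hours = np.asarray(hours, dtype=np.int64)
    H = len(hours)
    jid_all = np.zeros((H, GRID_BINS, GRID_BINS), dtype=np.float32)
    jid_social = np.zeros_like(jid_all)
    present = np.zeros((H, 2), dtype=bool)
    n_pairs = np.zeros((H, 2), dtype=np.int64)
    common, idx_new, idx_old = np.intersect1d(
        hours, features.hours, return_indices=True
    )
    jid_all[idx_new] = features.jid_all[idx_old]
    jid_social[idx_new] = features.jid_social[idx_old]
    present[idx_new] = features.present[idx_old]
    n_pairs[idx_new] = features.n_pairs[idx_old]
    return HourlyFeatureSeries(hours, jid_all, jid_social, present, n_pairs)


def jid_entropy(grid: JIDGrid | np.ndarray) -> float:
    """Differential entropy (bits) of the JID approximated on the grid.

    ``-sum p_cell * log2(p_cell / cell_area)`` with cell_area
    ``(3.5/50)^2``; a uniform density over the full support gives
    ``log2(12.25) ~ 3.615`` bits.  All-zero grids (no data) are
    undefined and return NaN.
    """
    p = grid.values if isinstance(grid, JIDGrid) else np.asarray(grid)
    total = p.sum()
    if total <= 0:
        return float("nan")
    p = p / total
    nz = p > 0
    return float(-(p[nz] * np.log2(p[nz] / CELL_AREA)).sum())


def mean_entropy(features: HourlyFeatureSeries, space: int = 0) -> float:
    """Subject-level entropy: mean JID entropy over present hours."""
    grids = features.jid_all if space == 0 else features.jid_social
    mask = features.present[:, space]
    if not mask.any():
        return float("nan")
    return float(np.mean([jid_entropy(grids[i]) for i in np.where(mask)[0]]))


def region_mass(
    values: np.ndarray, lo: float = GRID_LO, hi: float = 2.5
) -> float | np.ndarray:
    """Probability mass in the square sub-region lo <= log10-ITI < hi on
    both axes (default: the fast-ITI corner below ~316 ms)."""
    c = bin_centers()
    sel = (c >= lo) & (c < hi)
    v = np.asarray(values)
    return v[..., sel, :][..., :, sel].sum(axis=(-2, -1))
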