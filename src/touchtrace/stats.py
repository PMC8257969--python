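"""Evaluation statistics for model reconstructions of discharge counts.

Per detector channel: Pearson R between estimated and observed hourly
counts with a two-tailed t-test (t = R sqrt(n-2)/sqrt(1-R^2), dof =
n-2), Benjamini-Hochberg FDR across the family of tests, RMSE, a
daily-binned correlation (the diurnal-rhythm-free check), detector
sparsity, and the relation between model performance and data-channel
activity.

Hours whose full 9-hour behavioral context is empty are excluded from
the correlations (the model only emits its unconditional output
there).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _sstats
from statsmodels.stats.multitest import multipletests

from .detrend import DetectorSeries

__all__ = [
    "pearson_r_test",
    "bh_fdr",
    "daily_binned_correlation",
    "detector_sparsity",
    "performance_vs_activity",
    "rmse",
    "ChannelResult",
    "EvaluationReport",
    "evaluate_predictions",
]


def pearson_r_test(pred, obs) -> tuple[float, float, float]:
    """(R, t, p): sample Pearson correlation with a two-tailed t-test
    against R = 0 on n-2 degrees of freedom.

    Inputs must be paired, finite, length >= 3; zero-variance input
    yields (nan, nan, nan) — undefined, flagged by the caller.
    """
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.shape != obs.shape or pred.ndim != 1:
        raise ValueError("pred and obs must be 1-d arrays of equal length")
    n = len(pred)
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    if not (np.isfinite(pred).all() and np.isfinite(obs).all()):
        raise ValueError("inputs must be finite")
    if pred.std() == 0 or obs.std() == 0:
        return (float("nan"), float("nan"), float("nan"))
    r = float(np.corrcoef(pred, obs)[0, 1])
    r = min(1.0, max(-1.0, r))
    dof = n - 2
    if abs(r) == 1.0:
        return (r, float("inf") * np.sign(r), 0.0)
    t = r * np.sqrt(dof) / np.sqrt(1.0 - r * r)
    p = 2.0 * _sstats.t.sf(abs(t), dof)
    return (r, float(t), float(p))


def bh_fdr(pvals, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up procedure (independent / positively
    correlated tests): (reject flags, monotone adjusted p-values)."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any((pvals < 0) | (pvals > 1) | ~np.isfinite(pvals)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, adj, *_ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    return reject, adj


def rmse(pred, obs) -> float:
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    return float(np.sqrt(np.mean((pred - obs) ** 2)))


def daily_binned_correlation(
    pred, obs, hours, mask=None
) -> tuple[float, float, int]:
    """Correlation of day-summed series: (R_daily, p_daily, n_days).

    Both series are summed within calendar days (24-hour epoch-day
    bins); days with any masked or missing hour are dropped entirely so
    daily sums stay comparable.  Requires >= 5 complete days.
    """
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    hours = np.asarray(hours)
    if mask is None:
        mask = np.ones(len(hours), dtype=bool)
    days = hours // 24
    p_sum, o_sum = [], []
    for d in np.unique(days):
        sel = days == d
        if sel.sum() == 24 and mask[sel].all():
            p_sum.append(pred[sel].sum())
            o_sum.append(obs[sel].sum())
    if len(p_sum) < 5:
        raise ValueError(f"only {len(p_sum)} complete days; need >= 5")
    r, _, p = pearson_r_test(np.array(p_sum), np.array(o_sum))
    return r, p, len(p_sum)


def detector_sparsity(series: DetectorSeries) -> np.ndarray:
    """Fraction of recorded hours with zero counts, per detector
    (1 = never active, 0 = at least one event every hour)."""
    if len(series.hours) == 0:
        raise ValueError("empty detector series")
    return series.sparsity()


def performance_vs_activity(
    model_r: np.ndarray, sparsity: np.ndarray, entropy: np.ndarray | None = None
):
    """Correlate per-detector model R against detector sparsity (and,
    optionally, against mean JID entropy): {(R, t, p)} per diagnostic.

    Undefined (constant-input) correlations come back as NaN triples.
    """
    model_r = np.asarray(model_r, dtype=float)
    if len(model_r) < 4:
        raise ValueError("need >= 4 detector-level results")
    out = {}
    sparsity = np.asarray(sparsity, dtype=float)
    if sparsity.std() == 0:
        out["sparsity"] = (float("nan"), float("nan"), float("nan"))
    else:
        out["sparsity"] = pearson_r_test(model_r, sparsity)
    if entropy is not None:
        entropy = np.asarray(entropy, dtype=float)
        if entropy.std() == 0:
            out["entropy"] = (float("nan"), float("nan"), float("nan"))
        else:
            out["entropy"] = pearson_r_test(model_r, entropy)
    return out


@dataclass
class ChannelResult:
    name: str
    r: float
    t: float
    dof: int
    p: float
    fdr_rejected: bool
    rmse: float
    n_hours_evaluated: int


@dataclass
class EvaluationReport:
    channels: list[ChannelResult]
    daily: dict = field(default_factory=dict)       # name -> (R_daily, p_daily, n_days)
    diagnostics: dict = field(default_factory=dict)  # sparsity, mean entropy, ...

    def to_dict(self) -> dict:
        return {
            "channels": [c.__dict__ for c in self.channels],
            "daily": {k: list(v) for k, v in self.daily.items()},
            "diagnostics": self.diagnostics,
        }


def evaluate_predictions(
    pred_point: np.ndarray,
    targets: np.ndarray,
    hours: np.ndarray,
    evaluable: np.ndarray,
    channel_names: list[str],
    alpha: float = 0.05,
    daily: bool = True,
) -> EvaluationReport:
    """Full per-channel evaluation of point predictions.

    ``evaluable`` marks hours with behavioral data somewhere in the
    context window; only those enter R / RMSE.  FDR is applied across
    the channels evaluated here (family membership is the caller's
    choice — pass a combined family through ``bh_fdr`` directly for
    multi-subject corrections).
    """
    results = []
    pvals = []
    for c, name in enumerate(channel_names):
        sel = evaluable
        n = int(sel.sum())
        r, t, p = pearson_r_test(pred_point[sel, c], targets[sel, c])
        results.append(
            ChannelResult(
                name=name,
                r=r,
                t=t,
                dof=n - 2,
                p=p,
                fdr_rejected=False,
                rmse=rmse(pred_point[sel, c], targets[sel, c]),
                n_hours_evaluated=n,
            )
        )
        pvals.append(p if np.isfinite(p) else 1.0)
    reject, _ = bh_fdr(np.array(pvals), alpha=alpha)
    for res, rej in zip(results, reject):
        res.fdr_rejected = bool(rej)
    report = EvaluationReport(channels=results)
    if daily:
        for c, name in enumerate(channel_names):
            try:
                report.daily[name] = daily_binned_correlation(
                    pred_point[:, c], targets[:, c], hours, evaluable
                )
            except ValueError:
                pass
    return report
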