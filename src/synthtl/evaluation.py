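"""Forecast scoring and paired significance assessment.

Metrics: mean absolute error (MAE), root mean squared error (RMSE) and
prediction trend accuracy (PTA) — a multi-step variant of mean
directional accuracy that scores, for every (window, horizon step,
target variable) triple, whether the predicted direction of change
relative to the forecast origin (the last input point) matches the
observed direction.  PTA is reported as 1-PTA so that lower is better
for all metrics.

Significance of a paired difference between two forecasting arms (e.g.
transfer learning vs the uninformed baseline) is assessed with a moving
blocked bootstrap over time points combined with paired resampling over
seeds: the same resampled time blocks and the same resampled seed
indices are applied to both arms, the aggregated metric difference is
recomputed per replicate, and a percentile confidence interval is
reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, Optional, Tuple, Union

import numpy as np

from synthtl.forecasting import ForecastSet

__all__ = [
    "BootstrapResult",
    "mae",
    "rmse",
    "pta",
    "relative_change",
    "forecast_mae",
    "forecast_rmse",
    "forecast_pta",
    "per_timepoint_abs_error",
    "per_timepoint_trend_error",
    "blocked_bootstrap_diff_ci",
    "significance_flag",
]


def _check_shapes(pred: np.ndarray, obs: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.shape != obs.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {obs.shape}")
    if pred.size == 0:
        raise ValueError("empty input")
    return pred, obs


def mae(pred: np.ndarray, obs: np.ndarray) -> float:
    """Mean absolute elementwise error."""
    pred, obs = _check_shapes(pred, obs)
    return float(np.mean(np.abs(pred - obs)))


def rmse(pred: np.ndarray, obs: np.ndarray) -> float:
    """Root mean squared elementwise error (always >= MAE)."""
    pred, obs = _check_shapes(pred, obs)
    return float(np.sqrt(np.mean((pred - obs) ** 2)))


def pta(pred_windows: np.ndarray, obs_windows: np.ndarray,
        last_inputs: np.ndarray) -> float:
    """Prediction trend accuracy in [0, 1].

    Over all (window, horizon step h, target variable) triples, the
    fraction where sign(pred_{t0+h} - y_t0) equals
    sign(obs_{t0+h} - y_t0), with y_t0 the forecast-origin value (the
    last input point).  A zero change only matches a zero change, so
    flat forecasts get no credit for observed moves.
    """
    pred = np.asarray(pred_windows, dtype=float)
    obs = np.asarray(obs_windows, dtype=float)
    y0 = np.asarray(last_inputs, dtype=float)
    if pred.shape != obs.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {obs.shape}")
    if pred.size == 0:
        raise ValueError("empty input")
    if y0.shape != pred.shape[:1] + pred.shape[2:]:
        raise ValueError(
            f"origin values shape {y0.shape} incompatible with windows {pred.shape}")
    anchor = y0[:, None, ...]
    return float(np.mean(np.sign(pred - anchor) == np.sign(obs - anchor)))


def relative_change(tl_metric: float, baseline_metric: float) -> float:
    """Signed percent change of the TL metric vs a baseline; negative is
    an improvement."""
    if baseline_metric == 0:
        raise ZeroDivisionError("relative change undefined for zero baseline metric")
    return 100.0 * (tl_metric - baseline_metric) / baseline_metric


# -- convenience wrappers over ForecastSet ----------------------------------

def forecast_mae(fs: ForecastSet) -> float:
    return mae(fs.preds, fs.obs)


def forecast_rmse(fs: ForecastSet) -> float:
    return rmse(fs.preds, fs.obs)


def forecast_pta(fs: ForecastSet) -> float:
    return pta(fs.preds, fs.obs, fs.origin_values)


def per_timepoint_abs_error(fs: ForecastSet, n_timepoints: int) -> np.ndarray:
    """Mean absolute error per context time index.

    For overlapping windows, the error at a time point is the mean over
    all (window, target variable) cells whose target covers that point;
    points never forecast are NaN.  This defines the "over time points"
    axis of the blocked bootstrap operationally.
    """
    total = np.zeros(n_timepoints)
    count = np.zeros(n_timepoints)
    err = np.abs(fs.preds - fs.obs).mean(axis=2)  # (K, H)
    for k in range(fs.n_windows):
        idx = fs.target_time_idx[k]
        np.add.at(total, idx, err[k])
        np.add.at(count, idx, 1.0)
    with np.errstate(invalid="ignore"):
        return np.where(count > 0, total / np.maximum(count, 1), np.nan)


def per_timepoint_trend_error(fs: ForecastSet, n_timepoints: int) -> np.ndarray:
    """1 - (trend accuracy) per context time index, averaged over the
    windows and variables covering that point."""
    anchor = fs.origin_values[:, None, :]
    wrong = (np.sign(fs.preds - anchor) != np.sign(fs.obs - anchor)).mean(axis=2)
    total = np.zeros(n_timepoints)
    count = np.zeros(n_timepoints)
    for k in range(fs.n_windows):
        idx = fs.target_time_idx[k]
        np.add.at(total, idx, wrong[k])
        np.add.at(count, idx, 1.0)
    with np.errstate(invalid="ignore"):
        return np.where(count > 0, total / np.maximum(count, 1), np.nan)


@dataclass
class BootstrapResult:
    """Percentile CI for a paired metric difference (arm A - arm B)."""

    estimate: float
    ci_lower: float
    ci_upper: float
    level: float
    block_len: int
    n_boot: int
    seed: int

    def to_dict(self) -> Dict:
        return {"estimate": self.estimate, "ci_lower": self.ci_lower,
                "ci_upper": self.ci_upper, "level": self.level,
                "block_len": self.block_len, "n_boot": self.n_boot,
                "seed": self.seed}


MetricAggregator = Union[str, Callable[[np.ndarray], float]]


def _resolve_aggregator(metric: MetricAggregator) -> Callable[[np.ndarray], float]:
    if callable(metric):
        return metric
    if metric in ("mae", "1-pta", "mean"):
        # per-time-point errors are already absolute errors / trend-error
        # fractions, so the aggregate is their mean over seeds and time
        return lambda m: float(np.nanmean(m))
    raise ValueError(f"unknown metric aggregator {metric!r}")


def _moving_block_indices(n_time: int, block_len: int,
                          rng: np.random.Generator) -> np.ndarray:
    """Sample moving blocks with replacement until >= n_time, truncate."""
    if n_time <= block_len:
        return np.arange(n_time)
    n_blocks = int(np.ceil(n_time / block_len))
    starts = rng.integers(0, n_time - block_len + 1, size=n_blocks)
    idx = np.concatenate([np.arange(s, s + block_len) for s in starts])
    return idx[:n_time]


def blocked_bootstrap_diff_ci(errors_a: np.ndarray, errors_b: np.ndarray,
                              metric: MetricAggregator = "mae",
                              block_len: Optional[int] = None,
                              n_boot: int = 1000, level: float = 0.95,
                              seed: int = 0) -> BootstrapResult:
    """Paired moving-block bootstrap CI for the difference in an
    aggregated metric between two arms.

    ``errors_a`` and ``errors_b`` are (n_seeds, n_time) matrices of
    per-time-point errors on the same grid and seed set.  Each replicate
    resamples time blocks and seed indices with replacement, identically
    in both arms, then recomputes aggregate(A) - aggregate(B); the CI is
    the percentile interval at ``level``.  Default block length is
    ceil(n_time ** (1/3)).
    """
    a = np.atleast_2d(np.asarray(errors_a, dtype=float))
    b = np.atleast_2d(np.asarray(errors_b, dtype=float))
    if a.shape != b.shape:
        raise ValueError(f"paired error matrices must share shape: "
                         f"{a.shape} vs {b.shape}")
    n_seeds, n_time = a.shape
    if block_len is None:
        block_len = int(np.ceil(n_time ** (1.0 / 3.0)))
    if block_len < 1:
        raise ValueError("block_len must be >= 1")
    agg = _resolve_aggregator(metric)
    rng = np.random.default_rng(seed)
    estimate = agg(a) - agg(b)
    diffs = np.empty(n_boot)
    for r in range(n_boot):
        t_idx = _moving_block_indices(n_time, block_len, rng)
        s_idx = rng.integers(0, n_seeds, size=n_seeds)
        ra = a[np.ix_(s_idx, t_idx)]
        rb = b[np.ix_(s_idx, t_idx)]
        diffs[r] = agg(ra) - agg(rb)
    alpha = 1.0 - level
    lo, hi = np.quantile(diffs, [alpha / 2, 1 - alpha / 2])
    return BootstrapResult(estimate=float(estimate), ci_lower=float(lo),
                           ci_upper=float(hi), level=level,
                           block_len=block_len, n_boot=n_boot, seed=seed)


def significance_flag(result: BootstrapResult) -> bool:
    """True iff the confidence interval excludes zero (the boundary
    counts as non-exclusion)."""
    return bool(result.ci_lower > 0 or result.ci_upper < 0)
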