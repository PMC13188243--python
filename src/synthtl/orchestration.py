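"""Experiment runners: the size x diversity grid, the noise study,
best-configuration selection, splits, and dataset file I/O.

The study design: for every combination of synthetic dataset size and
diversity class (IC interval width x KP interval width), generate a
noise-free synthetic dataset, pre-train each architecture on it for each
seed, fine-tune the head on the target's training region, and score the
forecasts on the held-out test region against a paired uninformed DL
baseline (same architecture and seed, random initialisation) and a
single ODE-calibration baseline.  Noise enters only in a dedicated
follow-up study run at the best-performing (size, diversity) cell.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from synthtl.baselines import (CalibrationResult, calibrate_ode,
                               forecast_ode, train_dl_baseline)
from synthtl.evaluation import (blocked_bootstrap_diff_ci, forecast_mae,
                                forecast_pta, forecast_rmse,
                                per_timepoint_abs_error,
                                per_timepoint_trend_error, relative_change,
                                significance_flag)
from synthtl.forecasting import (ForecastModel, ForecastSet, TrainConfig,
                                 build_model, finetune, predict_series,
                                 pretrain)
from synthtl.ode_library import OdeSystem, get_system
from synthtl.synth_generator import (DEFAULT_NOISE_LEVELS, DiversityConfig,
                                     GenerationError, NoiseConfig, TimeGrid,
                                     TimeSeriesDataset, Trajectory,
                                     generate_dataset)

logger = logging.getLogger("synthtl")

__all__ = [
    "ExperimentConfig",
    "TargetSplit",
    "GridResult",
    "split_target",
    "run_grid",
    "select_best",
    "run_noise_study",
    "read_timeseries_csv",
    "write_timeseries_csv",
]


# ---------------------------------------------------------------------------
# Configuration and splits
# ---------------------------------------------------------------------------

@dataclass
class ExperimentConfig:
    """Everything needed to run the grid and noise studies.

    Defaults follow the standard study layout: sizes (1, 10, 100, 1000),
    four diversity classes for ICs and for KPs (16 diversity
    configurations per size), four architectures, five seeds, and six
    noise levels per noise (kind, operation) pair.
    """

    system: str
    train_end: int                       # inclusive index of the last train/val point
    input_len: int = 5
    horizon: int = 5
    target_vars: Optional[Sequence[str]] = None
    sizes: Sequence[int] = (1, 10, 100, 1000)
    ic_classes: Sequence[str] = ("S", "M", "L", "XL")
    kp_classes: Sequence[str] = ("S", "M", "L", "XL")
    architectures: Sequence[str] = ("LSTM", "GRU", "CNN", "DNN")
    seeds: Sequence[int] = (0, 1, 2, 3, 4)
    noise_pairs: Sequence[Tuple[str, str]] = (("measurement", "multiplicative"),
                                              ("environmental", "multiplicative"))
    noise_levels: Sequence[float] = DEFAULT_NOISE_LEVELS
    train: TrainConfig = field(default_factory=TrainConfig)
    bootstrap_n: int = 1000
    bootstrap_level: float = 0.95
    block_len: Optional[int] = None
    centers: Optional[Dict[str, float]] = None
    out_dir: Optional[str] = None

    def diversity_for(self, system: OdeSystem, ic_class: str,
                      kp_class: str) -> DiversityConfig:
        return DiversityConfig.from_classes(system, ic_class, kp_class,
                                            self.centers)

    def n_diversity_configurations(self) -> int:
        return len(self.ic_classes) * len(self.kp_classes)

    def n_grid_cells(self) -> int:
        return (len(self.sizes) * self.n_diversity_configurations()
                * len(self.architectures) * len(self.seeds))


@dataclass
class TargetSplit:
    """Train/validation/test partition of a target series.

    ``trainval`` covers indices 0..train_end (inclusive) and is what DL
    training (with its internal validation tail) and ODE calibration
    see; the test region is the half-open index range [train_end+1, N).
    """

    full: Trajectory
    train_end: int
    trainval: Trajectory
    test_region: Tuple[int, int]


def split_target(target: Trajectory, train_end: int,
                 horizon: int = 1) -> TargetSplit:
    """Split a target series at an inclusive training-boundary index."""
    n = target.grid.n_points
    if not 0 < train_end < n - 1:
        raise ValueError(f"train_end={train_end} out of range for series "
                         f"of {n} points")
    n_test = n - (train_end + 1)
    if n_test < horizon:
        raise ValueError(f"test region has {n_test} points, shorter than "
                         f"forecast horizon {horizon}")
    trainval = Trajectory(target.series_id + "/trainval",
                          TimeGrid(target.grid.points[:train_end + 1]),
                          target.values[:train_end + 1], target.variables)
    return TargetSplit(full=target, train_end=train_end, trainval=trainval,
                       test_region=(train_end + 1, n))


# ---------------------------------------------------------------------------
# Grid result container
# ---------------------------------------------------------------------------

@dataclass
class GridResult:
    """Per-(cell, seed) metric table plus per-cell aggregates.

    ``table`` has one row per attempted (size, ic, kp, architecture,
    seed) cell; failed cells are recorded with their failure reason,
    never dropped.  ``aggregates`` summarises each (size, ic, kp,
    architecture) over seeds: mean metrics, relative changes vs the
    paired DL baseline and the ODE baseline, bootstrap CIs and
    significance flags.
    """

    table: pd.DataFrame
    aggregates: pd.DataFrame
    ode_metrics: Dict[str, float] = field(default_factory=dict)

    def n_attempted(self) -> int:
        return len(self.table)

    def n_failed(self) -> int:
        return int((~self.table["success"]).sum()) if len(self.table) else 0


# ---------------------------------------------------------------------------
# Single-arm runners
# ---------------------------------------------------------------------------

def _metrics_from_fs(fs: ForecastSet) -> Dict[str, float]:
    p = forecast_pta(fs)
    return {"mae": forecast_mae(fs), "rmse": forecast_rmse(fs),
            "pta": p, "one_minus_pta": 1.0 - p}


def run_tl_arm(dataset: TimeSeriesDataset, split: TargetSplit,
               architecture: str, seed: int, cfg: ExperimentConfig
               ) -> Tuple[ForecastModel, ForecastSet]:
    """Pre-train on synthetic data, fine-tune the head on the target's
    training region, forecast the test region."""
    tv = list(cfg.target_vars) if cfg.target_vars else list(split.full.variables)
    tc = TrainConfig(**{**asdict(cfg.train), "seed": seed})
    model = build_model(architecture, cfg.input_len,
                        len(split.full.variables), cfg.horizon, len(tv),
                        seed=seed)
    model.target_vars = tv
    model, _ = pretrain(model, dataset, tc, target_vars=tv)
    model, _ = finetune(model, split.trainval, tc)
    fs = predict_series(model, split.full, split.test_region)
    return model, fs


def run_dl_arm(split: TargetSplit, architecture: str, seed: int,
               cfg: ExperimentConfig) -> Tuple[ForecastModel, ForecastSet]:
    """Train the same architecture from random initialisation on the
    target's training region only (paired seed with the TL arm)."""
    tv = list(cfg.target_vars) if cfg.target_vars else list(split.full.variables)
    tc = TrainConfig(**{**asdict(cfg.train), "seed": seed})
    init = build_model(architecture, cfg.input_len,
                       len(split.full.variables), cfg.horizon, len(tv),
                       seed=seed)
    init.target_vars = tv
    model, _ = train_dl_baseline(init, split.trainval, tc)
    fs = predict_series(model, split.full, split.test_region)
    return model, fs


def run_ode_arm(system: OdeSystem, split: TargetSplit, cfg: ExperimentConfig,
                seed: int = 0) -> Tuple[CalibrationResult, ForecastSet]:
    """Calibrate the ODE on train+validation and forecast the test region.

    The single continued simulation is evaluated through the same
    windowed ForecastSet machinery as the DL arms: for each evaluation
    window the prediction is the simulation's value at the window's
    target times, and the trend anchor is the observed value at the
    forecast origin.
    """
    calib = calibrate_ode(system, split.trainval, seed=seed)
    start, stop = split.test_region
    future_pts = split.full.grid.points[start:stop]
    ode_fc = forecast_ode(system, calib, split.trainval.grid, future_pts)
    tv = list(cfg.target_vars) if cfg.target_vars else list(split.full.variables)
    t_idx = [list(split.full.variables).index(v) for v in tv]
    lin, h = cfg.input_len, cfg.horizon
    preds, obs, origins, tidx = [], [], [], []
    for first_target in range(max(start, lin), stop - h + 1):
        rel = np.arange(first_target, first_target + h) - start
        preds.append(ode_fc.values[rel][:, t_idx])
        obs.append(split.full.values[first_target:first_target + h][:, t_idx])
        origins.append(split.full.values[first_target - 1, t_idx])
        tidx.append(np.arange(first_target, first_target + h))
    fs = ForecastSet(np.stack(preds), np.stack(obs), np.stack(origins),
                     np.stack(tidx), tv)
    return calib, fs


# ---------------------------------------------------------------------------
# Grid runner
# ---------------------------------------------------------------------------

def _default_grid(target: Trajectory) -> TimeGrid:
    return target.grid


def _cell_key_hash(parts: Sequence) -> str:
    return hashlib.sha1(json.dumps(list(map(str, parts))).encode()).hexdigest()[:12]


def run_grid(cfg: ExperimentConfig, target: Trajectory,
             grid: Optional[TimeGrid] = None) -> GridResult:
    """Run the full size x diversity x architecture x seed grid.

    Synthetic datasets are generated without noise; noise is studied
    separately by :func:`run_noise_study`.  Individual cell failures are
    logged and recorded, and the run continues.  Per-cell results are
    written incrementally to ``cfg.out_dir`` when set, keyed by a hash of
    the cell configuration, making interrupted runs resumable.
    """
    system = get_system(cfg.system)
    split = split_target(target, cfg.train_end, cfg.horizon)
    sim_grid = grid if grid is not None else _default_grid(target)
    out_dir = Path(cfg.out_dir) if cfg.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    n_time = target.grid.n_points
    test_slice = slice(*split.test_region)

    # ODE baseline: one calibration per target
    try:
        _, ode_fs = run_ode_arm(system, split, cfg)
        ode_metrics = _metrics_from_fs(ode_fs)
    except Exception as exc:  # record, keep going
        logger.warning("ODE baseline failed: %s", exc)
        ode_metrics = {"mae": np.nan, "rmse": np.nan, "pta": np.nan,
                       "one_minus_pta": np.nan, "failure": str(exc)}

    # DL baselines: one per (architecture, seed), shared across cells
    dl_cache: Dict[Tuple[str, int], Dict] = {}
    for arch in cfg.architectures:
        for seed in cfg.seeds:
            _, fs = run_dl_arm(split, arch, seed, cfg)
            dl_cache[(arch, seed)] = {
                "metrics": _metrics_from_fs(fs),
                "abs_err": per_timepoint_abs_error(fs, n_time)[test_slice],
                "trend_err": per_timepoint_trend_error(fs, n_time)[test_slice],
            }

    rows: List[Dict] = []
    agg_rows: List[Dict] = []
    for size in cfg.sizes:
        for ic in cfg.ic_classes:
            for kp in cfg.kp_classes:
                diversity = cfg.diversity_for(system, ic, kp)
                try:
                    dataset = generate_dataset(
                        system, diversity, NoiseConfig(kind="none"), size,
                        sim_grid, seed=_stable_seed(cfg.system, size, ic, kp))
                except GenerationError as exc:
                    logger.warning("cell (%s,%s,%s) generation failed: %s",
                                   size, ic, kp, exc)
                    for arch in cfg.architectures:
                        for seed in cfg.seeds:
                            rows.append(_failed_row(size, ic, kp, arch, seed,
                                                    f"generation: {exc}"))
                    continue
                for arch in cfg.architectures:
                    tl_abs, tl_trend, cell_rows = [], [], []
                    for seed in cfg.seeds:
                        cache_file = (out_dir / f"cell_{_cell_key_hash((cfg.system, size, ic, kp, arch, seed))}.json"
                                      ) if out_dir else None
                        if cache_file and cache_file.exists():
                            row = json.loads(cache_file.read_text())
                            row["_abs_err"] = np.array(row.pop("abs_err_list"))
                            row["_trend_err"] = np.array(row.pop("trend_err_list"))
                        else:
                            row = _run_cell(dataset, split, arch, seed, cfg,
                                            n_time, test_slice, size, ic, kp,
                                            dl_cache[(arch, seed)])
                            if cache_file:
                                dump = {k: v for k, v in row.items()
                                        if not k.startswith("_")}
                                dump["abs_err_list"] = row["_abs_err"].tolist()
                                dump["trend_err_list"] = row["_trend_err"].tolist()
                                cache_file.write_text(json.dumps(dump))
                        cell_rows.append(row)
                        if row["success"]:
                            tl_abs.append(row["_abs_err"])
                            tl_trend.append(row["_trend_err"])
                    rows.extend(cell_rows)
                    agg_rows.append(_aggregate_cell(
                        size, ic, kp, arch, cell_rows, tl_abs, tl_trend,
                        dl_cache, cfg, ode_metrics))

    table = pd.DataFrame([{k: v for k, v in r.items() if not k.startswith("_")}
                          for r in rows])
    aggregates = pd.DataFrame(agg_rows)
    result = GridResult(table=table, aggregates=aggregates,
                        ode_metrics=ode_metrics)
    if out_dir:
        table.to_csv(out_dir / "grid_table.csv", index=False)
        aggregates.to_csv(out_dir / "grid_aggregates.csv", index=False)
    return result


def _stable_seed(*parts) -> int:
    h = hashlib.sha1(json.dumps(list(map(str, parts))).encode()).digest()
    return int.from_bytes(h[:4], "little") % (2 ** 31)


def _failed_row(size, ic, kp, arch, seed, reason) -> Dict:
    return {"size": size, "ic_class": ic, "kp_class": kp, "architecture": arch,
            "seed": seed, "success": False, "failure": reason,
            "mae": np.nan, "rmse": np.nan, "pta": np.nan,
            "one_minus_pta": np.nan, "dl_mae": np.nan,
            "dl_one_minus_pta": np.nan,
            "_abs_err": np.array([]), "_trend_err": np.array([])}


def _run_cell(dataset, split, arch, seed, cfg, n_time, test_slice,
              size, ic, kp, dl_entry) -> Dict:
    try:
        _, fs = run_tl_arm(dataset, split, arch, seed, cfg)
        m = _metrics_from_fs(fs)
        return {"size": size, "ic_class": ic, "kp_class": kp,
                "architecture": arch, "seed": seed, "success": True,
                "failure": "", **m,
                "dl_mae": dl_entry["metrics"]["mae"],
                "dl_one_minus_pta": dl_entry["metrics"]["one_minus_pta"],
                "_abs_err": per_timepoint_abs_error(fs, n_time)[test_slice],
                "_trend_err": per_timepoint_trend_error(fs, n_time)[test_slice]}
    except Exception as exc:
        logger.warning("cell (%s,%s,%s,%s,seed=%s) failed: %s",
                       size, ic, kp, arch, seed, exc)
        return _failed_row(size, ic, kp, arch, seed, str(exc))


def _aggregate_cell(size, ic, kp, arch, cell_rows, tl_abs, tl_trend,
                    dl_cache, cfg, ode_metrics) -> Dict:
    ok = [r for r in cell_rows if r["success"]]
    out = {"size": size, "ic_class": ic, "kp_class": kp, "architecture": arch,
           "n_seeds": len(cell_rows), "n_success": len(ok)}
    if not ok:
        out.update({"mean_mae": np.nan, "mean_rmse": np.nan,
                    "mean_one_minus_pta": np.nan})
        return out
    out["mean_mae"] = float(np.mean([r["mae"] for r in ok]))
    out["mean_rmse"] = float(np.mean([r["rmse"] for r in ok]))
    out["mean_one_minus_pta"] = float(np.mean([r["one_minus_pta"] for r in ok]))
    seeds_ok = [r["seed"] for r in ok]
    dl_mae = float(np.mean([dl_cache[(arch, s)]["metrics"]["mae"] for s in seeds_ok]))
    dl_1mpta = float(np.mean([dl_cache[(arch, s)]["metrics"]["one_minus_pta"]
                              for s in seeds_ok]))
    out["dl_mean_mae"] = dl_mae
    out["dl_mean_one_minus_pta"] = dl_1mpta
    try:
        out["rel_mae_vs_dl"] = relative_change(out["mean_mae"], dl_mae)
        out["rel_1mpta_vs_dl"] = (relative_change(out["mean_one_minus_pta"], dl_1mpta)
                                  if dl_1mpta > 0 else np.nan)
    except ZeroDivisionError:
        out["rel_mae_vs_dl"] = np.nan
        out["rel_1mpta_vs_dl"] = np.nan
    if np.isfinite(ode_metrics.get("mae", np.nan)) and ode_metrics["mae"] > 0:
        out["rel_mae_vs_ode"] = relative_change(out["mean_mae"], ode_metrics["mae"])
    else:
        out["rel_mae_vs_ode"] = np.nan
    # paired blocked bootstrap over the test region
    if tl_abs:
        a = np.stack(tl_abs)
        b = np.stack([dl_cache[(arch, s)]["abs_err"] for s in seeds_ok])
        res = blocked_bootstrap_diff_ci(a, b, metric="mae",
                                        block_len=cfg.block_len,
                                        n_boot=cfg.bootstrap_n,
                                        level=cfg.bootstrap_level,
                                        seed=_stable_seed(size, ic, kp, arch))
        out["mae_diff_ci_lower"] = res.ci_lower
        out["mae_diff_ci_upper"] = res.ci_upper
        out["mae_diff_significant"] = significance_flag(res)
        at = np.stack(tl_trend)
        bt = np.stack([dl_cache[(arch, s)]["trend_err"] for s in seeds_ok])
        res_t = blocked_bootstrap_diff_ci(at, bt, metric="1-pta",
                                          block_len=cfg.block_len,
                                          n_boot=cfg.bootstrap_n,
                                          level=cfg.bootstrap_level,
                                          seed=_stable_seed(size, ic, kp, arch, "pta"))
        out["pta_diff_ci_lower"] = res_t.ci_lower
        out["pta_diff_ci_upper"] = res_t.ci_upper
        out["pta_diff_significant"] = significance_flag(res_t)
    return out


# ---------------------------------------------------------------------------
# Selection and noise study
# ---------------------------------------------------------------------------

def select_best(results: GridResult) -> Dict:
    """Pick the best (size, ic_class, kp_class, architecture) cell.

    Ranked by mean MAE across seeds; ties broken by mean 1-PTA, then by
    smaller dataset size.
    """
    agg = results.aggregates
    ok = agg[agg["n_success"] > 0].dropna(subset=["mean_mae"])
    if len(ok) == 0:
        raise ValueError("no successful cells to select from")
    ok = ok.sort_values(["mean_mae", "mean_one_minus_pta", "size"],
                        kind="mergesort")
    best = ok.iloc[0]
    return {"size": int(best["size"]), "ic_class": best["ic_class"],
            "kp_class": best["kp_class"], "architecture": best["architecture"],
            "mean_mae": float(best["mean_mae"]),
            "mean_one_minus_pta": float(best["mean_one_minus_pta"])}


def run_noise_study(cfg: ExperimentConfig, target: Trajectory,
                    best: Dict, grid: Optional[TimeGrid] = None) -> pd.DataFrame:
    """Rerun TL at the best (size, diversity, architecture) under each
    noise (kind, operation) pair and level.

    Only one noise type and operation is active at a time.  Infeasible
    combinations (generation failures, e.g. environmental noise driving
    stiff systems unstable) are recorded with their reason and skipped.
    """
    system = get_system(cfg.system)
    split = split_target(target, cfg.train_end, cfg.horizon)
    sim_grid = grid if grid is not None else _default_grid(target)
    diversity = cfg.diversity_for(system, best["ic_class"], best["kp_class"])
    arch = best["architecture"]
    size = best["size"]
    rows = []
    for kind, op in cfg.noise_pairs:
        for level in cfg.noise_levels:
            noise = NoiseConfig(kind=kind, operation=op, level=level)
            try:
                dataset = generate_dataset(
                    system, diversity, noise, size, sim_grid,
                    seed=_stable_seed(cfg.system, size, kind, op, level))
            except GenerationError as exc:
                rows.append({"noise_kind": kind, "noise_operation": op,
                             "noise_level": level, "seed": np.nan,
                             "success": False, "failure": str(exc),
                             "mae": np.nan, "one_minus_pta": np.nan})
                continue
            for seed in cfg.seeds:
                try:
                    _, fs = run_tl_arm(dataset, split, arch, seed, cfg)
                    m = _metrics_from_fs(fs)
                    rows.append({"noise_kind": kind, "noise_operation": op,
                                 "noise_level": level, "seed": seed,
                                 "success": True, "failure": "", **m})
                except Exception as exc:
                    rows.append({"noise_kind": kind, "noise_operation": op,
                                 "noise_level": level, "seed": seed,
                                 "success": False, "failure": str(exc),
                                 "mae": np.nan, "one_minus_pta": np.nan})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def write_timeseries_csv(dataset: TimeSeriesDataset, path,
                         sidecar: bool = True) -> None:
    """Write a dataset as wide CSV (`series_id,time,<vars...>`), one row
    per (series, time point), with a JSON provenance sidecar."""
    frames = []
    for tr in dataset.trajectories:
        df = pd.DataFrame(tr.values, columns=list(tr.variables))
        df.insert(0, "time", tr.grid.points)
        df.insert(0, "series_id", tr.series_id)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    if sidecar and dataset.config:
        Path(str(path) + ".provenance.json").write_text(
            json.dumps({"config": dataset.config, "seed": dataset.master_seed},
                       default=str, indent=1))


def read_timeseries_csv(path, system_name: str = "unknown") -> TimeSeriesDataset:
    """Read a wide CSV dataset; rows are sorted by (series_id, time)."""
    df = pd.read_csv(path)
    for col in ("series_id", "time"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    var_cols = [c for c in df.columns if c not in ("series_id", "time")]
    if not var_cols:
        raise ValueError(f"{path}: no variable columns found")
    bad = df[var_cols + ["time"]].apply(
        lambda c: pd.to_numeric(c, errors="coerce")).isna()
    if bad.to_numpy().any():
        rows = sorted(set(bad.any(axis=1).to_numpy().nonzero()[0].tolist()))
        raise ValueError(f"{path}: non-numeric cells in rows {rows[:10]}")
    df = df.sort_values(["series_id", "time"], kind="mergesort")
    trajectories = []
    for sid, group in df.groupby("series_id", sort=True):
        times = group["time"].to_numpy(dtype=float)
        if np.any(np.diff(times) <= 0):
            raise ValueError(f"{path}: non-monotone time for series {sid!r}")
        trajectories.append(Trajectory(str(sid), TimeGrid(times),
                                       group[var_cols].to_numpy(dtype=float),
                                       var_cols))
    return TimeSeriesDataset(system_name, trajectories)
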