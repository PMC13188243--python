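"""Sliding-window neural forecasters with pre-training and fine-tuning.

The transfer-learning protocol: a model (LSTM/GRU/CNN/DNN body plus a
two-layer perceptron head) is pre-trained on a synthetic dataset until
the validation loss stops improving, then only the head — the last two
parameterised layers — is fine-tuned for a small fixed number of epochs
on the target series.  Per-variable standardisation is fitted once on
the pre-training data and reused unchanged for fine-tuning and
inference, keeping the pre-trained representations valid.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from synthtl import nnet
from synthtl.synth_generator import TimeGrid, TimeSeriesDataset, Trajectory

__all__ = [
    "WindowSet",
    "ForecastModel",
    "TrainConfig",
    "ForecastSet",
    "make_windows",
    "dataset_windows",
    "build_model",
    "pretrain",
    "finetune",
    "predict_series",
]


@dataclass
class WindowSet:
    """Supervised windows cut from one or more series.

    ``inputs``: (K, L_in, n_vars); ``targets``: (K, H, n_targets);
    ``origins``: per-window (series_id, index of the last input point).
    """

    inputs: np.ndarray
    targets: np.ndarray
    origins: List[Tuple[str, int]]
    target_variable_names: Sequence[str]

    @property
    def n_windows(self) -> int:
        return self.inputs.shape[0]

    def concat(self, other: "WindowSet") -> "WindowSet":
        if self.n_windows == 0:
            return other
        if other.n_windows == 0:
            return self
        return WindowSet(np.concatenate([self.inputs, other.inputs]),
                         np.concatenate([self.targets, other.targets]),
                         self.origins + other.origins,
                         self.target_variable_names)


@dataclass
class TrainConfig:
    """Optimisation settings shared by pre-training, fine-tuning and the
    uninformed baseline."""

    max_epochs: int = 200
    patience: int = 5
    batch_size: int = 32
    learning_rate: float = 1e-3
    val_fraction: float = 0.10
    fine_tune_epochs: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.val_fraction < 1:
            raise ValueError("val_fraction must lie in (0, 1)")
        if self.fine_tune_epochs < 1:
            raise ValueError("fine_tune_epochs must be >= 1")


@dataclass
class ForecastModel:
    """Architecture + body/head parameter partition + scaler.

    The head always has exactly two parameterised layers; with the
    head-only trainable mask, body parameters are bit-identical before
    and after training.
    """

    architecture: str
    network: nnet.Network
    params: nnet.Params
    input_len: int
    horizon: int
    n_vars: int
    n_targets: int
    hyper: Dict = field(default_factory=dict)
    seed: int = 0
    scaler_mean: Optional[np.ndarray] = None   # per input variable
    scaler_std: Optional[np.ndarray] = None
    variables: Optional[Sequence[str]] = None
    target_vars: Optional[Sequence[str]] = None

    @property
    def body_param_names(self) -> List[str]:
        return [k for k in self.params if k.startswith("body.")]

    @property
    def head_param_names(self) -> List[str]:
        return [k for k in self.params if k.startswith("head.")]

    def copy(self) -> "ForecastModel":
        return replace(self, params={k: v.copy() for k, v in self.params.items()},
                       scaler_mean=None if self.scaler_mean is None else self.scaler_mean.copy(),
                       scaler_std=None if self.scaler_std is None else self.scaler_std.copy())

    # -- scaling ----------------------------------------------------------
    def fit_scaler(self, values: np.ndarray) -> None:
        """Fit per-variable standardisation; ``values`` is (..., n_vars)."""
        flat = values.reshape(-1, values.shape[-1])
        self.scaler_mean = flat.mean(axis=0)
        self.scaler_std = np.maximum(flat.std(axis=0), 1e-12)

    def _require_scaler(self) -> None:
        if self.scaler_mean is None:
            raise RuntimeError("scaler not fitted; train or fit_scaler first")

    def scale_inputs(self, x: np.ndarray) -> np.ndarray:
        self._require_scaler()
        return (x - self.scaler_mean) / self.scaler_std

    def _target_idx(self) -> np.ndarray:
        if self.variables is None or self.target_vars is None:
            raise RuntimeError("model not bound to variable names yet")
        return np.array([list(self.variables).index(v) for v in self.target_vars])

    def scale_targets(self, y: np.ndarray) -> np.ndarray:
        self._require_scaler()
        idx = self._target_idx()
        return (y - self.scaler_mean[idx]) / self.scaler_std[idx]

    def unscale_targets(self, y: np.ndarray) -> np.ndarray:
        self._require_scaler()
        idx = self._target_idx()
        return y * self.scaler_std[idx] + self.scaler_mean[idx]

    # -- inference --------------------------------------------------------
    def predict_windows(self, inputs: np.ndarray) -> np.ndarray:
        """Forecast (K, H, n_targets) in original units from raw inputs."""
        x = self.scale_inputs(inputs)
        out = self.network.forward(x, self.params)
        out = out.reshape(-1, self.horizon, self.n_targets)
        return self.unscale_targets(out)


def make_windows(series: Trajectory, input_len: int, horizon: int,
                 target_vars: Optional[Sequence[str]] = None) -> WindowSet:
    """All maximal stride-1 sliding windows of a series.

    K = max(0, N - input_len - horizon + 1); a series too short to hold a
    single window yields an empty WindowSet with a warning so that short
    series can be skipped in aggregation.
    """
    if input_len < 1 or horizon < 1:
        raise ValueError("input_len and horizon must be >= 1")
    tv = list(target_vars) if target_vars is not None else list(series.variables)
    t_idx = [list(series.variables).index(v) for v in tv]
    n = series.grid.n_points
    k = n - input_len - horizon + 1
    if k <= 0:
        warnings.warn(f"series {series.series_id!r} has {n} points, too short "
                      f"for input_len={input_len}, horizon={horizon}")
        return WindowSet(np.empty((0, input_len, len(series.variables))),
                         np.empty((0, horizon, len(tv))), [], tv)
    inputs = np.stack([series.values[i:i + input_len] for i in range(k)])
    targets = np.stack([series.values[i + input_len:i + input_len + horizon][:, t_idx]
                        for i in range(k)])
    origins = [(series.series_id, i + input_len - 1) for i in range(k)]
    return WindowSet(inputs, targets, origins, tv)


def dataset_windows(trajectories: Sequence[Trajectory], input_len: int,
                    horizon: int, target_vars: Optional[Sequence[str]] = None
                    ) -> WindowSet:
    ws: Optional[WindowSet] = None
    for tr in trajectories:
        w = make_windows(tr, input_len, horizon, target_vars)
        ws = w if ws is None else ws.concat(w)
    if ws is None:
        raise ValueError("no trajectories given")
    return ws


DEFAULT_HYPER = {
    "recurrent_units": 64,
    "cnn_channels": 32,
    "cnn_kernel": 3,
    "dense_units": 64,
    "head_hidden": 32,
}


def build_model(architecture: str, input_len: int, n_vars: int, horizon: int,
                n_targets: int, hyperparams: Optional[Dict] = None,
                seed: int = 0) -> ForecastModel:
    """Randomly initialise a forecaster, reproducibly from ``seed``."""
    hyper = dict(DEFAULT_HYPER)
    if hyperparams:
        hyper.update(hyperparams)
    body = nnet.make_body(architecture, input_len, n_vars, hyper)
    head = nnet.Head(body.feature_dim, hyper["head_hidden"], horizon * n_targets)
    net = nnet.Network(body, head)
    params = net.init_params(seed)
    return ForecastModel(architecture=architecture.upper(), network=net,
                         params=params, input_len=input_len, horizon=horizon,
                         n_vars=n_vars, n_targets=n_targets, hyper=hyper,
                         seed=seed)


def _train_loop(model: ForecastModel, train_x: np.ndarray, train_y: np.ndarray,
                val_x: np.ndarray, val_y: np.ndarray, cfg: TrainConfig,
                trainable: set, n_epochs: int) -> List[Dict]:
    """Minibatch Adam with per-epoch validation, early stopping and
    best-checkpoint restore.  Mutates ``model.params`` in place."""
    net = model.network
    opt = nnet.Adam(model.params, trainable, lr=cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed)
    best_val = np.inf
    best_params = {k: v.copy() for k, v in model.params.items()}
    since_best = 0
    log: List[Dict] = []
    n = train_x.shape[0]
    for epoch in range(n_epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            loss, grads = net.loss_and_grads(train_x[idx], train_y[idx], model.params)
            opt.step(model.params, grads)
            losses.append(loss)
        val_loss = net.loss(val_x, val_y, model.params)
        log.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                    "val_loss": val_loss})
        if val_loss < best_val:
            best_val = val_loss
            best_params = {k: v.copy() for k, v in model.params.items()}
            since_best = 0
        else:
            since_best += 1
            if since_best >= cfg.patience:
                break
    model.params = best_params
    return log


def _flatten_targets(y: np.ndarray) -> np.ndarray:
    return y.reshape(y.shape[0], -1)


def _split_series_for_validation(trajectories: Sequence[Trajectory],
                                 cfg: TrainConfig
                                 ) -> Tuple[List[Trajectory], List[Trajectory], str]:
    """Hold out whole series for validation; fall back to a time-tail
    split for single-series datasets."""
    n = len(trajectories)
    if n >= 2:
        rng = np.random.default_rng(cfg.seed)
        order = rng.permutation(n)
        n_val = max(1, int(round(cfg.val_fraction * n)))
        n_val = min(n_val, n - 1)
        val_idx = set(order[:n_val].tolist())
        train = [trajectories[i] for i in range(n) if i not in val_idx]
        val = [trajectories[i] for i in range(n) if i in val_idx]
        return train, val, "series"
    tr = trajectories[0]
    n_pts = tr.grid.n_points
    cut = max(2, int(round((1 - cfg.val_fraction) * n_pts)))
    head = Trajectory(tr.series_id + "/train", TimeGrid(tr.grid.points[:cut]),
                      tr.values[:cut], tr.variables)
    tail_start = max(0, cut - 1)  # overlap one point to keep tail windowable
    tail = Trajectory(tr.series_id + "/val", TimeGrid(tr.grid.points[tail_start:]),
                      tr.values[tail_start:], tr.variables)
    return [head], [tail], "time-tail (single series)"


def pretrain(model: ForecastModel, synthetic: TimeSeriesDataset,
             cfg: TrainConfig, target_vars: Optional[Sequence[str]] = None
             ) -> Tuple[ForecastModel, List[Dict]]:
    """Pre-train all parameters on a synthetic dataset.

    Holds out ``val_fraction`` of whole series for validation (time-tail
    fallback for a single series), trains with MSE until the validation
    loss ceases to improve, and returns the checkpoint with minimal
    validation loss plus the per-epoch loss log.
    """
    model = model.copy()
    tv = list(target_vars) if target_vars is not None else list(synthetic.variables)
    model.variables = list(synthetic.variables)
    model.target_vars = tv
    train_series, val_series, split_kind = _split_series_for_validation(
        synthetic.trajectories, cfg)
    model.fit_scaler(np.concatenate([t.values for t in train_series]))
    tw = dataset_windows(train_series, model.input_len, model.horizon, tv)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        vw = dataset_windows(val_series, model.input_len, model.horizon, tv)
    if vw.n_windows == 0:
        vw = tw
    if tw.n_windows == 0:
        raise ValueError("synthetic dataset too short to window")
    tx, ty = model.scale_inputs(tw.inputs), _flatten_targets(model.scale_targets(tw.targets))
    vx, vy = model.scale_inputs(vw.inputs), _flatten_targets(model.scale_targets(vw.targets))
    log = _train_loop(model, tx, ty, vx, vy, cfg,
                      trainable=set(model.params), n_epochs=cfg.max_epochs)
    for entry in log:
        entry["split"] = split_kind
    return model, log


def finetune(model: ForecastModel, target_train: Trajectory,
             cfg: TrainConfig) -> Tuple[ForecastModel, List[Dict]]:
    """Fine-tune only the two head layers on the target's training region.

    Runs exactly ``cfg.fine_tune_epochs`` epochs and restores the
    checkpoint with the best loss on the target's validation tail (the
    last ``val_fraction`` of training windows).  Body parameters are
    untouched, bitwise.
    """
    model = model.copy()
    if model.variables is None:
        model.variables = list(target_train.variables)
        model.target_vars = model.target_vars or list(target_train.variables)
    min_len = model.input_len + model.horizon
    if target_train.grid.n_points < min_len:
        raise ValueError(
            f"target train region has {target_train.grid.n_points} points; "
            f"needs at least input_len + horizon = {min_len}")
    if model.scaler_mean is None:
        model.fit_scaler(target_train.values)
    ws = make_windows(target_train, model.input_len, model.horizon,
                      model.target_vars)
    k = ws.n_windows
    n_val = max(1, int(round(cfg.val_fraction * k))) if k > 1 else 0
    if n_val and k - n_val >= 1:
        tw_x, tw_y = ws.inputs[:k - n_val], ws.targets[:k - n_val]
        vw_x, vw_y = ws.inputs[k - n_val:], ws.targets[k - n_val:]
    else:
        tw_x, tw_y = ws.inputs, ws.targets
        vw_x, vw_y = ws.inputs, ws.targets
    tx, ty = model.scale_inputs(tw_x), _flatten_targets(model.scale_targets(tw_y))
    vx, vy = model.scale_inputs(vw_x), _flatten_targets(model.scale_targets(vw_y))
    log = _train_loop(model, tx, ty, vx, vy, cfg,
                      trainable=set(model.head_param_names),
                      n_epochs=cfg.fine_tune_epochs)
    return model, log


@dataclass
class ForecastSet:
    """Per-window forecasts over an evaluation region, in original units.

    ``preds``/``obs``: (K, H, n_targets); ``origin_values``: the value of
    each target variable at the forecast origin (last input point);
    ``target_time_idx``: (K, H) indices into the context series' grid.
    """

    preds: np.ndarray
    obs: np.ndarray
    origin_values: np.ndarray
    target_time_idx: np.ndarray
    target_vars: Sequence[str]

    @property
    def n_windows(self) -> int:
        return self.preds.shape[0]


def predict_series(model: ForecastModel, context: Trajectory,
                   eval_region: Tuple[int, int]) -> ForecastSet:
    """Forecast every window whose target lies inside the evaluation region.

    ``eval_region`` is a half-open index range [start, stop) on the
    context grid.  Window inputs may extend into the training region;
    only the H-step target must fall entirely inside the region.
    Forecasts are returned in original units.
    """
    start, stop = eval_region
    lin, h = model.input_len, model.horizon
    t_idx = [list(context.variables).index(v) for v in model.target_vars]
    rows_in, rows_obs, rows_origin, rows_tidx = [], [], [], []
    for first_target in range(max(start, lin), stop - h + 1):
        i0 = first_target - lin
        rows_in.append(context.values[i0:first_target])
        rows_obs.append(context.values[first_target:first_target + h][:, t_idx])
        rows_origin.append(context.values[first_target - 1, t_idx])
        rows_tidx.append(np.arange(first_target, first_target + h))
    if not rows_in:
        warnings.warn("evaluation region admits no forecast windows")
        return ForecastSet(np.empty((0, h, len(t_idx))), np.empty((0, h, len(t_idx))),
                           np.empty((0, len(t_idx))), np.empty((0, h), dtype=int),
                           model.target_vars)
    preds = model.predict_windows(np.stack(rows_in))
    return ForecastSet(preds, np.stack(rows_obs), np.stack(rows_origin),
                       np.stack(rows_tidx), model.target_vars)
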