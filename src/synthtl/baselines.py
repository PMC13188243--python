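"""Comparison arms: uninformed deep learning and ODE calibration.

The DL baseline trains a randomly initialised forecaster of the same
architecture only on the target's training region, with the same loss,
early stopping and checkpointing as pre-training — under matched seeds
the transfer-learning run and the baseline differ only in their initial
parameters, making the comparison paired.

The ODE baseline fits the system's kinetic parameters to the combined
train and validation region by bounded least squares (multi-start over
log-uniform perturbations of the starting point) and forecasts by a
single deterministic simulation continued past the fitted region.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import least_squares

from synthtl.forecasting import (ForecastModel, TrainConfig, _flatten_targets,
                                 _train_loop, make_windows)
from synthtl.ode_library import OdeSystem
from synthtl.synth_generator import (NoiseConfig, SimulationFailure, TimeGrid,
                                     Trajectory, simulate_trajectory)

__all__ = [
    "CalibrationResult",
    "CalibrationError",
    "OdeForecast",
    "train_dl_baseline",
    "calibrate_ode",
    "forecast_ode",
]


class CalibrationError(RuntimeError):
    """All calibration restarts failed to converge."""


@dataclass
class CalibrationResult:
    """Outcome of fitting kinetic parameters to observations."""

    theta_hat: np.ndarray
    initial_state: np.ndarray
    residual: float
    converged: bool
    n_evaluations: int
    restart_residuals: List[float] = field(default_factory=list)

    def to_dict(self) -> Dict:
        return {"theta_hat": self.theta_hat.tolist(),
                "initial_state": self.initial_state.tolist(),
                "residual": self.residual, "converged": self.converged,
                "n_evaluations": self.n_evaluations,
                "restart_residuals": self.restart_residuals}


def train_dl_baseline(architecture_model: ForecastModel,
                      target_train: Trajectory, cfg: TrainConfig
                      ) -> Tuple[ForecastModel, List[Dict]]:
    """Train a randomly initialised model only on the target train region.

    ``architecture_model`` supplies the (untrained) initialisation; pass
    the output of :func:`synthtl.forecasting.build_model` with the same
    seed as the paired transfer-learning run.  The scaler is fitted on
    the target training data.  ``cfg.max_epochs == 0`` returns the
    initialisation unchanged.
    """
    model = architecture_model.copy()
    model.variables = list(target_train.variables)
    if model.target_vars is None:
        model.target_vars = list(target_train.variables)
    model.fit_scaler(target_train.values)
    if cfg.max_epochs == 0:
        return model, []
    ws = make_windows(target_train, model.input_len, model.horizon,
                      model.target_vars)
    if ws.n_windows == 0:
        raise ValueError(
            f"target train region too short; needs at least "
            f"{model.input_len + model.horizon} points")
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
                      trainable=set(model.params), n_epochs=cfg.max_epochs)
    return model, log


def _simulate_states(system: OdeSystem, theta: np.ndarray, y0: np.ndarray,
                     grid_points: np.ndarray) -> np.ndarray:
    traj = simulate_trajectory(system, theta, y0, TimeGrid(grid_points),
                               NoiseConfig(kind="none"))
    return traj.values


def calibrate_ode(system: OdeSystem, observations: Trajectory,
                  bounds: Optional[Tuple[np.ndarray, np.ndarray]] = None,
                  theta0: Optional[np.ndarray] = None,
                  n_restarts: int = 10, restart_spread: float = 0.5,
                  fit_initial_state: bool = False,
                  seed: int = 0) -> CalibrationResult:
    """Fit kinetic parameters to an observed trajectory.

    Minimises the sum of squared differences between the simulated
    trajectory (started from the first observed state, or from fitted
    initial values when ``fit_initial_state``) and the observations over
    all observed variables, weighting each variable by 1/sd so that
    differently scaled variables contribute comparably.  Bounded local
    least squares from ``theta0`` with a small multi-start over
    log-uniform perturbations; the best restart is returned.
    """
    n_obs = observations.grid.n_points
    if n_obs < 2 * system.n_params:
        raise ValueError(
            f"need at least {2 * system.n_params} observed time points for "
            f"{system.n_params} parameters, got {n_obs}")
    theta0 = (np.asarray(theta0, dtype=float) if theta0 is not None
              else system.center_theta())
    if bounds is None:
        lo = theta0 * 1e-3
        hi = theta0 * 1e3
        bounds = (lo, hi)
    y0_obs = observations.values[0].copy()
    weights = 1.0 / np.maximum(np.std(observations.values, axis=0), 1e-12)
    pts = observations.grid.points

    n_theta = system.n_params

    def residuals(x: np.ndarray) -> np.ndarray:
        theta = x[:n_theta]
        y0 = x[n_theta:] if fit_initial_state else y0_obs
        try:
            sim = _simulate_states(system, theta, y0, pts)
        except SimulationFailure:
            return np.full(observations.values.size, 1e6)
        return ((sim - observations.values) * weights).ravel()

    rng = np.random.default_rng(seed)
    starts = [theta0]
    for _ in range(max(0, n_restarts - 1)):
        factors = np.exp(rng.uniform(np.log(1 - restart_spread),
                                     np.log(1 + restart_spread), size=n_theta))
        starts.append(np.clip(theta0 * factors, bounds[0], bounds[1]))

    best = None
    restart_residuals: List[float] = []
    total_nfev = 0
    lo_full = np.concatenate([bounds[0], np.zeros_like(y0_obs)]) \
        if fit_initial_state else bounds[0]
    hi_full = np.concatenate([bounds[1], np.full_like(y0_obs, np.inf)]) \
        if fit_initial_state else bounds[1]
    for x0 in starts:
        x0_full = np.concatenate([x0, np.maximum(y0_obs, 1e-8)]) \
            if fit_initial_state else x0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = least_squares(residuals, x0_full, bounds=(lo_full, hi_full),
                                    method="trf", xtol=1e-10, ftol=1e-10)
            except Exception:
                continue
        total_nfev += res.nfev
        cost = float(np.sum(res.fun ** 2))
        restart_residuals.append(cost)
        if best is None or cost < best[0]:
            best = (cost, res)
    if best is None:
        raise CalibrationError(
            f"all {len(starts)} calibration restarts failed for system "
            f"{system.name!r} (theta0={theta0.tolist()})")
    cost, res = best
    theta_hat = res.x[:n_theta]
    y0_hat = res.x[n_theta:] if fit_initial_state else y0_obs
    return CalibrationResult(theta_hat=theta_hat, initial_state=y0_hat,
                             residual=cost, converged=bool(res.success),
                             n_evaluations=total_nfev,
                             restart_residuals=restart_residuals)


@dataclass
class OdeForecast:
    """Deterministic continuation of a calibrated simulation."""

    times: np.ndarray
    values: np.ndarray  # (n_future, n_vars)
    variables: Sequence[str]

    @property
    def n_points(self) -> int:
        return self.values.shape[0]

    def as_trajectory(self) -> Trajectory:
        return Trajectory("ode_forecast", TimeGrid(self.times), self.values,
                          self.variables)


def forecast_ode(system: OdeSystem, calibration: CalibrationResult,
                 fitted_grid: TimeGrid, future_points: np.ndarray) -> OdeForecast:
    """Continue the calibrated simulation over future time points.

    Re-simulates the fitted region to obtain the state at its last time
    point, then integrates deterministically over ``future_points``.
    An empty future yields an empty forecast.  For systems with
    non-negative states started positive the mechanistic forecast stays
    non-negative (up to solver tolerance).
    """
    future_points = np.asarray(future_points, dtype=float)
    if future_points.size == 0:
        return OdeForecast(future_points, np.empty((0, system.n_vars)),
                           system.variables)
    fitted = _simulate_states(system, calibration.theta_hat,
                              calibration.initial_state, fitted_grid.points)
    last_state = fitted[-1]
    t_last = float(fitted_grid.points[-1])
    if future_points[0] > t_last:
        pts = np.concatenate([[t_last], future_points])
        values = _simulate_states(system, calibration.theta_hat, last_state, pts)[1:]
    else:
        pts = future_points if future_points.size >= 2 \
            else np.array([future_points[0], future_points[0] + 1e-9])
        values = _simulate_states(system, calibration.theta_hat, last_state,
                                  pts)[:future_points.size]
    return OdeForecast(future_points, values, system.variables)
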