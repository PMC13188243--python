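"""Generation of ODE-derived synthetic time-series datasets.

A dataset is characterised by three knobs:

size
    Number of individual time series (typical study values: 1, 10, 100,
    1000).
diversity
    Width of the uniform sampling intervals for initial conditions (ICs)
    and kinetic parameters (KPs) around their center values; four width
    classes S < M < L < XL.
noise
    Either *measurement* noise (i.i.d. perturbation of each observed
    value after simulation) or *environmental* noise (perturbation of the
    ODE right-hand side itself, held constant between consecutive grid
    points so that its effect propagates through the dynamics), each
    applied additively or multiplicatively.

For environmental noise the system is solved piecewise on each interval
[t_i, t_{i+1}): a fresh noise vector e_{t_i} (one i.i.d. draw per
variable) perturbs the rate equations, with state continuity at interval
boundaries.  Multiplicative noise replaces the added term by a lognormal
factor with log-median 1 whose spread is parameterised by the requested
interquartile range (IQR).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.integrate import solve_ivp
from scipy.stats import norm

from synthtl.ode_library import OdeSystem

__all__ = [
    "TimeGrid",
    "IntervalSpec",
    "DiversityConfig",
    "NoiseConfig",
    "Trajectory",
    "TimeSeriesDataset",
    "WIDTH_CLASSES",
    "DEFAULT_NOISE_LEVELS",
    "SimulationFailure",
    "GenerationError",
    "resolve_interval",
    "sample_configuration",
    "sigma_from_iqr",
    "simulate_trajectory",
    "apply_measurement_noise",
    "generate_dataset",
    "generate_fixture_target",
]

#: Default half-width fraction of the sampling interval per diversity class.
WIDTH_CLASSES: Dict[str, float] = {"S": 0.05, "M": 0.20, "L": 0.50, "XL": 0.80}

#: Default six noise levels (IQR for multiplicative noise, sd-fraction for
#: additive noise), overridable in experiment configs.
DEFAULT_NOISE_LEVELS: Tuple[float, ...] = (0.01, 0.05, 0.1, 0.2, 0.5, 1.0)

_SOLVER_KW = dict(method="LSODA", rtol=1e-8, atol=1e-10)


class SimulationFailure(RuntimeError):
    """ODE solve failed or produced non-finite states."""


class GenerationError(RuntimeError):
    """Dataset generation exhausted its retry budget."""


@dataclass(frozen=True)
class TimeGrid:
    """Strictly increasing observation times t_1 .. t_N."""

    points: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        object.__setattr__(self, "points", pts)
        if pts.ndim != 1 or pts.size < 2:
            raise ValueError("time grid needs at least two points")
        if not np.all(np.isfinite(pts)):
            raise ValueError("time grid must be finite")
        if not np.all(np.diff(pts) > 0):
            raise ValueError("time grid must be strictly increasing")

    @property
    def n_points(self) -> int:
        return self.points.size

    @staticmethod
    def regular(t_start: float, t_end: float, n_points: int) -> "TimeGrid":
        return TimeGrid(np.linspace(t_start, t_end, n_points))


@dataclass(frozen=True)
class IntervalSpec:
    """A symmetric relative sampling interval [c(1-w), c(1+w)] around a center."""

    center: float
    width_class: str = "S"
    half_width_fraction: Optional[float] = None

    def resolved_width(self) -> float:
        if self.half_width_fraction is not None:
            return float(self.half_width_fraction)
        try:
            return WIDTH_CLASSES[self.width_class]
        except KeyError:
            raise ValueError(
                f"unknown width class {self.width_class!r}; "
                f"known: {sorted(WIDTH_CLASSES)}") from None


def resolve_interval(spec: IntervalSpec) -> Tuple[float, float]:
    """Resolve an interval spec into its (lower, upper) bounds.

    Raises an error when the interval would include non-positive values,
    since centers model strictly positive rates and abundances.
    """
    w = spec.resolved_width()
    if spec.center <= 0:
        raise ValueError(f"interval center must be positive, got {spec.center}")
    if not 0 <= w < 1:
        raise ValueError(
            f"half-width fraction must lie in [0, 1) to keep the interval "
            f"positive, got {w}")
    return spec.center * (1 - w), spec.center * (1 + w)


@dataclass(frozen=True)
class DiversityConfig:
    """Per-variable IC intervals and per-parameter KP intervals."""

    ic_specs: Mapping[str, IntervalSpec]
    kp_specs: Mapping[str, IntervalSpec]

    @staticmethod
    def from_classes(system: OdeSystem, ic_class: str, kp_class: str,
                     centers: Optional[Mapping[str, float]] = None) -> "DiversityConfig":
        """Build a config giving every IC one width class and every KP another."""
        c = dict(system.default_centers)
        if centers:
            c.update(centers)
        return DiversityConfig(
            ic_specs={v: IntervalSpec(c[v], ic_class) for v in system.variables},
            kp_specs={p: IntervalSpec(c[p], kp_class) for p in system.parameters},
        )

    def validate_for(self, system: OdeSystem) -> None:
        missing_v = [v for v in system.variables if v not in self.ic_specs]
        missing_p = [p for p in system.parameters if p not in self.kp_specs]
        if missing_v or missing_p:
            raise ValueError(
                f"diversity config incomplete for system {system.name!r}: "
                f"missing ICs {missing_v}, missing KPs {missing_p}")


@dataclass(frozen=True)
class NoiseConfig:
    """One (kind, operation, level) noise setting.

    ``level`` is the target IQR of the lognormal factor distribution for
    multiplicative noise, and the ratio of noise standard deviation to
    the relevant per-variable scale for additive noise.  Exactly one
    (kind, operation) combination is active at a time; ``level=0`` is the
    identity.
    """

    kind: str = "none"          # none | measurement | environmental
    operation: str = "additive"  # additive | multiplicative
    level: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("none", "measurement", "environmental"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.operation not in ("additive", "multiplicative"):
            raise ValueError(f"unknown noise operation {self.operation!r}")
        if self.level < 0:
            raise ValueError(f"noise level must be non-negative, got {self.level}")


@dataclass
class Trajectory:
    """A single simulated or observed time series on a grid.

    ``values`` has shape (N, n_vars) in model units.  ``provenance``
    records everything needed for exact regeneration: sampled parameter
    values, sampled initial conditions, noise configuration and seed.
    """

    series_id: str
    grid: TimeGrid
    values: np.ndarray
    variables: Sequence[str]
    provenance: Dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid.n_points, len(self.variables)):
            raise ValueError(
                f"values shape {self.values.shape} inconsistent with grid "
                f"({self.grid.n_points} points) and variables {list(self.variables)}")

    def column(self, var: str) -> np.ndarray:
        return self.values[:, list(self.variables).index(var)]


@dataclass
class TimeSeriesDataset:
    """A collection of trajectories sharing one grid and variable order."""

    system_name: str
    trajectories: List[Trajectory]
    config: Dict = field(default_factory=dict)
    master_seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.trajectories:
            g0 = self.trajectories[0].grid.points
            v0 = tuple(self.trajectories[0].variables)
            for tr in self.trajectories[1:]:
                if not np.array_equal(tr.grid.points, g0) or tuple(tr.variables) != v0:
                    raise ValueError("all trajectories must share grid and variable order")

    @property
    def n_series(self) -> int:
        return len(self.trajectories)

    @property
    def grid(self) -> TimeGrid:
        return self.trajectories[0].grid

    @property
    def variables(self) -> Sequence[str]:
        return self.trajectories[0].variables

    def stacked(self) -> np.ndarray:
        """All values as an (n_series, N, n_vars) array."""
        return np.stack([tr.values for tr in self.trajectories])


def sample_configuration(system: OdeSystem, diversity: DiversityConfig,
                         rng: np.random.Generator) -> Tuple[np.ndarray, np.ndarray]:
    """Draw one (theta, ics) pair uniformly from the diversity intervals.

    Each parameter and initial condition is drawn independently and
    uniformly from its resolved interval; reproducible from the generator
    state.
    """
    diversity.validate_for(system)
    theta = np.empty(system.n_params)
    for j, p in enumerate(system.parameters):
        lo, hi = resolve_interval(diversity.kp_specs[p])
        theta[j] = rng.uniform(lo, hi) if hi > lo else lo
    ics = np.empty(system.n_vars)
    for j, v in enumerate(system.variables):
        lo, hi = resolve_interval(diversity.ic_specs[v])
        ics[j] = rng.uniform(lo, hi) if hi > lo else lo
    return theta, ics


_Q75 = float(norm.ppf(0.75))


def sigma_from_iqr(iqr: float) -> float:
    """Lognormal shape parameter giving a factor distribution with the
    requested interquartile range.

    The noise factor is lognormal with log-median 1 (log-mean 0) and
    shape sigma; its quartiles are exp(+-sigma*q75) with q75 the standard
    normal 0.75 quantile, so IQR = 2*sinh(sigma*q75) and
    sigma = asinh(iqr/2) / q75.
    """
    if iqr < 0:
        raise ValueError(f"IQR must be non-negative, got {iqr}")
    return math.asinh(iqr / 2.0) / _Q75


def _integrate(system: OdeSystem, theta: np.ndarray, y0: np.ndarray,
               t_span: Tuple[float, float], t_eval: np.ndarray,
               rhs=None) -> np.ndarray:
    """Solve and return states at t_eval; raises SimulationFailure."""
    f = rhs if rhs is not None else system.rhs
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sol = solve_ivp(lambda t, y: f(y, t, theta), t_span, y0,
                        t_eval=t_eval, **_SOLVER_KW)
    if not sol.success or not np.all(np.isfinite(sol.y)):
        raise SimulationFailure(
            f"ODE solve failed for system {system.name!r}: {sol.message}")
    return sol.y.T


def _derivative_scales(clean: np.ndarray, grid: TimeGrid) -> np.ndarray:
    """Per-variable scale of the clean trajectory's finite-difference
    derivative; floor at tiny epsilon so zero-dynamics systems still
    accept additive environmental noise."""
    d = np.gradient(clean, grid.points, axis=0)
    scale = np.std(d, axis=0)
    return np.maximum(scale, 1e-12)


def simulate_trajectory(system: OdeSystem, theta: np.ndarray, ics: np.ndarray,
                        grid: TimeGrid, noise: NoiseConfig,
                        rng: Optional[np.random.Generator] = None,
                        series_id: str = "series_0") -> Trajectory:
    """Simulate one trajectory, with environmental noise folded into the
    dynamics.

    For ``kind`` in {none, measurement} this is a single clean adaptive
    solve with output at the grid points (measurement noise is applied
    afterwards by :func:`apply_measurement_noise`).  For environmental
    noise the system is solved piecewise: on each interval
    [t_i, t_{i+1}) a fresh noise vector perturbs the rate equations
    (added for additive noise, multiplied for multiplicative noise), with
    state continuity at the boundaries.
    """
    theta = np.asarray(theta, dtype=float)
    ics = np.asarray(ics, dtype=float)
    pts = grid.points
    prov: Dict = {"theta": theta.tolist(), "ics": ics.tolist(),
                  "noise": asdict(noise)}

    if noise.kind != "environmental" or noise.level == 0:
        values = _integrate(system, theta, ics, (pts[0], pts[-1]), pts)
        return Trajectory(series_id, grid, values, system.variables, prov)

    if rng is None:
        raise ValueError("environmental noise requires an rng")

    n = system.n_vars
    n_intervals = grid.n_points - 1
    if noise.operation == "additive":
        clean = _integrate(system, theta, ics, (pts[0], pts[-1]), pts)
        sd = noise.level * _derivative_scales(clean, grid)
        draws = rng.normal(0.0, 1.0, size=(n_intervals, n)) * sd
    else:
        sigma = sigma_from_iqr(noise.level)
        draws = rng.lognormal(0.0, sigma, size=(n_intervals, n))

    values = np.empty((grid.n_points, n))
    values[0] = ics
    state = ics
    base_rhs = system.rhs
    for i in range(n_intervals):
        e = draws[i]
        if noise.operation == "additive":
            def rhs(y, t, th, e=e):
                return base_rhs(y, t, th) + e
        else:
            def rhs(y, t, th, e=e):
                return base_rhs(y, t, th) * e
        seg = _integrate(system, theta, state, (pts[i], pts[i + 1]),
                         np.array([pts[i + 1]]), rhs=rhs)
        state = seg[-1]
        values[i + 1] = state
    prov["environmental_draws_shape"] = list(draws.shape)
    return Trajectory(series_id, grid, values, system.variables, prov)


def apply_measurement_noise(traj: Trajectory, noise: NoiseConfig,
                            rng: np.random.Generator) -> Trajectory:
    """Apply i.i.d. measurement noise to every value of a trajectory.

    Multiplicative: each value is multiplied by a lognormal factor with
    log-median 1 and shape ``sigma_from_iqr(level)``.  Additive: each
    value gets Gaussian noise with standard deviation
    ``level * sd_v`` where ``sd_v`` is the clean trajectory's per-variable
    standard deviation, scaling the noise to the measured quantity.
    """
    if noise.kind != "measurement":
        raise ValueError(f"apply_measurement_noise requires kind='measurement', "
                         f"got {noise.kind!r}")
    if noise.level == 0:
        return traj
    vals = traj.values
    if noise.operation == "multiplicative":
        factors = rng.lognormal(0.0, sigma_from_iqr(noise.level), size=vals.shape)
        noisy = vals * factors
    else:
        sd = np.std(vals, axis=0, keepdims=True)
        noisy = vals + rng.normal(0.0, 1.0, size=vals.shape) * (noise.level * sd)
    prov = dict(traj.provenance)
    prov["measurement_noise"] = asdict(noise)
    return Trajectory(traj.series_id, traj.grid, noisy, traj.variables, prov)


def _trajectory_ok(traj: Trajectory, nonneg: bool) -> bool:
    if not np.all(np.isfinite(traj.values)):
        return False
    # small solver undershoots below zero are tolerated relative to scale
    if nonneg:
        tol = 1e-8 * max(1.0, float(np.max(np.abs(traj.values))))
        if np.any(traj.values < -tol):
            return False
    return True


def generate_dataset(system: OdeSystem, diversity: DiversityConfig,
                     noise: NoiseConfig, n_series: int, grid: TimeGrid,
                     seed: int, max_retries_per_slot: int = 10) -> TimeSeriesDataset:
    """Generate a dataset of ``n_series`` independently sampled trajectories.

    Each series draws its own (theta, ICs) uniformly from the diversity
    intervals.  Trajectories that fail simulation or violate finiteness /
    non-negativity are discarded and re-drawn up to
    ``max_retries_per_slot`` times; retry counts are recorded in the
    dataset config.  Fully reproducible from ``seed``.
    """
    if n_series < 1:
        raise ValueError("n_series must be positive")
    rng = np.random.default_rng(seed)
    trajectories: List[Trajectory] = []
    retries: List[int] = []
    for k in range(n_series):
        attempt = 0
        while True:
            theta, ics = sample_configuration(system, diversity, rng)
            try:
                traj = simulate_trajectory(system, theta, ics, grid, noise, rng,
                                           series_id=f"series_{k:04d}")
                if noise.kind == "measurement" and noise.level > 0:
                    traj = apply_measurement_noise(traj, noise, rng)
                if _trajectory_ok(traj, system.nonneg):
                    break
                reason = "non-finite or negative values"
            except SimulationFailure as exc:
                reason = str(exc)
            attempt += 1
            if attempt > max_retries_per_slot:
                raise GenerationError(
                    f"series {k}: exhausted {max_retries_per_slot} retries "
                    f"({reason}); last theta={theta.tolist()}, ics={ics.tolist()}")
        retries.append(attempt)
        trajectories.append(traj)
    config = {
        "system": system.name,
        "n_series": n_series,
        "noise": asdict(noise),
        "seed": seed,
        "retry_counts": retries,
        "grid": {"t_start": float(grid.points[0]), "t_end": float(grid.points[-1]),
                 "n_points": grid.n_points},
    }
    return TimeSeriesDataset(system.name, trajectories, config, master_seed=seed)


def generate_fixture_target(system: OdeSystem, theta_true: np.ndarray,
                            ics: np.ndarray, grid: TimeGrid,
                            observation_noise_iqr: float, coherent: bool,
                            rng: np.random.Generator,
                            kp_scale: float = 3.0,
                            sine_amplitude_sds: float = 2.0,
                            sine_periods: float = 3.0) -> Trajectory:
    """Build a pseudo-real target series for pipeline testing.

    ``coherent=True`` gives one trajectory of the same system at the true
    parameters with multiplicative observation noise of the given IQR —
    a target whose dynamics the synthetic data can match.
    ``coherent=False`` gives a structurally different generator: the same
    system with one kinetic parameter scaled by ``kp_scale`` plus a
    phase-shifted additive sinusoid on each variable (amplitude in units
    of each variable's clean standard deviation), then the same noise —
    a target whose shapes the synthetic data cannot reproduce.
    """
    clean = simulate_trajectory(system, theta_true, ics, grid,
                                NoiseConfig(kind="none"), series_id="target")
    if coherent:
        traj = clean
    else:
        theta_alt = np.asarray(theta_true, dtype=float).copy()
        theta_alt[0] *= kp_scale
        alt = simulate_trajectory(system, theta_alt, ics, grid,
                                  NoiseConfig(kind="none"), series_id="target")
        sds = np.std(clean.values, axis=0, keepdims=True)
        t = grid.points[:, None]
        span = grid.points[-1] - grid.points[0]
        phases = np.arange(system.n_vars)[None, :] * (2 * np.pi / max(system.n_vars, 1))
        wave = np.sin(2 * np.pi * sine_periods * (t - grid.points[0]) / span + phases)
        vals = alt.values + sine_amplitude_sds * sds * wave
        if system.nonneg:
            vals = np.maximum(vals, 0.0)
        traj = Trajectory("target", grid, vals, system.variables,
                          {"fixture": "incoherent", "theta_alt": theta_alt.tolist()})
    if observation_noise_iqr > 0:
        traj = apply_measurement_noise(
            traj, NoiseConfig(kind="measurement", operation="multiplicative",
                              level=observation_noise_iqr), rng)
    prov = dict(traj.provenance)
    prov["coherent"] = coherent
    prov["observation_noise_iqr"] = observation_noise_iqr
    traj.provenance = prov
    return traj
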