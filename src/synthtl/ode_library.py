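"""Registry of biological ODE systems used for synthetic data generation.

Three textbook systems ship with the package:

``sir``
    Susceptible-infected-recovered epidemic model with frequency-dependent
    incidence (transmission scaled by 1/N_pop), the standard form for
    case-count waves.
``lv``
    The original Lotka-Volterra predator-prey model.
``sar``
    Substrate(nitrogen)-algae-rotifers chemostat: a three-state extension
    of Lotka-Volterra with Monod uptake kinetics, dilution and rotifer
    mortality.

Each system carries documented, editable center values for its kinetic
parameters and initial conditions; experiments read centers from config
and never hardcode them.  Users can register their own systems with
:func:`register_system`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, Mapping, Sequence

import numpy as np

__all__ = [
    "OdeSystem",
    "InvalidParameterError",
    "sir_rhs",
    "lv_rhs",
    "sar_rhs",
    "get_system",
    "register_system",
    "available_systems",
]


class InvalidParameterError(ValueError):
    """A kinetic parameter violates its admissibility constraint."""


RhsFunc = Callable[[np.ndarray, float, np.ndarray], np.ndarray]


@dataclass(frozen=True)
class OdeSystem:
    """A named dynamical system dy/dt = f(y, t, theta).

    Parameters
    ----------
    name
        Registry identifier.
    variables
        Ordered names of the ``n`` state variables.
    parameters
        Ordered names of the kinetic parameters entering the rate equations.
    rhs
        Map ``(y, t, theta) -> dy/dt`` with ``y, dy/dt`` of length ``n`` and
        ``theta`` ordered as ``parameters``.  Must be deterministic.
    default_centers
        Positive center value per variable (initial condition) and per
        kinetic parameter; used as the midpoints of the uniform sampling
        intervals during dataset generation.
    nonneg
        Whether states are physically constrained to remain non-negative
        (populations, concentrations, counts).
    """

    name: str
    variables: Sequence[str]
    parameters: Sequence[str]
    rhs: RhsFunc
    default_centers: Mapping[str, float] = field(default_factory=dict)
    nonneg: bool = True

    def __post_init__(self) -> None:
        missing = [k for k in (*self.variables, *self.parameters)
                   if k not in self.default_centers]
        if missing:
            raise ValueError(f"default_centers missing entries for {missing}")
        bad = {k: v for k, v in self.default_centers.items() if not v > 0}
        if bad:
            raise ValueError(f"default_centers must be strictly positive, got {bad}")

    @property
    def n_vars(self) -> int:
        return len(self.variables)

    @property
    def n_params(self) -> int:
        return len(self.parameters)

    def theta_from_mapping(self, values: Mapping[str, float]) -> np.ndarray:
        """Order a name->value mapping into a parameter vector."""
        return np.array([values[p] for p in self.parameters], dtype=float)

    def ic_from_mapping(self, values: Mapping[str, float]) -> np.ndarray:
        """Order a name->value mapping into an initial-state vector."""
        return np.array([values[v] for v in self.variables], dtype=float)

    def center_theta(self) -> np.ndarray:
        return self.theta_from_mapping(self.default_centers)

    def center_ics(self) -> np.ndarray:
        return self.ic_from_mapping(self.default_centers)


def sir_rhs(y: np.ndarray, t: float, theta: np.ndarray) -> np.ndarray:
    """SIR epidemic model with frequency-dependent incidence.

    State ``(S, I, R)`` in individuals; parameters ``(beta, gamma, N_pop)``:
    transmission rate, recovery rate, population size.  The three
    components sum to zero, so S+I+R is conserved along trajectories.
    """
    beta, gamma, n_pop = theta
    if not n_pop > 0:
        raise InvalidParameterError(f"population size N_pop must be positive, got {n_pop}")
    s, i, _ = y
    infection = beta * s * i / n_pop
    recovery = gamma * i
    return np.array([-infection, infection - recovery, recovery])


def lv_rhs(y: np.ndarray, t: float, theta: np.ndarray) -> np.ndarray:
    """Lotka-Volterra predator-prey model.

    State ``(x, y)`` = (prey, predator) counts; parameters
    ``(alpha, beta, delta, gamma)``: prey growth, predation rate,
    predator efficiency, predator death.  The coexistence equilibrium
    sits at ``(gamma/delta, alpha/beta)``.
    """
    alpha, beta, delta, gamma = theta
    prey, pred = y
    return np.array([alpha * prey - beta * prey * pred,
                     delta * prey * pred - gamma * pred])


def sar_rhs(y: np.ndarray, t: float, theta: np.ndarray) -> np.ndarray:
    """Substrate-algae-rotifers chemostat with Monod kinetics.

    State ``(S_n, A, R_t)``: limiting substrate (nitrogen), algae and
    rotifer concentrations.  Parameters ``(delta_d, S_in, mu_A, K_A,
    eps_A, mu_R, K_R, eps_R, m)``: dilution rate, inflow substrate
    concentration, algal maximum uptake rate and half-saturation, algal
    yield, rotifer maximum grazing rate and half-saturation, rotifer
    yield, rotifer mortality.
    """
    delta_d, s_in, mu_a, k_a, eps_a, mu_r, k_r, eps_r, m = theta
    if not (k_a > 0 and k_r > 0):
        raise InvalidParameterError(
            f"Monod half-saturation constants must be positive, got K_A={k_a}, K_R={k_r}")
    s_n, a, r_t = y
    uptake = mu_a * s_n / (k_a + s_n) * a          # algal growth
    grazing = mu_r * a / (k_r + a) * r_t           # rotifer growth
    return np.array([
        delta_d * (s_in - s_n) - uptake / eps_a,
        uptake - grazing / eps_r - delta_d * a,
        grazing - (delta_d + m) * r_t,
    ])


# Interval centers: SIR/LV use standard textbook magnitudes for an epidemic
# wave / oscillating predator-prey pair; SAR centers are in the range of
# published rotifer-algae chemostat fits.  All are editable config values.
_SIR_CENTERS = {"S": 990.0, "I": 10.0, "R": 1e-6,
                "beta": 0.3, "gamma": 0.1, "N_pop": 1000.0}
_LV_CENTERS = {"x": 10.0, "y": 5.0,
               "alpha": 1.1, "beta": 0.4, "delta": 0.1, "gamma": 0.4}
_SAR_CENTERS = {"S_n": 2.0, "A": 1.0, "R_t": 1.0,
                "delta_d": 0.55, "S_in": 80.0, "mu_A": 3.3, "K_A": 4.3,
                "eps_A": 0.25, "mu_R": 2.25, "K_R": 15.0, "eps_R": 0.25,
                "m": 0.055}

_REGISTRY: Dict[str, OdeSystem] = {}


def register_system(system: OdeSystem, overwrite: bool = False) -> None:
    """Add a user-defined system to the registry."""
    if system.name in _REGISTRY and not overwrite:
        raise ValueError(f"system {system.name!r} already registered")
    _REGISTRY[system.name] = system


def available_systems() -> list[str]:
    return sorted(_REGISTRY)


def get_system(name: str) -> OdeSystem:
    """Look up a registered ODE system by name."""
    try:
        return _REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown ODE system {name!r}; available: {available_systems()}") from None


register_system(OdeSystem(
    name="sir",
    variables=("S", "I", "R"),
    parameters=("beta", "gamma", "N_pop"),
    rhs=sir_rhs,
    default_centers=_SIR_CENTERS,
))
register_system(OdeSystem(
    name="lv",
    variables=("x", "y"),
    parameters=("alpha", "beta", "delta", "gamma"),
    rhs=lv_rhs,
    default_centers=_LV_CENTERS,
))
register_system(OdeSystem(
    name="sar",
    variables=("S_n", "A", "R_t"),
    parameters=("delta_d", "S_in", "mu_A", "K_A", "eps_A",
                "mu_R", "K_R", "eps_R", "m"),
    rhs=sar_rhs,
    default_centers=_SAR_CENTERS,
))
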