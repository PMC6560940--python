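"""Benchmark ODE systems, a model registry, and an adaptive RK solver.

Built-in systems:

* ``lotka_volterra`` — two-species predator–prey dynamics.
* ``fitzhugh_nagumo`` — spike generation in axons.
* ``biopathway`` — five protein isoforms coupled through mass-action and
  Michaelis–Menten kinetics; the last three states form a conserved moiety.
* ``soft_tissue`` — radial strain distribution in an arterial wall slice
  (abscissa is radius, not time).

Trajectories are integrated with an adaptive low-order Runge–Kutta pair
(scipy's RK23) under user-controllable tolerances.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "ODEModel",
    "SoftTissueConstants",
    "Trajectory",
    "IntegrationError",
    "lotka_volterra",
    "fitzhugh_nagumo",
    "biopathway",
    "soft_tissue",
    "get_model",
    "register_model",
    "available_models",
    "solve",
    "lotka_volterra_rhs",
    "fitzhugh_nagumo_rhs",
    "biopathway_rhs",
    "soft_tissue_rhs",
    "DEFAULT_TRUE_PARAMS",
    "DEFAULT_INITIAL_STATES",
]

_DEFAULT_BOUNDS = (1e-3, 1e2)


class IntegrationError(RuntimeError):
    """Numerical integration failed; carries the last good state."""

    def __init__(self, message: str, last_time: float, last_state: np.ndarray):
        super().__init__(message)
        self.last_time = last_time
        self.last_state = last_state


@dataclass(frozen=True)
class ODEModel:
    """A named right-hand side ``dx/dt = f(x, t, theta)`` with metadata."""

    name: str
    state_names: tuple[str, ...]
    param_names: tuple[str, ...]
    rhs: Callable[[np.ndarray, float, np.ndarray], np.ndarray]
    param_bounds: tuple[tuple[float, float], ...] = ()
    abscissa_label: str = "time"

    def __post_init__(self) -> None:
        if not self.param_bounds:
            object.__setattr__(
                self, "param_bounds", tuple(_DEFAULT_BOUNDS for _ in self.param_names)
            )
        if len(self.param_bounds) != len(self.param_names):
            raise ValueError("param_bounds must align with param_names")

    @property
    def n_states(self) -> int:
        return len(self.state_names)

    def theta_vector(self, theta: dict[str, float] | Sequence[float]) -> np.ndarray:
        if isinstance(theta, dict):
            missing = set(self.param_names) - set(theta)
            if missing:
                raise ValueError(f"missing parameters {sorted(missing)}")
            return np.array([theta[p] for p in self.param_names], dtype=float)
        vec = np.asarray(theta, dtype=float).ravel()
        if vec.size != len(self.param_names):
            raise ValueError("theta has wrong length")
        return vec

    def theta_dict(self, theta) -> dict[str, float]:
        vec = self.theta_vector(theta)
        return {p: float(v) for p, v in zip(self.param_names, vec)}


@dataclass
class Trajectory:
    """Solver output: abscissa grid plus one column per state."""

    times: np.ndarray
    states: np.ndarray  # (n, r)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float).ravel()
        self.states = np.atleast_2d(np.asarray(self.states, dtype=float))
        if self.states.shape[0] != self.times.size:
            raise ValueError("states must have one row per abscissa value")


# -- right-hand sides ------------------------------------------------------------

def lotka_volterra_rhs(x, theta) -> np.ndarray:
    """(alpha x1 - beta x1 x2, -gamma x2 + delta x1 x2)."""
    alpha, beta, gamma, delta = theta
    x1, x2 = x
    return np.array([alpha * x1 - beta * x1 * x2, -gamma * x2 + delta * x1 * x2])


def fitzhugh_nagumo_rhs(x, theta) -> np.ndarray:
    """(c (x1 - x1^3/3 + x2), -(x1 - a + b x2)/c)."""
    a, b, c = theta
    x1, x2 = x
    return np.array([c * (x1 - x1**3 / 3.0 + x2), -(x1 - a + b * x2) / c])


def biopathway_rhs(x, theta) -> np.ndarray:
    """Five-state signal-transduction pathway with a Michaelis-Menten branch.

    States are ordered (S, dS, R, RS, Rpp); parameters (k1..k6).  The sum
    R + RS + Rpp is conserved for every admissible state and theta.
    """
    k1, k2, k3, k4, k5, k6 = theta
    S, dS, R, RS, Rpp = x
    if k6 + Rpp <= 0:
        raise ValueError("Michaelis-Menten denominator k6 + [Rpp] must be positive")
    mm = k5 * Rpp / (k6 + Rpp)
    return np.array(
        [
            -k1 * S - k2 * S * R + k3 * RS,
            k1 * S,
            -k2 * S * R + k3 * RS + mm,
            k2 * S * R - k3 * RS - k4 * RS,
            k4 * RS - mm,
        ]
    )


@dataclass(frozen=True)
class SoftTissueConstants:
    """Known physiological constants of the arterial-wall model.

    The defaults below are placeholders chosen only to give a well-behaved
    admissible radius range; they are NOT measured physiological values and any real
    application must supply its own.
    """

    lambda_z: float = 1.2
    R_i: float = 0.7
    R_0: float = 1.3
    k: float = 1.0
    r_i: float = 0.7

    def __post_init__(self) -> None:
        for name in ("lambda_z", "R_i", "R_0", "k", "r_i"):
            if getattr(self, name) <= 0:
                raise ValueError(f"constant {name} must be positive")
        if not self.R_0 > self.R_i:
            raise ValueError("need R_0 > R_i")


def soft_tissue_rhs(sigma, r, theta, consts: SoftTissueConstants) -> float:
    """d(sigma)/dr for the thick-walled arterial tube; returns a scalar.

    The auxiliary chain is R -> (lambda1, lambda2) -> (I1, gamma, I4); the
    anisotropic fiber term engages only when I4 > 1.
    """
    a, b, a_f, b_f = theta
    if r <= 0:
        raise ValueError("radius must be positive")
    arg = (r * r - consts.r_i**2) * consts.k * consts.lambda_z + consts.r_i**2
    if arg < 0:
        raise ValueError("square-root argument in R(r) is negative")
    R = np.sqrt(arg)
    lam1 = R / (r * consts.k * consts.lambda_z)
    lam2 = consts.k * r / R
    I1 = lam1 * lam1 + lam2 * lam2 + consts.lambda_z**2
    gamma = 2.0 * np.pi / (3.0 * consts.R_0 - consts.R_i) * (R - consts.R_i) - np.pi / 3.0
    I4 = lam2 * lam2 * (np.cos(gamma) ** 2 + consts.lambda_z**2 * np.sin(gamma) ** 2)
    iso = a * np.exp(b * (I1 - 3.0)) * (lam2 * lam2 - lam1 * lam1)
    aniso = a_f * (I4 - 1.0) * np.exp(b_f * (I4 - 1.0) ** 2) if I4 > 1.0 else 0.0
    return (iso + aniso) / r


# -- built-in model factories ----------------------------------------------------

#: Generating parameter values used by the synthetic-data protocol.
#: lotka_volterra values are the standard benchmark settings; the
#: fitzhugh_nagumo and biopathway entries are conventional literature values
#: supplied as configurable defaults; soft_tissue values are synthetic
#: placeholders.
DEFAULT_TRUE_PARAMS: dict[str, dict[str, float]] = {
    "lotka_volterra": {"alpha": 1.0, "beta": 1.0, "gamma": 4.0, "delta": 1.0},
    "fitzhugh_nagumo": {"a": 0.2, "b": 0.2, "c": 3.0},
    "biopathway": {"k1": 0.07, "k2": 0.6, "k3": 0.05, "k4": 0.3, "k5": 0.017, "k6": 0.3},
    "soft_tissue": {"a": 1.0, "b": 1.0, "a_f": 1.0, "b_f": 1.0},
}

DEFAULT_INITIAL_STATES: dict[str, list[float]] = {
    "lotka_volterra": [0.5, 1.0],
    "fitzhugh_nagumo": [-1.0, 1.0],
    "biopathway": [1.0, 0.0, 1.0, 0.0, 0.0],
    "soft_tissue": [0.0],
}


def lotka_volterra() -> ODEModel:
    return ODEModel(
        name="lotka_volterra",
        state_names=("x1", "x2"),
        param_names=("alpha", "beta", "gamma", "delta"),
        rhs=lambda x, t, theta: lotka_volterra_rhs(x, theta),
    )


def fitzhugh_nagumo() -> ODEModel:
    return ODEModel(
        name="fitzhugh_nagumo",
        state_names=("x1", "x2"),
        param_names=("a", "b", "c"),
        rhs=lambda x, t, theta: fitzhugh_nagumo_rhs(x, theta),
    )


def biopathway() -> ODEModel:
    return ODEModel(
        name="biopathway",
        state_names=("S", "dS", "R", "RS", "Rpp"),
        param_names=("k1", "k2", "k3", "k4", "k5", "k6"),
        rhs=lambda x, t, theta: biopathway_rhs(x, theta),
    )


def soft_tissue(consts: SoftTissueConstants | None = None) -> ODEModel:
    consts = consts or SoftTissueConstants()
    return ODEModel(
        name="soft_tissue",
        state_names=("sigma",),
        param_names=("a", "b", "a_f", "b_f"),
        rhs=lambda x, r, theta: np.array([soft_tissue_rhs(x[0], r, theta, consts)]),
        abscissa_label="radius",
    )


_REGISTRY: dict[str, Callable[..., ODEModel]] = {
    "lotka_volterra": lotka_volterra,
    "fitzhugh_nagumo": fitzhugh_nagumo,
    "biopathway": biopathway,
    "soft_tissue": soft_tissue,
}


def register_model(name: str, factory: Callable[..., ODEModel], overwrite: bool = False) -> None:
    """Register a user model factory under ``name`` for CLI/config lookup."""
    if name in _REGISTRY and not overwrite:
        raise ValueError(f"model {name!r} already registered")
    _REGISTRY[name] = factory


def available_models() -> list[str]:
    return sorted(_REGISTRY)


def get_model(name: str, **kwargs) -> ODEModel:
    try:
        factory = _REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown model {name!r}; available: {available_models()}"
        ) from None
    return factory(**kwargs)


# -- numerical integration -------------------------------------------------------

def solve(
    model: ODEModel,
    theta,
    x0,
    span: tuple[float, float],
    t_eval=None,
    rtol: float = 1e-6,
    atol: float = 1e-8,
    dense: bool = False,
):
    """Integrate the model with an adaptive RK 2(3) pair.

    Returns a :class:`Trajectory` (at solver-chosen points unless ``t_eval``
    is given); with ``dense=True`` returns ``(Trajectory, dense_solution)``.
    """
    vec = model.theta_vector(theta)
    x0 = np.asarray(x0, dtype=float).ravel()
    if x0.size != model.n_states:
        raise ValueError(
            f"x0 has {x0.size} entries but model {model.name!r} has {model.n_states} states"
        )
    f0 = model.rhs(x0, float(span[0]), vec)
    if not np.all(np.isfinite(f0)):
        raise ValueError("right-hand side is non-finite at the initial state")
    sol = solve_ivp(
        lambda t, x: model.rhs(x, t, vec),
        span,
        x0,
        method="RK23",
        t_eval=None if t_eval is None else np.asarray(t_eval, dtype=float),
        rtol=rtol,
        atol=atol,
        dense_output=dense,
    )
    if not sol.success:
        raise IntegrationError(
            f"integration of {model.name!r} failed: {sol.message}",
            last_time=float(sol.t[-1]) if sol.t.size else float(span[0]),
            last_state=sol.y[:, -1] if sol.t.size else x0,
        )
    traj = Trajectory(times=sol.t, states=sol.y.T)
    return (traj, sol.sol) if dense else traj
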