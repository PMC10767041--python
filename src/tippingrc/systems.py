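"""Ground-truth ODE testbeds and a fixed-step RK4 integrator.

Two systems are shipped:

* a generic power-system model (4 states: machine angle ``delta_m``, rotor
  speed ``omega``, load angle ``delta``, load voltage ``V``) whose load
  reactive-power demand ``Q1`` drives a voltage collapse;
* a three-species food chain (resource ``R``, consumer ``C``, predator
  ``P``) whose resource-carrying capacity ``K`` drives predator extinction
  and reappearance.

Both right-hand sides are vectorized over leading batch axes so that a
whole parameter sweep integrates in lockstep. The integrator is classical
fixed-step RK4; no adaptivity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from tippingrc.features import Trajectory

__all__ = [
    "PowerSystemParams",
    "FoodChainParams",
    "SystemSpec",
    "rk4_step",
    "power_system_rhs",
    "food_chain_rhs",
    "power_system",
    "food_chain",
    "simulate",
    "simulate_batch",
    "SimulationBatch",
]


@dataclass(frozen=True)
class PowerSystemParams:
    """Constants of the generic power-system model.

    The derived constants ``e0_eff`` (effective EMF), ``y0_eff`` (effective
    admittance) and ``theta0_eff`` are recomputed from the primitives at
    construction, never hard-coded. ``theta0_eff`` does not enter the
    dynamics as written but is kept for completeness.

    ``q0`` defaults to 1.3; the alternative 0.3 can be passed explicitly.
    """

    k_pw: float = 0.4
    k_pv: float = 0.3
    k_qw: float = -0.03
    k_qv: float = -2.8
    k_qv2: float = 2.1
    t_load: float = 8.5
    p0: float = 0.6
    p1: float = 0.0
    y0: float = 3.33
    ym: float = 5.0
    pm: float = 1.0
    dm: float = 0.05
    theta0: float = 0.0
    em: float = 1.05
    m_inertia: float = 0.01464
    c_cap: float = 3.5
    e0: float = 1.0
    q0: float = 1.3

    @property
    def e0_eff(self) -> float:
        root = np.sqrt(
            1.0
            + self.c_cap**2 * self.y0**-2
            - 2.0 * self.c_cap / self.y0 * np.cos(self.theta0)
        )
        return self.e0 / root

    @property
    def y0_eff(self) -> float:
        root = np.sqrt(
            1.0
            + self.c_cap**2 * self.y0**-2
            - 2.0 * self.c_cap / self.y0 * np.cos(self.theta0)
        )
        return self.y0 * root

    @property
    def theta0_eff(self) -> float:
        # two-argument arctangent handles the 0/0-adjacent case at theta0=0
        return self.theta0 + np.arctan2(
            self.c_cap / self.y0 * np.sin(self.theta0),
            1.0 - self.c_cap / self.y0 * np.cos(self.theta0),
        )


@dataclass(frozen=True)
class FoodChainParams:
    """Constants of the three-species food chain model."""

    x_c: float = 0.4
    y_c: float = 2.009
    x_p: float = 0.08
    y_p: float = 2.876
    r0: float = 0.16129
    c0: float = 0.5

    def __post_init__(self) -> None:
        for name in ("x_c", "y_c", "x_p", "y_p", "r0", "c0"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")


def power_system_rhs(
    state: np.ndarray, q1: float | np.ndarray, params: PowerSystemParams | None = None
) -> np.ndarray:
    """Time derivative of ``(delta_m, omega, delta, V)``; batched over
    leading axes of ``state`` (and, broadcast-compatibly, of ``q1``)."""
    p = params or PowerSystemParams()
    state = np.asarray(state, dtype=np.float64)
    dm_, w, d_, v = state[..., 0], state[..., 1], state[..., 2], state[..., 3]
    e0p, y0p = p.e0_eff, p.y0_eff
    sin_md = np.sin(dm_ - d_)
    cos_md = np.cos(dm_ - d_)
    # Load power in the source form P = -E0'Y0'V sin(delta), Q = +E0'Y0'V
    # cos(delta) - ...: with these constants C/Y0 > 1, so the effective
    # source angle is pi and sign conventions that absorb it into Q alone
    # make the model blow up in one step from the printed initial condition.
    # This form reproduces the documented collapse at Q1 ~ 2.98982.
    p_load = -e0p * y0p * v * np.sin(d_) + p.em * p.ym * v * sin_md
    q_load = (
        e0p * y0p * v * np.cos(d_) - (y0p + p.ym) * v**2 + p.em * p.ym * v * cos_md
    )
    d_dm = w
    d_w = (-p.dm * w + p.pm - p.em * p.ym * sin_md * v) / p.m_inertia
    d_d = (-p.k_qv2 * v**2 - p.k_qv * v + q_load - p.q0 - q1) / p.k_qw
    d_v = (
        p.k_pw * p.k_qv2 * v**2
        + (p.k_pw * p.k_qv - p.k_qw * p.k_pv) * v
        + p.k_qw * (p_load - p.p0 - p.p1)
        - p.k_pw * (q_load - p.q0 - q1)
    ) / (p.t_load * p.k_qw * p.k_pv)
    return np.stack([d_dm, d_w, d_d, d_v], axis=-1)


def food_chain_rhs(
    state: np.ndarray, k_cap: float | np.ndarray, params: FoodChainParams | None = None
) -> np.ndarray:
    """Time derivative of ``(R, C, P)``; batched over leading axes."""
    p = params or FoodChainParams()
    state = np.asarray(state, dtype=np.float64)
    r, c, pr = state[..., 0], state[..., 1], state[..., 2]
    f_rc = p.y_c * r / (r + p.r0)
    f_cp = p.y_p * c / (c + p.c0)
    d_r = r * (1.0 - r / k_cap) - p.x_c * f_rc * c
    d_c = p.x_c * c * (f_rc - 1.0) - p.x_p * f_cp * pr
    d_p = p.x_p * pr * (f_cp - 1.0)
    return np.stack([d_r, d_c, d_p], axis=-1)


@dataclass(frozen=True)
class SystemSpec:
    """An ODE right-hand side with its printed defaults.

    ``rhs(state, theta)`` must accept batched states of shape ``(..., d)``
    and a scalar or ``(...)``-shaped bifurcation parameter.
    """

    name: str
    state_names: tuple[str, ...]
    rhs: Callable[[np.ndarray, np.ndarray], np.ndarray]
    x0: np.ndarray
    dt: float
    n_steps: int
    theta_name: str
    bound: float = 1e3
    collapse_floor: float | None = None  # flag collapse when this component < 0
    collapse_component: int | None = None

    @property
    def d(self) -> int:
        return len(self.state_names)


def power_system(params: PowerSystemParams | None = None) -> SystemSpec:
    """Power-system testbed with printed initial condition and step size."""
    p = params or PowerSystemParams()
    return SystemSpec(
        name="power",
        state_names=("delta_m", "omega", "delta", "V"),
        rhs=lambda state, q1: power_system_rhs(state, q1, p),
        x0=np.array([0.17, 0.05, 0.05, 0.83]),
        dt=0.05,
        n_steps=10000,
        theta_name="Q1",
        collapse_floor=0.0,
        collapse_component=3,  # V < 0 counts as voltage collapse
    )


def food_chain(params: FoodChainParams | None = None) -> SystemSpec:
    """Food-chain testbed with printed initial condition and step size."""
    p = params or FoodChainParams()
    return SystemSpec(
        name="foodchain",
        state_names=("R", "C", "P"),
        rhs=lambda state, k_cap: food_chain_rhs(state, k_cap, p),
        x0=np.array([0.6, 0.35, 0.9]),
        dt=0.1,
        n_steps=25000,
        theta_name="K",
    )


def rk4_step(
    rhs: Callable[[np.ndarray, np.ndarray], np.ndarray],
    state: np.ndarray,
    theta: float | np.ndarray,
    dt: float,
) -> np.ndarray:
    """One classical 4-stage Runge-Kutta update with fixed step ``dt``."""
    k1 = rhs(state, theta)
    k2 = rhs(state + 0.5 * dt * k1, theta)
    k3 = rhs(state + 0.5 * dt * k2, theta)
    k4 = rhs(state + dt * k3, theta)
    return state + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)


@dataclass
class SimulationBatch:
    """Result of a batched fixed-parameter simulation.

    ``states`` has shape ``(B, n_steps + 1, d)``; rows after an element's
    stop index are NaN. ``collapsed[b]`` is True when element ``b``
    left the admissible region (non-finite, beyond ``bound``, or below the
    collapse floor) before completing.
    """

    states: np.ndarray
    thetas: np.ndarray
    dt: float
    collapsed: np.ndarray
    stop_index: np.ndarray

    def trajectory(self, b: int, names: tuple[str, ...] = ()) -> Trajectory:
        return Trajectory(self.states[b, : self.stop_index[b] + 1], self.dt, names)


def simulate_batch(
    spec: SystemSpec,
    thetas: np.ndarray,
    n_steps: int | None = None,
    dt: float | None = None,
    x0: np.ndarray | None = None,
    bound: float | None = None,
) -> SimulationBatch:
    """Integrate one trajectory per entry of ``thetas`` in lockstep.

    Elements whose state becomes non-finite, exceeds ``bound`` in magnitude,
    or drops below the spec's collapse floor are frozen and flagged; the
    remaining elements keep integrating.
    """
    thetas = np.atleast_1d(np.asarray(thetas, dtype=np.float64))
    n_steps = spec.n_steps if n_steps is None else int(n_steps)
    dt = spec.dt if dt is None else float(dt)
    x0 = np.asarray(spec.x0 if x0 is None else x0, dtype=np.float64)
    bound = spec.bound if bound is None else float(bound)
    B, d = thetas.shape[0], spec.d

    out = np.full((B, n_steps + 1, d), np.nan)
    out[:, 0] = x0
    state = np.broadcast_to(x0, (B, d)).copy()
    collapsed = np.zeros(B, dtype=bool)
    stop = np.full(B, n_steps, dtype=np.intp)
    active = np.ones(B, dtype=bool)

    for t in range(n_steps):
        nxt = rk4_step(spec.rhs, state[active], thetas[active], dt)
        bad = ~np.isfinite(nxt).all(axis=1) | (np.abs(nxt) > bound).any(axis=1)
        if spec.collapse_component is not None and spec.collapse_floor is not None:
            bad |= nxt[:, spec.collapse_component] < spec.collapse_floor
        idx = np.flatnonzero(active)
        dead = idx[bad]
        if dead.size:
            collapsed[dead] = True
            stop[dead] = t  # last finite recorded row
            active[dead] = False
        ok = idx[~bad]
        if ok.size:
            out[ok, t + 1] = nxt[~bad]
            state[ok] = nxt[~bad]
        if not active.any():
            break
    return SimulationBatch(
        states=out, thetas=thetas, dt=dt, collapsed=collapsed, stop_index=stop
    )


def simulate(
    spec: SystemSpec,
    theta: float,
    n_steps: int | None = None,
    dt: float | None = None,
    x0: np.ndarray | None = None,
    bound: float | None = None,
) -> tuple[Trajectory, bool]:
    """Integrate a single trajectory; returns ``(trajectory, collapsed)``.

    The trajectory holds the recorded finite states only (length
    ``n_steps + 1`` when the run completes).
    """
    batch = simulate_batch(spec, np.array([theta]), n_steps, dt, x0, bound)
    return batch.trajectory(0, spec.state_names), bool(batch.collapsed[0])
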