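"""Autonomous one-step prediction with a trained NG-RC readout.

The trained model is iterated as ``x_{i+1} = x_i + W_out r~(x_i, theta_i)``
where the bifurcation parameter can be held fixed or varied per step
through a :class:`ParameterSchedule`. Batched variants run one prediction
per parameter value in lockstep for sweeps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from tippingrc.features import InsufficientHistoryError, Trajectory, get_plan
from tippingrc.training import ReadoutModel

__all__ = [
    "ParameterSchedule",
    "PredictionResult",
    "BatchPredictionResult",
    "step",
    "run",
    "run_batch",
]

DEFAULT_BOUND = 1e3


@dataclass(frozen=True)
class ParameterSchedule:
    """Per-step bifurcation-parameter values ``theta_i``.

    Construct through the factory classmethods; ``__call__(i)`` returns the
    parameter applied at prediction step ``i`` (0-based).
    """

    kind: str
    params: dict = field(default_factory=dict)

    @classmethod
    def constant(cls, value: float) -> "ParameterSchedule":
        return cls("constant", {"value": float(value)})

    @classmethod
    def step_switch(
        cls, before: float, after: float, switch_step: int
    ) -> "ParameterSchedule":
        """``before`` for steps < switch_step, ``after`` from then on."""
        return cls(
            "step_switch",
            {"before": float(before), "after": float(after), "switch_step": int(switch_step)},
        )

    @classmethod
    def sinusoid_plus_ramp(
        cls, baseline: float, amplitude: float, period_steps: float, slope_per_step: float
    ) -> "ParameterSchedule":
        """``baseline + amplitude*sin(2 pi i / period) + slope*i``.

        Defaults used by the packaged recipes are illustrative only.
        """
        return cls(
            "sinusoid_plus_ramp",
            {
                "baseline": float(baseline),
                "amplitude": float(amplitude),
                "period_steps": float(period_steps),
                "slope_per_step": float(slope_per_step),
            },
        )

    @classmethod
    def sequence(cls, values: Sequence[float]) -> "ParameterSchedule":
        vals = np.asarray(values, dtype=np.float64)
        if not np.isfinite(vals).all():
            raise ValueError("schedule sequence must be finite")
        return cls("sequence", {"values": tuple(float(v) for v in vals)})

    def __call__(self, i: int) -> float:
        p = self.params
        if self.kind == "constant":
            return p["value"]
        if self.kind == "step_switch":
            return p["before"] if i < p["switch_step"] else p["after"]
        if self.kind == "sinusoid_plus_ramp":
            return (
                p["baseline"]
                + p["amplitude"] * np.sin(2.0 * np.pi * i / p["period_steps"])
                + p["slope_per_step"] * i
            )
        if self.kind == "sequence":
            vals = p["values"]
            if i >= len(vals):
                raise IndexError(f"schedule sequence exhausted at step {i}")
            return vals[i]
        raise ValueError(f"unknown schedule kind {self.kind!r}")

    def values(self, n_steps: int) -> np.ndarray:
        out = np.array([self(i) for i in range(n_steps)], dtype=np.float64)
        if not np.isfinite(out).all():
            raise ValueError("schedule produced non-finite parameter values")
        return out


@dataclass
class PredictionResult:
    """Predicted trajectory with its applied parameter series.

    ``trajectory`` contains the warm-up's final state history followed only
    by finite predicted states; on early termination, ``termination_reason``
    is ``"non_finite"`` or ``"bound_exceeded"`` and no offending row is
    recorded.
    """

    trajectory: Trajectory
    theta_series: np.ndarray
    terminated_early: bool
    termination_reason: str
    steps_taken: int


@dataclass
class BatchPredictionResult:
    """One prediction per batch element, run in lockstep.

    ``states`` has shape ``(B, delta_t + n_steps, d)``; the first
    ``delta_t`` rows per element are the warm-up history, and rows after an
    early termination are NaN.
    """

    states: np.ndarray
    thetas: np.ndarray
    dt: float
    delta_t: int
    terminated_early: np.ndarray
    steps_taken: np.ndarray

    def predicted(self, b: int) -> np.ndarray:
        """Finite predicted states of element ``b`` (warm-up excluded)."""
        return self.states[b, self.delta_t : self.delta_t + self.steps_taken[b]]


def _check_warmup(model: ReadoutModel, history: np.ndarray) -> np.ndarray:
    hist = np.asarray(history, dtype=np.float64)
    if hist.ndim == 1:
        hist = hist[:, None]
    delta_t = model.cfg.delta_t
    if hist.shape[0] < delta_t:
        raise InsufficientHistoryError(
            f"warm-up of {hist.shape[0]} states is too short: the model needs "
            f"delta_t = {delta_t} states"
        )
    if hist.shape[-1] != model.d:
        raise ValueError(f"history dimension {hist.shape[-1]} != model d = {model.d}")
    return hist[-delta_t:]


def step(model: ReadoutModel, history: np.ndarray, theta: float) -> np.ndarray:
    """One prediction step from the last ``delta_t`` states in ``history``."""
    hist = _check_warmup(model, history)
    cfg = model.cfg
    plan = get_plan(model.d, cfg)
    last = hist.shape[0] - 1
    stacked = np.concatenate([hist[last - j * cfg.s] for j in range(cfg.k)])
    r_tilde = plan.expand(plan.monomials(stacked), cfg.gamma * theta)
    return hist[-1] + model.w_out @ r_tilde


def run(
    model: ReadoutModel,
    warmup: Trajectory | np.ndarray,
    schedule: ParameterSchedule,
    n_steps: int,
    bound: float = DEFAULT_BOUND,
) -> PredictionResult:
    """Iterate the model autonomously for ``n_steps`` under ``schedule``.

    Stops early when any predicted component is non-finite or exceeds
    ``bound`` in magnitude; the offending state is not recorded.
    """
    states = warmup.states if isinstance(warmup, Trajectory) else np.asarray(warmup)
    dt = warmup.dt if isinstance(warmup, Trajectory) else model.dt
    hist = _check_warmup(model, states)
    thetas = schedule.values(n_steps)
    batch = run_batch(model, hist[None, :, :], thetas[None, :], n_steps, bound, dt=dt)
    taken = int(batch.steps_taken[0])
    traj = Trajectory(batch.states[0, : model.cfg.delta_t + taken], dt)
    if not batch.terminated_early[0]:
        reason = "completed"
    else:
        last_try = step(model, traj.states, thetas[taken]) if taken >= 0 else None
        reason = "non_finite" if not np.isfinite(last_try).all() else "bound_exceeded"
    return PredictionResult(
        trajectory=traj,
        theta_series=thetas[:taken],
        terminated_early=bool(batch.terminated_early[0]),
        termination_reason=reason,
        steps_taken=taken,
    )


def run_batch(
    model: ReadoutModel,
    warmups: np.ndarray,
    thetas: np.ndarray,
    n_steps: int,
    bound: float = DEFAULT_BOUND,
    dt: float | None = None,
) -> BatchPredictionResult:
    """Run ``B`` autonomous predictions in lockstep.

    Parameters
    ----------
    warmups : ndarray, shape (B, >= delta_t, d)
        Initial histories (most recent state last).
    thetas : ndarray, shape (B,) or (B, n_steps)
        Constant parameter per element, or a per-step parameter series.
    """
    cfg = model.cfg
    plan = get_plan(model.d, cfg)
    delta_t = cfg.delta_t
    warmups = np.asarray(warmups, dtype=np.float64)
    if warmups.ndim != 3 or warmups.shape[1] < delta_t:
        raise InsufficientHistoryError(
            f"warmups must have shape (B, >= delta_t = {delta_t}, d)"
        )
    B, _, d = warmups.shape
    thetas = np.asarray(thetas, dtype=np.float64)
    if thetas.ndim == 1:
        theta_of = lambda t: thetas
    elif thetas.shape == (B, n_steps):
        theta_of = lambda t: thetas[:, t]
    else:
        raise ValueError("thetas must have shape (B,) or (B, n_steps)")

    out = np.full((B, delta_t + n_steps, d), np.nan)
    out[:, :delta_t] = warmups[:, -delta_t:]
    buf = warmups[:, -delta_t:, :].copy()
    active = np.ones(B, dtype=bool)
    taken = np.zeros(B, dtype=np.intp)
    # stacked layout: current state first, then successively older points
    offsets = np.array([delta_t - 1 - j * cfg.s for j in range(cfg.k)], dtype=np.intp)

    for t in range(n_steps):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        sub = buf[idx]
        stacked = sub[:, offsets, :].reshape(idx.size, cfg.k * d)
        r_tilde = plan.expand(plan.monomials(stacked), cfg.gamma * theta_of(t)[idx])
        nxt = sub[:, -1, :] + r_tilde @ model.w_out.T
        bad = ~np.isfinite(nxt).all(axis=1) | (np.abs(nxt) > bound).any(axis=1)
        dead = idx[bad]
        active[dead] = False
        ok = idx[~bad]
        if ok.size:
            out[ok, delta_t + t] = nxt[~bad]
            taken[ok] = t + 1
            buf[ok, :-1] = buf[ok, 1:]
            buf[ok, -1] = nxt[~bad]
    return BatchPredictionResult(
        states=out,
        thetas=thetas,
        dt=model.dt if dt is None else dt,
        delta_t=delta_t,
        terminated_early=taken < n_steps,
        steps_taken=taken,
    )
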