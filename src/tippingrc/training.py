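"""Multi-trajectory assembly and ridge regression for the NG-RC readout.

The readout ``W_out`` maps expanded feature vectors to one-step state
increments ``x_{i+1} - x_i``; training is a single regularized linear
solve, so the whole pipeline is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

from tippingrc.features import (
    FeatureConfig,
    FeatureOrderingManifest,
    Trajectory,
    feature_dimension,
    get_plan,
)

__all__ = ["TrainingSet", "ReadoutModel", "build_targets", "assemble", "ridge_solve", "fit_readout"]


@dataclass(frozen=True)
class TrainingSet:
    """Stationary training samples ``(trajectory, theta)`` sharing one config."""

    samples: tuple[tuple[Trajectory, float], ...]
    cfg: FeatureConfig

    def __post_init__(self) -> None:
        if not self.samples:
            raise ValueError("training set needs at least one sample")
        object.__setattr__(self, "samples", tuple(self.samples))
        d0, dt0 = self.samples[0][0].d, self.samples[0][0].dt
        for traj, theta in self.samples:
            if traj.d != d0:
                raise ValueError("all samples must share the state dimension")
            if traj.dt != dt0:
                raise ValueError("all samples must share the time step")
            if not np.isfinite(theta):
                raise ValueError("theta values must be finite")

    @property
    def d(self) -> int:
        return self.samples[0][0].d

    @property
    def dt(self) -> float:
        return self.samples[0][0].dt

    @property
    def thetas(self) -> tuple[float, ...]:
        return tuple(float(th) for _, th in self.samples)


@dataclass(frozen=True)
class ReadoutModel:
    """Trained readout matrix plus everything needed to run it."""

    w_out: np.ndarray  # (d, N_tilde)
    cfg: FeatureConfig
    manifest: FeatureOrderingManifest
    d: int
    dt: float
    train_thetas: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        w = np.asarray(self.w_out, dtype=np.float64)
        _, n_tilde = feature_dimension(self.d, self.cfg)
        if w.shape != (self.d, n_tilde):
            raise ValueError(
                f"w_out shape {w.shape} inconsistent with (d, N_tilde) = "
                f"({self.d}, {n_tilde})"
            )
        if not np.isfinite(w).all():
            raise ValueError("w_out contains non-finite entries")
        object.__setattr__(self, "w_out", w)
        object.__setattr__(self, "train_thetas", tuple(self.train_thetas))


def build_targets(traj: Trajectory, delta_t: int) -> np.ndarray:
    """Target matrix ``(d, T - delta_t - 1)`` of one-step increments.

    Column ``j`` is ``x_{i+1} - x_i`` for ``i = delta_t + j``, aligned with
    feature-matrix column ``j``.
    """
    T = len(traj)
    if T < delta_t + 2:
        raise ValueError(
            f"trajectory too short for targets: need >= delta_t + 2 = "
            f"{delta_t + 2} points, got {T}"
        )
    diffs = np.diff(traj.states, axis=0)  # row i -> x_{i+1} - x_i
    return diffs[delta_t:].T


def assemble(training: TrainingSet) -> tuple[np.ndarray, np.ndarray]:
    """Concatenated feature and target matrices over all samples.

    Each sample's feature block is built with its own theta through the
    parameter channel. Returns ``(R_M, Y_M)`` of shapes
    ``(N_tilde, sum_m m_j)`` and ``(d, sum_m m_j)``.
    """
    cfg = training.cfg
    plan = get_plan(training.d, cfg)
    r_blocks, y_blocks = [], []
    for traj, theta in training.samples:
        stacked = plan.stack_matrix(traj.states)
        r = plan.expand(plan.monomials(stacked), cfg.gamma * theta).T
        y = build_targets(traj, cfg.delta_t)
        if r.shape[1] != y.shape[1]:
            raise ValueError("feature/target column mismatch")
        r_blocks.append(r)
        y_blocks.append(y)
    return np.concatenate(r_blocks, axis=1), np.concatenate(y_blocks, axis=1)


def ridge_solve(
    r_m: np.ndarray, y_m: np.ndarray, beta: float, method: str = "svd"
) -> np.ndarray:
    """Minimize ``||Y - W R||^2 + beta ||W||^2`` for the readout ``W``.

    ``method="svd"`` (default) filters the singular spectrum of ``R``:
    ``W = Y V diag(s / (s^2 + beta)) U^T`` — the exact ridge minimizer,
    computed without forming the Gram matrix. The feature matrices of
    high-order polynomial dictionaries are so ill-conditioned that a
    Gram-based solve at the tiny regularizations used here returns a
    readout dominated by round-off.

    ``method="cholesky"`` solves the normal equations
    ``(R R^T + beta I) W^T = R Y^T`` with an SPD factorization (least-squares
    fallback); at ``beta = 0`` a singular Gram matrix raises a numerical
    error advising ``beta > 0``.
    """
    r_m = np.asarray(r_m, dtype=np.float64)
    y_m = np.asarray(y_m, dtype=np.float64)
    if beta < 0:
        raise ValueError("beta must be >= 0")
    if method == "svd":
        u, s, vt = np.linalg.svd(r_m, full_matrices=False)
        if beta == 0.0 and s[-1] <= s[0] * np.finfo(np.float64).eps * max(r_m.shape):
            raise np.linalg.LinAlgError(
                "feature matrix is numerically rank deficient at beta=0; use beta > 0"
            )
        filt = s / (s**2 + beta)
        return ((y_m @ vt.T) * filt) @ u.T
    if method == "cholesky":
        gram = r_m @ r_m.T
        gram[np.diag_indices_from(gram)] += beta
        rhs = r_m @ y_m.T  # (N_tilde, d)
        try:
            cho = linalg.cho_factor(gram, lower=True, check_finite=False)
            sol = linalg.cho_solve(cho, rhs, check_finite=False)
        except linalg.LinAlgError:
            if beta == 0.0:
                raise np.linalg.LinAlgError(
                    "feature Gram matrix is singular at beta=0; use beta > 0"
                )
            sol, *_ = linalg.lstsq(gram, rhs, check_finite=False, lapack_driver="gelsd")
        return sol.T
    raise ValueError(f"unknown method {method!r}")


def fit_readout(training: TrainingSet) -> ReadoutModel:
    """Assemble all samples and solve for the readout."""
    r_m, y_m = assemble(training)
    w = ridge_solve(r_m, y_m, training.cfg.beta)
    plan = get_plan(training.d, training.cfg)
    return ReadoutModel(
        w_out=w,
        cfg=training.cfg,
        manifest=plan.manifest,
        d=training.d,
        dt=training.dt,
        train_thetas=training.thetas,
    )
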