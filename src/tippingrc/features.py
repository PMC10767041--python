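"""NG-RC feature construction.

The feature pipeline maps a windowed piece of a trajectory to an expanded
feature vector in three stages:

1. time-delay stacking: the current state is concatenated with ``k - 1``
   older states spaced ``s`` steps apart;
2. polynomial dictionary: all unique monomials (combinations with
   repetition) of the stacked variables at each requested order;
3. elementwise post-processing: the monomial vector, optionally shifted by
   ``gamma * theta`` (the bifurcation-parameter channel), is concatenated
   with elementwise powers of itself and an optional leading bias entry.

All arithmetic is double precision and fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations_with_replacement
from math import comb
from typing import Sequence

import numpy as np

__all__ = [
    "Trajectory",
    "FeatureConfig",
    "FeatureOrderingManifest",
    "InsufficientHistoryError",
    "delay_embed",
    "poly_features",
    "feature_dimension",
    "postprocess",
    "feature_vector",
    "feature_matrix",
]


class InsufficientHistoryError(ValueError):
    """Raised when an index precedes the warm-up window ``delta_t = k * s``."""


@dataclass(frozen=True)
class Trajectory:
    """Uniformly sampled multivariate time series.

    Parameters
    ----------
    states : ndarray, shape (T, d)
        One row per time step, one column per state component.
    dt : float
        Sampling interval in model time units.
    names : tuple of str, optional
        Component names; defaults to ``x1 ... xd``.
    """

    states: np.ndarray
    dt: float
    names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        arr = np.asarray(self.states, dtype=np.float64)
        if arr.ndim == 1:
            arr = arr[:, None]
        if arr.ndim != 2 or arr.shape[0] < 1 or arr.shape[1] < 1:
            raise ValueError("states must be a (T, d) array with T >= 1, d >= 1")
        if not np.isfinite(arr).all():
            raise ValueError("trajectory contains non-finite entries")
        if not self.dt > 0:
            raise ValueError("dt must be positive")
        object.__setattr__(self, "states", arr)
        names = tuple(self.names) or tuple(f"x{j + 1}" for j in range(arr.shape[1]))
        if len(names) != arr.shape[1]:
            raise ValueError("names length must equal state dimension")
        object.__setattr__(self, "names", names)

    @property
    def d(self) -> int:
        return self.states.shape[1]

    def __len__(self) -> int:
        return self.states.shape[0]


@dataclass(frozen=True)
class FeatureConfig:
    """All NG-RC hyperparameters.

    Parameters
    ----------
    k : int
        Number of stacked time points (the current one plus ``k - 1`` past
        ones).
    s : int
        Spacing, in time steps, between the stacked points.
    poly_orders : tuple of int
        Orders of the unique-monomial dictionary (``O``); strictly
        increasing positive integers.
    post_orders : tuple of int
        Elementwise post-processing orders (``O_states``); strictly
        increasing non-negative integers, where 0 encodes a bias entry.
    gamma : float
        Scaling of the bifurcation-parameter channel.
    beta : float
        Ridge regularization strength used at training time.
    """

    k: int
    s: int
    poly_orders: tuple[int, ...]
    post_orders: tuple[int, ...]
    gamma: float = 0.0
    beta: float = 0.0

    def __post_init__(self) -> None:
        if self.k < 1 or self.s < 1:
            raise ValueError("k and s must be >= 1")
        po = tuple(int(o) for o in self.poly_orders)
        so = tuple(int(o) for o in self.post_orders)
        if not po or any(o < 1 for o in po) or list(po) != sorted(set(po)):
            raise ValueError("poly_orders must be strictly increasing positive integers")
        if not so or any(o < 0 for o in so) or list(so) != sorted(set(so)):
            raise ValueError("post_orders must be strictly increasing non-negative integers")
        if not np.isfinite(self.gamma):
            raise ValueError("gamma must be finite")
        if not (np.isfinite(self.beta) and self.beta >= 0):
            raise ValueError("beta must be finite and >= 0")
        object.__setattr__(self, "poly_orders", po)
        object.__setattr__(self, "post_orders", so)

    @property
    def delta_t(self) -> int:
        """Warm-up length in time steps (features before it are undefined)."""
        return self.k * self.s

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "s": self.s,
            "poly_orders": list(self.poly_orders),
            "post_orders": list(self.post_orders),
            "gamma": self.gamma,
            "beta": self.beta,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureConfig":
        return cls(
            k=int(d["k"]),
            s=int(d["s"]),
            poly_orders=tuple(d["poly_orders"]),
            post_orders=tuple(d["post_orders"]),
            gamma=float(d["gamma"]),
            beta=float(d["beta"]),
        )


@dataclass(frozen=True)
class FeatureOrderingManifest:
    """Deterministic layout of the expanded feature vector.

    Serialized with every trained model so that readout-matrix columns stay
    portable across processes.

    Attributes
    ----------
    stacked_vars : tuple of (delay index, component index)
        Order of the delay-stacked variables; delay index ``j`` means the
        state ``j * s`` steps in the past.
    monomials : tuple of tuple of int
        For each monomial, the sorted stacked-variable indices with
        multiplicity (graded order: by total degree, then lexicographic).
    post_layout : tuple of (order, monomial index)
        One entry per expanded-feature slot; the bias slot is ``(0, -1)``.
    """

    stacked_vars: tuple[tuple[int, int], ...]
    monomials: tuple[tuple[int, ...], ...]
    post_layout: tuple[tuple[int, int], ...]

    def __len__(self) -> int:
        return len(self.post_layout)

    def to_dict(self) -> dict:
        return {
            "stacked_vars": [list(v) for v in self.stacked_vars],
            "monomials": [list(m) for m in self.monomials],
            "post_layout": [list(p) for p in self.post_layout],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureOrderingManifest":
        return cls(
            stacked_vars=tuple(tuple(v) for v in d["stacked_vars"]),
            monomials=tuple(tuple(m) for m in d["monomials"]),
            post_layout=tuple(tuple(p) for p in d["post_layout"]),
        )


def build_manifest(d: int, cfg: FeatureConfig) -> FeatureOrderingManifest:
    """Enumerate the full feature layout for state dimension ``d``."""
    stacked = tuple((j, c) for j in range(cfg.k) for c in range(d))
    D = d * cfg.k
    monos: list[tuple[int, ...]] = []
    for o in cfg.poly_orders:
        monos.extend(combinations_with_replacement(range(D), o))
    layout: list[tuple[int, int]] = []
    for o in cfg.post_orders:
        if o == 0:
            layout.append((0, -1))
        else:
            layout.extend((o, m) for m in range(len(monos)))
    return FeatureOrderingManifest(
        stacked_vars=stacked, monomials=tuple(monos), post_layout=tuple(layout)
    )


class FeaturePlan:
    """Precomputed index arrays for vectorized feature evaluation.

    Reused across every feature-matrix build and prediction step with the
    same ``(d, cfg)`` pair; evaluation is pure NumPy gathers and products.
    """

    def __init__(self, d: int, cfg: FeatureConfig):
        self.d = int(d)
        self.cfg = cfg
        self.D = self.d * cfg.k
        self._combos = [
            np.array(list(combinations_with_replacement(range(self.D), o)), dtype=np.intp)
            for o in cfg.poly_orders
        ]
        self.n_monomials = sum(c.shape[0] for c in self._combos)
        self.n_features = sum(
            1 if o == 0 else self.n_monomials for o in cfg.post_orders
        )
        self.manifest = build_manifest(self.d, cfg)

    def stack(self, states: np.ndarray, i: int) -> np.ndarray:
        """Delay-stack ``states`` (T, d) at time index ``i`` -> (D,)."""
        cfg = self.cfg
        if i < cfg.delta_t:
            raise InsufficientHistoryError(
                f"index {i} precedes the warm-up window: features require "
                f"i >= delta_t = k*s = {cfg.delta_t}"
            )
        rows = [states[i - j * cfg.s] for j in range(cfg.k)]
        return np.concatenate(rows)

    def monomials(self, stacked: np.ndarray) -> np.ndarray:
        """Evaluate the monomial dictionary; batched over leading axes."""
        v = np.asarray(stacked, dtype=np.float64)
        parts = []
        for combo in self._combos:
            if combo.shape[1] == 1:
                parts.append(v[..., combo[:, 0]])
            else:
                parts.append(np.prod(v[..., combo], axis=-1))
        return np.concatenate(parts, axis=-1)

    def expand(self, r: np.ndarray, gamma_theta: float | np.ndarray = 0.0) -> np.ndarray:
        """Shift monomials by ``gamma * theta`` and apply post-processing.

        The shift is applied to every monomial entry *before* the
        elementwise powers; the bias entry is generated afterwards and is
        not shifted.
        """
        r = np.asarray(r, dtype=np.float64)
        gt = np.asarray(gamma_theta, dtype=np.float64)
        shifted = r + (gt[..., None] if gt.ndim else gt)
        parts = []
        for o in self.cfg.post_orders:
            if o == 0:
                parts.append(np.ones(shifted.shape[:-1] + (1,), dtype=np.float64))
            elif o == 1:
                parts.append(shifted)
            else:
                parts.append(shifted**o)
        return np.concatenate(parts, axis=-1)

    def stack_matrix(self, states: np.ndarray) -> np.ndarray:
        """Delay-stack all admissible rows of ``states`` (T, d).

        Returns an ``(T - delta_t - 1, D)`` array whose row ``j`` is the
        stacked vector at time index ``i = delta_t + j``; the last point is
        excluded because its one-step target would fall outside the data.
        """
        cfg = self.cfg
        T = states.shape[0]
        m = T - cfg.delta_t - 1
        if m < 1:
            raise ValueError(
                f"trajectory too short: need at least delta_t + 2 = "
                f"{cfg.delta_t + 2} points, got {T}"
            )
        cols = [
            states[cfg.delta_t - j * cfg.s : cfg.delta_t - j * cfg.s + m]
            for j in range(cfg.k)
        ]
        return np.concatenate(cols, axis=1)


_PLAN_CACHE: dict[tuple, FeaturePlan] = {}


def get_plan(d: int, cfg: FeatureConfig) -> FeaturePlan:
    """Cached :class:`FeaturePlan` lookup (gamma/beta excluded from the key)."""
    key = (int(d), cfg.k, cfg.s, cfg.poly_orders, cfg.post_orders)
    plan = _PLAN_CACHE.get(key)
    if plan is None:
        plan = _PLAN_CACHE[key] = FeaturePlan(d, cfg)
    return plan


def delay_embed(traj: Trajectory, k: int, s: int, i: int) -> np.ndarray:
    """Stacked vector ``(x_i, x_{i-s}, ..., x_{i-(k-1)s})`` of dimension d*k.

    Defined only for ``i >= k * s`` (the conservative warm-up window).
    """
    if k < 1 or s < 1:
        raise ValueError("k and s must be >= 1")
    if i < k * s:
        raise InsufficientHistoryError(
            f"index {i} precedes the warm-up window: need i >= delta_t = k*s = {k * s}"
        )
    if i >= len(traj):
        raise IndexError(f"index {i} out of range for trajectory of length {len(traj)}")
    rows = [traj.states[i - j * s] for j in range(k)]
    return np.concatenate(rows)


def poly_features(v: np.ndarray, poly_orders: Sequence[int]) -> np.ndarray:
    """All unique monomials of ``v`` at each order, in manifest order.

    The output dimension is ``N = sum_o C(D + o - 1, o)`` for ``D = len(v)``.
    """
    orders = tuple(int(o) for o in poly_orders)
    if not orders:
        raise ValueError("poly_orders must be non-empty")
    v = np.asarray(v, dtype=np.float64)
    if v.shape[-1] < 1:
        raise ValueError("input vector must have dimension >= 1")
    parts = []
    for o in orders:
        combos = np.array(
            list(combinations_with_replacement(range(v.shape[-1]), o)), dtype=np.intp
        )
        parts.append(np.prod(v[..., combos], axis=-1))
    return np.concatenate(parts, axis=-1)


def feature_dimension(d: int, cfg: FeatureConfig) -> tuple[int, int]:
    """Return ``(N, N_tilde)``: monomial and expanded feature dimensions."""
    D = d * cfg.k
    n = sum(comb(D + o - 1, o) for o in cfg.poly_orders)
    n_tilde = sum(1 if o == 0 else n for o in cfg.post_orders)
    return n, n_tilde


def postprocess(r: np.ndarray, post_orders: Sequence[int]) -> np.ndarray:
    """Concatenate, in order: a 1 for order 0, elementwise o-th powers else."""
    r = np.asarray(r, dtype=np.float64)
    parts = []
    for o in post_orders:
        if o == 0:
            parts.append(np.ones(r.shape[:-1] + (1,), dtype=np.float64))
        elif o == 1:
            parts.append(r)
        else:
            parts.append(r**o)
    return np.concatenate(parts, axis=-1)


def feature_vector(
    history: np.ndarray, cfg: FeatureConfig, theta: float = 0.0, *, d: int | None = None
) -> np.ndarray:
    """Expanded feature vector from a ``(>= delta_t, d)`` block of history.

    The most recent state is the last row. The parameter channel adds
    ``gamma * theta`` to every monomial entry before post-processing.
    """
    if not np.isfinite(theta):
        raise ValueError("theta must be finite")
    hist = np.asarray(history, dtype=np.float64)
    if hist.ndim == 1:
        hist = hist[:, None]
    if d is not None and hist.shape[1] != d:
        raise ValueError(f"history dimension {hist.shape[1]} != expected {d}")
    need = (cfg.k - 1) * cfg.s + 1
    if hist.shape[0] < need:
        raise InsufficientHistoryError(
            f"history of {hist.shape[0]} states is too short: need at least "
            f"{need} (warm-up delta_t = {cfg.delta_t})"
        )
    plan = get_plan(hist.shape[1], cfg)
    last = hist.shape[0] - 1
    stacked = np.concatenate([hist[last - j * cfg.s] for j in range(cfg.k)])
    return plan.expand(plan.monomials(stacked), cfg.gamma * theta)


def feature_matrix(
    traj: Trajectory, cfg: FeatureConfig, theta: float = 0.0
) -> np.ndarray:
    """Feature matrix ``(N_tilde, T - delta_t - 1)`` of a full trajectory.

    Column ``j`` is the feature vector built from time index
    ``i = delta_t + j``, aligned with the one-step target
    ``x_{i+1} - x_i``.
    """
    if not np.isfinite(theta):
        raise ValueError("theta must be finite")
    plan = get_plan(traj.d, cfg)
    stacked = plan.stack_matrix(traj.states)
    r = plan.monomials(stacked)
    return plan.expand(r, cfg.gamma * theta).T
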