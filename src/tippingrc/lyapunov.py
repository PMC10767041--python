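"""Largest Lyapunov exponent via the Rosenstein algorithm.

States are taken as fully observed, so no delay reconstruction is
performed: for each sampled point the nearest neighbor with a temporal
separation larger than the dominant period is tracked forward, and the
slope of the mean log-separation curve gives the exponent (per model time
unit).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from tippingrc.features import Trajectory

__all__ = [
    "LyapunovEstimate",
    "rosenstein_lambda_max",
    "classify_regime",
    "dominant_period_steps",
]

_EPS = 1e-15


class LyapunovEstimationError(ValueError):
    """Raised when no admissible neighbor pairs exist."""


@dataclass
class LyapunovEstimate:
    """Result of a Rosenstein largest-Lyapunov-exponent fit."""

    lambda_max: float
    divergence_curve: np.ndarray  # mean log separation vs. step
    fit_range: tuple[int, int]
    n_pairs: int
    degenerate: bool = False


def dominant_period_steps(x: np.ndarray) -> int:
    """Dominant period, in steps, from the mean frequency of the spectrum.

    Follows the Rosenstein prescription: the reciprocal of the
    power-weighted mean frequency of the observable.
    """
    x = np.asarray(x, dtype=np.float64)
    x = x - x.mean()
    if np.allclose(x, 0.0):
        return 1
    power = np.abs(np.fft.rfft(x)) ** 2
    freqs = np.fft.rfftfreq(x.size)
    power[0] = 0.0
    total = power.sum()
    if total <= 0:
        return 1
    mean_freq = float((freqs * power).sum() / total)
    if mean_freq <= 0:
        return 1
    return max(1, int(round(1.0 / mean_freq)))


def rosenstein_lambda_max(
    traj: Trajectory,
    min_separation: int | None = None,
    horizon: int = 300,
    fit_range: tuple[int, int] | None = None,
    discard_frac: float = 0.2,
    max_pairs: int = 2000,
) -> LyapunovEstimate:
    """Estimate the largest Lyapunov exponent of a fully observed trajectory.

    Parameters
    ----------
    min_separation : int, optional
        Minimum temporal separation (steps) between a point and its
        neighbor; defaults to the dominant period of the first component.
    horizon : int
        Number of steps over which separations are tracked.
    fit_range : (start, end), optional
        Step window for the least-squares slope; defaults to
        ``(0, horizon // 2)``.
    discard_frac : float
        Leading fraction of the trajectory dropped as transient.
    max_pairs : int
        Cap on reference points (deterministic even subsampling).
    """
    data = traj.states[int(len(traj) * discard_frac) :]
    n = data.shape[0]
    if n < horizon + 10:
        raise LyapunovEstimationError(
            f"trajectory too short for horizon {horizon}: {n} post-transient points"
        )
    if min_separation is None:
        min_separation = dominant_period_steps(data[:, 0])
    min_separation = max(1, min(int(min_separation), n // 4))
    if fit_range is None:
        fit_range = (0, horizon // 2)
    lo, hi = int(fit_range[0]), int(fit_range[1])
    if not (0 <= lo < hi <= horizon):
        raise ValueError("fit_range must satisfy 0 <= start < end <= horizon")

    n_ref = n - horizon
    spread = float(np.max(np.ptp(data, axis=0)))
    if spread < _EPS:
        # constant trajectory: zero separation everywhere, flag degenerate
        curve = np.full(horizon + 1, np.log(_EPS))
        return LyapunovEstimate(0.0, curve, (lo, hi), 0, degenerate=True)

    tree = cKDTree(data[:n_ref])
    candidates = np.arange(n_ref)
    if n_ref > max_pairs:
        stride = n_ref / max_pairs
        candidates = (np.arange(max_pairs) * stride).astype(np.intp)

    # nearest neighbor with |i - j| > min_separation: query more neighbors
    # until every reference point has an admissible one
    kq = 2
    pairs_i: np.ndarray = candidates
    pairs_j = np.full(candidates.size, -1, dtype=np.intp)
    while True:
        _, nbrs = tree.query(data[candidates], k=min(kq, n_ref))
        sep_ok = np.abs(nbrs - candidates[:, None]) > min_separation
        has = sep_ok.any(axis=1)
        first = np.argmax(sep_ok, axis=1)
        pairs_j = np.where(has, nbrs[np.arange(candidates.size), first], -1)
        if has.all() or kq >= n_ref:
            break
        kq = min(kq * 4, n_ref)
    keep = pairs_j >= 0
    pairs_i, pairs_j = pairs_i[keep], pairs_j[keep]
    if pairs_i.size == 0:
        raise LyapunovEstimationError(
            "no neighbor pairs with the required temporal separation"
        )

    steps = np.arange(horizon + 1)
    ii = pairs_i[:, None] + steps[None, :]
    jj = pairs_j[:, None] + steps[None, :]
    valid = jj < n  # ii < n by construction of n_ref
    jj = np.minimum(jj, n - 1)
    dists = np.linalg.norm(data[ii] - data[jj], axis=-1)
    logs = np.log(np.maximum(dists, _EPS))
    logs[~valid] = np.nan
    curve = np.nanmean(logs, axis=0)

    t = steps[lo:hi].astype(np.float64)
    y = curve[lo:hi]
    ok = np.isfinite(y)
    slope = float(np.polyfit(t[ok], y[ok], 1)[0]) if ok.sum() >= 2 else 0.0
    return LyapunovEstimate(
        lambda_max=slope / traj.dt,
        divergence_curve=curve,
        fit_range=(lo, hi),
        n_pairs=int(pairs_i.size),
        degenerate=False,
    )


def classify_regime(estimate: LyapunovEstimate, tol: float = 0.01) -> str:
    """``"chaotic"`` iff ``lambda_max > tol``; ties go to ``"periodic"``."""
    return "chaotic" if estimate.lambda_max > tol else "periodic"
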