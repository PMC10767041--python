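"""Parameter sweeps, attractor summaries, and tipping-point location.

A sweep integrates (ground truth) or autonomously predicts (trained model)
one trajectory per grid value, summarizes the attractor by the strict
local maxima of a chosen observable after a transient discard, optionally
estimates the largest Lyapunov exponent, and flags collapse/extinction.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from tippingrc.features import Trajectory
from tippingrc.lyapunov import LyapunovEstimationError, rosenstein_lambda_max
from tippingrc.predictor import run_batch
from tippingrc.systems import SystemSpec, simulate_batch
from tippingrc.training import ReadoutModel, TrainingSet, fit_readout

__all__ = [
    "BifurcationSweep",
    "TippingReport",
    "GammaScanResult",
    "attractor_summary",
    "sweep_ground_truth",
    "sweep_model",
    "locate_tipping",
    "gamma_scan",
]

EXTINCT_FLOOR = 1e-6
EXTINCT_TAIL_FRAC = 0.2


def attractor_summary(
    values: np.ndarray, discard_frac: float = 0.5
) -> tuple[np.ndarray, float]:
    """Strict local maxima of an observable after a transient discard.

    Returns ``(maxima, stat)`` where ``stat`` is the mean of the maxima
    (NaN when the summary is empty, e.g. for a collapsed trajectory).
    """
    x = np.asarray(values, dtype=np.float64)
    x = x[int(x.size * discard_frac) :]
    x = x[np.isfinite(x)]
    if x.size < 3:
        return np.empty(0), float("nan")
    mid = x[1:-1]
    peaks = mid[(mid > x[:-2]) & (mid > x[2:])]
    stat = float(peaks.mean()) if peaks.size else float("nan")
    return peaks, stat


@dataclass
class BifurcationSweep:
    """Per-parameter attractor summaries over an increasing grid."""

    thetas: np.ndarray
    maxima: list[np.ndarray]  # per-theta local-maxima sets of the observable
    stat: np.ndarray  # mean of maxima per theta
    lambda_max: np.ndarray  # NaN where not computed or collapsed
    collapsed: np.ndarray
    source: str  # "ground_truth" | "ngrc_model"
    observable: str

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.thetas) > 0):
            raise ValueError("theta grid must be strictly increasing")


@dataclass
class TippingReport:
    """Located transitions on a sweep grid."""

    tipping_theta: float | None  # first collapse-flagged grid value
    jump_theta: float | None  # grid value of maximal statistic discontinuity
    window: tuple[float, float]


def _tail_extinct(values: np.ndarray, floor: float, tail_frac: float) -> bool:
    """True when the observable stays below ``floor`` over the final
    ``tail_frac`` of the finite samples."""
    x = np.asarray(values)
    x = x[np.isfinite(x)]
    if x.size == 0:
        return True
    tail = x[int(x.size * (1.0 - tail_frac)) :]
    return bool((tail < floor).all())


def _lambda_for(
    states: np.ndarray, dt: float, lyapunov_kwargs: dict
) -> float:
    traj = Trajectory(states, dt)
    try:
        est = rosenstein_lambda_max(traj, **lyapunov_kwargs)
    except LyapunovEstimationError:
        return float("nan")
    return float("nan") if est.degenerate else est.lambda_max


def sweep_ground_truth(
    spec: SystemSpec,
    theta_grid: np.ndarray,
    n_steps: int | None = None,
    dt: float | None = None,
    observable: int | None = None,
    discard_frac: float = 0.5,
    compute_lyapunov: bool = False,
    lyapunov_kwargs: dict | None = None,
    extinct_floor: float | None = None,
) -> BifurcationSweep:
    """RK4-integrate every grid value from the printed initial condition.

    ``observable`` is a state-component index; defaults to the spec's
    collapse component (power: V) or the last component (food chain: P).
    ``extinct_floor``, when set, additionally flags grid values whose
    observable stays below the floor over the trailing 20% of samples.
    """
    theta_grid = np.asarray(theta_grid, dtype=np.float64)
    obs = observable
    if obs is None:
        obs = spec.collapse_component if spec.collapse_component is not None else spec.d - 1
    sim = simulate_batch(spec, theta_grid, n_steps=n_steps, dt=dt)
    return _summarize(
        states=sim.states,
        hard_collapsed=sim.collapsed,
        thetas=theta_grid,
        dt=sim.dt,
        obs=obs,
        obs_name=spec.state_names[obs],
        discard_frac=discard_frac,
        compute_lyapunov=compute_lyapunov,
        lyapunov_kwargs=lyapunov_kwargs or {},
        extinct_floor=extinct_floor,
        source="ground_truth",
    )


def sweep_model(
    model: ReadoutModel,
    spec: SystemSpec,
    theta_grid: np.ndarray,
    n_steps: int | None = None,
    observable: int | None = None,
    discard_frac: float = 0.5,
    compute_lyapunov: bool = False,
    lyapunov_kwargs: dict | None = None,
    extinct_floor: float | None = None,
    bound: float = 1e3,
    warmup_transient: int = 200,
) -> BifurcationSweep:
    """Autonomous model prediction per grid value.

    Warm-ups of length ``delta_t`` are generated by RK4 of the ground-truth
    system at each test parameter, starting from the printed initial
    condition and skipping ``warmup_transient`` steps first (handing the
    raw off-attractor transient to the one-step integrator makes it
    diverge even at training parameters). Collapse is flagged on early
    termination (divergence) or, with ``extinct_floor`` set, on a
    permanently sub-floor observable.
    """
    theta_grid = np.asarray(theta_grid, dtype=np.float64)
    obs = observable
    if obs is None:
        obs = spec.collapse_component if spec.collapse_component is not None else spec.d - 1
    n_steps = spec.n_steps if n_steps is None else int(n_steps)
    delta_t = model.cfg.delta_t
    warm = simulate_batch(spec, theta_grid, n_steps=warmup_transient + delta_t - 1)
    if warm.collapsed.any():
        raise ValueError(
            "ground-truth warm-up collapsed inside the sweep window; "
            "reduce warmup_transient"
        )
    pred = run_batch(
        model, warm.states[:, -delta_t:, :], theta_grid, n_steps - delta_t, bound=bound
    )
    return _summarize(
        states=pred.states,
        hard_collapsed=pred.terminated_early,
        thetas=theta_grid,
        dt=model.dt,
        obs=obs,
        obs_name=spec.state_names[obs],
        discard_frac=discard_frac,
        compute_lyapunov=compute_lyapunov,
        lyapunov_kwargs=lyapunov_kwargs or {},
        extinct_floor=extinct_floor,
        source="ngrc_model",
    )


def _summarize(
    states: np.ndarray,
    hard_collapsed: np.ndarray,
    thetas: np.ndarray,
    dt: float,
    obs: int,
    obs_name: str,
    discard_frac: float,
    compute_lyapunov: bool,
    lyapunov_kwargs: dict,
    extinct_floor: float | None,
    source: str,
) -> BifurcationSweep:
    B = thetas.shape[0]
    maxima: list[np.ndarray] = []
    stat = np.full(B, np.nan)
    lam = np.full(B, np.nan)
    collapsed = np.asarray(hard_collapsed, dtype=bool).copy()
    for b in range(B):
        series = states[b, :, obs]
        if extinct_floor is not None and _tail_extinct(
            series, extinct_floor, EXTINCT_TAIL_FRAC
        ):
            collapsed[b] = True
        peaks, st = attractor_summary(series, discard_frac)
        maxima.append(peaks)
        stat[b] = st
        if compute_lyapunov and not collapsed[b]:
            finite = states[b][np.isfinite(states[b]).all(axis=1)]
            lam[b] = _lambda_for(finite, dt, lyapunov_kwargs)
    return BifurcationSweep(
        thetas=thetas,
        maxima=maxima,
        stat=stat,
        lambda_max=lam,
        collapsed=collapsed,
        source=source,
        observable=obs_name,
    )


def locate_tipping(
    sweep: BifurcationSweep, window: tuple[float, float] | None = None
) -> TippingReport:
    """First collapse-flagged grid value and largest statistic jump.

    The jump is reported at the *second* grid value of the consecutive pair
    with the maximal absolute difference of the mean-of-maxima statistic.
    """
    thetas = sweep.thetas
    if window is None:
        window = (float(thetas[0]), float(thetas[-1]))
    lo, hi = window
    mask = (thetas >= lo) & (thetas <= hi)
    if not mask.any():
        raise ValueError("window contains no grid points")
    idx = np.flatnonzero(mask)
    flags = sweep.collapsed[idx]
    tipping = float(thetas[idx[np.argmax(flags)]]) if flags.any() else None

    stat = sweep.stat[idx]
    diffs = np.abs(np.diff(stat))
    jump = None
    if diffs.size and np.isfinite(diffs).any():
        j = int(np.nanargmax(diffs))
        if np.isfinite(diffs[j]) and diffs[j] > 0:
            jump = float(thetas[idx[j + 1]])
    return TippingReport(tipping_theta=tipping, jump_theta=jump, window=(lo, hi))


def locate_lambda_sign_change(
    sweep: BifurcationSweep, tol: float = 0.0
) -> float | None:
    """First grid value where the Lyapunov profile turns non-positive.

    Scans consecutive pairs and returns the second grid value of the first
    pair going from ``lambda > tol`` to a finite ``lambda <= tol``.
    """
    lam = sweep.lambda_max
    for i in range(1, lam.size):
        if (
            np.isfinite(lam[i - 1])
            and np.isfinite(lam[i])
            and lam[i - 1] > tol
            and lam[i] <= tol
        ):
            return float(sweep.thetas[i])
    return None


def locate_reappearance(
    sweep: BifurcationSweep, window: tuple[float, float] | None = None
) -> float | None:
    """Smallest grid value opening the trailing run of non-collapsed points.

    Near a reverse global bifurcation, isolated grid values below the
    boundary can survive the full integration time (long chaotic
    transients), so the boundary is taken as the first grid value after the
    *last* collapse flag rather than the first unflagged value.
    """
    thetas = sweep.thetas
    if window is None:
        window = (float(thetas[0]), float(thetas[-1]))
    mask = (thetas >= window[0]) & (thetas <= window[1])
    if not mask.any():
        raise ValueError("window contains no grid points")
    idx = np.flatnonzero(mask)
    flags = sweep.collapsed[idx]
    if not flags.any():
        return float(thetas[idx[0]])
    last = np.flatnonzero(flags)[-1]
    if last + 1 >= idx.size:
        return None
    return float(thetas[idx[last + 1]])


@dataclass
class GammaScanResult:
    """Per-gamma predicted Lyapunov profiles plus their pointwise envelope."""

    gammas: np.ndarray
    eval_thetas: np.ndarray
    lambda_profiles: np.ndarray  # (n_gamma, n_theta)
    envelope_min: np.ndarray
    envelope_max: np.ndarray
    collapsed: np.ndarray  # (n_gamma, n_theta)


def gamma_scan(
    training: TrainingSet,
    gammas: np.ndarray,
    eval_thetas: np.ndarray,
    spec: SystemSpec,
    n_steps: int | None = None,
    lyapunov_kwargs: dict | None = None,
    bound: float = 1e3,
    warmup_transient: int = 200,
) -> GammaScanResult:
    """Retrain per gamma on identical data and sweep the evaluation grid."""
    gammas = np.atleast_1d(np.asarray(gammas, dtype=np.float64))
    eval_thetas = np.asarray(eval_thetas, dtype=np.float64)
    profiles = np.full((gammas.size, eval_thetas.size), np.nan)
    collapsed = np.zeros((gammas.size, eval_thetas.size), dtype=bool)
    for g, gamma in enumerate(gammas):
        cfg_g = replace(training.cfg, gamma=float(gamma))
        model = fit_readout(TrainingSet(training.samples, cfg_g))
        sweep = sweep_model(
            model,
            spec,
            eval_thetas,
            n_steps=n_steps,
            compute_lyapunov=True,
            lyapunov_kwargs=lyapunov_kwargs,
            bound=bound,
            warmup_transient=warmup_transient,
        )
        profiles[g] = sweep.lambda_max
        collapsed[g] = sweep.collapsed
    return GammaScanResult(
        gammas=gammas,
        eval_thetas=eval_thetas,
        lambda_profiles=profiles,
        envelope_min=np.nanmin(profiles, axis=0),
        envelope_max=np.nanmax(profiles, axis=0),
        collapsed=collapsed,
    )
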