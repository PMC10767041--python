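"""Packaged experiment recipes and the experiment runner.

The two built-in recipes reproduce the shipped testbeds end to end:
generate stationary training trajectories over the training parameter
grid, fit the readout, sweep the model over evaluation windows, and locate
the transitions. Everything is deterministic, so rerunning a recipe into a
clean directory yields byte-identical artifacts.
"""

from __future__ import annotations

import json
import platform
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from tippingrc import io as trc_io
from tippingrc.bifurcation import (
    locate_reappearance,
    locate_tipping,
    sweep_ground_truth,
    sweep_model,
)
from tippingrc.features import FeatureConfig, Trajectory
from tippingrc.systems import SystemSpec, food_chain, power_system, simulate
from tippingrc.training import ReadoutModel, TrainingSet, fit_readout

__all__ = [
    "ExperimentConfig",
    "POWER_RECIPE",
    "FOODCHAIN_RECIPE",
    "RECIPES",
    "get_system",
    "make_training_set",
    "train_recipe",
    "run_experiment",
]

_SYSTEMS = {"power": power_system, "foodchain": food_chain}


def get_system(name: str) -> SystemSpec:
    try:
        return _SYSTEMS[name]()
    except KeyError:
        raise ValueError(
            f"unknown system {name!r}; available: {sorted(_SYSTEMS)}"
        ) from None


@dataclass(frozen=True)
class ExperimentConfig:
    """Declarative description of a train-sweep-report experiment.

    ``transient_skip`` drops that many leading steps of each training
    trajectory before fitting (the raw transient from the printed initial
    condition destabilizes the learned integrator). ``warmup_transient``
    plays the same role for the RK4 warm-ups of prediction sweeps.
    """

    system: str
    train_thetas: tuple[float, ...]
    n_points: int
    cfg: FeatureConfig
    transient_skip: int = 0
    sweep_start: float = 0.0
    sweep_stop: float = 0.0
    sweep_step: float = 0.0
    n_predict: int | None = None
    warmup_transient: int = 200
    lyapunov_horizon: int = 400
    extinct_floor: float | None = None
    compute_lyapunov: bool = False
    gamma_grid: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        get_system(self.system)  # validates the name
        if not self.train_thetas:
            raise ValueError("train_thetas must be non-empty")
        if self.n_points < self.cfg.delta_t + 2:
            raise ValueError("n_points too small for the feature warm-up")
        if self.transient_skip < 0 or self.warmup_transient < 0:
            raise ValueError("transient lengths must be >= 0")
        object.__setattr__(self, "train_thetas", tuple(float(t) for t in self.train_thetas))
        object.__setattr__(self, "gamma_grid", tuple(float(g) for g in self.gamma_grid))

    def theta_grid(self) -> np.ndarray:
        n = int(round((self.sweep_stop - self.sweep_start) / self.sweep_step)) + 1
        return np.round(self.sweep_start + self.sweep_step * np.arange(n), 10)

    def to_dict(self) -> dict:
        d = {
            "system": self.system,
            "train_thetas": list(self.train_thetas),
            "n_points": self.n_points,
            "cfg": self.cfg.to_dict(),
            "transient_skip": self.transient_skip,
            "sweep_start": self.sweep_start,
            "sweep_stop": self.sweep_stop,
            "sweep_step": self.sweep_step,
            "n_predict": self.n_predict,
            "warmup_transient": self.warmup_transient,
            "lyapunov_horizon": self.lyapunov_horizon,
            "extinct_floor": self.extinct_floor,
            "compute_lyapunov": self.compute_lyapunov,
            "gamma_grid": list(self.gamma_grid),
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        d["cfg"] = FeatureConfig.from_dict(d["cfg"])
        d["train_thetas"] = tuple(d["train_thetas"])
        d["gamma_grid"] = tuple(d.get("gamma_grid") or ())
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


# Printed training grids and architectures of the two testbeds. Deviations
# from the published hyperparameters (power beta, transient handling) are
# noted in the README.
POWER_RECIPE = ExperimentConfig(
    system="power",
    train_thetas=(2.98953, 2.98956, 2.98960, 2.98964, 2.98967, 2.98969, 2.98975),
    n_points=10000,
    cfg=FeatureConfig(
        k=2, s=2, poly_orders=(1, 2, 3), post_orders=(0, 1, 2, 3), gamma=0.6, beta=1e-9
    ),
    transient_skip=500,
    sweep_start=2.98978,
    sweep_stop=2.98984,
    sweep_step=1e-6,
    warmup_transient=200,
    lyapunov_horizon=400,
)

FOODCHAIN_RECIPE = ExperimentConfig(
    system="foodchain",
    train_thetas=(0.92, 0.925, 0.93, 0.935, 0.94, 0.945, 0.95),
    n_points=25000,
    cfg=FeatureConfig(
        k=4, s=4, poly_orders=(1, 2), post_orders=(0, 1, 2, 3), gamma=0.4, beta=1e-3
    ),
    transient_skip=0,
    sweep_start=0.99,
    sweep_stop=1.005,
    sweep_step=0.00025,
    warmup_transient=200,
    lyapunov_horizon=600,
    extinct_floor=1e-6,
)

RECIPES = {"paper-power": POWER_RECIPE, "paper-foodchain": FOODCHAIN_RECIPE}


def make_training_set(config: ExperimentConfig) -> TrainingSet:
    """Simulate the stationary training samples of a recipe."""
    spec = get_system(config.system)
    samples = []
    for theta in config.train_thetas:
        traj, collapsed = simulate(
            spec, theta, n_steps=config.transient_skip + config.n_points - 1
        )
        if collapsed:
            raise ValueError(f"training trajectory at theta={theta} collapsed")
        states = traj.states[config.transient_skip :]
        samples.append((Trajectory(states, spec.dt, spec.state_names), theta))
    return TrainingSet(tuple(samples), config.cfg)


def train_recipe(config: ExperimentConfig) -> ReadoutModel:
    return fit_readout(make_training_set(config))


def _sweep_csv(path: Path, sweep) -> None:
    rows = ["theta,lambda_max,collapsed,n_maxima,stat"]
    for i, th in enumerate(sweep.thetas):
        rows.append(
            f"{float(th)!r},{float(sweep.lambda_max[i])!r},{int(sweep.collapsed[i])},"
            f"{len(sweep.maxima[i])},{float(sweep.stat[i])!r}"
        )
    path.write_text("\n".join(rows) + "\n")


def _scatter_csv(path: Path, sweep) -> None:
    rows = ["theta,maximum"]
    for th, peaks in zip(sweep.thetas, sweep.maxima):
        rows.extend(f"{float(th)!r},{float(p)!r}" for p in peaks)
    path.write_text("\n".join(rows) + "\n")


def run_experiment(config: ExperimentConfig, out_dir: str | Path) -> Path:
    """Train, sweep both ground truth and model, and write all artifacts.

    Writes: the resolved config, the trained model, per-theta summary and
    scatter CSVs for both sources, and a tipping report. Returns the
    artifact directory.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t_start = time.time()
    config.to_yaml(out / "config.yaml")

    spec = get_system(config.system)
    model = train_recipe(config)
    trc_io.save_model(out / "model.json", model)

    grid = config.theta_grid()
    lyap = {"horizon": config.lyapunov_horizon}
    truth = sweep_ground_truth(
        spec,
        grid,
        compute_lyapunov=config.compute_lyapunov,
        lyapunov_kwargs=lyap,
        extinct_floor=config.extinct_floor,
    )
    pred = sweep_model(
        model,
        spec,
        grid,
        n_steps=config.n_predict,
        compute_lyapunov=config.compute_lyapunov,
        lyapunov_kwargs=lyap,
        extinct_floor=config.extinct_floor,
        warmup_transient=config.warmup_transient,
    )
    _sweep_csv(out / "sweep_truth.csv", truth)
    _sweep_csv(out / "sweep_model.csv", pred)
    _scatter_csv(out / "scatter_truth.csv", truth)
    _scatter_csv(out / "scatter_model.csv", pred)

    report = {
        "ground_truth": _tipping_dict(truth),
        "ngrc_model": _tipping_dict(pred),
        "manifest": {
            "config_file": "config.yaml",
            "wall_time_s": round(time.time() - t_start, 3),
            "numpy": np.__version__,
            "python": platform.python_version(),
        },
    }
    (out / "tipping_report.json").write_text(json.dumps(report, indent=2) + "\n")
    return out


def _tipping_dict(sweep) -> dict:
    rep = locate_tipping(sweep)
    return {
        "tipping_theta": rep.tipping_theta,
        "jump_theta": rep.jump_theta,
        "reappearance_theta": locate_reappearance(sweep),
        "window": list(rep.window),
    }
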