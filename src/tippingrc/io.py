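"""On-disk formats: trajectory CSV with side-car metadata, model files.

Trajectories are plain CSV (header row of component names, one row per
time step) plus a ``<name>.meta.json`` side-car holding ``dt``, ``d``,
``theta`` and any termination metadata. Models are JSON; floats are stored
via their shortest round-tripping decimal representation, so a
save/load cycle is bit-exact.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from tippingrc.features import FeatureConfig, FeatureOrderingManifest, Trajectory
from tippingrc.training import ReadoutModel

__all__ = [
    "save_trajectory",
    "load_trajectory",
    "save_model",
    "load_model",
    "meta_path",
]


def meta_path(path: str | Path) -> Path:
    p = Path(path)
    return p.with_name(p.name + ".meta.json")


def save_trajectory(
    path: str | Path,
    traj: Trajectory,
    theta: float | None = None,
    extra_meta: dict | None = None,
) -> None:
    """Write a trajectory CSV and its ``.meta.json`` side-car."""
    p = Path(path)
    lines = [",".join(traj.names)]
    lines.extend(",".join(repr(float(v)) for v in row) for row in traj.states)
    p.write_text("\n".join(lines) + "\n")
    meta = {"dt": traj.dt, "d": traj.d, "theta": theta, "names": list(traj.names)}
    if extra_meta:
        meta.update(extra_meta)
    meta_path(p).write_text(json.dumps(meta, indent=2) + "\n")


def load_trajectory(path: str | Path) -> tuple[Trajectory, dict]:
    """Read a trajectory CSV; returns ``(trajectory, metadata)``.

    The side-car is required for ``dt``; a missing side-car raises.
    """
    p = Path(path)
    mp = meta_path(p)
    if not mp.exists():
        raise FileNotFoundError(f"missing side-car metadata file {mp}")
    meta = json.loads(mp.read_text())
    with p.open() as fh:
        names = tuple(fh.readline().strip().split(","))
        states = np.loadtxt(fh, delimiter=",", ndmin=2)
    return Trajectory(states, float(meta["dt"]), names), meta


def save_model(path: str | Path, model: ReadoutModel) -> None:
    """Serialize a trained readout to JSON (bit-exact round-trip)."""
    payload = {
        "w_out": [[repr(float(v)) for v in row] for row in model.w_out],
        "cfg": model.cfg.to_dict(),
        "manifest": model.manifest.to_dict(),
        "d": model.d,
        "dt": repr(float(model.dt)),
        "train_thetas": [repr(float(t)) for t in model.train_thetas],
    }
    Path(path).write_text(json.dumps(payload) + "\n")


def load_model(path: str | Path) -> ReadoutModel:
    payload = json.loads(Path(path).read_text())
    w = np.array([[float(v) for v in row] for row in payload["w_out"]], dtype=np.float64)
    return ReadoutModel(
        w_out=w,
        cfg=FeatureConfig.from_dict(payload["cfg"]),
        manifest=FeatureOrderingManifest.from_dict(payload["manifest"]),
        d=int(payload["d"]),
        dt=float(payload["dt"]),
        train_thetas=tuple(float(t) for t in payload["train_thetas"]),
    )
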