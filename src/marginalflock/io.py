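"""File formats: HDF5 trajectories, XYZ export, TSV curves, flat configs.

Trajectories go to an HDF5 container with ``/params`` (all resolved
model, rule, box and protocol fields as attributes) and ``/samples``
(datasets ``t``, ``positions`` and ``velocities``).  Correlation curves
are delimiter-separated text with a JSON metadata sidecar.  Run
configurations are flat ``key = value`` text files mapping 1:1 onto the
model, neighbour-rule, box and protocol fields.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

import h5py
import numpy as np

from .model import ModelParams
from .observables import CorrelationCurve
from .simulate import (BoxGeometry, HeterogeneitySpec, NeighbourRule, Protocol,
                       Trajectory)

__all__ = [
    "save_trajectory",
    "load_trajectory",
    "export_xyz",
    "write_correlation_curve",
    "read_correlation_curve",
    "read_config",
    "write_config",
    "config_to_objects",
    "CONFIG_KEYS",
]

PathLike = Union[str, Path]


def save_trajectory(traj: Trajectory, path: PathLike) -> None:
    """Write a trajectory container with /params attributes and /samples data."""
    with h5py.File(path, "w") as f:
        p = f.create_group("params")
        for key, val in traj.meta.items():
            p.attrs[key] = val
        s = f.create_group("samples")
        s.create_dataset("t", data=traj.times)
        s.create_dataset("positions", data=traj.positions)
        s.create_dataset("velocities", data=traj.velocities)


def load_trajectory(path: PathLike) -> Trajectory:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"trajectory file not found: {path}")
    try:
        with h5py.File(path, "r") as f:
            meta = {k: _plain(v) for k, v in f["params"].attrs.items()}
            times = f["samples/t"][...]
            pos = f["samples/positions"][...]
            vel = f["samples/velocities"][...]
    except OSError as exc:
        raise ValueError(f"malformed trajectory file {path}: {exc}") from exc
    return Trajectory(times, pos, vel, meta)


def _plain(v):
    if isinstance(v, bytes):
        return v.decode()
    if isinstance(v, np.generic):
        return v.item()
    if isinstance(v, np.ndarray):
        return v.tolist()
    return v


def export_xyz(traj: Trajectory, path: PathLike) -> None:
    """Plain-text XYZ-style export, one frame per sampled state.

    Each frame: an atom-count line, a comment line with the sample time,
    then one ``id x y z vx vy vz`` row per agent.
    """
    n = traj.n_agents
    with open(path, "w") as f:
        for k in range(len(traj)):
            f.write(f"{n}\n")
            f.write(f"t={traj.times[k]:.6f}\n")
            for i in range(n):
                x, y, z = traj.positions[k, i]
                vx, vy, vz = traj.velocities[k, i]
                f.write(f"{i} {x:.8g} {y:.8g} {z:.8g} {vx:.8g} {vy:.8g} {vz:.8g}\n")


def write_correlation_curve(curve: CorrelationCurve, path: PathLike) -> None:
    """TSV with columns (r_lo, r_hi, r_center, C, pairs) plus a JSON sidecar."""
    path = Path(path)
    with open(path, "w") as f:
        f.write("r_lo\tr_hi\tr_center\tC\tpairs\n")
        centers = curve.centers
        for k in range(curve.C.shape[0]):
            f.write(f"{curve.edges[k]:.10g}\t{curve.edges[k + 1]:.10g}\t"
                    f"{centers[k]:.10g}\t{curve.C[k]:.10g}\t{int(curve.counts[k])}\n")
    meta = {"r0": curve.r0, "xi": curve.xi, "frames": curve.frames}
    with open(path.with_suffix(path.suffix + ".meta.json"), "w") as f:
        json.dump(meta, f, indent=2)


def read_correlation_curve(path: PathLike) -> CorrelationCurve:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"correlation curve file not found: {path}")
    data = np.genfromtxt(path, delimiter="\t", names=True)
    data = np.atleast_1d(data)
    edges = np.append(data["r_lo"], data["r_hi"][-1])
    curve = CorrelationCurve(edges, data["C"], data["pairs"].astype(np.int64))
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        curve.r0 = meta.get("r0")
        curve.xi = meta.get("xi")
        curve.frames = meta.get("frames", 1)
    return curve


# configuration keys and their parsers; schema is flat key = value text
CONFIG_KEYS = {
    "control": str, "J": float, "g": float, "lambda": float, "T": float,
    "v0": float, "dt": float,
    "rule": str, "r_c": float, "n_c": int,
    "L1": float, "L2": float, "L3": float,
    "thermalization": int, "production": int, "stride": int, "seed": int,
    "freeze_network": lambda s: s.strip().lower() in ("1", "true", "yes"),
    "het_indices": lambda s: tuple(int(t) for t in s.replace(",", " ").split()),
    "het_v0": float, "het_T": float,
}


def read_config(path: PathLike) -> dict:
    """Parse a flat ``key = value`` configuration file.

    Unknown keys and unparsable values are reported with the offending
    field name; missing files raise FileNotFoundError distinctly.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    cfg: dict = {}
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, val = (t.strip() for t in line.split("=", 1))
        if key not in CONFIG_KEYS:
            raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
        try:
            cfg[key] = CONFIG_KEYS[key](val)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}:{lineno}: bad value for {key!r}: {val!r}") from exc
    return cfg


def write_config(cfg: dict, path: PathLike) -> None:
    with open(path, "w") as f:
        for key, val in cfg.items():
            if key not in CONFIG_KEYS:
                raise ValueError(f"unknown config key {key!r}")
            if key == "het_indices":
                val = " ".join(str(i) for i in val)
            f.write(f"{key} = {val}\n")


def config_to_objects(cfg: dict):
    """Resolve a flat config into (params, rule, box, protocol, het, freeze)."""
    params = ModelParams(
        J=cfg.get("J", 1.0), g=cfg.get("g", 0.0), lam=cfg.get("lambda", 0.0),
        T=cfg.get("T", 0.0), v0=cfg.get("v0", 1.0), dt=cfg.get("dt", 0.01),
        control=cfg.get("control", "marginal"))
    rule = NeighbourRule(kind=cfg.get("rule", "metric"), r_c=cfg.get("r_c", 1.2),
                         n_c=cfg.get("n_c", 6))
    box = BoxGeometry(cfg.get("L1", 8.0), cfg.get("L2", cfg.get("L1", 8.0)),
                      cfg.get("L3", cfg.get("L1", 8.0)))
    protocol = Protocol(thermalization=cfg.get("thermalization", 2000),
                        production=cfg.get("production", 100_000),
                        stride=cfg.get("stride", 100),
                        seed=cfg.get("seed", 0))
    het = None
    if "het_indices" in cfg:
        het = HeterogeneitySpec(indices=cfg["het_indices"], v0=cfg.get("het_v0"),
                                T=cfg.get("het_T"))
    return params, rule, box, protocol, het, cfg.get("freeze_network", False)
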