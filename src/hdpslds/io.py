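"""Readers, writers, configuration and run manifests.

Trajectory CSV dialect: comma-separated, '.' decimal, UTF-8, header row;
columns ``frame, t, psi_x, psi_y[, psi_z][, x, y, z, state]`` with truth
columns optional on read.  Coordinates are physical (um) and the sampling
interval is carried explicitly by the ``t`` column.  Ensembles and chains
go to HDF5; configs to YAML; every pipeline stage can write a manifest
(config snapshot + seeds + file hashes) sufficient to re-run it
bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
import tempfile
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
import h5py
import numpy as np
import pandas as pd
import yaml

from .simulate import DGPConfig, RegionRules, Trajectory
from .dynamics import ContinuousStateParams

_REL_TOL = 1e-6


class SchemaError(ValueError):
    pass


# ---------------------------------------------------------------------------
# trajectory CSV


def write_trajectory_csv(traj: Trajectory, path) -> None:
    n, d_obs = traj.psi.shape
    cols = {"frame": np.arange(n), "t": traj.t}
    for i, name in enumerate(["psi_x", "psi_y", "psi_z"][:d_obs]):
        cols[name] = traj.psi[:, i]
    for i, name in enumerate(["x", "y", "z"]):
        cols[name] = traj.r[:, i]
    cols["state"] = traj.s
    # %.17g keeps every float bit so read-back is value-exact
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.17g")


def read_trajectory_csv(path) -> Trajectory:
    """Read a trajectory; verifies uniform sampling, attaches truth when present."""
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("frame", "t", "psi_x", "psi_y"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    t = df["t"].to_numpy(dtype=float)
    if t.size < 2:
        raise SchemaError(f"{path}: need at least 2 rows")
    dt = t[1] - t[0]
    dev = np.abs(np.diff(t) - dt)
    bad = np.flatnonzero(dev > _REL_TOL * abs(dt))
    if bad.size:
        raise SchemaError(
            f"{path}: non-uniform timestamps at rows {bad[:10] + 1} "
            f"(max deviation {dev.max():g}, dt {dt:g})")
    obs_cols = [c for c in ("psi_x", "psi_y", "psi_z") if c in df.columns]
    psi = df[obs_cols].to_numpy(dtype=float)
    if {"x", "y", "z"}.issubset(df.columns):
        r = df[["x", "y", "z"]].to_numpy(dtype=float)
    else:
        r = np.full((t.size, 3), np.nan)
    s = df["state"].to_numpy(dtype=np.int64) if "state" in df.columns \
        else np.zeros(t.size, dtype=np.int64)
    return Trajectory(t=t, r=r, psi=psi, s=s)


# ---------------------------------------------------------------------------
# ensemble HDF5


def write_ensemble_h5(ensemble, path) -> None:
    with h5py.File(path, "w") as f:
        for k, tr in enumerate(ensemble):
            g = f.create_group(f"traj_{k}")
            g.create_dataset("t", data=tr.t)
            g.create_dataset("r", data=tr.r)
            g.create_dataset("psi", data=tr.psi)
            g.create_dataset("s", data=tr.s)


def read_ensemble_h5(path):
    out = []
    with h5py.File(path, "r") as f:
        keys = sorted(f.keys(), key=lambda k: int(k.split("_")[1]))
        for k in keys:
            g = f[k]
            out.append(Trajectory(t=g["t"][()], r=g["r"][()],
                                  psi=g["psi"][()], s=g["s"][()]))
    return out


# ---------------------------------------------------------------------------
# chain HDF5


def write_chain_h5(chain, path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["dt"] = chain.dt
        f.attrs["n_sweeps"] = chain.n_sweeps
        f.attrs["L"] = chain.cfg.L
        f.create_dataset("modes", data=np.array([s.modes for s in chain.samples],
                                                dtype=np.int16))
        for name in ("beta", "mus", "Fs", "Sigmas", "R", "pi"):
            f.create_dataset(name, data=np.array([getattr(s, name if name != "R"
                                                          else "R") for s in chain.samples]))
        for name in ("gamma", "alpha_plus_kappa", "rho", "joint_loglik"):
            f.create_dataset(name, data=np.array([getattr(s, name)
                                                  for s in chain.samples]))


# ---------------------------------------------------------------------------
# configuration


def dgp_config_to_dict(cfg: DGPConfig) -> dict:
    b = cfg.base
    return {
        "base": {"rbar": b.rbar.tolist(), "B": b.B.tolist(), "C": b.C.tolist(),
                 "kBT": b.kBT, "R": b.R.tolist()},
        "D_alt_factor": cfg.D_alt_factor,
        "B_alt_factor": cfg.B_alt_factor,
        "regions": {"C1": cfg.regions.C1, "C2": cfg.regions.C2,
                    "y_alt": cfg.regions.y_alt,
                    "rbar_alt": cfg.regions.rbar_alt.tolist()},
        "n_obs": cfg.n_obs, "dt": cfg.dt, "n_traj": cfg.n_traj,
        "seed": cfg.seed, "switching_mode": cfg.switching_mode,
    }


def dgp_config_from_dict(d: dict) -> DGPConfig:
    b = d["base"]
    base = ContinuousStateParams(rbar=np.array(b["rbar"]), B=np.array(b["B"]),
                                 C=np.array(b["C"]), kBT=b.get("kBT", 1.0),
                                 R=np.array(b["R"]))
    reg = d.get("regions", {})
    regions = RegionRules(C1=reg.get("C1", -0.3), C2=reg.get("C2", 0.3),
                          y_alt=reg.get("y_alt", -0.3),
                          rbar_alt=np.array(reg.get("rbar_alt", [0.3, 0.0, -0.3])))
    return DGPConfig(base=base, D_alt_factor=d.get("D_alt_factor", 0.1),
                     B_alt_factor=d.get("B_alt_factor", 10.0), regions=regions,
                     n_obs=d["n_obs"], dt=d["dt"], n_traj=d["n_traj"],
                     seed=d.get("seed", 0),
                     switching_mode=d.get("switching_mode", "region"))


def save_config_yaml(d: dict, path) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(d, f, sort_keys=True)


def load_config_yaml(path) -> dict:
    with open(path) as f:
        return yaml.safe_load(f)


# ---------------------------------------------------------------------------
# manifests and atomic output writing


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for block in iter(lambda: f.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()


@dataclass
class RunManifest:
    stage: str
    config: dict
    seeds: dict
    package_version: str = "0.1.0"
    timestamp: str = field(default_factory=lambda: datetime.now(timezone.utc).isoformat())
    inputs: dict = field(default_factory=dict)     # path -> sha256
    outputs: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunManifest":
        return cls(**d)


def _atomic_write(path: Path, writer) -> None:
    """Write via a temp file + rename so partial failures leave nothing behind."""
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    os.close(fd)
    try:
        writer(tmp)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_outputs(report, manifest: RunManifest, out_dir) -> dict:
    """Write a scenario report's tables + the manifest atomically.

    Emits <name>_scores.csv (trajectory_id, hamming, match_score),
    <name>_summary.json, and manifest_<name>.json; returns path map.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if not os.access(out_dir, os.W_OK):
        raise PermissionError(f"output directory {out_dir} is not writable")
    name = report.name.replace("=", "_").replace("/", "_")
    paths = {}

    scores = pd.DataFrame({
        "trajectory_id": np.arange(len(report.results)),
        "hamming": [r.hamming for r in report.results],
        "match_score": [r.match_score for r in report.results],
    })
    p = out_dir / f"{name}_scores.csv"
    _atomic_write(p, lambda tmp: scores.to_csv(tmp, index=False))
    paths["scores"] = p

    summary = dict(report.summary_row())
    summary["cond_matrix"] = np.where(np.isnan(report.cond_matrix), None,
                                      report.cond_matrix).tolist()
    summary["cond_labels"] = report.cond_labels.tolist()
    p = out_dir / f"{name}_summary.json"
    _atomic_write(p, lambda tmp: Path(tmp).write_text(json.dumps(summary, indent=1)))
    paths["summary"] = p

    manifest.outputs = {str(v): file_sha256(v) for v in paths.values()}
    p = out_dir / f"manifest_{name}.json"
    _atomic_write(p, lambda tmp: Path(tmp).write_text(
        json.dumps(manifest.to_dict(), indent=1)))
    paths["manifest"] = p
    return paths
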