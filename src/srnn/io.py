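"""Plain-text serialization: walks, feature sets, network checkpoints.

Walks are single-column CSVs of integer states with a JSON sidecar carrying
geometry, bin size, timestep and seed.  Feature sets are states x features
CSV matrices with a JSON sidecar (p, sigma, s, seed, geometry).  Checkpoints
are a directory of CSVs (J, n, x_prev) plus a JSON config echo.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .envs import Environment, Walk, grid, ring
from .features import FeatureSet
from .model import RNNConfig, RNNState

__all__ = [
    "save_walk",
    "load_walk",
    "save_features",
    "load_features",
    "save_checkpoint",
    "load_checkpoint",
]


def _env_meta(env: Environment) -> dict:
    return {
        "geometry": env.geometry,
        "n_states": env.n_states,
        "shape": list(env.shape) if env.shape else None,
        "bin_size": env.bin_size,
        "dt": env.dt,
    }


def _env_from_meta(meta: dict) -> Environment:
    if meta["geometry"] == "ring":
        return ring(meta["n_states"], meta["bin_size"], meta["dt"])
    h, w = meta["shape"]
    return grid(h, w, meta["bin_size"], meta["dt"])


def save_walk(walk: Walk, path: str | Path) -> None:
    """Write ``<path>.csv`` (states) and ``<path>.json`` (environment/seed)."""
    path = Path(path)
    np.savetxt(path.with_suffix(".csv"), walk.states, fmt="%d", header="state", comments="")
    meta = _env_meta(walk.env) | {"seed": walk.seed}
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def load_walk(path: str | Path) -> Walk:
    path = Path(path)
    states = np.loadtxt(path.with_suffix(".csv"), skiprows=1, dtype=int)
    meta = json.loads(path.with_suffix(".json").read_text())
    return Walk(np.atleast_1d(states), _env_from_meta(meta), meta.get("seed"))


def save_features(fs: FeatureSet, path: str | Path) -> None:
    path = Path(path)
    np.savetxt(path.with_suffix(".csv"), fs.Phi, delimiter=",")
    meta = _env_meta(fs.env) | {
        "p": fs.p,
        "sigma": fs.sigma,
        "s": fs.s,
        "seed": fs.seed,
        "degenerate": fs.degenerate.astype(int).tolist(),
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def load_features(path: str | Path) -> FeatureSet:
    path = Path(path)
    Phi = np.loadtxt(path.with_suffix(".csv"), delimiter=",")
    meta = json.loads(path.with_suffix(".json").read_text())
    return FeatureSet(
        Phi,
        _env_from_meta(meta),
        p=meta["p"],
        sigma=meta["sigma"],
        s=meta["s"],
        seed=meta["seed"],
        degenerate=np.asarray(meta["degenerate"], dtype=bool),
    )


def save_checkpoint(state: RNNState, cfg: RNNConfig, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    np.savetxt(outdir / "J.csv", state.J, delimiter=",")
    np.savetxt(outdir / "n.csv", state.n, delimiter=",")
    np.savetxt(outdir / "x_prev.csv", state.x_prev, delimiter=",")
    (outdir / "meta.json").write_text(json.dumps({"t": state.t, "config": vars(cfg)}, indent=1, default=str))


def load_checkpoint(outdir: str | Path) -> tuple[RNNState, RNNConfig]:
    outdir = Path(outdir)
    meta = json.loads((outdir / "meta.json").read_text())
    cfg_kwargs = {k: v for k, v in meta["config"].items()}
    for key in ("gamma_B", "gamma_R", "lambda_", "eta_static", "tol_tmax", "alpha_n"):
        cfg_kwargs[key] = float(cfg_kwargs[key])
    state = RNNState(
        J=np.atleast_2d(np.loadtxt(outdir / "J.csv", delimiter=",")),
        n=np.atleast_1d(np.loadtxt(outdir / "n.csv", delimiter=",")),
        x_prev=np.atleast_1d(np.loadtxt(outdir / "x_prev.csv", delimiter=",")),
        t=int(meta["t"]),
    )
    return state, RNNConfig(**cfg_kwargs)
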