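"""Serialization of tensors, configurations, traces; run manifests.

Transition models and optimization traces go to HDF5 (sparse matrices
as CSR triplets); macrostate configurations to CSV with one row per
microstate; run manifests to JSON.  Every artifact written by the CLI
embeds the manifest of the run that produced it so results stay
traceable to a configuration and seed.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml
from scipy import sparse

from . import __version__
from .macrostates import MacrostateConfig
from .microstates import Grid, TransitionModel
from .optimizer import IterationRecord, OptimizationTrace

__all__ = [
    "load_yaml_config",
    "make_manifest",
    "save_model",
    "load_model",
    "save_trace",
    "load_trace",
    "config_to_frame",
    "save_config_csv",
    "load_config_csv",
]


def load_yaml_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config file {path} does not contain a mapping")
    return cfg


def make_manifest(config: dict, seed: int | None) -> dict:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return {
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "seed": seed,
        "sensopt_version": __version__,
        "numpy_version": np.__version__,
        "created_unix": time.time(),
    }


def _write_manifest(h5: h5py.File, manifest: dict | None) -> None:
    if manifest is not None:
        h5.attrs["manifest"] = json.dumps(manifest)


def _read_manifest(h5: h5py.File) -> dict | None:
    raw = h5.attrs.get("manifest")
    return json.loads(raw) if raw is not None else None


def _write_csr(g: h5py.Group, mat: sparse.csr_matrix) -> None:
    g.create_dataset("data", data=mat.data)
    g.create_dataset("indices", data=mat.indices)
    g.create_dataset("indptr", data=mat.indptr)
    g.attrs["shape"] = mat.shape


def _read_csr(g: h5py.Group) -> sparse.csr_matrix:
    return sparse.csr_matrix(
        (g["data"][:], g["indices"][:], g["indptr"][:]), shape=tuple(g.attrs["shape"])
    )


def save_model(path, model: TransitionModel, grid: Grid, manifest: dict | None = None) -> None:
    """Write a transition model and its grid to one HDF5 file."""
    with h5py.File(path, "w") as h5:
        _write_manifest(h5, manifest)
        h5.create_dataset("visit_counts", data=model.visit_counts)
        for k, t in enumerate(model.tm):
            _write_csr(h5.create_group(f"tm/{k}"), t)
        g = h5.create_group("grid")
        g.attrs["cell_size"] = grid.cell_size
        g.attrs["x0"] = grid.x0
        g.attrs["y0"] = grid.y0
        g.create_dataset("id_of", data=grid.id_of)
        g.create_dataset("nearest_id", data=grid.nearest_id)


def load_model(path) -> tuple[TransitionModel, Grid, dict | None]:
    with h5py.File(path, "r") as h5:
        manifest = _read_manifest(h5)
        visits = h5["visit_counts"][:]
        tm = [_read_csr(h5[f"tm/{k}"]) for k in sorted(h5["tm"], key=int)]
        g = h5["grid"]
        id_of = g["id_of"][:]
        grid = _rebuild_grid(
            id_of, g["nearest_id"][:], float(g.attrs["cell_size"]),
            float(g.attrs["x0"]), float(g.attrs["y0"]),
        )
    return TransitionModel(tm=tm, visit_counts=visits), grid, manifest


def _rebuild_grid(id_of, nearest_id, cell_size, x0, y0) -> Grid:
    nrows, ncols = id_of.shape
    order = np.argsort(id_of[id_of >= 0], kind="stable")
    rc = np.column_stack(np.nonzero(id_of >= 0))[order]
    centers = np.column_stack(
        [x0 + (rc[:, 1] + 0.5) * cell_size, y0 + (rc[:, 0] + 0.5) * cell_size]
    )
    return Grid(
        cell_size=cell_size, x0=x0, y0=y0, nrows=nrows, ncols=ncols,
        rowcol=rc, centers=centers, id_of=id_of, nearest_id=nearest_id,
    )


def save_trace(path, trace: OptimizationTrace, manifest: dict | None = None) -> None:
    """Write an optimization trace (per-iteration history + best config)."""
    with h5py.File(path, "w") as h5:
        _write_manifest(h5, manifest)
        recs = trace.records
        h5.attrs["best_psi"] = trace.best_psi
        h5.attrs["best_iter"] = trace.best_iter
        h5.create_dataset("best_labels", data=trace.best_config.labels)
        g = h5.create_group("iterations")
        for name in ("n_macro", "mean_pred", "mean_decorr", "mean_self_conn", "mean_psi", "n_ops"):
            g.create_dataset(name, data=np.array([getattr(r, name) for r in recs]))
        g.create_dataset(
            "operation", data=np.array([r.operation for r in recs], dtype="S8")
        )
        # ragged per-state components, concatenated with offsets
        for name in ("pred", "decorr", "self_conn"):
            arrs = [getattr(r, name) for r in recs]
            g.create_dataset(name, data=np.concatenate(arrs) if arrs else np.empty(0))
        g.create_dataset(
            "offsets", data=np.r_[0, np.cumsum([len(r.pred) for r in recs])]
        )


def load_trace(path) -> tuple[OptimizationTrace, dict | None]:
    with h5py.File(path, "r") as h5:
        manifest = _read_manifest(h5)
        g = h5["iterations"]
        off = g["offsets"][:]
        n_iter = len(off) - 1
        cols = {
            name: g[name][:]
            for name in ("n_macro", "mean_pred", "mean_decorr", "mean_self_conn", "mean_psi", "n_ops")
        }
        ops = [o.decode() for o in g["operation"][:]]
        flat = {name: g[name][:] for name in ("pred", "decorr", "self_conn")}
        records = [
            IterationRecord(
                iter_index=i,
                n_macro=int(cols["n_macro"][i]),
                mean_pred=float(cols["mean_pred"][i]),
                mean_decorr=float(cols["mean_decorr"][i]),
                mean_self_conn=float(cols["mean_self_conn"][i]),
                mean_psi=float(cols["mean_psi"][i]),
                operation=ops[i],
                n_ops=int(cols["n_ops"][i]),
                pred=flat["pred"][off[i] : off[i + 1]],
                decorr=flat["decorr"][off[i] : off[i + 1]],
                self_conn=flat["self_conn"][off[i] : off[i + 1]],
            )
            for i in range(n_iter)
        ]
        trace = OptimizationTrace(
            records=records,
            best_config=MacrostateConfig(labels=h5["best_labels"][:]),
            best_psi=float(h5.attrs["best_psi"]),
            best_iter=int(h5.attrs["best_iter"]),
        )
    return trace, manifest


def config_to_frame(config: MacrostateConfig, grid: Grid) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "microstate_id": np.arange(config.n_micro),
            "row": grid.rowcol[:, 0],
            "col": grid.rowcol[:, 1],
            "macrostate_label": config.labels,
        }
    )


def save_config_csv(path, config: MacrostateConfig, grid: Grid, manifest: dict | None = None) -> None:
    config_to_frame(config, grid).to_csv(path, index=False)
    if manifest is not None:
        Path(path).with_suffix(".manifest.json").write_text(json.dumps(manifest, indent=2))


def load_config_csv(path) -> MacrostateConfig:
    frame = pd.read_csv(path)
    return MacrostateConfig(labels=frame["macrostate_label"].to_numpy())
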