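"""Flat-table interchange of airway trees and YAML configuration.

The interchange format is one row per airway with columns
``i, j, parent, D, L, terminal, delta_mu, delta_e, delta_m, phi, gamma``
(parent is the flat row index of the parent airway, -1 for the
trachea), written as CSV or JSON records.  Geometry and species
parameter sets round-trip through plain mappings for YAML configs.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .exchange import SpeciesParams
from .geometry import GeometryParams, LungTree

__all__ = [
    "tree_to_frame",
    "frame_to_tree",
    "save_tree",
    "load_tree",
    "params_to_dict",
    "params_from_dict",
    "load_config",
    "save_config",
]

_COLUMNS = ["i", "j", "parent", "D", "L", "terminal",
            "delta_mu", "delta_e", "delta_m", "phi", "gamma"]


def tree_to_frame(tree: LungTree) -> pd.DataFrame:
    return pd.DataFrame({
        "i": tree.generation,
        "j": tree.index,
        "parent": tree.parent,
        "D": tree.diameter,
        "L": tree.length,
        "terminal": tree.terminal.astype(int),
        "delta_mu": tree.delta_mu,
        "delta_e": tree.delta_e,
        "delta_m": tree.delta_m,
        "phi": tree.phi,
        "gamma": tree.gamma,
    })


def frame_to_tree(
    frame: pd.DataFrame, params: GeometryParams | None = None, seed: int = -1
) -> LungTree:
    """Rebuild a tree from its flat table (children derived from parents)."""
    missing = set(_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"tree table is missing columns: {sorted(missing)}")
    n = len(frame)
    parent = frame["parent"].to_numpy(dtype=np.int64)
    child_minor = np.full(n, -1, dtype=np.int64)
    child_major = np.full(n, -1, dtype=np.int64)
    idx = frame["j"].to_numpy(dtype=np.int64)
    for k in range(n):
        p = parent[k]
        if p >= 0:
            if idx[k] % 2 == 1:
                child_minor[p] = k
            else:
                child_major[p] = k
    tree = LungTree(
        generation=frame["i"].to_numpy(dtype=np.int64),
        index=idx,
        parent=parent,
        child_minor=child_minor,
        child_major=child_major,
        diameter=frame["D"].to_numpy(dtype=float),
        length=frame["L"].to_numpy(dtype=float),
        delta_mu=frame["delta_mu"].to_numpy(dtype=float),
        delta_e=frame["delta_e"].to_numpy(dtype=float),
        delta_m=frame["delta_m"].to_numpy(dtype=float),
        phi=frame["phi"].to_numpy(dtype=float),
        gamma=frame["gamma"].to_numpy(dtype=float),
        params=params or GeometryParams(),
        seed=seed,
    )
    if not np.array_equal(tree.terminal.astype(int), frame["terminal"].to_numpy()):
        raise ValueError("terminal flags inconsistent with parent links")
    return tree


def save_tree(tree: LungTree, path: str | Path) -> None:
    path = Path(path)
    frame = tree_to_frame(tree)
    if path.suffix == ".json":
        frame.to_json(path, orient="records")
    else:
        frame.to_csv(path, index=False)


def load_tree(path: str | Path, params: GeometryParams | None = None) -> LungTree:
    path = Path(path)
    if path.suffix == ".json":
        frame = pd.read_json(path, orient="records")
    else:
        frame = pd.read_csv(path)
    return frame_to_tree(frame, params=params)


def params_to_dict(params) -> dict:
    out = dataclasses.asdict(params)
    return {k: list(v) if isinstance(v, tuple) else v for k, v in out.items()}


def params_from_dict(d: dict, cls=GeometryParams):
    fields = {f.name for f in dataclasses.fields(cls)}
    kwargs = {
        k: tuple(v) if isinstance(v, list) else v
        for k, v in d.items() if k in fields
    }
    return cls(**kwargs)


def load_config(path: str | Path) -> tuple[GeometryParams, SpeciesParams]:
    """YAML config with optional ``geometry`` and ``species`` sections."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    geom = params_from_dict(raw.get("geometry", {}), GeometryParams)
    sp = params_from_dict(raw.get("species", {}), SpeciesParams)
    return geom, sp


def save_config(path: str | Path, geom: GeometryParams, sp: SpeciesParams) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(
            {"geometry": params_to_dict(geom), "species": params_to_dict(sp)}, fh
        )
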