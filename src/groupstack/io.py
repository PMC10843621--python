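"""Reading and writing designs, group maps, and run manifests."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Tuple, Union

import numpy as np
import pandas as pd

from .solvers import GroupedDesign

PathLike = Union[str, Path]


def load_design(data_path: PathLike, group_path: PathLike,
                response: str = "y") -> GroupedDesign:
    """Load a design from a CSV/TSV table and a column -> group map.

    The data file needs a header; ``response`` names the response column
    and all remaining columns are numeric predictors.  The group map is a
    JSON object ``{column: group}`` or two-column whitespace/comma text.
    Predictors must be pre-encoded numerics; missing values are rejected
    with their coordinates.
    """
    data_path = Path(data_path)
    sep = "\t" if data_path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(data_path, sep=sep)
    if df.columns.duplicated().any():
        dups = df.columns[df.columns.duplicated()].tolist()
        raise ValueError(f"duplicate column names: {dups}")
    if response not in df.columns:
        raise ValueError(f"response column {response!r} not found")
    if df.isna().any().any():
        rows, cols = np.nonzero(df.isna().to_numpy())
        coords = [(int(r), df.columns[c]) for r, c in zip(rows[:5], cols[:5])]
        raise ValueError(f"missing values at (row, column): {coords}")
    predictors = [c for c in df.columns if c != response]
    for c in predictors:
        if not np.issubdtype(df[c].dtype, np.number):
            raise ValueError(f"non-numeric predictor column {c!r}")
    gmap = load_group_map(group_path)
    unmapped = [c for c in predictors if c not in gmap]
    if unmapped:
        raise ValueError(f"columns missing from group map: {unmapped}")
    groups = np.array([gmap[c] for c in predictors])
    return GroupedDesign(df[predictors].to_numpy(float),
                         df[response].to_numpy(float), groups,
                         column_names=predictors)


def load_group_map(path: PathLike) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json" or text.lstrip().startswith("{"):
        raw = json.loads(text)
        return {str(k): v for k, v in raw.items()}
    gmap = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.replace(",", " ").split()
        if len(parts) != 2:
            raise ValueError(f"malformed group-map line: {line!r}")
        gmap[parts[0]] = parts[1]
    return gmap


def save_design(design: GroupedDesign, data_path: PathLike,
                group_path: PathLike, response: str = "y") -> None:
    names = design.column_names or [f"x{j + 1}" for j in range(design.p)]
    df = pd.DataFrame(design.X, columns=names)
    df[response] = design.y
    df.to_csv(data_path, index=False)
    gmap = {name: (int(g) if np.issubdtype(np.asarray(g).dtype, np.integer)
                   else str(g))
            for name, g in zip(names, design.groups)}
    Path(group_path).write_text(json.dumps(gmap, indent=1))


def split_train_test(design: GroupedDesign, fraction: float = 0.7,
                     seed: int = 0) -> Tuple[GroupedDesign, GroupedDesign]:
    """Seeded random split into round(fraction * n) training rows + rest."""
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    n = design.n
    n_train = int(round(fraction * n))
    if n_train < 2 or n - n_train < 2:
        raise ValueError("train or test set would have fewer than 2 rows")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return design.subset(np.sort(perm[:n_train])), \
        design.subset(np.sort(perm[n_train:]))


def write_manifest(path: PathLike, **fields) -> None:
    """Record everything needed to reproduce a run (config, seeds, version)."""
    from . import __version__
    doc = {"groupstack_version": __version__, **fields}
    Path(path).write_text(json.dumps(doc, indent=1, default=str))
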