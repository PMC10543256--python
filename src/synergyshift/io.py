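"""Readers and writers for the field's standard text and HDF5 formats.

Supported formats:

* GMT — tab-delimited gene set collections (set id, description,
  members...).
* GCT 1.3 — text expression matrices with optional row/column
  metadata blocks.
* GCTX — HDF5-backed matrices using the common layout
  ``0/DATA/0/matrix`` plus ``0/META/ROW/id`` and ``0/META/COL/id``.
  The matrix is stored as (rows x columns), float64.
* Perturbation metadata — TSV with one row per experiment
  (columns: experiment_id, perturbagen_id, type, target, cell_line,
  dose, time, tas).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd

from .enrichment import GeneSet

logger = logging.getLogger(__name__)

META_COLUMNS = (
    "experiment_id",
    "perturbagen_id",
    "type",
    "target",
    "cell_line",
    "dose",
    "time",
    "tas",
)


# ---------------------------------------------------------------- GMT

def read_gmt(path: str | Path) -> list[GeneSet]:
    sets: list[GeneSet] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: GMT line needs >=3 fields")
            sets.append(GeneSet(parts[0], parts[2:]))
    return sets


def write_gmt(sets: Sequence[GeneSet], path: str | Path, descriptions: dict | None = None) -> None:
    descriptions = descriptions or {}
    with open(path, "w") as fh:
        for gs in sets:
            desc = descriptions.get(gs.set_id, "na")
            fh.write("\t".join([gs.set_id, desc, *gs.members]) + "\n")


# ---------------------------------------------------------------- GCT

def read_gct(path: str | Path) -> pd.DataFrame:
    """Read a GCT 1.2/1.3 file into a genes x samples DataFrame.

    Row/column metadata blocks in 1.3 files are skipped (the data
    matrix and ids are returned).
    """
    with open(path) as fh:
        version = fh.readline().strip()
        if version not in ("#1.2", "#1.3"):
            raise ValueError(f"{path}: not a GCT file (version line {version!r})")
        dims = fh.readline().split()
        if version == "#1.2":
            nrow, ncol = int(dims[0]), int(dims[1])
            nrmeta, ncmeta = 0, 0
        else:
            nrow, ncol, nrmeta, ncmeta = (int(x) for x in dims[:4])
        df = pd.read_csv(fh, sep="\t", index_col=0)
    # drop row-metadata columns and column-metadata rows
    data = df.iloc[ncmeta:, nrmeta:]
    data = data.astype(float)
    if data.shape != (nrow, ncol):
        raise ValueError(
            f"{path}: declared shape ({nrow},{ncol}) != data shape {data.shape}"
        )
    data.index = data.index.astype(str)
    data.index.name = "id"
    return data


def write_gct(df: pd.DataFrame, path: str | Path) -> None:
    """Write a genes x samples DataFrame as GCT 1.3 (no metadata)."""
    with open(path, "w") as fh:
        fh.write("#1.3\n")
        fh.write(f"{df.shape[0]}\t{df.shape[1]}\t0\t0\n")
        out = df.copy()
        out.index.name = "id"
        out.to_csv(fh, sep="\t", float_format="%.10g")


# --------------------------------------------------------------- GCTX

def read_gctx(path: str | Path) -> pd.DataFrame:
    with h5py.File(path, "r") as f:
        matrix = f["0/DATA/0/matrix"][()]
        rows = [r.decode() if isinstance(r, bytes) else str(r) for r in f["0/META/ROW/id"][()]]
        cols = [c.decode() if isinstance(c, bytes) else str(c) for c in f["0/META/COL/id"][()]]
    if matrix.shape != (len(rows), len(cols)):
        raise ValueError(f"{path}: matrix shape {matrix.shape} mismatches ids")
    return pd.DataFrame(matrix, index=rows, columns=cols)


def write_gctx(df: pd.DataFrame, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["version"] = np.bytes_("GCTX1.0")
        # track_times=False keeps reruns byte-identical
        f.create_dataset(
            "0/DATA/0/matrix", data=df.to_numpy(dtype=np.float64), track_times=False
        )
        f.create_dataset(
            "0/META/ROW/id", data=np.array(df.index.astype(str), dtype="S"),
            track_times=False,
        )
        f.create_dataset(
            "0/META/COL/id", data=np.array(df.columns.astype(str), dtype="S"),
            track_times=False,
        )


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Dispatch on extension: .gct, .gctx, else plain TSV (genes x samples)."""
    path = Path(path)
    if path.suffix == ".gct":
        return read_gct(path)
    if path.suffix == ".gctx":
        return read_gctx(path)
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    df.index = df.index.astype(str)
    return df.astype(float)


# ------------------------------------------------------- metadata TSV

def read_perturbation_meta(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype={"experiment_id": str}, comment="#")
    missing = set(META_COLUMNS) - set(meta.columns)
    if missing:
        raise ValueError(f"{path}: metadata TSV lacks columns {sorted(missing)}")
    meta = meta.set_index("experiment_id")
    meta["tas"] = meta["tas"].astype(float)
    return meta


def write_perturbation_meta(meta: pd.DataFrame, path: str | Path) -> None:
    out = meta.reset_index() if meta.index.name == "experiment_id" else meta
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")


# ------------------------------------------------------- ranked lists

def read_rnk(path: str | Path) -> pd.Series:
    """Two-column TSV (gene, score) -> Series (unsorted, caller ranks)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", names=["gene", "score"])
    return pd.Series(df["score"].to_numpy(dtype=float), index=df["gene"].astype(str))


def write_rnk(s: pd.Series, path: str | Path) -> None:
    s.to_csv(path, sep="\t", header=False, float_format="%.10g")
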