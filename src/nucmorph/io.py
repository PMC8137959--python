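"""File-format contracts: NPY masks, cell_shapes.csv, clinical CSV.

The on-disk layout mirrors the source dataset:
``Cells/{patient_id}/{patch_id}/{cell_number}.npy`` for masks (2D
binary arrays, NPY v1.0), ``cell_shapes.csv`` for per-nucleus features
(tuple-valued columns serialized as ``"(x, y)"`` strings), and plain
CSV for the clinical and patient-feature tables.  Cell numbers are not
assumed consecutive.
"""

from __future__ import annotations

import ast
import re
from pathlib import Path
from typing import Iterator, Union

import numpy as np
import pandas as pd

from .morphometry import CELL_SHAPES_COLUMNS, NucleusFeatures


class FormatError(ValueError):
    pass


PathLike = Union[str, Path]


# ---------------------------------------------------------------------------
# masks
# ---------------------------------------------------------------------------


def read_mask(path: PathLike) -> np.ndarray:
    """Load one nucleus mask; validates rank and binary values."""
    path = Path(path)
    try:
        arr = np.load(path, allow_pickle=False)
    except (OSError, ValueError) as e:
        raise FormatError(f"cannot read NPY mask {path}: {e}") from e
    if arr.ndim != 2:
        raise FormatError(f"expected 2-dimensional mask, got {arr.ndim}D: {path}")
    if not np.all(np.isin(np.unique(arr), (0, 1))):
        raise FormatError(f"non-binary mask (values outside {{0,1}}): {path}")
    return arr.astype(np.uint8)


def write_mask(mask: np.ndarray, path: PathLike) -> None:
    """Save one mask as NPY; round-trips bit-exactly via read_mask."""
    arr = np.asarray(mask)
    if arr.ndim != 2:
        raise FormatError(f"expected 2-dimensional mask, got {arr.ndim}D")
    if not np.all(np.isin(np.unique(arr), (0, 1))):
        raise FormatError("non-binary mask")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.save(path, arr.astype(np.uint8))


def iter_cells_dir(cells_dir: PathLike) -> Iterator[tuple[str, str, int, Path]]:
    """Yield (patient_id, patch_id, cell_number, path) from a Cells/ tree.

    Layout: ``Cells/{patient_id}/{patch_id}/{cell_number}.npy``; cell
    numbers may be non-consecutive.  Deterministic (sorted) order.
    """
    root = Path(cells_dir)
    if not root.is_dir():
        raise FormatError(f"Cells directory not found: {root}")
    for pdir in sorted(p for p in root.iterdir() if p.is_dir()):
        for patchdir in sorted(d for d in pdir.iterdir() if d.is_dir()):
            files = []
            for f in patchdir.glob("*.npy"):
                try:
                    files.append((int(f.stem), f))
                except ValueError:
                    raise FormatError(f"non-integer cell number in filename: {f}")
            for cell_no, f in sorted(files):  # numeric, not lexicographic
                yield pdir.name, patchdir.name, cell_no, f


def write_cohort_masks(
    masks: dict[str, list[tuple[str, int, np.ndarray]]], cells_dir: PathLike
) -> int:
    """Write a gen_cohort mask dictionary as a Cells/ tree; returns count."""
    n = 0
    for pid, cells in masks.items():
        for patch_id, cell_no, mask in cells:
            write_mask(mask, Path(cells_dir) / pid / patch_id / f"{cell_no}.npy")
            n += 1
    return n


# ---------------------------------------------------------------------------
# cell_shapes.csv
# ---------------------------------------------------------------------------

_TUPLE_RE = re.compile(r"^\s*\(\s*(-?[\d.eE+]+)\s*,\s*(-?[\d.eE+]+)\s*\)\s*$")


def parse_xy(s: str) -> tuple[float, float]:
    """Parse a ``"(x, y)"`` string (whitespace-tolerant)."""
    m = _TUPLE_RE.match(str(s))
    if not m:
        raise FormatError(f"cannot parse coordinate tuple: {s!r}")
    return float(m.group(1)), float(m.group(2))


def write_cell_shapes(features: list[NucleusFeatures], path: PathLike) -> pd.DataFrame:
    """Write per-nucleus features with the dataset's exact column names."""
    df = pd.DataFrame([f.to_row() for f in features], columns=CELL_SHAPES_COLUMNS)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return df


def read_cell_shapes(path: PathLike) -> pd.DataFrame:
    """Read a cell_shapes.csv; numeric columns coerced, tuples kept as text."""
    df = pd.read_csv(path)
    missing = [c for c in CELL_SHAPES_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"cell_shapes table missing columns: {missing}")
    for col in CELL_SHAPES_COLUMNS:
        if col in ("patient_id", "patch_id", "rectCenter", "rectDimension", "ellip_centroid"):
            continue
        df[col] = pd.to_numeric(df[col])
    return df


# ---------------------------------------------------------------------------
# clinical and patient-feature tables
# ---------------------------------------------------------------------------


def read_clinical(path: PathLike) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"clinical table not found: {path}")
    return pd.read_csv(path)


def write_table(df: pd.DataFrame, path: PathLike) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
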