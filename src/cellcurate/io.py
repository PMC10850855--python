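"""Readers and writers for frame images and cell tables.

Images are single-page TIFFs, one file per frame, ordered by lexicographic
filename. Cell tables come in two dialects:

* CSV with columns ``frame, cell_id, mesh`` where ``mesh`` is a JSON-encoded
  n x 4 array of rows — the canonical, diffable on-disk form;
* a pickled pandas DataFrame with the same columns holding numpy arrays
  (read-only compatibility with notebook-era exports).

Feature tables (frame, cell_id, contour, 26 features, optional label) use the
same two dialects, with the contour JSON-encoded in CSV.
"""

from __future__ import annotations

import json
import logging
import pickle
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .exceptions import FormatError, InputError, ValidationError
from .mesh import CellMesh, CellRecord, Contour

logger = logging.getLogger(__name__)

TIFF_SUFFIXES = (".tif", ".tiff", ".TIF", ".TIFF")


def read_image_frames(directory_path) -> dict[int, np.ndarray]:
    """Load every TIFF in a directory as ``{frame_index: 2-D array}``.

    Frames are indexed 0..k-1 in lexicographic filename order.
    """
    directory = Path(directory_path)
    if not directory.is_dir():
        raise InputError(f"image directory not found: {directory}")
    files = sorted(p for p in directory.iterdir() if p.suffix in TIFF_SUFFIXES)
    if not files:
        raise InputError(f"no TIFF files in {directory}")
    frames: dict[int, np.ndarray] = {}
    for index, path in enumerate(files):
        try:
            image = tifffile.imread(path)
        except Exception as exc:  # noqa: BLE001 - re-raised with the filename
            raise FormatError(f"cannot read TIFF {path.name}: {exc}") from exc
        image = np.asarray(image)
        if image.ndim != 2:
            raise FormatError(f"{path.name}: expected a single 2-D page")
        if not np.all(np.isfinite(image.astype(float))):
            raise FormatError(f"{path.name}: non-finite pixel values")
        frames[index] = image
    return frames


def write_image_frames(frames, directory_path) -> list[Path]:
    """Write frames as zero-padded ``frame_%04d.tif`` files."""
    directory = Path(directory_path)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for index in sorted(frames):
        path = directory / f"frame_{index:04d}.tif"
        tifffile.imwrite(path, frames[index])
        paths.append(path)
    return paths


def _mesh_from_cell(raw, one_based: bool) -> CellMesh:
    arr = np.asarray(raw, dtype=float)
    if one_based:
        arr = arr - 1.0
    return CellMesh(arr)


def _records_from_frame_table(
    df: pd.DataFrame, one_based: bool
) -> tuple[list[CellRecord], int]:
    required = {"frame", "cell_id", "mesh"}
    if not required.issubset(df.columns):
        raise FormatError(
            f"cell table must have columns {sorted(required)}, "
            f"got {list(df.columns)}"
        )
    seen = set()
    records, dropped = [], 0
    for _, row in df.iterrows():
        key = (int(row["frame"]), int(row["cell_id"]))
        if key in seen:
            raise ValidationError(f"duplicate (frame, cell_id) = {key}")
        seen.add(key)
        try:
            mesh = _mesh_from_cell(row["mesh"], one_based)
            records.append(CellRecord(key[0], key[1], mesh))
        except (ValidationError, ValueError) as exc:
            dropped += 1
            logger.warning("dropping record %s: %s", key, exc)
    return records, dropped


def read_cell_table(path, *, one_based: bool = False) -> list[CellRecord]:
    """Read a cell table (CSV or pickled DataFrame) into CellRecords.

    Records whose mesh cannot be parsed or violates the mesh invariants are
    dropped with a logged warning. ``one_based`` shifts coordinates by -1 for
    tables exported from 1-based tools.
    """
    records, _ = read_cell_table_with_report(path, one_based=one_based)
    return records


def read_cell_table_with_report(
    path, *, one_based: bool = False
) -> tuple[list[CellRecord], int]:
    """As :func:`read_cell_table`, also returning the dropped-record count."""
    path = Path(path)
    if not path.is_file():
        raise InputError(f"cell table not found: {path}")
    if path.suffix.lower() == ".csv":
        df = pd.read_csv(path)
        try:
            df["mesh"] = df["mesh"].map(json.loads)
        except (KeyError, TypeError, ValueError) as exc:
            raise FormatError(f"{path.name}: mesh column is not JSON") from exc
    else:
        try:
            df = pd.read_pickle(path)
        except (pickle.UnpicklingError, EOFError, ValueError) as exc:
            raise FormatError(f"unsupported cell-table dialect: {path.name}") from exc
        if not isinstance(df, pd.DataFrame):
            raise FormatError(f"{path.name}: pickle does not hold a DataFrame")
    return _records_from_frame_table(df, one_based)


def write_cell_table(records, path) -> Path:
    """Write CellRecords as CSV (mesh JSON-encoded) or pickle by suffix."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(
        {
            "frame": [r.frame for r in records],
            "cell_id": [r.cell_id for r in records],
            "mesh": [r.mesh.coords for r in records],
        }
    )
    if path.suffix.lower() == ".csv":
        out = df.copy()
        out["mesh"] = out["mesh"].map(lambda m: json.dumps(m.tolist()))
        out.to_csv(path, index=False)
    else:
        df.to_pickle(path)
    return path


def write_feature_table(table: pd.DataFrame, path) -> Path:
    """Write a feature table; CSV gets JSON-encoded contours."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() == ".csv":
        out = table.copy()
        if "contour" in out.columns:
            out["contour"] = out["contour"].map(
                lambda c: json.dumps(np.asarray(c, dtype=float).tolist())
                if c is not None and not (np.isscalar(c) and pd.isna(c))
                else ""
            )
        out.to_csv(path, index=False)
    else:
        table.to_pickle(path)
    return path


def read_feature_table(path) -> pd.DataFrame:
    """Read a feature table written by :func:`write_feature_table`."""
    path = Path(path)
    if not path.is_file():
        raise InputError(f"feature table not found: {path}")
    if path.suffix.lower() == ".csv":
        df = pd.read_csv(path)
        if "contour" in df.columns:
            df["contour"] = df["contour"].map(
                lambda s: np.asarray(json.loads(s), dtype=float)
                if isinstance(s, str) and s
                else None
            )
        return df
    try:
        df = pd.read_pickle(path)
    except (pickle.UnpicklingError, EOFError, ValueError) as exc:
        raise FormatError(f"unsupported feature-table dialect: {path.name}") from exc
    if not isinstance(df, pd.DataFrame):
        raise FormatError(f"{path.name}: pickle does not hold a DataFrame")
    return df


def contour_column(contour: Contour) -> np.ndarray:
    """Canonical array form stored in the feature table's contour column."""
    return np.asarray(contour.vertices, dtype=float)
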