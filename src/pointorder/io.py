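"""Reading and writing centroid tables and metric tables.

Supported inputs are the tabular formats microscopy pipelines commonly
emit after particle detection (e.g. ImageJ centroid exports): comma- or
tab-separated text (``.csv``, ``.tsv``, ``.dat``, ``.txt``) and Excel
spreadsheets (``.xlsx``).  One object per row; the first two numeric
columns are taken as x and y, an optional third numeric column may be
flagged as the object radius.  Header rows are skipped automatically.

Unit handling is done exactly once, here: if ``pixel_size`` is given the
coordinates (and radii) are multiplied into physical units at read time,
and every downstream computation is unit-agnostic.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .pattern import ObservationWindow, PointPattern

__all__ = ["read_pattern", "write_pattern", "write_metrics", "write_manifest"]


def _load_table(path: Path) -> pd.DataFrame:
    suffix = path.suffix.lower()
    if suffix in {".xlsx", ".xls"}:
        return pd.read_excel(path, header=None)
    if not path.read_text().strip():
        raise ValueError(f"{path}: no points")
    # Delimited text: sniff the separator among comma / tab / whitespace.
    # Cells stay strings here; _numeric_columns converts them with
    # Python's correctly rounded float() so coordinates round-trip exactly.
    return pd.read_csv(
        path, header=None, sep=None, engine="python", comment="#", dtype=str
    )


def _cell_to_float(value):
    try:
        return float(value)
    except (TypeError, ValueError):
        return np.nan


def _numeric_columns(table: pd.DataFrame) -> pd.DataFrame:
    """Coerce to numeric, dropping header rows and non-numeric columns."""
    num = table.apply(lambda col: col.map(_cell_to_float))
    # rows that are entirely NaN were headers or blank lines
    num = num.dropna(how="all")
    # keep columns that are numeric on every remaining row
    keep = [c for c in num.columns if num[c].notna().all()]
    return num[keep]


def read_pattern(
    path: str | Path,
    window: ObservationWindow | None = None,
    pixel_size: float | None = None,
    *,
    radius_column: bool = False,
    image_convention: bool = False,
    label: str | None = None,
    unit: str | None = None,
) -> PointPattern:
    """Read a centroid table into a :class:`PointPattern`.

    Parameters
    ----------
    path
        Delimited text or spreadsheet file, one object per row.
    window
        Explicit observation window (in final units, i.e. after the
        ``pixel_size`` conversion).  If omitted, the tight bounding box
        of the points is used.
    pixel_size
        If given, coordinates are multiplied by this factor (length per
        pixel) to convert pixel coordinates into physical units.
    radius_column
        Treat the third numeric column as a per-object radius.
    image_convention
        Input uses image coordinates (y increasing downward).  The y
        axis is flipped at read time so the in-memory pattern always has
        y increasing upward.
    label, unit
        Metadata carried on the returned pattern.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        table = _load_table(path)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: no points") from None
    num = _numeric_columns(table)
    if num.shape[0] == 0:
        raise ValueError(f"{path}: no points")
    if num.shape[1] < 2:
        raise ValueError(f"{path}: need at least two numeric columns (x, y)")
    cols = list(num.columns)
    xy = num[cols[:2]].to_numpy(dtype=float)
    radii = None
    if radius_column:
        if num.shape[1] < 3:
            raise ValueError(f"{path}: radius column requested but absent")
        radii = num[cols[2]].to_numpy(dtype=float)

    if image_convention:
        xy = xy.copy()
        xy[:, 1] = -xy[:, 1]
    if pixel_size is not None:
        xy = xy * float(pixel_size)
        if radii is not None:
            radii = radii * float(pixel_size)
    if window is None:
        window = ObservationWindow.bounding(xy)
    return PointPattern(
        xy,
        window,
        pixel_size=pixel_size,
        radii=radii,
        label=label if label is not None else path.stem,
        unit=unit if unit is not None else ("px" if pixel_size is None else "length"),
    )


def write_pattern(pattern: PointPattern, path: str | Path) -> None:
    """Write a pattern as a two- (or three-) column CSV readable by
    :func:`read_pattern`."""
    path = Path(path)
    cols = {"x": pattern.points[:, 0], "y": pattern.points[:, 1]}
    if pattern.radii is not None:
        cols["radius"] = pattern.radii
    # %.17g guarantees binary round-trip of float64 coordinates
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.17g")


def write_metrics(records: Sequence[Mapping[str, Any]], path: str | Path) -> None:
    """Write keyed records as a comma-separated table with a header row.

    An empty record list yields a header-only file (the schema cannot be
    inferred, so the header is empty).  Values round-trip through
    :func:`pandas.read_csv` at full repr precision.
    """
    path = Path(path)
    df = pd.DataFrame(list(records))
    df.to_csv(path, index=False)


def write_manifest(manifest: Mapping[str, Any], path: str | Path) -> None:
    """Write the JSON run manifest (window, unit, seed, parameters)."""

    def _default(obj):
        if isinstance(obj, ObservationWindow):
            return obj.as_dict()
        if isinstance(obj, np.generic):
            return obj.item()
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        raise TypeError(f"not JSON serializable: {type(obj)}")

    Path(path).write_text(json.dumps(dict(manifest), indent=2, default=_default) + "\n")
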