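"""Read/write segmented-cell tables (CSV/TSV), incl. the QuPath dialect.

Two column dialects are supported:

``generic``
    ``cell_id, x, y`` plus one column per marker named after the marker;
    any extra columns are preserved as passthrough metadata.
``qupath``
    The QuPath measurement-export layout: ``Object ID``,
    ``Centroid X µm`` / ``Centroid Y µm`` (both the micro sign and the
    ASCII ``um`` spelling are accepted) and per-marker mean-intensity
    columns such as ``CD3: Cell: Mean``.

Internal units are μm; a ``scale`` factor converts pixel-based exports.
UTF-8 with BOM is tolerated, and the delimiter is sniffed from the header
unless given explicitly.
"""

from __future__ import annotations

import re
import warnings
from pathlib import Path

import pandas as pd

from .cells import MARKERS, CellTable

_QUPATH_ID = "Object ID"
_QUPATH_X = "Centroid X µm"
_QUPATH_Y = "Centroid Y µm"
_QUPATH_MARKER_FMT = "{marker}: Cell: Mean"

# micro sign (µ, U+00B5), Greek mu (μ, U+03BC) and plain "um" all match
_MICRON_RE = r"(?:µm|μm|um)"


def _sniff_sep(path: Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    if path.suffix.lower() in {".tsv", ".txt"}:
        return "\t"
    with open(path, encoding="utf-8-sig") as fh:
        header = fh.readline()
    return "\t" if header.count("\t") > header.count(",") else ","


def _find_column(columns: list[str], canonical: str, kind: str) -> str:
    """Locate a QuPath coordinate column, tolerating micro-sign variants."""
    axis = "X" if "X" in canonical else "Y"
    pat = re.compile(rf"^Centroid {axis} {_MICRON_RE}$")
    for c in columns:
        if pat.match(c.strip()):
            return c
    raise ValueError(f"missing {kind} column {canonical!r} in header {columns}")


def read_cell_table(
    path: str | Path,
    dialect: str = "generic",
    marker_map: dict[str, str] | None = None,
    case_id: str = "case",
    group: str = "",
    sep: str | None = None,
    scale: float = 1.0,
) -> CellTable:
    """Load a segmented-cell table into the canonical :class:`CellTable`.

    ``marker_map`` maps file columns to marker names; if omitted, marker
    columns are auto-detected (bare marker names in the generic dialect,
    ``<marker>: Cell: Mean`` in the QuPath dialect). Row order is
    preserved and unknown columns ride along as passthrough metadata.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=_sniff_sep(path, sep), encoding="utf-8-sig")
    df.columns = [str(c).strip() for c in df.columns]

    if dialect == "generic":
        for col in ("x", "y"):
            if col not in df.columns:
                raise ValueError(f"missing coordinate column {col!r} in {path.name}")
        id_col, x_col, y_col = "cell_id", "x", "y"
        if id_col not in df.columns:
            raise ValueError(f"missing id column 'cell_id' in {path.name}")
        if marker_map is None:
            marker_map = {m: m for m in MARKERS if m in df.columns}
    elif dialect == "qupath":
        x_col = _find_column(list(df.columns), _QUPATH_X, "coordinate")
        y_col = _find_column(list(df.columns), _QUPATH_Y, "coordinate")
        id_col = _QUPATH_ID if _QUPATH_ID in df.columns else None
        if marker_map is None:
            marker_map = {}
            for m in MARKERS:
                col = _QUPATH_MARKER_FMT.format(marker=m)
                if col in df.columns:
                    marker_map[col] = m
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    missing = [c for c in marker_map if c not in df.columns]
    if missing:
        raise ValueError(f"marker columns not found: {missing}")

    out = pd.DataFrame()
    if id_col is not None:
        out["cell_id"] = df[id_col]
    else:
        out["cell_id"] = range(len(df))
    for target, source in (("x", x_col), ("y", y_col)):
        coords = pd.to_numeric(df[source], errors="coerce")
        bad = coords.index[coords.isna() & df[source].notna()]
        if len(bad):
            raise ValueError(f"non-numeric coordinate in column {source!r}, row {bad[0]}")
        out[target] = coords * scale
    markers = []
    for col, marker in marker_map.items():
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.index[vals.isna() & df[col].notna()]
        if len(bad):
            raise ValueError(
                f"non-numeric intensity in column {col!r} (marker {marker}), row {bad[0]}"
            )
        out[marker] = vals
        markers.append(marker)

    consumed = {x_col, y_col, *marker_map} | ({id_col} if id_col else set())
    for col in df.columns:
        if col not in consumed:
            out[col] = df[col]
    if len(out) == 0:
        warnings.warn(f"{path.name}: header-only file, empty cell table")
    return CellTable(data=out, markers=tuple(markers), case_id=case_id, group=group)


def write_cell_table(
    table: CellTable, path: str | Path, dialect: str = "generic", sep: str | None = None
) -> Path:
    """Write a cell table; ``read_cell_table`` round-trips it.

    Functional flags and ground-truth columns are ordinary 0/1 / label
    columns and survive the round trip untouched.
    """
    path = Path(path)
    sep = sep or ("\t" if path.suffix.lower() in {".tsv", ".txt"} else ",")
    df = table.data.copy()
    if dialect == "qupath":
        rename = {"cell_id": _QUPATH_ID, "x": _QUPATH_X, "y": _QUPATH_Y}
        rename.update({m: _QUPATH_MARKER_FMT.format(marker=m) for m in table.markers})
        df = df.rename(columns=rename)
    elif dialect != "generic":
        raise ValueError(f"unknown dialect {dialect!r}")
    df.to_csv(path, sep=sep, index=False)
    return path
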