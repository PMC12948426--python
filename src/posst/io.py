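"""Readers and writers for Visium spot positions, scalefactors and
per-spot annotation tables.

Handles both on-disk dialects of the spaceranger positions file:
``tissue_positions_list.csv`` (v1, headerless) and ``tissue_positions.csv``
(v2, with header).  Annotation tables map barcodes to categorical labels
(histology, niche) and numeric value columns (deconvolved abundances,
signature scores).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .lattice import SpotLattice

__all__ = [
    "SlideBundle",
    "FormatError",
    "read_tissue_positions",
    "write_tissue_positions",
    "read_scalefactors",
    "read_annotations",
    "write_table",
]

logger = logging.getLogger(__name__)

#: Nominal Visium spot diameter in μm, used to convert the fullres
#: spot-diameter scalefactor into pixels per μm.
SPOT_DIAMETER_UM = 55.0

V1_COLUMNS = [
    "barcode",
    "in_tissue",
    "array_row",
    "array_col",
    "pxl_row_in_fullres",
    "pxl_col_in_fullres",
]


class FormatError(ValueError):
    """Malformed input file (wrong column count, bad header, bad JSON)."""


@dataclass
class SlideBundle:
    """One slide's lattice plus physical calibration and provenance."""

    slide_id: str
    spots: SpotLattice
    spacing_um: float = 100.0
    source_dialect: str = "synthetic"

    def __post_init__(self) -> None:
        if self.spacing_um <= 0:
            raise ValueError("spacing_um must be positive")


def _detect_dialect(path: Path) -> str:
    with open(path) as fh:
        first = fh.readline()
    return "v2" if "barcode" in first.lower() else "v1"


def read_tissue_positions(
    path: str | Path,
    dialect: str = "auto",
    in_tissue_only: bool = True,
) -> SpotLattice:
    """Parse a spaceranger tissue-positions file into a :class:`SpotLattice`.

    Parameters
    ----------
    path
        ``tissue_positions_list.csv`` (v1, headerless) or
        ``tissue_positions.csv`` (v2, with header).
    dialect
        ``"auto"`` selects v2 when the first line contains the token
        ``barcode``, else v1; or force ``"v1"``/``"v2"``.
    in_tissue_only
        Drop spots with ``in_tissue == 0`` (the default, matching how the
        files are consumed in practice).

    Notes
    -----
    Physical coordinates are stored with ``x = pxl_col_in_fullres`` and
    ``y = pxl_row_in_fullres`` so that (x, y) is a conventional right-handed
    image coordinate pair.  Array coordinates are kept 0-based as emitted.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "auto":
        dialect = _detect_dialect(path)
    if dialect not in ("v1", "v2"):
        raise ValueError(f"unknown dialect {dialect!r}")

    header = 0 if dialect == "v2" else None
    try:
        raw = pd.read_csv(path, header=header, dtype={0: str})
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: {exc}") from exc

    if dialect == "v1":
        if raw.shape[1] != 6:
            raise FormatError(
                f"{path}: v1 positions file must have 6 columns, found {raw.shape[1]}"
            )
        raw.columns = V1_COLUMNS
    else:
        raw.columns = [c.strip().lower() for c in raw.columns]
        missing = [c for c in V1_COLUMNS if c not in raw.columns]
        if missing:
            raise FormatError(f"{path}: missing columns {missing}")

    bad = raw[V1_COLUMNS[1:]].isna().any(axis=1)
    if bad.any():
        line0 = int(np.flatnonzero(bad.to_numpy())[0]) + 1 + (dialect == "v2")
        raise FormatError(f"{path}: unparseable row at line {line0 + 1}")

    raw["barcode"] = raw["barcode"].astype(str)
    if raw["barcode"].duplicated().any():
        dups = raw.loc[raw["barcode"].duplicated(), "barcode"].unique().tolist()
        raise ValueError(f"{path}: duplicate barcodes {dups}")

    if in_tissue_only:
        raw = raw[raw["in_tissue"].astype(int) == 1]

    spots = pd.DataFrame(
        {
            "array_row": raw["array_row"].astype(int).to_numpy(),
            "array_col": raw["array_col"].astype(int).to_numpy(),
            "x": raw["pxl_col_in_fullres"].astype(float).to_numpy(),
            "y": raw["pxl_row_in_fullres"].astype(float).to_numpy(),
        },
        index=pd.Index(raw["barcode"], name="barcode"),
    )
    return SpotLattice(spots)


def write_tissue_positions(
    lattice: SpotLattice,
    path: str | Path,
    dialect: str = "v2",
    in_tissue: int = 1,
) -> None:
    """Write a lattice back out in either positions-file dialect."""
    out = pd.DataFrame(
        {
            "barcode": lattice.barcodes,
            "in_tissue": in_tissue,
            "array_row": lattice.spots["array_row"].to_numpy(),
            "array_col": lattice.spots["array_col"].to_numpy(),
            "pxl_row_in_fullres": lattice.spots["y"].to_numpy(),
            "pxl_col_in_fullres": lattice.spots["x"].to_numpy(),
        }
    )
    if dialect == "v2":
        out.to_csv(path, index=False)
    elif dialect == "v1":
        out.to_csv(path, index=False, header=False)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_scalefactors(path: str | Path) -> dict:
    """Read ``scalefactors_json.json`` and derive a pixel→μm conversion.

    Returns the parsed mapping with an added key ``pixels_per_um``, computed
    as ``spot_diameter_fullres / 55`` (the nominal 55 μm Visium spot
    diameter).  Callers without scalefactors fall back to normalized units.
    """
    path = Path(path)
    try:
        with open(path) as fh:
            factors = json.load(fh)
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: invalid JSON ({exc})") from exc
    missing = [k for k in ("spot_diameter_fullres",) if k not in factors]
    if missing:
        raise FormatError(f"{path}: missing required keys {missing}")
    factors = dict(factors)
    factors["pixels_per_um"] = float(factors["spot_diameter_fullres"]) / SPOT_DIAMETER_UM
    return factors


@dataclass
class AnnotationTable:
    """Per-spot annotations keyed by barcode.

    ``dropped_rows`` records (row index, column) pairs removed under the
    missing-value policy so that nothing disappears silently.
    """

    table: pd.DataFrame
    label_columns: list[str] = field(default_factory=list)
    value_columns: list[str] = field(default_factory=list)
    dropped_rows: list[tuple[int, str]] = field(default_factory=list)

    def unmatched_barcodes(self, lattice: SpotLattice) -> list[str]:
        """Annotation barcodes absent from the lattice (reported, not dropped)."""
        return [b for b in self.table.index if b not in lattice.spots.index]

    def attach(self, lattice: SpotLattice, warn_unmatched: bool = True) -> SpotLattice:
        """Join annotations onto the lattice, warning about orphan barcodes."""
        orphans = self.unmatched_barcodes(lattice)
        if orphans and warn_unmatched:
            warnings.warn(
                f"{len(orphans)} annotation barcodes not in lattice "
                f"(e.g. {orphans[:3]})",
                stacklevel=2,
            )
        return lattice.with_columns(self.table, self.label_columns, self.value_columns)


def read_annotations(
    path: str | Path,
    label_columns: list[str] | None = None,
    value_columns: list[str] | None = None,
    barcode_column: str = "barcode",
    missing_policy: str = "drop",
) -> AnnotationTable:
    """Read a per-spot annotation CSV/TSV.

    Parameters
    ----------
    path
        Delimited table with a mandatory barcode column; the separator is
        sniffed from the extension (``.tsv``/``.txt`` → tab, else comma).
    label_columns, value_columns
        Which columns to treat as categorical labels vs numeric values.
        Defaults: all non-barcode columns are labels.
    missing_policy
        ``"drop"`` removes a row from value analyses when a declared numeric
        column is missing (recorded in ``dropped_rows``); ``"zero"``
        substitutes 0.  Label entries are retained either way.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    table = pd.read_csv(path, sep=sep, dtype={barcode_column: str})
    if barcode_column not in table.columns:
        raise FormatError(
            f"{path}: barcode column {barcode_column!r} not found "
            f"(columns: {list(table.columns)})"
        )
    table = table.set_index(barcode_column)
    table.index.name = "barcode"

    if label_columns is None and value_columns is None:
        label_columns = list(table.columns)
    label_columns = list(label_columns or [])
    value_columns = list(value_columns or [])
    for col in label_columns + value_columns:
        if col not in table.columns:
            raise FormatError(f"{path}: declared column {col!r} not in table")

    for col in label_columns:
        table[col] = table[col].astype("string").str.strip()

    dropped: list[tuple[int, str]] = []
    if missing_policy not in ("drop", "zero"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    for col in value_columns:
        numeric = pd.to_numeric(table[col], errors="coerce")
        bad = numeric.isna() & table[col].notna()
        # Values present but non-numeric are a validation error, not a
        # missing-data case.
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"{path}: non-numeric value {table[col].iloc[row]!r} in declared "
                f"numeric column {col!r} at row {row}"
            )
        if numeric.isna().any():
            rows = np.flatnonzero(numeric.isna().to_numpy())
            if missing_policy == "zero":
                numeric = numeric.fillna(0.0)
            dropped.extend((int(r), col) for r in rows)
            logger.info(
                "%s: %d missing values in %r handled by policy %r",
                path, len(rows), col, missing_policy,
            )
        if np.isinf(numeric.dropna().to_numpy(dtype=float)).any():
            raise ValueError(f"{path}: non-finite value in numeric column {col!r}")
        table[col] = numeric
    return AnnotationTable(table, label_columns, value_columns, dropped)


def write_table(df: pd.DataFrame, path: str | Path, index: bool = True) -> None:
    """Write any module output as TSV with a stable column order."""
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")
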