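"""Reading and writing screen tables and microplate maps.

On-disk formats are plain delimited text (TSV by default, comma
selectable). The long (tidy) measurement table is the canonical
representation; plate-shaped grids are an import convenience converted
immediately to long format. Well coordinates are 1-based (A1 = row A,
column 1).

Numeric round-trip: tables are written with pandas' shortest-repr float
formatting, so write → read reproduces every float value bit-exactly.
"""

from __future__ import annotations

import string
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import FormatError, IntegrityError, LayoutError, ValidationError
from .screen import (
    CATEGORIES,
    MEASUREMENT_COLUMNS,
    RECORD_COLUMNS,
    ScreenDataset,
    make_library,
)

__all__ = [
    "read_measurements",
    "read_measurement_tables",
    "write_measurements",
    "read_library",
    "write_library",
    "read_binder_set",
    "write_binder_set",
    "read_records",
    "write_records",
    "read_plate_map",
    "write_plate_map",
    "map_well",
    "invert_well",
    "map_plates",
]

_ROWS_96 = string.ascii_uppercase[:8]
_ROWS_384 = string.ascii_uppercase[:16]


# ---------------------------------------------------------------------------
# measurement tables


def _parse_measurement_frame(raw: pd.DataFrame, path) -> pd.DataFrame:
    missing = set(MEASUREMENT_COLUMNS) - set(raw.columns)
    if missing:
        raise FormatError(
            f"{path}: missing mandatory column(s) {sorted(missing)}"
        )
    df = raw.copy()
    # +2: header line plus 1-based numbering
    lines = np.arange(len(df)) + 2
    rep = pd.to_numeric(df["replicate"], errors="coerce")
    bad = rep.isna() | (rep != rep.round())
    if bad.any():
        raise ValidationError(
            f"{path}: non-integer replicate at line {lines[bad.to_numpy()][0]}"
        )
    df["replicate"] = rep.astype(int)
    for col in ("luciferase_rlu", "elisa_rlu"):
        check = pd.to_numeric(df[col], errors="coerce")
        bad = check.isna()
        if bad.any():
            raise ValidationError(
                f"{path}: non-numeric {col} at line {lines[bad.to_numpy()][0]}"
            )
        neg = check < 0
        if neg.any():
            raise ValidationError(
                f"{path}: negative {col} at line {lines[neg.to_numpy()][0]}"
            )
        # astype(float) is exact for round-trip decimal text; to_numeric is not
        df[col] = df[col].astype(float)
    keys = df[["rna_id", "protein_id", "replicate"]]
    if keys.duplicated().any():
        dup = tuple(keys[keys.duplicated()].iloc[0])
        raise IntegrityError(f"{path}: duplicate (rna, protein, replicate) key {dup}")
    return df


def _stub_library(protein_ids: Iterable[str]) -> pd.DataFrame:
    ids = sorted(set(protein_ids))
    return make_library(
        pd.DataFrame(
            {
                "protein_id": ids,
                "symbol": ids,
                "category": "CONTROL",
                "pfam_domains": "",
            }
        )
    )


def read_measurement_tables(
    path, *, sep: str = "\t", library: pd.DataFrame | None = None
) -> dict[str, ScreenDataset]:
    """Read a measurement file and assemble one dataset per rna_id.

    Assembly is permutation-invariant in the input row order. When no
    library is supplied, a stub annotation (category CONTROL, no
    domains) is synthesized from the protein ids present.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        raw = pd.read_csv(path, sep=sep, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file") from exc
    df = _parse_measurement_frame(raw, path)
    lib = library if library is not None else _stub_library(df["protein_id"])
    return {
        str(rna): ScreenDataset(rna_id=str(rna), measurements=sub.reset_index(drop=True), library=lib)
        for rna, sub in df.groupby("rna_id", sort=True)
    }


def read_measurements(
    path, *, sep: str = "\t", library: pd.DataFrame | None = None
) -> ScreenDataset:
    """Read a single-RNA measurement table into a :class:`ScreenDataset`."""
    datasets = read_measurement_tables(path, sep=sep, library=library)
    if len(datasets) != 1:
        raise FormatError(
            f"{path}: expected a single rna_id, found {sorted(datasets)}"
        )
    return next(iter(datasets.values()))


def write_measurements(data, path, *, sep: str = "\t") -> None:
    """Write a ScreenDataset (or raw long-format frame) as delimited text."""
    df = data.measurements if isinstance(data, ScreenDataset) else data
    cols = [c for c in df.columns if c in MEASUREMENT_COLUMNS + ("plate_id", "well")]
    df[cols].to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# library / annotation tables


def read_library(path, *, sep: str = "\t") -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep=sep, dtype=str).fillna({"pfam_domains": ""})
    return make_library(df)


def write_library(library: pd.DataFrame, path, *, sep: str = "\t") -> None:
    out = library.copy()
    out["pfam_domains"] = out["pfam_domains"].map(lambda s: ";".join(sorted(s)))
    out.to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# common-binder sets (one protein_id per line, order = descending rank)


def write_binder_set(members: Sequence[str], path) -> None:
    Path(path).write_text("".join(f"{m}\n" for m in members))


def read_binder_set(path) -> tuple[str, ...]:
    return tuple(
        line.strip() for line in Path(path).read_text().splitlines() if line.strip()
    )


# ---------------------------------------------------------------------------
# record (status) tables


def write_records(records: pd.DataFrame, path, *, sep: str = "\t") -> None:
    cols = [c for c in RECORD_COLUMNS if c in records.columns]
    records[cols].to_csv(path, sep=sep, index=False)


def read_records(path, *, sep: str = "\t") -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep)
    if "is_interactor" in df.columns:
        col = df["is_interactor"]
        if col.dtype == object:  # bools or "True"/"False" strings, blanks for NA
            col = col.map(
                lambda v: {"True": True, "False": False}.get(v, v)
                if isinstance(v, str)
                else v
            )
        df["is_interactor"] = col.astype("boolean")
    return df


# ---------------------------------------------------------------------------
# 96 -> 384 well plate maps


def _parse_well(well: str | tuple[str, int]) -> tuple[str, int]:
    if isinstance(well, tuple):
        return well[0].upper(), int(well[1])
    well = well.strip()
    return well[0].upper(), int(well[1:])


def map_well(
    plate: int, well: str | tuple[str, int], scheme: str = "interleaved"
) -> tuple[str, int]:
    """Map a well of source 96-plate ``plate`` (1-4) to its 384-well position.

    ``interleaved``: plate k occupies every other row/column with row
    offset (k-1)//2 and column offset (k-1)%2 — the common automated
    quadrant-stamping pattern. ``block``: plate k fills one contiguous
    384-well quadrant.
    """
    if plate not in (1, 2, 3, 4):
        raise LayoutError(f"source plate must be 1-4, got {plate}")
    row, col = _parse_well(well)
    r = _ROWS_96.index(row)
    c = col - 1
    if not (0 <= r < 8 and 0 <= c < 12):
        raise LayoutError(f"invalid 96-well position {row}{col}")
    if scheme == "interleaved":
        r384 = 2 * r + (plate - 1) // 2
        c384 = 2 * c + (plate - 1) % 2
    elif scheme == "block":
        r384 = r + 8 * ((plate - 1) // 2)
        c384 = c + 12 * ((plate - 1) % 2)
    else:
        raise LayoutError(f"unknown quadrant scheme {scheme!r}")
    return _ROWS_384[r384], c384 + 1


def invert_well(
    well: str | tuple[str, int], scheme: str = "interleaved"
) -> tuple[int, tuple[str, int]]:
    """Inverse of :func:`map_well`: 384-well position -> (plate, 96-well)."""
    row, col = _parse_well(well)
    r = _ROWS_384.index(row)
    c = col - 1
    if not (0 <= r < 16 and 0 <= c < 24):
        raise LayoutError(f"invalid 384-well position {row}{col}")
    if scheme == "interleaved":
        plate = 2 * (r % 2) + (c % 2) + 1
        r96, c96 = r // 2, c // 2
    elif scheme == "block":
        plate = 2 * (r // 8) + (c // 12) + 1
        r96, c96 = r % 8, c % 12
    else:
        raise LayoutError(f"unknown quadrant scheme {scheme!r}")
    return plate, (_ROWS_96[r96], c96 + 1)


def map_plates(
    transfection_maps: Sequence[pd.DataFrame] | Mapping[int, pd.DataFrame],
    scheme: str = "interleaved",
) -> pd.DataFrame:
    """Combine four 96-well layout grids into one 384-well layout grid.

    Each input is an 8x12 grid (rows A-H, columns 1-12) of arbitrary
    content (e.g. protein ids). The mapping is a bijection: every 96-well
    position lands on exactly one 384-well position.
    """
    if isinstance(transfection_maps, Mapping):
        plates = [transfection_maps[k] for k in sorted(transfection_maps)]
    else:
        plates = list(transfection_maps)
    if len(plates) != 4:
        raise LayoutError(f"expected exactly 4 source plates, got {len(plates)}")
    out = pd.DataFrame(
        np.full((16, 24), None, dtype=object),
        index=list(_ROWS_384),
        columns=range(1, 25),
    )
    for k, grid in enumerate(plates, start=1):
        if grid.shape != (8, 12):
            raise LayoutError(f"source plate {k} is not 8x12: {grid.shape}")
        for i, row in enumerate(_ROWS_96):
            for j in range(12):
                r384, c384 = map_well(k, (row, j + 1), scheme=scheme)
                out.loc[r384, c384] = grid.iat[i, j]
    return out


def read_plate_map(path, *, sep: str = ",") -> pd.DataFrame:
    """Read a plate-map grid (row letters as index, numeric column headers)."""
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.columns = [int(c) for c in df.columns]
    df.index = [str(r).upper() for r in df.index]
    return df


def write_plate_map(grid: pd.DataFrame, path, *, sep: str = ",") -> None:
    grid.to_csv(path, sep=sep)
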