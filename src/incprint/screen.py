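"""Core containers for incPRINT screen data.

An incPRINT screen tests a library of FLAG-tagged proteins against one
MS2-tagged RNA. Every (protein, RNA) pair is measured in biological
duplicate with two readouts per well: NanoLuc luciferase luminescence
(RNA-protein interaction intensity) and anti-FLAG ELISA (test-protein
expression level), both in relative light units (RLU).

The canonical in-memory representations are pandas objects:

* a *measurement table* in long (tidy) format, one row per well, with
  columns ``rna_id, protein_id, replicate, luciferase_rlu, elisa_rlu``
  (plus optional ``plate_id, well``);
* a *library table* indexed by ``protein_id`` with columns ``symbol``,
  ``category`` and ``pfam_domains`` (a frozenset of Pfam accessions);
* a *record table* (see :func:`incprint.qc.to_records`), one row per
  (protein, RNA) pair, carrying both replicates side by side together
  with the QC status, replicate means, normalized score and hit flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np
import pandas as pd

from .exceptions import FormatError, IntegrityError, ValidationError

__all__ = [
    "Status",
    "CATEGORIES",
    "MEASUREMENT_COLUMNS",
    "RECORD_COLUMNS",
    "make_library",
    "ScreenDataset",
]

#: Valid protein library categories.
CATEGORIES = ("RBP", "TF", "CHROMATIN", "CONTROL")

#: Mandatory columns of a long-format measurement table.
MEASUREMENT_COLUMNS = (
    "rna_id",
    "protein_id",
    "replicate",
    "luciferase_rlu",
    "elisa_rlu",
)

#: Columns of a per-(protein, RNA) record table.
RECORD_COLUMNS = (
    "protein_id",
    "rna_id",
    "lum_1",
    "lum_2",
    "elisa_1",
    "elisa_2",
    "status",
    "mean_lum",
    "mean_elisa",
    "normalized_score",
    "is_interactor",
)


class Status(IntEnum):
    """Per-(protein, RNA) analysis status.

    ``LOW_EXPRESSION`` and ``DISCORDANT`` correspond to the screen's
    published status annotations 2 and 3; ``SINGLE_REPLICATE`` is an
    extension for incomplete plates, which are retained and flagged
    rather than silently dropped.
    """

    ANALYZED = 1
    LOW_EXPRESSION = 2
    DISCORDANT = 3
    SINGLE_REPLICATE = 4


def make_library(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalize a protein annotation table.

    Parameters
    ----------
    df : DataFrame
        Must contain columns ``protein_id``, ``symbol``, ``category`` and
        ``pfam_domains``; ``pfam_domains`` entries may be iterables of
        accessions or semicolon-separated strings (empty allowed).

    Returns
    -------
    DataFrame indexed by ``protein_id`` with ``pfam_domains`` coerced to
    frozensets.
    """
    required = {"protein_id", "symbol", "category", "pfam_domains"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"library table missing column(s): {sorted(missing)}")
    if df["protein_id"].duplicated().any():
        dupes = df.loc[df["protein_id"].duplicated(), "protein_id"].tolist()
        raise IntegrityError(f"duplicate protein_id in library: {dupes[:5]}")
    bad = set(df["category"]) - set(CATEGORIES)
    if bad:
        raise ValidationError(
            f"unknown categories {sorted(bad)}; expected one of {CATEGORIES}"
        )

    def _domains(value) -> frozenset:
        if isinstance(value, str):
            return frozenset(d for d in value.split(";") if d)
        if value is None or (isinstance(value, float) and np.isnan(value)):
            return frozenset()
        return frozenset(value)

    out = df.copy()
    out["pfam_domains"] = out["pfam_domains"].map(_domains)
    return out.set_index("protein_id", drop=False).rename_axis(None)


@dataclass
class ScreenDataset:
    """All duplicate measurements for one tagged RNA plus the library.

    Validates on construction: measurements must reference known
    proteins, carry non-negative finite readouts, and have unique
    (rna_id, protein_id, replicate) keys. Proteins present with a single
    replicate are recorded in :attr:`incomplete_proteins`, not dropped.
    """

    rna_id: str
    measurements: pd.DataFrame
    library: pd.DataFrame
    incomplete_proteins: tuple[str, ...] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        m = self.measurements
        missing = set(MEASUREMENT_COLUMNS) - set(m.columns)
        if missing:
            raise FormatError(f"measurement table missing column(s): {sorted(missing)}")
        if not (m["rna_id"] == self.rna_id).all():
            extra = sorted(set(m["rna_id"]) - {self.rna_id})
            raise IntegrityError(
                f"dataset for {self.rna_id!r} contains foreign rna_id(s) {extra}"
            )
        if not set(m["replicate"]).issubset({1, 2}):
            raise ValidationError("replicate must be 1 or 2")
        for col in ("luciferase_rlu", "elisa_rlu"):
            vals = m[col].to_numpy(dtype=float)
            if not np.isfinite(vals).all():
                raise ValidationError(f"{col} contains non-finite values")
            if (vals < 0).any():
                raise ValidationError(f"{col} contains negative values")
        keys = m[["rna_id", "protein_id", "replicate"]]
        if keys.duplicated().any():
            dup = keys[keys.duplicated()].iloc[0].tolist()
            raise IntegrityError(f"duplicate measurement key {tuple(dup)}")
        unknown = set(m["protein_id"]) - set(self.library.index)
        if unknown:
            raise IntegrityError(
                f"measurements reference proteins absent from the library: "
                f"{sorted(unknown)[:5]}"
            )
        counts = m.groupby("protein_id")["replicate"].nunique()
        self.incomplete_proteins = tuple(sorted(counts.index[counts < 2]))

    @property
    def n_proteins(self) -> int:
        return self.measurements["protein_id"].nunique()

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ScreenDataset):
            return NotImplemented
        key = ["rna_id", "protein_id", "replicate"]
        a = self.measurements.sort_values(key).reset_index(drop=True)
        b = other.measurements.sort_values(key).reset_index(drop=True)
        cols = list(MEASUREMENT_COLUMNS)
        return (
            self.rna_id == other.rna_id
            and a[cols].equals(b[cols])
            and self.library.equals(other.library)
        )
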