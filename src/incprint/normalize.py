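"""Common-binder identification and median normalization.

To compare interaction intensities across RNA datasets measured with
different gains, each dataset is rescaled by the median interaction
score of a fixed set of *common binders*: the n proteins (default 200)
with top-ranking luciferase scores in the MS2-tag-only control screen,
assumed to bind every MS2-tagged RNA. The control is a normalization
reference only — it is never subtracted as a binding-specificity
background.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import (
    DegenerateControlError,
    InsufficientDataError,
    InsufficientOverlapError,
)
from .screen import Status

logger = logging.getLogger(__name__)

__all__ = [
    "CommonBinderSet",
    "NormalizationFactor",
    "identify_common_binders",
    "normalize_dataset",
]


@dataclass(frozen=True)
class CommonBinderSet:
    """Top-n proteins by mean luciferase in the control screen.

    ``members`` is ordered by descending mean luminescence, ties broken
    by protein_id for determinism.
    """

    source_rna_id: str
    n: int
    members: tuple[str, ...]

    def __post_init__(self):
        if len(self.members) != self.n:
            raise ValueError(
                f"binder set has {len(self.members)} members, expected {self.n}"
            )


@dataclass(frozen=True)
class NormalizationFactor:
    rna_id: str
    median_common: float
    n_common_found: int


def identify_common_binders(
    control_records: pd.DataFrame, n: int = 200
) -> CommonBinderSet:
    """Rank the control screen's ANALYZED proteins and take the top n.

    Ranking uses the replicate-averaged luminescence after QC (statuses
    2/3 excluded). Ties at the rank-n boundary are broken by protein_id
    and reported in the log.
    """
    if n < 1:
        raise ValueError("n must be positive")
    analyzed = control_records[control_records["status"] == Status.ANALYZED]
    if analyzed["mean_lum"].isna().any():
        raise InsufficientDataError(
            "control records lack mean_lum; run average_replicates first"
        )
    if len(analyzed) < n:
        raise InsufficientDataError(
            f"control screen has {len(analyzed)} ANALYZED proteins, "
            f"fewer than the requested {n} common binders"
        )
    ranked = analyzed.sort_values(
        ["mean_lum", "protein_id"], ascending=[False, True], kind="mergesort"
    )
    boundary = ranked["mean_lum"].iloc[n - 1]
    if len(ranked) > n and ranked["mean_lum"].iloc[n] == boundary:
        logger.info(
            "common-binder rank-%d boundary tie at score %.6g broken by protein_id",
            n, boundary,
        )
    members = tuple(ranked["protein_id"].iloc[:n])
    rna_id = str(control_records["rna_id"].iloc[0]) if len(control_records) else ""
    return CommonBinderSet(source_rna_id=rna_id, n=n, members=members)


def normalize_dataset(
    records: pd.DataFrame,
    binders: CommonBinderSet,
    *,
    min_overlap: int = 50,
) -> tuple[pd.DataFrame, NormalizationFactor]:
    """Divide every mean luminescence by the median common-binder score.

    Binders absent or filtered in this dataset are skipped; the factor is
    the median over those found, guarded by ``min_overlap``. The
    transform is a positive rescaling: within-dataset ranking is
    preserved exactly, and the median of the found binders' normalized
    scores is 1 by construction.
    """
    records = records.copy()
    analyzed = records["status"] == Status.ANALYZED
    found_mask = analyzed & records["protein_id"].isin(binders.members)
    n_found = int(found_mask.sum())
    if n_found < min_overlap:
        raise InsufficientOverlapError(
            f"only {n_found} of {binders.n} common binders ANALYZED in "
            f"dataset (minimum {min_overlap})"
        )
    median_common = float(np.median(records.loc[found_mask, "mean_lum"]))
    if median_common <= 0:
        raise DegenerateControlError(
            f"common-binder median is {median_common}; cannot normalize"
        )
    records.loc[analyzed, "normalized_score"] = (
        records.loc[analyzed, "mean_lum"] / median_common
    )
    rna_id = str(records["rna_id"].iloc[0]) if len(records) else ""
    factor = NormalizationFactor(
        rna_id=rna_id, median_common=median_common, n_common_found=n_found
    )
    logger.info(
        "normalization [%s]: median of %d common binders = %.6g RLU",
        rna_id, n_found, median_common,
    )
    return records, factor
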