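"""Interactor classification and cross-RNA comparison.

A protein is called an interactor of an RNA when its normalized
interaction score reaches the dataset's intensity cutoff. Because the
score distribution is hit-sparse (~97% of proteins do not interact),
the default automated cutoff is a robust background estimate,
median + k * 1.4826 * MAD (k = 5), computed per RNA dataset after
normalization; a manual cutoff reproduces a figure-style analysis.

The cross-RNA comparison matrix contains every protein that interacts
with at least one compared RNA and is expressed (ANALYZED) in all
compared screens.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage

from .exceptions import DegenerateBackgroundError
from .screen import Status

logger = logging.getLogger(__name__)

__all__ = [
    "HitCallConfig",
    "CutoffResult",
    "ComparisonMatrix",
    "call_interactors",
    "build_comparison",
    "rank_plot_table",
]

#: Scale factor making the MAD a consistent estimator of the normal sigma.
MAD_SCALE = 1.4826


@dataclass(frozen=True)
class HitCallConfig:
    cutoff_mode: str = "robust_background"
    manual_cutoff: float | None = None
    k_mad: float = 5.0

    def __post_init__(self):
        if self.cutoff_mode not in ("manual", "robust_background"):
            raise ValueError(f"unknown cutoff mode {self.cutoff_mode!r}")
        if self.cutoff_mode == "manual":
            if self.manual_cutoff is None or self.manual_cutoff <= 0:
                raise ValueError("manual mode requires a positive manual_cutoff")
        if self.k_mad <= 0:
            raise ValueError("k_mad must be positive")


@dataclass(frozen=True)
class CutoffResult:
    rna_id: str
    cutoff: float
    cutoff_mode: str
    n_hits: int
    n_analyzed: int

    @property
    def hit_fraction(self) -> float:
        return self.n_hits / self.n_analyzed if self.n_analyzed else float("nan")


@dataclass(frozen=True)
class ComparisonMatrix:
    """Normalized scores and hit mask for proteins x RNAs."""

    scores: pd.DataFrame
    mask: pd.DataFrame

    @property
    def protein_ids(self) -> tuple[str, ...]:
        return tuple(self.scores.index)

    @property
    def rna_ids(self) -> tuple[str, ...]:
        return tuple(self.scores.columns)


def call_interactors(
    records: pd.DataFrame, config: HitCallConfig | None = None
) -> tuple[pd.DataFrame, CutoffResult]:
    """Set is_interactor = (normalized_score >= cutoff) on ANALYZED records."""
    config = config or HitCallConfig()
    records = records.copy()
    analyzed = records["status"] == Status.ANALYZED
    scores = records.loc[analyzed, "normalized_score"].to_numpy(dtype=float)
    if np.isnan(scores).any():
        raise ValueError("normalized_score missing on ANALYZED records; normalize first")
    if config.cutoff_mode == "manual":
        cutoff = float(config.manual_cutoff)
    else:
        med = float(np.median(scores))
        mad = float(np.median(np.abs(scores - med)))
        if mad == 0:
            raise DegenerateBackgroundError(
                "score MAD is zero; the robust background cutoff is undefined "
                "— use manual cutoff mode"
            )
        cutoff = med + config.k_mad * MAD_SCALE * mad
    hits = scores >= cutoff
    records.loc[analyzed, "is_interactor"] = hits
    rna_id = str(records["rna_id"].iloc[0]) if len(records) else ""
    result = CutoffResult(
        rna_id=rna_id,
        cutoff=cutoff,
        cutoff_mode=config.cutoff_mode,
        n_hits=int(hits.sum()),
        n_analyzed=int(analyzed.sum()),
    )
    logger.info(
        "hit calling [%s]: cutoff=%.4g (%s), %d hits of %d analyzed (%.2f%%)",
        rna_id, cutoff, config.cutoff_mode, result.n_hits, result.n_analyzed,
        100 * result.hit_fraction,
    )
    return records, result


def build_comparison(
    called: Mapping[str, pd.DataFrame], *, order: str = "cluster"
) -> ComparisonMatrix:
    """Assemble the cross-RNA comparison matrix from called record tables.

    Included proteins are the union of each screen's interactors,
    intersected with the proteins ANALYZED (expressed) in every compared
    screen. ``order`` is "cluster" (average-linkage hierarchical
    clustering on log10 scores) or "input" (protein_id order).
    """
    if len(called) < 2:
        raise ValueError("comparison requires at least two called screens")
    if order not in ("cluster", "input"):
        raise ValueError(f"unknown ordering {order!r}")
    hits: set[str] = set()
    expressed_all: set[str] | None = None
    for rna, recs in called.items():
        analyzed = recs.loc[recs["status"] == Status.ANALYZED, "protein_id"]
        hit_ids = recs.loc[recs["is_interactor"].fillna(False).astype(bool), "protein_id"]
        hits |= set(hit_ids)
        expressed = set(analyzed)
        expressed_all = expressed if expressed_all is None else expressed_all & expressed
    include = sorted(hits & (expressed_all or set()))
    if not include:
        warnings.warn("no protein satisfies the comparison inclusion rule", stacklevel=2)
        empty = pd.DataFrame(index=[], columns=list(called))
        return ComparisonMatrix(scores=empty, mask=empty.astype(bool))

    scores = pd.DataFrame(index=include, columns=list(called), dtype=float)
    mask = pd.DataFrame(False, index=include, columns=list(called))
    for rna, recs in called.items():
        sub = recs.set_index("protein_id").loc[include]
        scores[rna] = sub["normalized_score"].astype(float)
        mask[rna] = sub["is_interactor"].fillna(False).astype(bool)

    if order == "cluster" and len(include) >= 3:
        z = linkage(np.log10(scores.to_numpy(dtype=float)), method="average")
        leaf_order = leaves_list(z)
        scores = scores.iloc[leaf_order]
        mask = mask.iloc[leaf_order]
    return ComparisonMatrix(scores=scores, mask=mask)


def rank_plot_table(records: pd.DataFrame) -> pd.DataFrame:
    """Ranked table for the sorted interaction-intensity dot plot.

    ANALYZED records sorted by ascending normalized score (ties by
    protein_id), with 1-based ranks.
    """
    analyzed = records[records["status"] == Status.ANALYZED]
    ordered = analyzed.sort_values(
        ["normalized_score", "protein_id"], kind="mergesort", ignore_index=True
    )
    return pd.DataFrame(
        {
            "rank": np.arange(1, len(ordered) + 1),
            "protein_id": ordered["protein_id"],
            "normalized_score": ordered["normalized_score"],
            "is_interactor": ordered["is_interactor"].astype("boolean"),
        }
    )
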