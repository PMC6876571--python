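"""High-level modelling interface: ScreenModel.fit() -> ScreenResults.

This is a thin facade over the stage modules (qc, normalize, hitcall,
enrichment) in the style of a statsmodels model: construct the model
from data and configuration, call :meth:`ScreenModel.fit`, and inspect
the returned results object (estimates, diagnostics, ``summary()``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import io as _io
from . import qc as _qc
from .enrichment import enrich
from .exceptions import IncPrintError
from .hitcall import ComparisonMatrix, CutoffResult, HitCallConfig, build_comparison, call_interactors
from .normalize import (
    CommonBinderSet,
    NormalizationFactor,
    identify_common_binders,
    normalize_dataset,
)
from .screen import ScreenDataset, Status

__all__ = ["AnalysisConfig", "ScreenModel", "ScreenResults"]


@dataclass(frozen=True)
class AnalysisConfig:
    """All tunable parameters of the analysis, with the defaults used
    throughout: valley/quantile expression policy, mean/s.d. < 1.5
    discordance rule, 200 common binders, robust median + 5 MAD cutoff,
    BH-corrected one-sided proportion tests with the 3-occurrence rule."""

    expression: _qc.ExpressionFilterConfig = field(
        default_factory=_qc.ExpressionFilterConfig
    )
    discordance: _qc.DiscordanceConfig = field(default_factory=_qc.DiscordanceConfig)
    n_common_binders: int = 200
    min_binder_overlap: int = 50
    hitcall: HitCallConfig = field(default_factory=HitCallConfig)
    alpha: float = 0.05
    min_count: int = 3
    correction: str = "fdr_bh"
    comparison_order: str = "cluster"
    include_control_in_comparison: bool = False


class ScreenModel:
    """An incPRINT screen analysis over one control and >= 0 test RNAs.

    Parameters
    ----------
    datasets : mapping rna_id -> ScreenDataset
        Must include the control (MS2-tag-only) dataset.
    control : str
        rna_id of the control dataset used to define common binders.
    config : AnalysisConfig, optional
    """

    def __init__(
        self,
        datasets: Mapping[str, ScreenDataset],
        control: str = "MS2",
        config: AnalysisConfig | None = None,
    ):
        if control not in datasets:
            raise IncPrintError(f"control dataset {control!r} not supplied")
        self.datasets = dict(datasets)
        self.control = control
        self.config = config or AnalysisConfig()

    @classmethod
    def from_tables(
        cls,
        measurements: pd.DataFrame,
        library: pd.DataFrame,
        control: str = "MS2",
        config: AnalysisConfig | None = None,
    ) -> "ScreenModel":
        """Build from a long measurement table covering all RNAs."""
        datasets = {
            str(rna): ScreenDataset(
                rna_id=str(rna), measurements=sub.reset_index(drop=True), library=library
            )
            for rna, sub in measurements.groupby("rna_id", sort=True)
        }
        return cls(datasets, control=control, config=config)

    @property
    def test_rna_ids(self) -> tuple[str, ...]:
        return tuple(r for r in self.datasets if r != self.control)

    def fit(self) -> "ScreenResults":
        """Run QC, normalization, hit calling, comparison and enrichment."""
        cfg = self.config
        records: dict[str, pd.DataFrame] = {}
        qc_reports: dict[str, _qc.QCReport] = {}
        replicate_r2: dict[str, dict[str, float]] = {}
        for rna, ds in self.datasets.items():
            recs, report = _qc.apply_qc(ds, cfg.expression, cfg.discordance)
            records[rna] = recs
            qc_reports[rna] = report
            r2 = {}
            for signal in ("luciferase", "elisa"):
                try:
                    r2[signal] = _qc.replicate_correlation(ds, signal)
                except IncPrintError:
                    r2[signal] = float("nan")
            replicate_r2[rna] = r2

        binders = identify_common_binders(records[self.control], cfg.n_common_binders)
        factors: dict[str, NormalizationFactor] = {}
        cutoffs: dict[str, CutoffResult] = {}
        for rna in self.datasets:
            records[rna], factors[rna] = normalize_dataset(
                records[rna], binders, min_overlap=cfg.min_binder_overlap
            )
            records[rna], cutoffs[rna] = call_interactors(records[rna], cfg.hitcall)

        compare_ids = (
            tuple(self.datasets)
            if cfg.include_control_in_comparison
            else self.test_rna_ids
        )
        comparison = (
            build_comparison(
                {r: records[r] for r in compare_ids}, order=cfg.comparison_order
            )
            if len(compare_ids) >= 2
            else None
        )

        enrichment: dict[str, pd.DataFrame] = {}
        for rna in self.test_rna_ids:
            recs = records[rna]
            hit_ids = recs.loc[
                recs["is_interactor"].fillna(False).astype(bool), "protein_id"
            ]
            enrichment[rna] = enrich(
                hit_ids,
                self.datasets[rna].library,
                alpha=cfg.alpha,
                min_count=cfg.min_count,
                correction=cfg.correction,
            )
        return ScreenResults(
            model=self,
            records=records,
            qc_reports=qc_reports,
            replicate_r2=replicate_r2,
            common_binders=binders,
            factors=factors,
            cutoffs=cutoffs,
            comparison=comparison,
            enrichment=enrichment,
        )


@dataclass
class ScreenResults:
    """Fitted screen analysis: per-RNA record tables plus derived objects."""

    model: ScreenModel
    records: dict[str, pd.DataFrame]
    qc_reports: dict[str, _qc.QCReport]
    replicate_r2: dict[str, dict[str, float]]
    common_binders: CommonBinderSet
    factors: dict[str, NormalizationFactor]
    cutoffs: dict[str, CutoffResult]
    comparison: ComparisonMatrix | None
    enrichment: dict[str, pd.DataFrame]

    def hit_ids(self, rna_id: str) -> tuple[str, ...]:
        recs = self.records[rna_id]
        mask = recs["is_interactor"].fillna(False).astype(bool)
        return tuple(recs.loc[mask, "protein_id"])

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for rna, recs in self.records.items():
            counts = recs["status"].value_counts()
            cut = self.cutoffs[rna]
            rows.append(
                {
                    "rna_id": rna,
                    "n_proteins": len(recs),
                    "analyzed": int(counts.get(Status.ANALYZED, 0)),
                    "low_expression": int(counts.get(Status.LOW_EXPRESSION, 0)),
                    "discordant": int(counts.get(Status.DISCORDANT, 0)),
                    "single_replicate": int(counts.get(Status.SINGLE_REPLICATE, 0)),
                    "r2_luciferase": self.replicate_r2[rna]["luciferase"],
                    "r2_elisa": self.replicate_r2[rna]["elisa"],
                    "norm_factor_rlu": self.factors[rna].median_common,
                    "binders_found": self.factors[rna].n_common_found,
                    "cutoff": cut.cutoff,
                    "hits": cut.n_hits,
                    "hit_pct": 100 * cut.hit_fraction,
                    "enriched_domains": int(
                        self.enrichment[rna]["enriched"].sum()
                    )
                    if rna in self.enrichment
                    else 0,
                }
            )
        return pd.DataFrame(rows).set_index("rna_id")

    def summary(self) -> str:
        """Human-readable per-RNA summary table."""
        frame = self.summary_frame()
        with pd.option_context("display.width", 200, "display.float_format",
                               lambda v: f"{v:.4g}"):
            body = frame.to_string()
        header = (
            f"incPRINT screen analysis — control: {self.model.control}, "
            f"{len(self.records)} dataset(s), "
            f"{self.common_binders.n} common binders\n"
        )
        return header + body

    def to_summary_dict(self) -> dict:
        """Machine-readable run summary (everything recomputable from the
        persisted record tables)."""
        cfg = self.model.config
        per_rna = {}
        for rna, recs in self.records.items():
            report = self.qc_reports[rna]
            cut = self.cutoffs[rna]
            per_rna[rna] = {
                "status_counts": report.status_counts,
                "elisa_threshold_log2": report.expression.threshold,
                "expression_policy": report.expression.policy_used,
                "discordance_high_level": report.discordance.high_level,
                "replicate_r2": self.replicate_r2[rna],
                "normalization_factor": self.factors[rna].median_common,
                "n_common_binders_found": self.factors[rna].n_common_found,
                "cutoff": cut.cutoff,
                "cutoff_mode": cut.cutoff_mode,
                "n_hits": cut.n_hits,
                "hit_fraction": cut.hit_fraction,
                "n_enriched_domains": int(self.enrichment[rna]["enriched"].sum())
                if rna in self.enrichment
                else None,
            }
        return {
            "control": self.model.control,
            "n_common_binders": cfg.n_common_binders,
            "correction": cfg.correction,
            "alpha": cfg.alpha,
            "min_count": cfg.min_count,
            "datasets": per_rna,
        }

    def save(self, out_dir, *, sep: str = "\t") -> None:
        """Persist all stage outputs as delimited text."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for rna, recs in self.records.items():
            _io.write_records(recs, out / f"records_{rna}.tsv", sep=sep)
            if rna in self.enrichment:
                self.enrichment[rna].to_csv(
                    out / f"enrichment_{rna}.tsv", sep=sep, index=False
                )
        _io.write_binder_set(self.common_binders.members, out / "common_binders.txt")
        if self.comparison is not None and len(self.comparison.scores):
            self.comparison.scores.to_csv(out / "comparison_scores.tsv", sep=sep)
            self.comparison.mask.to_csv(out / "comparison_mask.tsv", sep=sep)

    # plotting ----------------------------------------------------------
    def plot_rank(self, rna_id: str, ax=None):
        from .plotting import plot_rank

        return plot_rank(self.records[rna_id], self.cutoffs[rna_id].cutoff, ax=ax)

    def plot_heatmap(self, ax=None):
        from .plotting import plot_comparison_heatmap

        if self.comparison is None:
            raise IncPrintError("no comparison matrix (fewer than two test RNAs)")
        return plot_comparison_heatmap(self.comparison, ax=ax)

    def plot_volcano(self, rna_id: str, ax=None):
        from .plotting import plot_volcano

        return plot_volcano(self.enrichment[rna_id], ax=ax)
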