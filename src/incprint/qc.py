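"""Quality-control filters for incPRINT screens.

Two filters are applied to each (protein, RNA) pair before scoring:

1. *Low expression* (status 2): log2-transformed ELISA values are binned
   to assess the distribution of tagged-protein expression, and proteins
   whose summary ELISA statistic falls in the low mode are removed. The
   distribution is bimodal in practice (failed vs productive
   transfection), so the default policy cuts at the valley between the
   two largest modes and falls back to a fixed quantile when the
   histogram is unimodal.
2. *Replicate discordance* (status 3): pairs whose luciferase replicates
   disagree (mean / s.d. < 1.5) are removed, unless both duplicates show
   a high interaction score — strong interactions are kept even when
   noisy.

Surviving pairs (status 1) are scored as the arithmetic mean of the two
luciferase replicates.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import (
    ContractError,
    DegenerateDistributionError,
    InsufficientDataError,
    UndefinedCorrelationError,
)
from .screen import RECORD_COLUMNS, ScreenDataset, Status

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionFilterConfig",
    "DiscordanceConfig",
    "ExpressionFilterResult",
    "DiscordanceResult",
    "to_records",
    "filter_low_expression",
    "filter_discordant",
    "discordance_ratio",
    "average_replicates",
    "record_mean",
    "replicate_correlation",
    "apply_qc",
]


# ---------------------------------------------------------------------------
# configs / results


@dataclass(frozen=True)
class ExpressionFilterConfig:
    """Policy for the low-expression (status 2) threshold.

    policy : "valley" cuts at the histogram valley between the two
        largest modes of mean log2(ELISA + pseudocount), with
        Freedman-Diaconis bin width and a 3-bin moving-average smooth;
        falls back to the fixed quantile when no valley exists.
        "quantile" always uses the fixed quantile.
    """

    policy: str = "valley"
    quantile: float = 0.20
    pseudocount: float = 1.0
    smooth_bins: int = 3

    def __post_init__(self):
        if self.policy not in ("valley", "quantile"):
            raise ValueError(f"unknown expression policy {self.policy!r}")
        if not 0 < self.quantile < 1:
            raise ValueError("quantile must be in (0, 1)")


@dataclass(frozen=True)
class DiscordanceConfig:
    """Replicate-discordance (status 3) rule: mean/s.d. < ratio_min.

    The s.d. of a duplicate pair uses the sample (n-1) denominator by
    default (``sd_ddof=1``), i.e. s.d. = |a-b|/sqrt(2). Pairs where both
    replicates exceed the high-score level are exempt; the level is the
    ``high_quantile`` of replicate-averaged luminescence, or the explicit
    ``high_cutoff`` when given.
    """

    ratio_min: float = 1.5
    high_quantile: float = 0.95
    high_cutoff: float | None = None
    sd_ddof: int = 1


@dataclass(frozen=True)
class ExpressionFilterResult:
    threshold: float
    policy_used: str
    n_flagged: int
    n_evaluated: int


@dataclass(frozen=True)
class DiscordanceResult:
    high_level: float
    n_flagged: int
    n_exempt: int


# ---------------------------------------------------------------------------
# record assembly


def to_records(dataset: ScreenDataset) -> pd.DataFrame:
    """Pivot a dataset into one row per (protein, RNA) pair.

    Pairs with both replicates start as ANALYZED; pairs with a single
    replicate are flagged SINGLE_REPLICATE and excluded from downstream
    statistics without being dropped from the table.
    """
    m = dataset.measurements
    wide = m.pivot(index="protein_id", columns="replicate",
                   values=["luciferase_rlu", "elisa_rlu"])
    records = pd.DataFrame(
        {
            "protein_id": wide.index,
            "rna_id": dataset.rna_id,
            "lum_1": wide.get(("luciferase_rlu", 1)),
            "lum_2": wide.get(("luciferase_rlu", 2)),
            "elisa_1": wide.get(("elisa_rlu", 1)),
            "elisa_2": wide.get(("elisa_rlu", 2)),
        }
    ).reset_index(drop=True)
    complete = records["lum_1"].notna() & records["lum_2"].notna()
    records["status"] = np.where(complete, Status.ANALYZED, Status.SINGLE_REPLICATE)
    records["mean_lum"] = np.nan
    records["mean_elisa"] = np.nan
    records["normalized_score"] = np.nan
    records["is_interactor"] = pd.array([pd.NA] * len(records), dtype="boolean")
    return records.sort_values("protein_id", ignore_index=True)[list(RECORD_COLUMNS)]


# ---------------------------------------------------------------------------
# low-expression filter


def _elisa_summary(records: pd.DataFrame, pseudocount: float) -> pd.Series:
    """Mean of log2(elisa + pseudocount) over available replicates."""
    logs = np.log2(records[["elisa_1", "elisa_2"]].to_numpy(dtype=float) + pseudocount)
    return pd.Series(np.nanmean(logs, axis=1), index=records.index)


def _valley_threshold(values: np.ndarray, config: ExpressionFilterConfig) -> float | None:
    """Valley between the two largest modes of the smoothed histogram.

    Returns None when the smoothed histogram is unimodal (no valley).
    """
    iqr = np.subtract(*np.percentile(values, [75, 25]))
    if iqr == 0:
        return None
    width = 2 * iqr / len(values) ** (1 / 3)  # Freedman-Diaconis
    span = values.max() - values.min()
    n_bins = int(np.clip(math.ceil(span / width), 10, 200))
    counts, edges = np.histogram(values, bins=n_bins)
    kernel = np.ones(config.smooth_bins) / config.smooth_bins
    smooth = np.convolve(counts, kernel, mode="same")
    # local maxima of the smoothed histogram
    peaks = [
        i
        for i in range(len(smooth))
        if (i == 0 or smooth[i] > smooth[i - 1])
        and (i == len(smooth) - 1 or smooth[i] >= smooth[i + 1])
    ]
    if len(peaks) < 2:
        return None
    top_two = sorted(sorted(peaks, key=lambda i: smooth[i], reverse=True)[:2])
    lo, hi = top_two
    if hi - lo < 2:
        return None
    valley = lo + 1 + int(np.argmin(smooth[lo + 1 : hi]))
    return float((edges[valley] + edges[valley + 1]) / 2)


def filter_low_expression(
    records: pd.DataFrame, config: ExpressionFilterConfig | None = None
) -> tuple[pd.DataFrame, ExpressionFilterResult]:
    """Assign LOW_EXPRESSION status from the log2 ELISA distribution.

    The threshold is derived from all records with an ELISA summary
    (statuses ANALYZED and LOW_EXPRESSION), which makes the filter
    idempotent; only ANALYZED records can be newly flagged, and raising
    the threshold can only flag more proteins (monotonicity).
    """
    config = config or ExpressionFilterConfig()
    records = records.copy()
    summary = _elisa_summary(records, config.pseudocount)
    pool = records["status"].isin([Status.ANALYZED, Status.LOW_EXPRESSION])
    values = summary[pool].to_numpy(dtype=float)
    if len(values) == 0:
        raise InsufficientDataError("no records with ELISA summaries")
    raw = records.loc[pool, ["elisa_1", "elisa_2"]].to_numpy(dtype=float)
    if np.nanmax(raw) == 0:
        raise DegenerateDistributionError(
            "all ELISA readouts are zero; no expression threshold derivable"
        )

    threshold = None
    policy_used = config.policy
    if config.policy == "valley":
        threshold = _valley_threshold(values, config)
        if threshold is None:
            policy_used = f"quantile (valley fallback, q={config.quantile})"
    if threshold is None:
        threshold = float(np.quantile(values, config.quantile))
        if config.policy == "quantile":
            policy_used = f"quantile (q={config.quantile})"

    flag = pool & (summary < threshold)
    records.loc[pool, "status"] = Status.ANALYZED
    records.loc[flag, "status"] = Status.LOW_EXPRESSION
    result = ExpressionFilterResult(
        threshold=threshold,
        policy_used=policy_used,
        n_flagged=int(flag.sum()),
        n_evaluated=int(pool.sum()),
    )
    logger.info(
        "low-expression filter [%s]: threshold=%.4f log2(RLU), flagged %d of %d",
        policy_used, threshold, result.n_flagged, result.n_evaluated,
    )
    return records, result


# ---------------------------------------------------------------------------
# replicate-discordance filter


def discordance_ratio(a: float, b: float, *, sd_ddof: int = 1) -> float:
    """mean / s.d. of a duplicate pair; +inf when the replicates agree exactly."""
    mean = (a + b) / 2
    sd = abs(a - b) / math.sqrt(2) if sd_ddof == 1 else abs(a - b) / 2
    if sd == 0:
        return math.inf
    return mean / sd


def filter_discordant(
    records: pd.DataFrame, config: DiscordanceConfig | None = None
) -> tuple[pd.DataFrame, DiscordanceResult]:
    """Assign DISCORDANT status where mean/s.d. < ratio_min.

    The high-score exemption level is computed over the expression-passing
    two-replicate population (statuses ANALYZED and DISCORDANT), so the
    filter is idempotent: re-running it on its own output flags nothing new.
    """
    config = config or DiscordanceConfig()
    records = records.copy()
    pool = records["status"].isin([Status.ANALYZED, Status.DISCORDANT])
    lum = records.loc[pool, ["lum_1", "lum_2"]].to_numpy(dtype=float)
    if lum.size == 0:
        return records, DiscordanceResult(high_level=math.nan, n_flagged=0, n_exempt=0)
    means = lum.mean(axis=1)
    denom = math.sqrt(2) if config.sd_ddof == 1 else 2.0
    sds = np.abs(lum[:, 0] - lum[:, 1]) / denom
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = np.where(sds == 0, np.inf, means / np.where(sds == 0, 1, sds))
    if config.high_cutoff is not None:
        high_level = float(config.high_cutoff)
    else:
        high_level = float(np.quantile(means, config.high_quantile))
    both_high = lum.min(axis=1) > high_level
    discordant = (ratios < config.ratio_min) & ~both_high
    exempt = (ratios < config.ratio_min) & both_high

    status = np.where(discordant, Status.DISCORDANT, Status.ANALYZED)
    records.loc[pool, "status"] = status
    result = DiscordanceResult(
        high_level=high_level,
        n_flagged=int(discordant.sum()),
        n_exempt=int(exempt.sum()),
    )
    logger.info(
        "discordance filter: ratio_min=%.3g, high level=%.4g RLU, "
        "flagged %d (exempted %d)",
        config.ratio_min, high_level, result.n_flagged, result.n_exempt,
    )
    return records, result


# ---------------------------------------------------------------------------
# replicate averaging


def record_mean(record: pd.Series) -> float:
    """Interaction value of a single ANALYZED record (mean of the pair)."""
    if Status(record["status"]) is not Status.ANALYZED:
        raise ContractError(
            f"average requested for record with status "
            f"{Status(record['status']).name}"
        )
    return (record["lum_1"] + record["lum_2"]) / 2


def average_replicates(records: pd.DataFrame) -> pd.DataFrame:
    """Set mean_lum (and mean_elisa, for reporting) on ANALYZED records."""
    records = records.copy()
    analyzed = records["status"] == Status.ANALYZED
    records.loc[analyzed, "mean_lum"] = (
        records.loc[analyzed, "lum_1"] + records.loc[analyzed, "lum_2"]
    ) / 2
    records.loc[analyzed, "mean_elisa"] = (
        records.loc[analyzed, "elisa_1"] + records.loc[analyzed, "elisa_2"]
    ) / 2
    return records


# ---------------------------------------------------------------------------
# replicate reproducibility


def replicate_correlation(
    dataset: ScreenDataset, signal: str = "luciferase", *, log: bool = True
) -> float:
    """Squared Pearson correlation of median-normalized replicates.

    Each replicate vector is divided by its own median; with ``log=True``
    (default) the correlation is computed on log2 of the normalized
    values (dropping non-positive entries), matching the log-log scale
    on which screen reproducibility is judged.
    """
    col = {"luciferase": "luciferase_rlu", "elisa": "elisa_rlu"}.get(signal)
    if col is None:
        raise ValueError(f"signal must be 'luciferase' or 'elisa', got {signal!r}")
    wide = dataset.measurements.pivot(
        index="protein_id", columns="replicate", values=col
    ).dropna()
    if len(wide) < 3:
        raise InsufficientDataError(
            f"need >= 3 proteins with both replicates, have {len(wide)}"
        )
    x = wide[1].to_numpy(dtype=float)
    y = wide[2].to_numpy(dtype=float)
    mx, my = np.median(x), np.median(y)
    if mx == 0 or my == 0:
        raise DegenerateDistributionError("replicate median is zero")
    x, y = x / mx, y / my
    if log:
        keep = (x > 0) & (y > 0)
        x, y = np.log2(x[keep]), np.log2(y[keep])
        if len(x) < 3:
            raise InsufficientDataError("fewer than 3 positive pairs for log scale")
    if np.std(x) == 0 or np.std(y) == 0:
        raise UndefinedCorrelationError("zero variance in a replicate vector")
    r = float(np.corrcoef(x, y)[0, 1])
    return r * r


# ---------------------------------------------------------------------------
# convenience


@dataclass(frozen=True)
class QCReport:
    expression: ExpressionFilterResult
    discordance: DiscordanceResult
    status_counts: dict = field(default_factory=dict)


def apply_qc(
    dataset: ScreenDataset,
    expression: ExpressionFilterConfig | None = None,
    discordance: DiscordanceConfig | None = None,
) -> tuple[pd.DataFrame, QCReport]:
    """Full QC chain: assemble records, both filters, replicate averaging."""
    records = to_records(dataset)
    records, expr_result = filter_low_expression(records, expression)
    records, disc_result = filter_discordant(records, discordance)
    records = average_replicates(records)
    counts = {
        Status(k).name: int(v)
        for k, v in records["status"].value_counts().sort_index().items()
    }
    return records, QCReport(expr_result, disc_result, counts)
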