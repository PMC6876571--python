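"""Pfam-domain enrichment among an RNA's interactors.

Each domain present in the screened library is tested for
over-representation in the interactor set versus the library with a
two-sample pooled-proportion z-test (one-sided "greater" by default):

    p1 = k_hits / n_hits,  p2 = k_lib / n_lib,
    p  = (k_hits + k_lib) / (n_hits + n_lib),
    z  = (p1 - p2) / sqrt(p (1 - p) (1/n_hits + 1/n_lib)),

with the upper-tail standard-normal p-value. Domains count once per
protein (presence/absence). A domain is flagged enriched when it occurs
at least ``min_count`` times among the interactors (default 3) and its
multiplicity-corrected p-value is below alpha (default 0.05,
Benjamini-Hochberg; Bonferroni selectable).
"""

from __future__ import annotations

import logging
import math
import warnings
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .exceptions import IntegrityError

logger = logging.getLogger(__name__)

__all__ = [
    "DomainCount",
    "ProportionTestResult",
    "count_domains",
    "proportion_test",
    "enrich",
]

_CORRECTIONS = {"fdr_bh": "fdr_bh", "bonferroni": "bonferroni"}


class DomainCount(NamedTuple):
    pfam_id: str
    k_hits: int
    n_hits: int
    k_lib: int
    n_lib: int


class ProportionTestResult(NamedTuple):
    z: float
    p: float
    degenerate: bool


def count_domains(hits: Iterable[str], library: pd.DataFrame) -> pd.DataFrame:
    """Count per-domain carriers in the hit set and in the whole library.

    ``library`` is an annotation table indexed by protein_id with a
    ``pfam_domains`` column of sets (see :func:`incprint.screen.make_library`).
    Domains are presence/absence per protein; duplicate annotations on a
    protein count once.
    """
    hit_ids = set(hits)
    unknown = hit_ids - set(library.index)
    if unknown:
        raise IntegrityError(
            f"hit protein(s) absent from library: {sorted(unknown)[:5]}"
        )
    n_lib = len(library)
    n_hits = len(hit_ids)
    k_lib: dict[str, int] = {}
    k_hits: dict[str, int] = {}
    for pid, domains in library["pfam_domains"].items():
        in_hits = pid in hit_ids
        for d in set(domains):
            k_lib[d] = k_lib.get(d, 0) + 1
            if in_hits:
                k_hits[d] = k_hits.get(d, 0) + 1
    rows = [
        DomainCount(d, k_hits.get(d, 0), n_hits, k_lib[d], n_lib)
        for d in sorted(k_lib)
    ]
    return pd.DataFrame(rows, columns=DomainCount._fields)


def proportion_test(
    count: DomainCount | tuple, alternative: str = "greater"
) -> ProportionTestResult:
    """Two-sample pooled-proportion z-test for one domain.

    When the pooled proportion is 0 or 1 the statistic is undefined; the
    result carries z = nan, the alternative's trivial p-value, and a
    degenerate flag.
    """
    pfam_id, k_hits, n_hits, k_lib, n_lib = count
    if n_hits < 1 or n_lib < 1:
        raise ValueError("n_hits and n_lib must be positive")
    if not (0 <= k_hits <= n_hits and 0 <= k_lib <= n_lib):
        raise ValueError(f"inconsistent counts for {pfam_id}: {count}")
    p1 = k_hits / n_hits
    p2 = k_lib / n_lib
    pooled = (k_hits + k_lib) / (n_hits + n_lib)
    if pooled in (0.0, 1.0):
        p = 1.0 if alternative == "greater" else (1.0 if alternative == "less" else 1.0)
        return ProportionTestResult(z=math.nan, p=p, degenerate=True)
    se = math.sqrt(pooled * (1 - pooled) * (1 / n_hits + 1 / n_lib))
    z = (p1 - p2) / se
    if alternative == "greater":
        p = float(norm.sf(z))
    elif alternative == "less":
        p = float(norm.cdf(z))
    elif alternative == "two-sided":
        p = float(2 * norm.sf(abs(z)))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return ProportionTestResult(z=z, p=p, degenerate=False)


def enrich(
    hits: Iterable[str],
    library: pd.DataFrame,
    *,
    alpha: float = 0.05,
    min_count: int = 3,
    correction: str = "fdr_bh",
    alternative: str = "greater",
) -> pd.DataFrame:
    """Full enrichment table over all library domains, sorted by p_corrected.

    The ``enriched`` flag applies both the occurrence rule
    (k_hits >= min_count) and the corrected-alpha rule
    (p_corrected < alpha).
    """
    if correction not in _CORRECTIONS:
        raise ValueError(f"correction must be one of {sorted(_CORRECTIONS)}")
    hits = list(hits)
    columns = [
        "pfam_id", "k_hits", "n_hits", "k_lib", "n_lib",
        "z", "p_raw", "p_corrected", "degenerate", "enriched",
    ]
    if not hits:
        warnings.warn("empty hit set; returning empty enrichment table", stacklevel=2)
        return pd.DataFrame(columns=columns)
    counts = count_domains(hits, library)
    results = [
        proportion_test(DomainCount(*row), alternative=alternative)
        for row in counts.itertuples(index=False)
    ]
    table = counts.copy()
    table["z"] = [r.z for r in results]
    table["p_raw"] = [r.p for r in results]
    table["degenerate"] = [r.degenerate for r in results]
    _, p_corr, _, _ = multipletests(
        table["p_raw"].to_numpy(), alpha=alpha, method=_CORRECTIONS[correction]
    )
    table["p_corrected"] = np.maximum(p_corr, table["p_raw"])
    table["enriched"] = (table["k_hits"] >= min_count) & (table["p_corrected"] < alpha)
    table = table.sort_values(
        ["p_corrected", "pfam_id"], kind="mergesort", ignore_index=True
    )
    logger.info(
        "enrichment: %d domains tested, %d enriched (correction=%s, alpha=%g, "
        "min_count=%d)",
        len(table), int(table["enriched"].sum()), correction, alpha, min_count,
    )
    return table[columns]
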