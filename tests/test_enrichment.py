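"""Domain counting, pooled-proportion z-test, enrichment table."""

import math
import warnings

import numpy as np
import pytest
from scipy.stats import chi2_contingency
from statsmodels.stats.proportion import proportions_ztest

from helpers import make_domain_library
from incprint import count_domains, enrich, proportion_test
from incprint.enrichment import DomainCount
from incprint.exceptions import IntegrityError


def _random_library(rng, n=50, domains=("D1", "D2", "D3", "D4")):
    mapping = {}
    for i in range(n):
        present = [d for d in domains if rng.random() < 0.3]
        mapping[f"P{i:03d}"] = present
    return mapping


def test_hits_equal_library_gives_identical_counts():
    mapping = _random_library(np.random.default_rng(0))
    lib = make_domain_library(mapping)
    counts = count_domains(list(mapping), lib)
    assert (counts["k_hits"] == counts["k_lib"]).all()
    assert (counts["n_hits"] == counts["n_lib"]).all()


def test_duplicate_domain_annotations_count_once():
    lib = make_domain_library({"P1": ["D1", "D1", "D1"], "P2": ["D1"], "P3": []})
    counts = count_domains(["P1"], lib).set_index("pfam_id")
    assert counts.loc["D1", "k_hits"] == 1
    assert counts.loc["D1", "k_lib"] == 2


def test_counts_match_exhaustive_enumeration():
    rng = np.random.default_rng(42)
    mapping = _random_library(rng)
    hits = [pid for pid in mapping if rng.random() < 0.25]
    counts = count_domains(hits, make_domain_library(mapping)).set_index("pfam_id")
    for domain in counts.index:
        k_lib = sum(domain in doms for doms in mapping.values())
        k_hits = sum(domain in mapping[pid] for pid in hits)
        assert counts.loc[domain, "k_lib"] == k_lib
        assert counts.loc[domain, "k_hits"] == k_hits


def test_unknown_hit_protein_raises():
    lib = make_domain_library({"P1": ["D1"]})
    with pytest.raises(IntegrityError, match="GHOST"):
        count_domains(["GHOST"], lib)


# ---------------------------------------------------------------------------
# proportion test


def test_equal_proportions_give_z_zero_p_half():
    result = proportion_test(DomainCount("D", 5, 50, 240, 2400))
    assert result.z == pytest.approx(0.0, abs=1e-12)
    assert result.p == pytest.approx(0.5, abs=1e-12)


def test_z_squared_equals_pearson_chisquare():
    """Identity with the uncorrected chi-square on the 2x2 table."""
    rng = np.random.default_rng(7)
    for _ in range(100):
        n_hits = int(rng.integers(5, 100))
        n_lib = int(rng.integers(n_hits, 3000))
        k_hits = int(rng.integers(1, n_hits))
        k_lib = int(rng.integers(k_hits, min(n_lib, k_hits + 1000)))
        if k_lib == n_lib:
            k_lib -= 1
        z, _, degenerate = proportion_test(DomainCount("D", k_hits, n_hits, k_lib, n_lib))
        assert not degenerate
        table = [[k_hits, n_hits - k_hits], [k_lib, n_lib - k_lib]]
        chi2 = chi2_contingency(table, correction=False).statistic
        assert z * z == pytest.approx(chi2, rel=1e-9)


def test_agrees_with_statsmodels_ztest():
    z, p, _ = proportion_test(DomainCount("D", 12, 40, 90, 900))
    z_sm, p_sm = proportions_ztest([12, 90], [40, 900], alternative="larger")
    assert z == pytest.approx(z_sm, rel=1e-12)
    assert p == pytest.approx(p_sm, rel=1e-12)


def test_degenerate_pooled_proportion():
    result = proportion_test(DomainCount("D", 0, 10, 0, 100))
    assert math.isnan(result.z)
    assert result.p == 1.0
    assert result.degenerate


def test_swapping_samples_flips_z_sign():
    a = proportion_test(DomainCount("D", 9, 30, 50, 500))
    b = proportion_test(DomainCount("D", 50, 500, 9, 30))
    assert a.z == pytest.approx(-b.z, rel=1e-12)


# ---------------------------------------------------------------------------
# enrichment table


def _planted_library(rng, n_lib=400, n_hits=40, hit_freq=0.8, lib_freq=0.05):
    mapping = {}
    hits = []
    for i in range(n_lib):
        pid = f"P{i:03d}"
        is_hit = i < n_hits
        freq = hit_freq if is_hit else lib_freq
        doms = ["TARGET"] if rng.random() < freq else []
        if rng.random() < 0.25:
            doms.append("NEUTRAL")
        mapping[pid] = doms
        if is_hit:
            hits.append(pid)
    return make_domain_library(mapping), hits


def test_strongly_planted_domain_is_enriched():
    lib, hits = _planted_library(np.random.default_rng(3))
    table = enrich(hits, lib).set_index("pfam_id")
    assert bool(table.loc["TARGET", "enriched"])
    assert table.loc["TARGET", "p_corrected"] < 1e-6


def test_min_count_rule_blocks_rare_domains():
    # domain carried by exactly the 2 hits and nothing else: tiny p, k_hits = 2
    mapping = {f"P{i:03d}": [] for i in range(500)}
    mapping["P000"] = ["RARE"]
    mapping["P001"] = ["RARE"]
    mapping["P002"] = ["OTHER"]
    lib = make_domain_library(mapping)
    table = enrich(["P000", "P001"], lib).set_index("pfam_id")
    assert table.loc["RARE", "p_corrected"] < 0.05
    assert not bool(table.loc["RARE", "enriched"])


def test_correction_is_monotone():
    rng = np.random.default_rng(11)
    mapping = _random_library(rng, n=200, domains=tuple(f"D{i}" for i in range(12)))
    hits = [pid for pid in mapping if rng.random() < 0.2]
    for correction in ("fdr_bh", "bonferroni"):
        table = enrich(hits, make_domain_library(mapping), correction=correction)
        assert (table["p_corrected"] >= table["p_raw"]).all()
        assert (table["p_corrected"] <= 1.0).all()
        assert table["p_corrected"].is_monotonic_increasing


def test_empty_hit_set_warns_and_returns_empty():
    lib = make_domain_library({"P1": ["D1"]})
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        table = enrich([], lib)
    assert len(table) == 0
    assert any("empty hit set" in str(w.message) for w in caught)
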