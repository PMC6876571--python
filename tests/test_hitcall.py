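"""Interactor calling, cross-RNA comparison, ranked table."""

import warnings

import numpy as np
import pytest

from helpers import make_called_records, make_records
from incprint import (
    HitCallConfig,
    ScreenModel,
    SimulationConfig,
    Status,
    build_comparison,
    call_interactors,
    rank_plot_table,
    simulate_screen,
)
from incprint.exceptions import DegenerateBackgroundError
from incprint.simulate import DomainModel


def _normalized_records(scores, rna="R1"):
    recs = make_records([(s, s) for s in scores], rna_id=rna)
    recs["mean_lum"] = [float(s) for s in scores]
    recs["normalized_score"] = [float(s) for s in scores]
    return recs


def test_manual_cutoff_at_maximum_calls_only_argmax():
    scores = [0.5, 1.0, 9.0, 3.0]
    recs, result = call_interactors(
        _normalized_records(scores),
        HitCallConfig(cutoff_mode="manual", manual_cutoff=9.0),
    )
    assert result.n_hits == 1
    assert recs.loc[recs["is_interactor"].fillna(False), "protein_id"].tolist() == [
        "P0003"
    ]


def test_raising_cutoff_never_adds_hits():
    rng = np.random.default_rng(12)
    scores = rng.lognormal(0, 0.5, 300)
    previous = None
    for cutoff in (0.5, 1.0, 2.0, 4.0):
        recs, _ = call_interactors(
            _normalized_records(scores),
            HitCallConfig(cutoff_mode="manual", manual_cutoff=cutoff),
        )
        hits = set(recs.loc[recs["is_interactor"].fillna(False), "protein_id"])
        if previous is not None:
            assert hits <= previous
        previous = hits


def test_background_only_screen_has_sub_percent_hit_rate():
    """Robust median + 5 MAD cutoff on a null screen calls <1% of proteins."""
    config = SimulationConfig(
        n_proteins=1500,
        n_common_binders=100,
        rna_ids=("MS2", "RNA_A"),
        frac_true_interactors=0.0,
        common_binder_effect=1.0,
        seed=31,
    )
    datasets, truth = simulate_screen(config)
    assert truth.interactors["RNA_A"] == frozenset()
    from incprint import AnalysisConfig

    results = ScreenModel(
        datasets, config=AnalysisConfig(n_common_binders=100, min_binder_overlap=30)
    ).fit()
    assert results.cutoffs["RNA_A"].hit_fraction < 0.01


def test_zero_mad_is_degenerate():
    with pytest.raises(DegenerateBackgroundError, match="manual"):
        call_interactors(_normalized_records([2.0] * 50))


def test_noiseless_screen_recovers_planted_interactors_exactly(small_analysis_config):
    config = SimulationConfig(
        n_proteins=400,
        n_common_binders=40,
        rna_ids=("MS2", "RNA_A", "RNA_B"),
        replicate_cv=0.0,
        seed=13,
    )
    datasets, truth = simulate_screen(config)
    results = ScreenModel(datasets, config=small_analysis_config).fit()
    for rna in ("RNA_A", "RNA_B"):
        assert set(results.hit_ids(rna)) == set(truth.interactors[rna])


# ---------------------------------------------------------------------------
# comparison matrix


def test_comparison_inclusion_rule_hand_cases():
    a = make_called_records(
        [
            ("P1", Status.ANALYZED, 5.0, True),
            ("P2", Status.ANALYZED, 0.5, False),
            ("P3", Status.ANALYZED, 0.4, False),
        ],
        "RNA1",
    )
    b = make_called_records(
        [
            ("P1", Status.LOW_EXPRESSION, np.nan, None),
            ("P2", Status.ANALYZED, 6.0, True),
            ("P3", Status.ANALYZED, 0.7, False),
        ],
        "RNA2",
    )
    matrix = build_comparison({"RNA1": a, "RNA2": b}, order="input")
    # P1 is a hit but unexpressed in RNA2's screen -> excluded
    assert matrix.protein_ids == ("P2",)
    assert bool(matrix.mask.loc["P2", "RNA2"]) is True


def test_disjoint_hit_sets_union_when_fully_expressed():
    a = make_called_records(
        [("P1", 1, 9.0, True), ("P2", 1, 0.2, False), ("P3", 1, 0.3, False)], "RNA1"
    )
    b = make_called_records(
        [("P1", 1, 0.2, False), ("P2", 1, 8.0, True), ("P3", 1, 0.2, False)], "RNA2"
    )
    matrix = build_comparison({"RNA1": a, "RNA2": b}, order="input")
    assert set(matrix.protein_ids) == {"P1", "P2"}


def test_comparison_matches_set_algebra_oracle(small_sim, small_analysis_config):
    datasets, _ = small_sim
    results = ScreenModel(datasets, config=small_analysis_config).fit()
    matrix = results.comparison
    hits_union, expressed = set(), None
    for rna in ("RNA_A", "RNA_B"):
        recs = results.records[rna]
        hits_union |= set(results.hit_ids(rna))
        exp = set(recs.loc[recs["status"] == Status.ANALYZED, "protein_id"])
        expressed = exp if expressed is None else expressed & exp
    assert set(matrix.protein_ids) == (hits_union & expressed)
    assert matrix.scores.shape == matrix.mask.shape


def test_empty_comparison_warns_not_raises():
    a = make_called_records([("P1", 1, 0.5, False)], "RNA1")
    b = make_called_records([("P1", 1, 0.4, False)], "RNA2")
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        matrix = build_comparison({"RNA1": a, "RNA2": b})
    assert any("inclusion" in str(w.message) for w in caught)
    assert len(matrix.protein_ids) == 0


# ---------------------------------------------------------------------------
# ranked table


def test_rank_table_matches_stable_sort_oracle():
    rng = np.random.default_rng(17)
    scores = rng.lognormal(0, 1, 1000)
    recs, _ = call_interactors(
        _normalized_records(scores),
        HitCallConfig(cutoff_mode="manual", manual_cutoff=float(np.max(scores))),
    )
    table = rank_plot_table(recs)
    oracle = sorted(zip(scores, recs["protein_id"]))
    assert table["protein_id"].tolist() == [pid for _, pid in oracle]
    assert table["rank"].tolist() == list(range(1, 1001))


def test_rank_table_idempotent_on_sorted_input():
    recs = _normalized_records([1.0, 2.0, 3.0])
    recs["is_interactor"] = False
    once = rank_plot_table(recs)
    assert once["normalized_score"].is_monotonic_increasing
    reversed_recs = recs.iloc[::-1].reset_index(drop=True)
    assert rank_plot_table(reversed_recs)["protein_id"].tolist() == once[
        "protein_id"
    ].tolist()
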