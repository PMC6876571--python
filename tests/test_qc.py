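"""Expression filter, discordance filter, averaging, replicate correlation."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from helpers import make_records
from incprint import (
    DiscordanceConfig,
    ExpressionFilterConfig,
    ScreenDataset,
    Status,
    average_replicates,
    filter_discordant,
    filter_low_expression,
    replicate_correlation,
)
from incprint.exceptions import (
    ContractError,
    DegenerateDistributionError,
    UndefinedCorrelationError,
)
from incprint.qc import apply_qc, discordance_ratio, record_mean, to_records

NO_EXEMPTION = DiscordanceConfig(high_cutoff=math.inf)


# ---------------------------------------------------------------------------
# discordance filter


def test_identical_replicates_retained():
    recs = make_records([(1000.0, 1000.0)])
    out, _ = filter_discordant(recs, NO_EXEMPTION)
    assert out["status"].iloc[0] == Status.ANALYZED
    assert discordance_ratio(1000.0, 1000.0) == math.inf


def test_divergent_pair_is_discordant():
    # sample s.d. of a pair is |a-b|/sqrt(2): ratio = 500/565.69 = 0.884 < 1.5
    assert discordance_ratio(100.0, 900.0) == pytest.approx(
        500 / (800 / math.sqrt(2)), abs=1e-12
    )
    out, _ = filter_discordant(make_records([(100.0, 900.0)]), NO_EXEMPTION)
    assert out["status"].iloc[0] == Status.DISCORDANT


def test_high_score_pair_exempt_despite_ratio():
    config = DiscordanceConfig(high_cutoff=50_000.0)
    out, result = filter_discordant(make_records([(100_000.0, 900_000.0)]), config)
    assert out["status"].iloc[0] == Status.ANALYZED
    assert result.n_exempt == 1


@settings(derandomize=True, max_examples=100, deadline=None)
@given(
    a=st.floats(1.0, 1e6),
    b=st.floats(1.0, 1e6),
    c=st.floats(0.01, 100.0),
)
def test_discordance_decision_is_scale_invariant(a, b, c):
    r1 = discordance_ratio(a, b)
    r2 = discordance_ratio(a * c, b * c)
    assert (r1 < 1.5) == (r2 < 1.5) or math.isclose(r1, 1.5, rel_tol=1e-9)


def test_discordance_filter_idempotent():
    rng = np.random.default_rng(4)
    pairs = list(zip(rng.lognormal(5, 1, 300), rng.lognormal(5, 1, 300)))
    once, _ = filter_discordant(make_records(pairs))
    twice, _ = filter_discordant(once)
    assert once["status"].equals(twice["status"])


# ---------------------------------------------------------------------------
# low-expression filter


def _bimodal_records(n_low=120, n_high=480, low=32.0, high=4096.0):
    pairs = [(1000.0, 1000.0)] * (n_low + n_high)
    elisa = [(low, low)] * n_low + [(high, high)] * n_high
    return make_records(pairs, elisa_pairs=elisa)


def test_quantile_policy_flags_separated_low_mode():
    recs = _bimodal_records(n_low=120, n_high=480)
    out, result = filter_low_expression(
        recs, ExpressionFilterConfig(policy="quantile", quantile=0.20)
    )
    flagged = out[out["status"] == Status.LOW_EXPRESSION]
    assert len(flagged) == 120
    assert set(flagged.index) == set(range(120))
    assert result.n_flagged == 120


def test_valley_policy_flags_low_mode_of_simulated_screen(small_sim):
    datasets, truth = small_sim
    records = to_records(datasets["MS2"])
    out, result = filter_low_expression(records)
    assert "quantile" not in result.policy_used  # found a genuine valley
    flagged = set(out.loc[out["status"] == Status.LOW_EXPRESSION, "protein_id"])
    planted = truth.low_expression
    # nearly all planted low-expression proteins are caught, few extras
    assert len(flagged & planted) / len(planted) > 0.9
    assert len(flagged - planted) < 0.05 * len(out)


def test_identical_elisa_flags_nothing():
    recs = make_records([(10.0, 10.0)] * 20, elisa_pairs=[(500.0, 500.0)] * 20)
    out, result = filter_low_expression(recs)
    assert (out["status"] == Status.ANALYZED).all()
    assert "fallback" in result.policy_used


def test_all_zero_elisa_is_degenerate():
    recs = make_records([(10.0, 10.0)] * 5, elisa_pairs=[(0.0, 0.0)] * 5)
    with pytest.raises(DegenerateDistributionError):
        filter_low_expression(recs)


def test_threshold_monotonicity():
    rng = np.random.default_rng(9)
    elisa = rng.lognormal(6, 2, 200)
    recs = make_records([(1.0, 1.0)] * 200, elisa_pairs=list(zip(elisa, elisa)))
    flagged = {}
    for q in (0.1, 0.3, 0.5):
        out, _ = filter_low_expression(
            recs, ExpressionFilterConfig(policy="quantile", quantile=q)
        )
        flagged[q] = set(out.loc[out["status"] == Status.LOW_EXPRESSION, "protein_id"])
    assert flagged[0.1] <= flagged[0.3] <= flagged[0.5]


def test_statuses_partition_library(small_sim):
    datasets, _ = small_sim
    for ds in datasets.values():
        records, report = apply_qc(ds)
        assert sum(report.status_counts.values()) == len(ds.library)
        assert records["status"].isin(list(Status)).all()


def test_full_scale_screen_retains_expected_expressed_fraction(default_sim):
    """A ~3000-protein screen whose low mode holds ~20% of the library
    retains an expressed set near 2405 proteins."""
    datasets, _ = default_sim
    records, _ = apply_qc(datasets["MS2"])
    expressed = records["status"].isin([Status.ANALYZED, Status.DISCORDANT]).sum()
    assert abs(expressed - 2405) <= 100


# ---------------------------------------------------------------------------
# replicate averaging


def test_average_examples():
    recs = average_replicates(make_records([(1000.0, 1100.0), (250.0, 250.0)]))
    assert recs["mean_lum"].tolist() == [1050.0, 250.0]


def test_average_matches_bruteforce_recomputation():
    rng = np.random.default_rng(1)
    pairs = [(float(a), float(b)) for a, b in rng.lognormal(5, 1, (50, 2))]
    recs = average_replicates(make_records(pairs))
    expected = [(a + b) / 2 for a, b in pairs]  # spreadsheet-style recompute
    assert recs["mean_lum"].tolist() == expected


def test_average_requires_analyzed_status():
    recs = make_records([(10.0, 20.0)], status=Status.DISCORDANT)
    with pytest.raises(ContractError):
        record_mean(recs.iloc[0])
    out = average_replicates(recs)
    assert out["mean_lum"].isna().all()


# ---------------------------------------------------------------------------
# replicate correlation


def _paired_dataset(x, y, rna="R1"):
    n = len(x)
    ids = [f"P{i:04d}" for i in range(n)]
    m = pd.DataFrame(
        {
            "rna_id": rna,
            "protein_id": ids * 2,
            "replicate": [1] * n + [2] * n,
            "luciferase_rlu": list(x) + list(y),
            "elisa_rlu": 1.0,
        }
    )
    lib = pd.DataFrame(
        {"protein_id": ids, "symbol": ids, "category": "RBP", "pfam_domains": ""}
    )
    from incprint import make_library

    return ScreenDataset(rna_id=rna, measurements=m, library=make_library(lib))


def test_identical_replicates_give_r2_one():
    x = np.random.default_rng(2).lognormal(5, 1, 50)
    assert replicate_correlation(_paired_dataset(x, x)) == pytest.approx(1.0)


def test_scaled_replicates_give_r2_one():
    x = np.random.default_rng(3).lognormal(5, 1, 50)
    assert replicate_correlation(_paired_dataset(x, 2 * x)) == pytest.approx(1.0)


def test_r2_matches_textbook_covariance_formula():
    rng = np.random.default_rng(8)
    x = rng.lognormal(5, 1, 200)
    y = x * rng.lognormal(0, 0.3, 200)
    r2 = replicate_correlation(_paired_dataset(x, y))
    # independent recomputation from the definition
    lx, ly = np.log2(x / np.median(x)), np.log2(y / np.median(y))
    cov = ((lx - lx.mean()) * (ly - ly.mean())).sum()
    expected = cov**2 / (((lx - lx.mean()) ** 2).sum() * ((ly - ly.mean()) ** 2).sum())
    assert r2 == pytest.approx(expected, abs=1e-12)


def test_constant_replicate_vector_is_undefined():
    x = np.full(10, 7.0)
    y = np.arange(1.0, 11.0)
    with pytest.raises(UndefinedCorrelationError):
        replicate_correlation(_paired_dataset(x, y))
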