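"""Unit and property tests for the CLix scoring layer."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from clix.core import (
    CORTICAL_REGIONS,
    HIPPOCAMPAL_REGIONS,
    REGIONS,
    RegionCounts,
    ReferenceModel,
    Subtype,
    build_reference,
    classify_subtype,
    compute_clix,
    hippocampal_cortical_ratio,
    percentile,
)
from clix.errors import ReferenceTooSmallError, ScoreRangeError, ValidationError

# ---------------------------------------------------------------------------
# independent oracles (deliberately naive)


def oracle_percentile(value, ref):
    below = sum(1 for r in ref if r < value)
    equal = sum(1 for r in ref if r == value)
    return 100.0 * (below + 0.5 * equal) / len(ref)


def oracle_ratio(c: RegionCounts, eps=0.5):
    hipp = (c.ca1 + c.subiculum) / 2
    cort = (c.sup_temporal + c.inf_parietal + c.mid_frontal) / 3
    return (hipp + eps) / (cort + eps)


def oracle_clix_score(c: RegionCounts, ref: ReferenceModel):
    hipp = (
        oracle_percentile(c.ca1, ref.per_region_counts["ca1"])
        + oracle_percentile(c.subiculum, ref.per_region_counts["subiculum"])
    ) / 2
    cort = (
        sum(
            oracle_percentile(getattr(c, r), ref.per_region_counts[r])
            for r in CORTICAL_REGIONS
        )
        / 3
    )
    rpct = oracle_percentile(oracle_ratio(c, ref.pseudocount), ref.ratio_values)
    return 0.4 * (rpct + hipp + (100 - cort)) / 3


def random_counts(rng, high=60.0):
    return RegionCounts(*rng.uniform(0, high, size=5))


def random_reference(rng, n=40):
    return build_reference([random_counts(rng) for _ in range(n)])


# ---------------------------------------------------------------------------
# percentile


def test_percentile_below_support_is_zero():
    assert percentile(-1.0, list(range(1, 11))) == 0.0
    assert percentile(100.0, list(range(1, 11))) == 100.0


def test_percentile_midpoint_of_odd_distinct_reference():
    ref = [1, 2, 3, 4, 5, 6, 7, 8, 9]
    assert percentile(5, ref) == pytest.approx(100 * (4 + 0.5) / 9) == 50.0


def test_percentile_empty_reference_rejected():
    with pytest.raises(ValidationError):
        percentile(1.0, [])


def test_percentile_matches_counting_oracle(rng):
    for _ in range(200):
        ref = np.sort(rng.integers(0, 20, size=rng.integers(1, 30)).astype(float))
        v = float(rng.integers(-2, 22))
        assert percentile(v, ref) == pytest.approx(
            oracle_percentile(v, ref), abs=1e-12
        )


@given(
    st.lists(st.floats(0, 1e6), min_size=1, max_size=50),
    st.floats(0, 1e6),
    st.floats(0, 1e6),
)
def test_percentile_monotone_in_value(ref, a, b):
    ref = sorted(ref)
    lo, hi = min(a, b), max(a, b)
    assert percentile(lo, ref) <= percentile(hi, ref)


# ---------------------------------------------------------------------------
# ratio


def test_ratio_symmetric_compartments_give_one():
    c = RegionCounts(10, 10, 10, 10, 10)
    assert hippocampal_cortical_ratio(c, pseudocount=0.5) == 1.0
    assert hippocampal_cortical_ratio(c, pseudocount=2.0) == 1.0


def test_ratio_zero_cortex_stays_finite():
    c = RegionCounts(10, 10, 0, 0, 0)
    assert hippocampal_cortical_ratio(c, pseudocount=0.5) == pytest.approx(21.0)


def test_ratio_matches_arithmetic_oracle(rng):
    for _ in range(50):
        c = random_counts(rng)
        assert hippocampal_cortical_ratio(c) == pytest.approx(oracle_ratio(c))


def test_region_counts_validation():
    with pytest.raises(ValidationError):
        RegionCounts(-1, 0, 0, 0, 0)
    with pytest.raises(ValidationError):
        RegionCounts(math.nan, 1, 1, 1, 1)
    with pytest.raises(ValidationError):
        RegionCounts(math.inf, 1, 1, 1, 1)
    # a fully missing compartment is rejected even in permissive mode
    with pytest.raises(ValidationError):
        RegionCounts(math.nan, math.nan, 1, 1, 1, allow_missing=True)


# ---------------------------------------------------------------------------
# build_reference


def test_build_reference_identity_on_known_input():
    cases = [RegionCounts(i, i, i, i, i) for i in range(1, 101)]
    ref = build_reference(cases)
    assert ref.n_reference == 100
    assert list(ref.per_region_counts["ca1"]) == list(range(1, 101))


def test_build_reference_rejects_small_input():
    with pytest.raises(ReferenceTooSmallError):
        build_reference([])
    with pytest.raises(ReferenceTooSmallError):
        build_reference([RegionCounts(1, 1, 1, 1, 1)] * 19)


def test_build_reference_ratios_match_brute_force(rng):
    cases = [random_counts(rng) for _ in range(50)]
    ref = build_reference(cases)
    expected = sorted(oracle_ratio(c) for c in cases)
    assert np.allclose(ref.ratio_values, expected)


def test_build_reference_order_invariant(rng):
    cases = [random_counts(rng) for _ in range(30)]
    ref1 = build_reference(cases)
    ref2 = build_reference(list(reversed(cases)))
    for r in REGIONS:
        assert np.array_equal(ref1.per_region_counts[r], ref2.per_region_counts[r])
    assert np.array_equal(ref1.ratio_values, ref2.ratio_values)


def test_reference_json_round_trip(tmp_path, rng):
    ref = random_reference(rng)
    path = tmp_path / "ref.json"
    ref.save(path)
    back = ReferenceModel.load(path)
    assert back.n_reference == ref.n_reference
    assert np.array_equal(back.ratio_values, ref.ratio_values)
    for r in REGIONS:
        assert np.array_equal(back.per_region_counts[r], ref.per_region_counts[r])


# ---------------------------------------------------------------------------
# compute_clix


def _symmetric_reference():
    # 21 distinct values per region; middle element 11 -> percentile 50;
    # middle reference ratio 1.0 matches a case with equal compartments
    per_region = {r: np.arange(1.0, 22.0) for r in REGIONS}
    ratios = np.linspace(0.5, 1.5, 21)
    return ReferenceModel(
        per_region_counts=per_region,
        ratio_values=ratios,
        n_reference=21,
        provenance="synthetic symmetric reference",
    )


def test_midpoint_case_scores_twenty():
    # all five counts sit at the mid-rank-50 point, and the case ratio
    # (5.5/5.5 = 1.0) is the middle reference ratio -> composite 50 -> 20.0
    ref = _symmetric_reference()
    res = compute_clix(RegionCounts(11, 11, 11, 11, 11), ref)
    assert res.hippocampal_pct == 50.0
    assert res.cortical_pct == 50.0
    assert res.ratio_pct == 50.0
    assert res.score == pytest.approx(20.0)
    assert res.subtype is Subtype.TYPICAL


def test_extreme_case_attains_forty(rng):
    # hippocampal counts above the whole reference support, cortical counts
    # below it, and a ratio exceeding every reference ratio -> score 40
    ref = random_reference(rng)
    hi = 10.0 * float(max(arr.max() for arr in ref.per_region_counts.values())) + 100
    res = compute_clix(RegionCounts(hi, hi, 0, 0, 0), ref)
    assert all((arr > 0).all() for arr in (ref.per_region_counts[r] for r in CORTICAL_REGIONS))
    assert res.score == pytest.approx(40.0)
    assert res.subtype is Subtype.LIMBIC_PREDOMINANT


def test_random_cases_match_independent_composite_oracle(rng):
    ref = random_reference(rng)
    for _ in range(30):
        c = random_counts(rng, high=80.0)
        res = compute_clix(c, ref)
        assert abs(res.score - oracle_clix_score(c, ref)) < 1e-9


def test_missing_region_rejected_unless_opted_in():
    ref = _symmetric_reference()
    c = RegionCounts(11, math.nan, 11, 11, 11, allow_missing=True)
    with pytest.raises(ValidationError):
        compute_clix(c, ref)
    res = compute_clix(c, ref, allow_missing=True)
    assert res.score == pytest.approx(20.0)  # remaining regions still mid-rank


def test_weights_are_configurable():
    ref = _symmetric_reference()
    # weight only the ratio component: extreme ratio pushes score to 40
    c = RegionCounts(30.0, 30.0, 11, 11, 11)
    res = compute_clix(c, ref, weights=(1.0, 0.0, 0.0))
    assert res.score == pytest.approx(40.0)


# ---------------------------------------------------------------------------
# classify_subtype


@pytest.mark.parametrize(
    "score,expected",
    [
        (0.0, Subtype.HIPPOCAMPAL_SPARING),
        (5.0, Subtype.HIPPOCAMPAL_SPARING),
        (9.999999, Subtype.HIPPOCAMPAL_SPARING),
        (10.0, Subtype.TYPICAL),
        (29.999999, Subtype.TYPICAL),
        (30.0, Subtype.LIMBIC_PREDOMINANT),
        (40.0, Subtype.LIMBIC_PREDOMINANT),
    ],
)
def test_subtype_bins(score, expected):
    assert classify_subtype(score) is expected


@pytest.mark.parametrize("score", [-0.1, 40.1, 100.0])
def test_subtype_rejects_out_of_range(score):
    with pytest.raises(ScoreRangeError):
        classify_subtype(score)


# ---------------------------------------------------------------------------
# contract properties

counts_strategy = st.builds(
    RegionCounts,
    *[st.floats(0, 500, allow_nan=False) for _ in range(5)],
)


@given(counts_strategy, st.integers(0, 10_000))
def test_score_always_within_bounds(counts, ref_seed):
    ref = random_reference(np.random.default_rng(ref_seed))
    res = compute_clix(counts, ref)
    assert 0.0 <= res.score <= 40.0
    assert 0.0 <= res.hippocampal_pct <= 100.0
    assert 0.0 <= res.cortical_pct <= 100.0
    assert 0.0 <= res.ratio_pct <= 100.0
    assert res.ratio > 0


@given(counts_strategy, st.integers(0, 10_000), st.sampled_from(REGIONS), st.floats(0.1, 200))
def test_score_monotone_in_single_region(counts, ref_seed, region, delta):
    ref = random_reference(np.random.default_rng(ref_seed))
    base = compute_clix(counts, ref).score
    bumped = compute_clix(
        RegionCounts(
            **{r: getattr(counts, r) + (delta if r == region else 0) for r in REGIONS}
        ),
        ref,
    ).score
    if region in HIPPOCAMPAL_REGIONS:
        assert bumped >= base - 1e-9
    else:
        assert bumped <= base + 1e-9


@given(counts_strategy, st.integers(0, 10_000))
def test_subtype_consistent_with_score(counts, ref_seed):
    ref = random_reference(np.random.default_rng(ref_seed))
    res = compute_clix(counts, ref)
    assert classify_subtype(res.score) is res.subtype
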