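"""The irreducible-region miner against its brute-force oracle and its
published behavioural properties."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from covmine import (
    ConfigurationError,
    DomainError,
    GenomicInterval,
    MiningParams,
    SampleLookupError,
    brute_force_regions,
    find_irreducible_regions,
    fixed_mu,
    fraction_of_max,
    fraction_of_min,
    is_irreducible,
    region_based_coverage,
    support_count,
    support_filter,
)
from covmine.mining import IrreducibleRegion, maximal_irreducible_intervals

from conftest import make_track


def mine(values, mu, minsup, strict=False, start=0):
    from covmine import TrackKind

    track = make_track(values, start=start, kind=TrackKind.SMOOTHED)
    regions = find_irreducible_regions(track, "s1", MiningParams(mu, minsup, strict))
    return [(r.interval.start, r.interval.end) for r in regions]


def brute(values, mu, minsup, strict=False):
    regions = brute_force_regions(np.asarray(values, float), MiningParams(mu, minsup, strict))
    return [(r.interval.start, r.interval.end) for r in regions]


class TestIsIrreducible:
    @pytest.mark.parametrize("v,mu,expected", [(5, 5, True), (4.9, 5, False)])
    def test_single_element_base_case(self, v, mu, expected):
        assert is_irreducible([v], mu) is expected

    def test_interior_dip_tolerated_when_means_stay_high(self):
        # splits: [10]/[2,10] means (10, 6); [10,2]/[10] means (6, 10)
        assert is_irreducible([10, 2, 10], 5)

    def test_weak_suffix_breaks_irreducibility(self):
        assert not is_irreducible([10, 2], 5)  # right part of the split: mean 2

    def test_strict_mode_rejects_equality(self):
        assert is_irreducible([5, 5, 5], 5)
        assert not is_irreducible([5, 5, 5], 5, strict=True)
        assert is_irreducible([6, 6], 5, strict=True)

    def test_empty_vector_is_domain_error(self):
        with pytest.raises(DomainError):
            is_irreducible([], 5)

    def test_matches_explicit_split_enumeration(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            v = rng.poisson(4, rng.integers(1, 12)).astype(float)
            mu = float(rng.choice([2, 4, 5]))
            if len(v) == 1:
                by_splits = v[0] >= mu
            else:
                by_splits = all(
                    v[:k].mean() >= mu and v[k:].mean() >= mu
                    for k in range(1, len(v))
                )
            assert is_irreducible(v, mu) == bool(by_splits)


class TestFindIrreducibleRegions:
    def test_nothing_above_threshold(self):
        assert mine(np.zeros(40), 5, 1) == []

    def test_constant_vector_is_one_region(self):
        track = make_track(np.full(50, 7))
        (region,) = find_irreducible_regions(track, "s1", MiningParams(5, 10))
        assert (region.interval.start, region.interval.end) == (0, 50)
        assert region.mean_value == pytest.approx(7.0)

    def test_worked_example_with_width_filter(self):
        assert mine([10, 2, 10, 0, 0, 8], 5, 1) == [(0, 3), (5, 6)]
        assert mine([10, 2, 10, 0, 0, 8], 5, 2) == [(0, 3)]

    def test_boundary_equality_is_non_strict(self):
        assert mine([5, 5, 5], 5, 1) == [(0, 3)]

    def test_track_origin_offsets_genome_coordinates(self):
        assert mine([0, 9, 9, 0], 5, 1, start=1000) == [(1001, 1003)]

    def test_unknown_sample_is_lookup_error(self):
        track = make_track([1, 2, 3])
        with pytest.raises(SampleLookupError):
            find_irreducible_regions(track, "nope", MiningParams(5, 1))

    def test_negative_values_rejected(self):
        with pytest.raises(DomainError):
            mine([3, -1, 3], 2, 1)


class TestOracleEquivalence:
    @pytest.mark.parametrize("mu", [2.0, 5.0, 10.0])
    @pytest.mark.parametrize("dist", ["poisson", "nb"])
    def test_fast_miner_equals_brute_force(self, mu, dist):
        rng = np.random.default_rng(int(mu) * 100 + len(dist))
        for _ in range(60):
            n = int(rng.integers(1, 120))
            if dist == "poisson":
                v = rng.poisson(3, n).astype(float)
            else:
                v = rng.negative_binomial(2, 0.3, n).astype(float)
            for minsup in (1, 5, 25):
                for strict in (False, True):
                    assert mine(v, mu, minsup, strict) == brute(v, mu, minsup, strict)

    def test_fractional_values_after_smoothing_also_agree(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            v = rng.gamma(2.0, 2.0, int(rng.integers(1, 80)))
            assert mine(v, 3.5, 3) == brute(v, 3.5, 3)

    def test_oracle_refuses_oversized_input(self):
        with pytest.raises(ConfigurationError):
            brute_force_regions(np.ones(20_000), MiningParams(1, 1))


def _assert_region_invariants(values, regions, params):
    values = np.asarray(values, float)
    prev_end = -1
    for r in regions:
        s, e = r.interval.start, r.interval.end
        seg = values[s:e]
        assert e - s >= params.minsup
        assert seg.mean() >= params.mu - 1e-9
        assert seg[0] >= params.mu and seg[-1] >= params.mu
        assert is_irreducible(seg, params.mu, params.strict)
        # one-position extensions are not irreducible (maximality)
        if s > 0:
            assert not is_irreducible(values[s - 1 : e], params.mu, params.strict)
        if e < len(values):
            assert not is_irreducible(values[s : e + 1], params.mu, params.strict)
        assert s > prev_end  # sorted and pairwise disjoint
        prev_end = e


class TestMiningInvariants:
    @given(
        v=st.lists(st.integers(0, 20), min_size=1, max_size=80),
        mu=st.sampled_from([1.0, 3.0, 5.0, 8.0]),
        minsup=st.sampled_from([1, 3, 10]),
        strict=st.booleans(),
    )
    @settings(max_examples=300, deadline=None, derandomize=True)
    def test_every_mined_region_satisfies_the_contract(self, v, mu, minsup, strict):
        values = np.asarray(v, float)
        params = MiningParams(mu, minsup, strict)
        track = make_track(values)
        regions = find_irreducible_regions(track, "s1", params)
        _assert_region_invariants(values, regions, params)

    def test_minsup_filters_after_maximality(self):
        # the long region [0,3) subsumes [0,1) and [2,3); with minsup=2 the
        # short fragments must not reappear to satisfy the width condition
        assert mine([10, 2, 10, 0, 0, 8], 5, 2) == [(0, 3)]
        assert mine([10, 2, 10, 0, 0, 8], 8, 2) == []


class TestPublishedBehaviours:
    def test_single_interior_dip_does_not_split_the_region(self):
        # a high block whose coverage occasionally drops below mu keeps
        # the property of irreducibility: one region, not two
        v = np.full(60, 20.0)
        v[30] = 3.0
        assert mine(v, 11, 5) == [(0, 60)]

    def test_isolated_spike_fails_the_width_condition(self):
        v = np.zeros(100)
        v[50] = 500.0
        assert mine(v, 5, 2) == []
        assert mine(v, 5, 1) == [(50, 51)]

    def test_region_boundaries_start_and_end_above_mu(self):
        rng = np.random.default_rng(23)
        v = rng.poisson(6, 300).astype(float)
        params = MiningParams(5, 3)
        for r in find_irreducible_regions(make_track(v), "s1", params):
            assert v[r.interval.start] >= 5 and v[r.interval.end - 1] >= 5

    def test_runtime_grows_roughly_linearly(self):
        import time

        base = np.tile(np.r_[np.full(30, 9.0), np.zeros(20)], 200)  # n = 10k
        big = np.tile(base, 10)  # n = 100k, same shape
        t0 = time.perf_counter()
        maximal_irreducible_intervals(base, 5.0)
        t1 = time.perf_counter()
        maximal_irreducible_intervals(big, 5.0)
        t2 = time.perf_counter()
        assert (t2 - t1) <= 20 * (t1 - t0) + 0.05


class TestRegionBasedCoverage:
    def test_constant_vector_takes_highest_supported_level(self):
        track = make_track(np.full(20, 12))
        out = region_based_coverage(track, "s1", [5, 10, 15], 1)
        assert np.array_equal(out.values[0], np.full(20, 10.0))

    def test_zero_vector_stays_zero(self):
        track = make_track(np.zeros(30))
        out = region_based_coverage(track, "s1", [2, 4], 1)
        assert not out.values.any()

    def test_worked_ladder_example(self):
        track = make_track([10, 2, 10, 0, 0, 8])
        out = region_based_coverage(track, "s1", [5, 8], 1)
        assert out.values[0].tolist() == [8, 5, 8, 0, 0, 8]

    def test_values_come_from_ladder_and_removing_levels_never_raises_output(self):
        rng = np.random.default_rng(9)
        ladder = [2.0, 5.0, 9.0]
        for _ in range(25):
            v = rng.poisson(5, int(rng.integers(5, 120)))
            track = make_track(v)
            full = region_based_coverage(track, "s1", ladder, 3).values[0]
            assert set(np.unique(full)) <= set(ladder) | {0.0}
            for drop in range(3):
                sub = [m for i, m in enumerate(ladder) if i != drop]
                reduced = region_based_coverage(track, "s1", sub, 3).values[0]
                assert np.all(reduced <= full)

    @pytest.mark.parametrize("ladder", [[], [5, 3], [0, 5], [-1, 5]])
    def test_bad_ladder_rejected(self, ladder):
        with pytest.raises(ConfigurationError):
            region_based_coverage(make_track([1, 2]), "s1", ladder, 1)


class TestSupportFilter:
    def _regions(self, *spans):
        params = MiningParams(5, 1)
        return [
            IrreducibleRegion(GenomicInterval("chr1", s, e, "+"), 9.0, params)
            for s, e in spans
        ]

    def test_no_regions_means_no_support(self):
        gene = GenomicInterval("chr1", 0, 100, "+")
        per_sample = {f"s{i}": [] for i in range(6)}
        assert not support_filter(per_sample, gene, 1)

    def test_threshold_sweeps_across_sample_counts(self):
        gene = GenomicInterval("chr1", 100, 200, "+")
        per_sample = {
            "s1": self._regions((120, 160)),
            "s2": self._regions((150, 260)),
            "s3": self._regions((10, 90)),  # does not overlap the gene
            "s4": self._regions((199, 210)),
            "s5": [],
            "s6": self._regions((100, 110), (150, 155)),  # counts once
        }
        assert support_count(per_sample, gene) == 4
        for k in (1, 2, 3, 4):
            assert support_filter(per_sample, gene, k)
        for k in (5, 6):
            assert not support_filter(per_sample, gene, k)

    def test_min_samples_must_be_positive(self):
        with pytest.raises(ConfigurationError):
            support_filter({}, GenomicInterval("chr1", 0, 1), 0)


class TestMuResolvers:
    def test_fixed(self):
        assert fixed_mu(7.5)(np.arange(10)) == 7.5

    def test_fraction_of_extrema_use_current_slice(self):
        v = np.array([2.0, 10.0, 4.0])
        assert fraction_of_max(0.5)(v) == 5.0
        assert fraction_of_min(2.0)(v) == 4.0

    def test_bad_fractions_rejected(self):
        with pytest.raises(ConfigurationError):
            fraction_of_max(0.0)
        with pytest.raises(ConfigurationError):
            fraction_of_min(-1.0)
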