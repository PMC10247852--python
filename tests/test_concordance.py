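"""Concordance classification, matched-pair summaries, ladders and Venn counts."""

import numpy as np
import pytest

from ffpewes.concordance import (
    build_ladder,
    compare_callsets,
    concordance_from_counts,
    coverage_intersect,
    matched_pair_summary,
    round_half_up,
    stratified_concordance,
    venn_partition,
)
from ffpewes.core import CallSet, CoverageTrack, GenomicInterval, RegionSet, VariantCall, VariantKey

from conftest import mask_of, random_regionset, regions_from_mask


def key(pos):
    return VariantKey("chr1", pos, "A", "G")


def callset(keys, sample="s", material="ffpe"):
    cs = CallSet(sample, material, "ensemble")
    for k in keys:
        cs.add(VariantCall(k, callers=frozenset(["ensemble"])))
    return cs


TARGET = RegionSet("target", [GenomicInterval("chr1", 0, 10_000)])


class TestCompareCallsets:
    def test_identical_sets_are_perfect(self, rng):
        keys = {key(int(p)) for p in rng.integers(1, 9000, size=60)}
        r = compare_callsets(callset(keys, "t", "truth"), callset(keys), TARGET)
        assert (r.tp, r.fp, r.fn) == (len(keys), 0, 0)
        assert r.sensitivity == 1.0 and r.ppv == 1.0

    def test_random_sets_match_set_oracle(self, rng):
        for _ in range(40):
            truth_keys = {key(int(p)) for p in rng.integers(1, 9000, size=50)}
            test_keys = {key(int(p)) for p in rng.integers(1, 9000, size=50)}
            r = compare_callsets(
                callset(truth_keys, "t", "truth"), callset(test_keys), TARGET
            )
            assert r.tp == len(truth_keys & test_keys)
            assert r.fn == len(truth_keys - test_keys)
            assert r.fp == len(test_keys - truth_keys)
            # count identities hold on every comparison
            assert r.tp + r.fn == len(truth_keys)
            assert r.tp + r.fp == len(test_keys)

    def test_region_restriction_never_increases_counts(self, rng):
        truth_keys = {key(int(p)) for p in rng.integers(1, 9000, size=80)}
        test_keys = {key(int(p)) for p in rng.integers(1, 9000, size=80)}
        t, s = callset(truth_keys, "t", "truth"), callset(test_keys)
        full = compare_callsets(t, s, TARGET)
        for _ in range(10):
            sub = random_regionset(rng, n=10)
            r = compare_callsets(t, s, sub)
            assert r.tp <= full.tp and r.fp <= full.fp and r.fn <= full.fn

    def test_zero_denominators_are_missing_not_zero(self):
        r = compare_callsets(callset([], "t", "truth"), callset([]), TARGET)
        assert r.sensitivity is None and r.ppv is None

    def test_planted_labels_recovered_exactly(self, rng):
        # construct a comparison with known per-variant classes
        tp = {key(int(p)) for p in rng.integers(1, 3000, size=30)}
        fn = {key(int(p)) for p in rng.integers(3001, 6000, size=10)}
        fp = {key(int(p)) for p in rng.integers(6001, 9000, size=20)}
        r = compare_callsets(callset(tp | fn, "t", "truth"), callset(tp | fp), TARGET)
        assert (r.tp, r.fn, r.fp) == (len(tp), len(fn), len(fp))


class TestFromCounts:
    def test_overlap_cannot_exceed_sizes(self):
        with pytest.raises(ValueError):
            concordance_from_counts(10, 10, 11)

    def test_ratio_arithmetic(self):
        r = concordance_from_counts(100, 120, 90)
        assert (r.fn, r.fp) == (10, 30)
        assert r.sensitivity == pytest.approx(0.9)
        assert r.ppv == pytest.approx(0.75)


class TestMatchedSummary:
    def test_single_result_is_its_own_mean(self):
        r = concordance_from_counts(100, 110, 95)
        s = matched_pair_summary([r])
        assert s.mean["tp"] == 95 and s.minimum["fp"] == s.maximum["fp"] == 15

    def test_thirteen_synthetic_results_match_manual_means(self, rng):
        results = [
            concordance_from_counts(
                int(rng.integers(900, 1100)),
                int(rng.integers(900, 1100)),
                int(rng.integers(500, 880)),
            )
            for _ in range(13)
        ]
        s = matched_pair_summary(results)
        for f in ("tp", "fp", "fn", "sensitivity", "ppv"):
            vals = [getattr(r, f) for r in results]
            assert s.mean[f] == pytest.approx(float(np.mean(vals)))
            assert s.minimum[f] == min(vals) and s.maximum[f] == max(vals)

    def test_undefined_ratios_excluded_from_means(self):
        results = [
            concordance_from_counts(0, 10, 0),  # sensitivity undefined
            concordance_from_counts(10, 10, 10),
        ]
        s = matched_pair_summary(results)
        assert s.mean["sensitivity"] == 1.0


class TestCoverageIntersect:
    def _tracks(self, da, db):
        target = RegionSet("t", [GenomicInterval("chr1", 0, len(da))])
        return (
            CoverageTrack("a", target, da),
            CoverageTrack("b", target, db),
        )

    def test_uniform_above_threshold_keeps_whole_target(self):
        a, b = self._tracks(np.full(100, 30), np.full(100, 30))
        assert coverage_intersect(a, b, 20).total_bases == 100

    def test_one_empty_track_gives_empty_set(self):
        a, b = self._tracks(np.full(100, 30), np.zeros(100, dtype=int))
        assert coverage_intersect(a, b, 20).total_bases == 0

    def test_random_tracks_match_mask_oracle(self, rng):
        for _ in range(25):
            da = rng.integers(0, 40, size=200)
            db = rng.integers(0, 40, size=200)
            a, b = self._tracks(da, db)
            got = coverage_intersect(a, b, 20)
            want = regions_from_mask(
                {"chr1": (da >= 20) & (db >= 20), "chr2": np.zeros(1, dtype=bool)}
            )
            assert got.intervals == want.intervals

    def test_mismatched_targets_raise(self):
        a = CoverageTrack("a", RegionSet("t1", [GenomicInterval("chr1", 0, 10)]), np.zeros(10, dtype=int))
        b = CoverageTrack("b", RegionSet("t2", [GenomicInterval("chr1", 5, 15)]), np.zeros(10, dtype=int))
        with pytest.raises(ValueError):
            coverage_intersect(a, b, 20)


class TestStratified:
    def test_target_only_ladder_equals_plain_comparison(self, rng):
        truth_keys = {key(int(p)) for p in rng.integers(1, 9000, size=40)}
        test_keys = {key(int(p)) for p in rng.integers(1, 9000, size=40)}
        t, s = callset(truth_keys, "t", "truth"), callset(test_keys)
        [r] = stratified_concordance(t, s, [("target", TARGET)])
        plain = compare_callsets(t, s, TARGET)
        assert (r.tp, r.fp, r.fn) == (plain.tp, plain.fp, plain.fn)

    def test_planted_errors_vanish_when_their_region_is_excluded(self):
        bad = RegionSet("bad", [GenomicInterval("chr1", 1000, 2000)])
        tp = {key(p) for p in range(3000, 3030)}
        fn = {key(p) for p in range(1100, 1110)}  # planted inside bad
        fp = {key(p) for p in range(1200, 1220)}
        t, s = callset(tp | fn, "t", "truth"), callset(tp | fp)
        ladder = build_ladder(TARGET, exclude=[bad])
        raw, cleaned = stratified_concordance(t, s, ladder)
        assert raw.fp == 20 and raw.fn == 10
        assert cleaned.fp == 0 and cleaned.fn == 0
        assert cleaned.tp == 30

    def test_exclusion_rungs_never_increase_discordance(self, rng):
        truth_keys = {key(int(p)) for p in rng.integers(1, 9000, size=200)}
        test_keys = {key(int(p)) for p in rng.integers(1, 9000, size=200)}
        t, s = callset(truth_keys, "t", "truth"), callset(test_keys)
        ladder = build_ladder(
            TARGET, exclude=[random_regionset(rng, n=8) for _ in range(4)]
        )
        results = stratified_concordance(t, s, ladder)
        for prev, cur in zip(results, results[1:]):
            assert cur.fp + cur.fn <= prev.fp + prev.fn


class TestVenn:
    def test_identical_sets_fill_only_triple_class(self, rng):
        keys = {key(int(p)) for p in rng.integers(1, 9000, size=30)}
        counts = venn_partition(
            callset(keys, "a"), callset(keys, "b"), callset(keys, "c")
        )
        assert counts["abc"] == len(keys)
        assert sum(v for k, v in counts.items() if k != "abc") == 0

    def test_pairwise_disjoint_sets(self):
        counts = venn_partition(
            callset({key(1)}, "a"), callset({key(2)}, "b"), callset({key(3)}, "c")
        )
        assert (counts["a_only"], counts["b_only"], counts["c_only"]) == (1, 1, 1)
        assert counts["abc"] == 0

    def test_classes_sum_to_union_inclusion_exclusion(self, rng):
        for _ in range(20):
            sets = [
                {key(int(p)) for p in rng.integers(1, 400, size=60)} for _ in range(3)
            ]
            counts = venn_partition(
                callset(sets[0], "a"), callset(sets[1], "b"), callset(sets[2], "c")
            )
            assert sum(counts.values()) == len(sets[0] | sets[1] | sets[2])
            # inclusion-exclusion on the triple overlap
            a, b, c = (len(s) for s in sets)
            ab, ac, bc = (
                len(sets[0] & sets[1]),
                len(sets[0] & sets[2]),
                len(sets[1] & sets[2]),
            )
            abc = len(sets[0] & sets[1] & sets[2])
            assert sum(counts.values()) == a + b + c - ab - ac - bc + abc


def test_round_half_up_matches_report_convention():
    assert round_half_up(0.9765, 2) == 0.98
    assert round_half_up(0.99937, 3) == 0.999
    assert round_half_up(0.0005, 3) == 0.001  # half goes up, not to even
    assert round_half_up(29.1667, 0) == 29.0
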