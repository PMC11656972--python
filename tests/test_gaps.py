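import numpy as np
import pytest

from covgap.gaps import (
    BiasUndefinedError,
    CoverageGap,
    GapParams,
    bias_score,
    detect_gaps,
    extract_sequences,
    filter_by_length,
    gap_bias,
    merge_gaps,
)
from covgap.io_formats import ContigSet, DepthTrack, GenomicInterval


def _track(*arrays, names=None):
    names = names or [f"c{i+1}" for i in range(len(arrays))]
    return DepthTrack({n: np.array(a) for n, a in zip(names, arrays)})


class TestDetectGaps:
    def test_single_interior_run(self):
        ivs = detect_gaps(_track([3, 3, 0, 0, 0, 3]), 0)
        assert ivs == [GenomicInterval("c1", 2, 5)]

    def test_all_positive_depth_no_gaps(self):
        assert detect_gaps(_track([1, 2, 3, 4]), 0) == []

    def test_adjacent_runs_stay_separate(self):
        ivs = detect_gaps(_track([0, 0, 1, 0]), 0)
        assert ivs == [GenomicInterval("c1", 0, 2), GenomicInterval("c1", 3, 4)]

    def test_threshold_is_inclusive(self):
        ivs = detect_gaps(_track([5, 2, 2, 5]), 2)
        assert ivs == [GenomicInterval("c1", 1, 3)]

    def test_brute_force_oracle_equivalence(self):
        """detect_gaps equals a per-position scan on 1000 random depth arrays."""
        rng = np.random.default_rng(123)
        for _ in range(1000):
            n = int(rng.integers(1, 60))
            depth = rng.integers(0, 3, size=n)
            threshold = int(rng.integers(0, 2))
            got = detect_gaps(_track(depth), threshold)
            # oracle: walk positions, open/close runs
            expected = []
            start = None
            for i, d in enumerate(depth):
                if d <= threshold and start is None:
                    start = i
                elif d > threshold and start is not None:
                    expected.append(GenomicInterval("c1", start, i))
                    start = None
            if start is not None:
                expected.append(GenomicInterval("c1", start, n))
            assert got == expected

    def test_conservation_every_low_position_in_exactly_one_gap(self):
        rng = np.random.default_rng(7)
        depth = rng.integers(0, 2, size=500)
        gaps = detect_gaps(_track(depth), 0)
        member_of = np.zeros(500, dtype=int)
        for iv in gaps:
            member_of[iv.start : iv.end] += 1
        assert np.array_equal(member_of == 1, depth == 0)


class TestMergeGaps:
    def test_merge_within_distance(self):
        ivs = [GenomicInterval("c", 2, 5), GenomicInterval("c", 6, 9)]
        assert merge_gaps(ivs, 1) == [GenomicInterval("c", 2, 9)]

    def test_separation_above_d_not_merged(self):
        ivs = [GenomicInterval("c", 2, 5), GenomicInterval("c", 6, 9)]
        assert merge_gaps(ivs, 0) == ivs

    def test_touching_intervals_merge_at_d0(self):
        ivs = [GenomicInterval("c", 0, 3), GenomicInterval("c", 3, 6)]
        assert merge_gaps(ivs, 0) == [GenomicInterval("c", 0, 6)]

    def test_different_contigs_never_merge(self):
        ivs = [GenomicInterval("a", 0, 5), GenomicInterval("b", 5, 9)]
        assert merge_gaps(ivs, 1000) == ivs

    def test_unsorted_input_rejected(self):
        ivs = [GenomicInterval("c", 10, 20), GenomicInterval("c", 0, 5)]
        with pytest.raises(ValueError, match="sorted"):
            merge_gaps(ivs, 0)

    def test_idempotent_and_monotone_in_d(self):
        rng = np.random.default_rng(99)
        for _ in range(50):
            pos = np.sort(rng.choice(300, size=20, replace=False))
            ivs = [
                GenomicInterval("c", int(s), int(e))
                for s, e in zip(pos[0::2], pos[1::2])
            ]
            d1, d2 = sorted(rng.integers(0, 40, size=2))
            m1, m2 = merge_gaps(ivs, int(d1)), merge_gaps(ivs, int(d2))
            assert merge_gaps(m1, int(d1)) == m1  # idempotent
            # monotone: every d1-gap lies inside some d2-gap
            for iv in m1:
                assert any(
                    o.start <= iv.start and iv.end <= o.end for o in m2
                )
            assert len(m2) <= len(m1)


class TestFilterByLength:
    def test_min_length_is_inclusive(self):
        ivs = [GenomicInterval("c", 0, 999), GenomicInterval("c", 2000, 3000)]
        assert filter_by_length(ivs, 1000) == [GenomicInterval("c", 2000, 3000)]

    def test_exact_1000bp_gap_retained(self):
        ivs = [GenomicInterval("c", 0, 1000)]
        assert filter_by_length(ivs, 1000) == ivs

    def test_empty_input(self):
        assert filter_by_length([], 1000) == []


class TestBias:
    def test_unbiased_flanks_score_zero(self):
        assert bias_score(10.0, 10.0) == 0.0

    def test_zero_flank_coverage_scores_minus_one(self):
        assert bias_score(0.0, 10.0) == -1.0

    def test_triple_coverage_scores_half(self):
        assert bias_score(30.0, 10.0) == 0.5

    def test_undefined_when_no_reads(self):
        with pytest.raises(BiasUndefinedError):
            bias_score(0.0, 0.0)

    def test_bounded_and_monotone_on_random_pairs(self):
        rng = np.random.default_rng(5)
        f = rng.uniform(0, 100, size=10_000)
        g = rng.uniform(1e-6, 100, size=10_000)
        scores = np.array([bias_score(fi, gi) for fi, gi in zip(f, g)])
        assert (scores >= -1).all() and (scores <= 1).all()
        # equals 0 iff f == g
        assert np.allclose(scores[np.isclose(f, g)], 0.0)
        # strictly increasing in f at fixed g
        fs = np.linspace(0, 50, 200)
        vals = [bias_score(x, 10.0) for x in fs]
        assert all(a < b for a, b in zip(vals, vals[1:]))

    def test_gap_bias_uses_flanks_truncated_at_ends(self):
        depth = np.concatenate([np.full(50, 6), np.zeros(20), np.full(30, 6)])
        track = _track(depth)
        bias, f = gap_bias(GenomicInterval("c1", 50, 70), track, flank=100)
        assert f == 6.0  # windows truncated to the 80 covered positions
        g = track.genome_mean
        assert bias == pytest.approx(2 * 6 / (g + 6) - 1)


class TestExtract:
    def test_hand_slice(self):
        contigs = ContigSet([("c", "AACGTTT")])
        gaps = extract_sequences([GenomicInterval("c", 2, 5)], contigs)
        assert gaps[0].sequence == "CGT"

    def test_full_contig_gap(self):
        contigs = ContigSet([("c", "AACGTTT")])
        gaps = extract_sequences([GenomicInterval("c", 0, 7)], contigs)
        assert gaps[0].sequence == "AACGTTT"

    def test_out_of_bounds_rejected(self):
        contigs = ContigSet([("c", "AACGTTT")])
        with pytest.raises(ValueError, match="exceeds"):
            extract_sequences([GenomicInterval("c", 2, 50)], contigs)

    def test_bed_sorted_order_and_bias_attached(self):
        contigs = ContigSet([("c", "A" * 100)])
        track = _track(np.concatenate([np.zeros(10), np.full(90, 4)]))
        gaps = extract_sequences(
            [GenomicInterval("c1", 40, 50), GenomicInterval("c1", 0, 10)],
            ContigSet([("c1", "A" * 100)]),
            depth=track,
        )
        assert [g.interval.start for g in gaps] == [0, 40]
        assert all(g.bias is not None for g in gaps)


def test_gap_params_validation():
    with pytest.raises(ValueError):
        GapParams(min_length=-1)
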