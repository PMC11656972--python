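import numpy as np
import pytest

from covgap.io_formats import ContigSet
from covgap.simulate import (
    AncientParams,
    insert_copies,
    random_sequence,
    reads_ancient,
    reads_random,
    reads_uniform,
    simulate_scenario,
)


class TestRandomSequence:
    def test_reproducible_from_seed(self):
        assert random_sequence(4, seed=5) == random_sequence(4, seed=5)
        assert random_sequence(50, seed=5) != random_sequence(50, seed=6)

    def test_gc_content_near_half(self):
        s = random_sequence(5000, seed=1)
        gc = (s.count("G") + s.count("C")) / len(s)
        assert 0.45 < gc < 0.55

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            random_sequence(0, seed=1)


class TestInsertCopies:
    def test_length_bookkeeping_single_copy(self):
        template = ContigSet([("t", random_sequence(1_000_000, seed=2))])
        modified, truth = insert_copies(template, "ACGTACGTAC", 1, seed=3)
        assert modified.total_length() == 1_000_010
        assert len(truth.loci) == 1 and len(truth.loci[0]) == 10

    def test_25_copies_of_5kb(self):
        template = ContigSet([("t", random_sequence(2_000_000, seed=4))])
        insert = random_sequence(5000, seed=5)
        modified, truth = insert_copies(template, insert, 25, seed=6)
        assert modified.total_length() == 2_000_000 + 125_000
        assert len(truth.loci) == 25

    def test_splice_inverse_restores_template(self):
        template = ContigSet([("t", random_sequence(500_000, seed=7))])
        insert = random_sequence(2000, seed=8)
        modified, truth = insert_copies(template, insert, 5, seed=9)
        seq = modified["t"]
        for iv in sorted(truth.loci, key=lambda i: -i.start):
            assert seq[iv.start : iv.end] == insert
            seq = seq[: iv.start] + seq[iv.end :]
        assert seq == template["t"]

    def test_spacing_and_margins_respected(self):
        template = ContigSet([("t", random_sequence(2_000_000, seed=10))])
        _, truth = insert_copies(template, random_sequence(5000, seed=11), 25, seed=12)
        loci = sorted(truth.loci, key=lambda iv: iv.start)
        assert loci[0].start >= 10_000
        assert loci[-1].end <= 2_125_000 - 10_000
        for a, b in zip(loci, loci[1:]):
            assert b.start - a.end >= 25_000

    def test_infeasible_spacing_rejected(self):
        template = ContigSet([("t", random_sequence(100_000, seed=13))])
        with pytest.raises(ValueError, match="spacing"):
            insert_copies(template, "ACGTACGTAC", 25, seed=14)


class TestReadsUniform:
    def test_stride_arithmetic_1x(self):
        genome = ContigSet([("c", random_sequence(1000, seed=15))])
        reads = reads_uniform(genome, coverage=1, read_length=100)
        assert len(reads) == 10
        assert reads[0].sequence == genome["c"][0:100]
        assert reads[-1].sequence == genome["c"][900:1000]

    def test_interior_positions_covered_exactly_5x(self):
        genome = ContigSet([("c", random_sequence(2000, seed=16))])
        reads = reads_uniform(genome, coverage=5, read_length=100)
        depth = np.zeros(2000)
        pos = 0
        for r in reads:
            start = genome["c"].find(r.sequence)
            depth[start : start + 100] += 1
        assert (depth[100:1900] == 5).all()

    def test_error_free_reads_are_exact_substrings(self):
        genome = ContigSet([("c", random_sequence(3000, seed=17))])
        for r in reads_uniform(genome, coverage=2, read_length=100):
            assert r.sequence in genome["c"]

    def test_errors_injected_at_requested_rate(self):
        genome = ContigSet([("c", random_sequence(50_000, seed=18))])
        reads = reads_uniform(genome, coverage=1, read_length=100,
                              error_rate=0.02, seed=19)
        mismatches = sum(
            sum(a != b for a, b in zip(r.sequence, genome["c"][i * 100 : i * 100 + 100]))
            for i, r in enumerate(reads)
        )
        rate = mismatches / (len(reads) * 100)
        assert 0.012 < rate < 0.028


class TestReadsRandom:
    def test_read_count_and_mean_depth(self):
        genome = ContigSet([("c", random_sequence(1_000_000, seed=20))])
        reads = reads_random(genome, coverage=10, read_length=100, seed=21)
        assert len(reads) == 100_000
        # mean per-position depth (total bases / genome length) within 5%
        total_bases = sum(len(r) for r in reads)
        assert abs(total_bases / 1_000_000 - 10) < 0.5

    def test_reproducible_from_seed(self):
        genome = ContigSet([("c", random_sequence(10_000, seed=22))])
        a = reads_random(genome, 2, seed=23)
        b = reads_random(genome, 2, seed=23)
        assert [r.sequence for r in a] == [r.sequence for r in b]

    def test_1x_coverage_leaves_zero_depth_positions(self):
        genome = ContigSet([("c", random_sequence(100_000, seed=24))])
        reads = reads_random(genome, coverage=1, read_length=100, seed=25)
        depth = np.zeros(100_000, dtype=int)
        for r in reads:
            start = genome["c"].find(r.sequence)
            depth[start : start + len(r)] += 1
        assert (depth == 0).sum() > 0


class TestReadsAncient:
    def test_category_proportions(self):
        genome = ContigSet([("c", random_sequence(200_000, seed=26))])
        reads = reads_ancient(genome, coverage=2, seed=27)
        n = len(reads)
        frac_b = sum(r.id.startswith("bact") for r in reads) / n
        frac_m = sum(r.id.startswith("modern") for r in reads) / n
        frac_e = sum(r.id.startswith("endo") for r in reads) / n
        assert abs(frac_b - 0.10) < 0.02
        assert abs(frac_m - 0.08) < 0.02
        assert abs(frac_e - 0.82) < 0.02

    def test_fragment_length_distribution(self):
        genome = ContigSet([("c", random_sequence(500_000, seed=28))])
        params = AncientParams()
        reads = reads_ancient(genome, coverage=1, params=params, seed=29)
        lengths = [len(r) for r in reads if r.id.startswith("endo")]
        assert len(lengths) > 5000
        assert abs(np.mean(lengths) - 50) < 2
        assert min(lengths) >= params.fragment_min
        assert max(lengths) <= params.fragment_max

    def test_no_damage_means_exact_substrings(self):
        genome = ContigSet([("c", random_sequence(50_000, seed=30))])
        params = AncientParams(deamination_p0=0.0)
        from covgap.io_formats import reverse_complement

        for r in reads_ancient(genome, coverage=0.5, params=params, seed=31):
            if not r.id.startswith("endo"):
                continue
            assert (
                r.sequence in genome["c"]
                or reverse_complement(r.sequence) in genome["c"]
            )

    def test_deamination_produces_ct_and_ga_changes(self):
        genome = ContigSet([("c", random_sequence(100_000, seed=32))])
        reads = reads_ancient(genome, coverage=1, seed=33)
        # damaged endogenous reads should no longer all be exact substrings
        from covgap.io_formats import reverse_complement

        endo = [r for r in reads if r.id.startswith("endo")][:500]
        exact = sum(
            r.sequence in genome["c"] or reverse_complement(r.sequence) in genome["c"]
            for r in endo
        )
        assert exact < len(endo)

    def test_contamination_fractions_must_sum_below_one(self):
        with pytest.raises(ValueError):
            AncientParams(frac_bacterial=0.7, frac_modern=0.4)


class TestScenario:
    def test_scenario_reproducible(self):
        a = simulate_scenario(coverage=1, seed=1, template_length=100_000, n_copies=2,
                              insert_length=2000)
        b = simulate_scenario(coverage=1, seed=1, template_length=100_000, n_copies=2,
                              insert_length=2000)
        assert a.modified == b.modified
        assert [r.sequence for r in a.reads] == [r.sequence for r in b.reads]

    def test_read_seed_decouples_reads_from_genome(self):
        a = simulate_scenario(mode="random", coverage=1, seed=1,
                              template_length=100_000, n_copies=2,
                              insert_length=2000, read_seed=5)
        b = simulate_scenario(mode="random", coverage=1, seed=1,
                              template_length=100_000, n_copies=2,
                              insert_length=2000, read_seed=6)
        assert a.modified == b.modified
        assert [r.sequence for r in a.reads] != [r.sequence for r in b.reads]
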