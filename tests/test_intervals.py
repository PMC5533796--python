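"""Interval data model, I/O round-trips, and peak-set algebra vs per-base oracles."""

import numpy as np
import pytest

from peaklink.intervals import (
    GenomeModel,
    GenomicInterval,
    PeakSet,
    classify_multiway,
    consensus_peaks,
    intersect_sets,
    read_chrom_sizes,
    read_intervals,
    subtract_peaks,
    write_intervals,
)

from conftest import (
    oracle_intersect_pairs,
    oracle_overlaps_set,
    random_peakset,
)


class TestDataModel:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"chrom": "chr1", "start": 10, "end": 10},
            {"chrom": "chr1", "start": 20, "end": 10},
            {"chrom": "chr1", "start": -1, "end": 10},
            {"chrom": "", "start": 0, "end": 10},
            {"chrom": "chr1", "start": 0, "end": 10, "q_value": 0.0},
            {"chrom": "chr1", "start": 0, "end": 10, "q_value": 1.5},
            {"chrom": "chr1", "start": 0, "end": 10, "strand": "x"},
        ],
    )
    def test_invalid_interval_rejected(self, kwargs):
        with pytest.raises(ValueError):
            GenomicInterval(**kwargs)

    def test_duplicates_rejected_by_default(self):
        ivs = [GenomicInterval("chr1", 0, 10), GenomicInterval("chr1", 0, 10)]
        with pytest.raises(ValueError, match="duplicate"):
            PeakSet("x", ivs)
        assert len(PeakSet("x", ivs, allow_duplicates=True)) == 2

    def test_out_of_bounds_interval_rejected(self, toy_genome):
        with pytest.raises(ValueError, match="exceeds"):
            PeakSet("x", [GenomicInterval("chr1", 0, 200_000)], toy_genome)
        with pytest.raises(ValueError, match="unknown chromosome"):
            PeakSet("x", [GenomicInterval("chrX", 0, 10)], toy_genome)


class TestIO:
    def test_bed_line_maps_to_interval(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t100\t200\n")
        ps = read_intervals(p, dialect="bed")
        assert len(ps) == 1
        assert ps[0].key() == ("chr1", 100, 200)

    def test_narrowpeak_q_converted_to_linear(self, tmp_path):
        p = tmp_path / "a.narrowPeak"
        p.write_text("chr1\t0\t100\tpk1\t0\t.\t7.5\t-1\t5.0\t50\n")
        iv = read_intervals(p, dialect="narrowPeak")[0]
        assert iv.q_value == pytest.approx(1e-5)
        assert iv.score == 7.5

    def test_dedup_flag_collapses_duplicates(self, tmp_path):
        # expected unique line count computed by brute-force set comparison
        lines = ["chr1\t0\t10", "chr1\t5\t20", "chr1\t0\t10"]
        expected = len({tuple(l.split("\t")) for l in lines})
        p = tmp_path / "a.bed"
        p.write_text("\n".join(lines) + "\n")
        assert len(read_intervals(p, dedup=True)) == expected == 2
        with pytest.raises(ValueError, match="duplicate"):
            read_intervals(p)

    @pytest.mark.parametrize(
        "content,match",
        [
            ("chr1\t50\t20\n", ":1"),          # start >= end, line number named
            ("chr1\t0\n", ":1"),               # too few columns
            ("chr1\t0\t10\n" + "chr1\tx\t20\n", ":2"),
        ],
    )
    def test_malformed_line_names_line_number(self, tmp_path, content, match):
        p = tmp_path / "bad.bed"
        p.write_text(content)
        with pytest.raises(ValueError, match=match):
            read_intervals(p)

    def test_unknown_chromosome_with_genome(self, tmp_path, toy_genome):
        p = tmp_path / "a.bed"
        p.write_text("chrZ\t0\t10\n")
        with pytest.raises(ValueError, match="unknown chromosome"):
            read_intervals(p, genome=toy_genome)

    @pytest.mark.parametrize("dialect", ["bed", "narrowPeak"])
    def test_round_trip_bit_exact(self, tmp_path, dialect):
        rng = np.random.default_rng(0)
        ivs = [
            GenomicInterval(
                "chr1",
                int(s),
                int(s) + int(rng.integers(1, 500)),
                name=f"pk{i}",
                score=float(rng.uniform(0, 100)),
                q_value=float(10.0 ** -rng.uniform(0.5, 12)) if dialect == "narrowPeak" else None,
                strand="+",
            )
            for i, s in enumerate(rng.integers(0, 10_000, size=30))
        ]
        ps = PeakSet("rt", ivs, allow_duplicates=True)
        p = tmp_path / f"rt.{dialect}"
        write_intervals(ps, p, dialect=dialect)
        back = read_intervals(p, dialect=dialect)
        for orig, rec in zip(ps, back):
            assert rec.key() == orig.key()
            assert rec.name == orig.name
            assert rec.score == orig.score
            if dialect == "narrowPeak":
                assert rec.q_value == pytest.approx(orig.q_value, rel=1e-12)

    def test_chrom_sizes_reader(self, tmp_path):
        p = tmp_path / "g.sizes"
        p.write_text("chr1\t1000\nchr2\t500\n")
        g = read_chrom_sizes(p)
        assert g.chromosomes == {"chr1": 1000, "chr2": 500}


class TestIntersect:
    def test_disjoint_empty(self):
        a = PeakSet("a", [GenomicInterval("chr1", 0, 100)])
        b = PeakSet("b", [GenomicInterval("chr1", 200, 300)])
        assert intersect_sets(a, b).empty

    def test_half_overlap_arithmetic(self):
        a = PeakSet("a", [GenomicInterval("chr1", 0, 100)])
        b = PeakSet("b", [GenomicInterval("chr1", 50, 150)])
        t = intersect_sets(a, b)
        assert len(t) == 1
        assert t.loc[0, "overlap_bp"] == 50
        assert t.loc[0, "fraction_a"] == 0.5

    def test_mismatched_genomes_error(self, toy_genome):
        other = GenomeModel({"chr1": 50_000})
        a = PeakSet("a", [GenomicInterval("chr1", 0, 10)], toy_genome)
        b = PeakSet("b", [GenomicInterval("chr1", 0, 10)], other)
        with pytest.raises(ValueError, match="different genomes"):
            intersect_sets(a, b)

    def test_symmetry_of_overlap_bp(self, toy_genome):
        rng = np.random.default_rng(1)
        a = random_peakset(rng, toy_genome, 60, label="a")
        b = random_peakset(rng, toy_genome, 60, label="b")
        ab = intersect_sets(a, b)
        ba = intersect_sets(b, a)
        assert {(r.a_index, r.b_index, r.overlap_bp) for r in ab.itertuples()} == {
            (r.b_index, r.a_index, r.overlap_bp) for r in ba.itertuples()
        }

    def test_matches_per_base_oracle_on_random_sets(self):
        genome = GenomeModel({"chr1": 10_000})
        rng = np.random.default_rng(2)
        a = random_peakset(rng, genome, 100, max_len=300, label="a")
        b = random_peakset(rng, genome, 100, max_len=300, label="b")
        got = {
            (r.a_index, r.b_index, r.overlap_bp)
            for r in intersect_sets(a, b).itertuples()
        }
        assert got == oracle_intersect_pairs(a, b, 1)


class TestConsensus:
    def test_identical_replicates_identity(self, toy_genome):
        rng = np.random.default_rng(3)
        a = random_peakset(rng, toy_genome, 20)
        cons = consensus_peaks([a, a])
        assert [iv.key() for iv in cons] == [iv.key() for iv in a]

    def test_empty_replicate_vacuous(self, toy_genome):
        rng = np.random.default_rng(3)
        a = random_peakset(rng, toy_genome, 20)
        empty = PeakSet("e", [], toy_genome)
        assert len(consensus_peaks([a, empty])) == 0

    def test_single_replicate_error(self, toy_genome):
        a = random_peakset(np.random.default_rng(3), toy_genome, 5)
        with pytest.raises(ValueError, match=">= 2 replicates"):
            consensus_peaks([a])

    def test_three_replicates_match_allpairs_oracle(self):
        genome = GenomeModel({"chr1": 20_000})
        rng = np.random.default_rng(4)
        reps = [random_peakset(rng, genome, 40, max_len=400, label=f"r{i}") for i in range(3)]
        cons = consensus_peaks(reps, min_bp=5)
        expected = [
            iv for iv in reps[0]
            if all(oracle_overlaps_set(iv, other, 5) for other in reps[1:])
        ]
        assert [iv.key() for iv in cons] == [iv.key() for iv in expected]


class TestSubtract:
    def test_empty_background_unchanged(self, toy_genome):
        a = random_peakset(np.random.default_rng(5), toy_genome, 15)
        out = subtract_peaks(a, PeakSet("e", [], toy_genome))
        assert [iv.key() for iv in out] == [iv.key() for iv in a]

    def test_self_subtraction_empty(self, toy_genome):
        a = random_peakset(np.random.default_rng(5), toy_genome, 15)
        assert len(subtract_peaks(a, a)) == 0

    def test_partition_invariant(self, toy_genome):
        rng = np.random.default_rng(6)
        a = random_peakset(rng, toy_genome, 40, label="a")
        b = random_peakset(rng, toy_genome, 40, label="b")
        kept = subtract_peaks(a, b)
        removed = [iv for iv in a if oracle_overlaps_set(iv, b, 1)]
        assert sorted(
            [iv.key() for iv in kept] + [iv.key() for iv in removed]
        ) == sorted(iv.key() for iv in a)


class TestClassifyMultiway:
    def test_identical_sets_all_shared(self, toy_genome):
        a = random_peakset(np.random.default_rng(7), toy_genome, 10, label="a")
        cats = classify_multiway([a, a.with_label("b"), a.with_label("c")])
        assert len(cats["shared_with_all"]) == len(a)
        assert all(len(cats[k]) == 0 for k in cats if k != "shared_with_all")

    def test_disjoint_sets_all_unique(self):
        a = PeakSet("a", [GenomicInterval("chr1", 0, 10)])
        b = PeakSet("b", [GenomicInterval("chr1", 100, 110)])
        c = PeakSet("c", [GenomicInterval("chr1", 200, 210)])
        cats = classify_multiway([a, b, c])
        assert len(cats["unique"]) == 1

    def test_too_many_sets_error(self, toy_genome):
        sets = [random_peakset(np.random.default_rng(i), toy_genome, 3, label=str(i))
                for i in range(4)]
        with pytest.raises(ValueError, match="2 or 3"):
            classify_multiway(sets)

    def test_categories_partition_first_set_vs_oracle(self):
        genome = GenomeModel({"chr1": 30_000})
        rng = np.random.default_rng(8)
        a = random_peakset(rng, genome, 50, max_len=500, label="a")
        b = random_peakset(rng, genome, 50, max_len=500, label="b")
        c = random_peakset(rng, genome, 50, max_len=500, label="c")
        cats = classify_multiway([a, b, c], min_bp=1)
        # partition: disjoint categories, union == a
        all_keys = [iv.key() for ps in cats.values() for iv in ps]
        assert sorted(all_keys) == sorted(iv.key() for iv in a)
        # each assignment matches the per-base oracle
        for iv in a:
            in_b = oracle_overlaps_set(iv, b, 1)
            in_c = oracle_overlaps_set(iv, c, 1)
            expected = (
                "shared_with_all" if in_b and in_c
                else "shared_with_b" if in_b
                else "shared_with_c" if in_c
                else "unique"
            )
            assert iv in cats[expected].intervals


def test_all_operations_agree_with_perbase_oracle_randomized():
    """Randomized property: algebra ops equal the per-base oracle."""
    for trial in range(25):
        rng = np.random.default_rng(100 + trial)
        genome = GenomeModel({"chr1": int(rng.integers(5_000, 50_000))})
        min_bp = int(rng.integers(1, 30))
        a = random_peakset(rng, genome, int(rng.integers(5, 40)), max_len=800, label="a")
        b = random_peakset(rng, genome, int(rng.integers(5, 40)), max_len=800, label="b")
        got = {(r.a_index, r.b_index, r.overlap_bp)
               for r in intersect_sets(a, b, min_bp=min_bp).itertuples()}
        assert got == oracle_intersect_pairs(a, b, min_bp)
        kept = subtract_peaks(a, b, min_bp=min_bp)
        expected = [iv for iv in a if not oracle_overlaps_set(iv, b, min_bp)]
        assert [iv.key() for iv in kept] == [iv.key() for iv in expected]
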