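"""Random-region sampling, empirical overlap p-values, Yates chi-square,
and repeat enrichment, checked against analytic and exhaustive oracles."""

import numpy as np
import pytest
from scipy import stats
from scipy.stats import chi2_contingency

from peaklink.intervals import GenomeModel, GenomicInterval, PeakSet
from peaklink.randomization import (
    CoverageIndex,
    RandomizationConfig,
    chi_square_yates,
    median_overlap_chisq,
    per_peak_overlap_significance,
    repeat_enrichment,
    sample_random_regions,
)

from conftest import random_peakset


class TestCoverageIndex:
    def test_matches_perbase_counts(self, toy_genome):
        rng = np.random.default_rng(0)
        b = random_peakset(rng, toy_genome, 80, label="b")
        masks = {c: np.zeros(L, dtype=bool) for c, L in toy_genome.chromosomes.items()}
        for iv in b:
            masks[iv.chrom][iv.start:iv.end] = True
        cov = CoverageIndex(b)
        for _ in range(200):
            chrom = "chr1" if rng.random() < 0.5 else "chr2"
            L = toy_genome.chromosomes[chrom]
            s = int(rng.integers(0, L - 1))
            e = int(rng.integers(s + 1, L + 1))
            got = cov.overlap_bp(chrom, np.array([s]), np.array([e]))[0]
            assert got == masks[chrom][s:e].sum()


class TestSampling:
    def test_forced_placement_on_exact_fit(self):
        genome = GenomeModel({"chr1": 100})
        template = PeakSet("t", [GenomicInterval("chr1", 0, 100)], genome)
        out = sample_random_regions(template, genome, RandomizationConfig(n_iterations=5, seed=1))
        for it in out:
            assert it[0].key() == ("chr1", 0, 100)

    def test_interval_longer_than_genome_error(self):
        genome = GenomeModel({"chr1": 100})
        template = PeakSet("t", [GenomicInterval("chr1", 0, 99)], genome)
        big = PeakSet("t", [GenomicInterval("chr1", 0, 99, name="x")],
                      allow_duplicates=True)
        big.intervals[0].end = 500  # longer than any chromosome
        with pytest.raises(ValueError, match="longer than every chromosome"):
            sample_random_regions(big, genome, RandomizationConfig(n_iterations=1, seed=0))

    def test_default_iterations_is_1000(self):
        assert RandomizationConfig().n_iterations == 1000

    def test_start_positions_uniform(self):
        # 100 bp template on a 1 kb chromosome: valid starts 0..900
        genome = GenomeModel({"chr1": 1000})
        template = PeakSet("t", [GenomicInterval("chr1", 0, 100)], genome)
        cfg = RandomizationConfig(n_iterations=10_000, seed=42)
        starts = [it[0].start for it in sample_random_regions(template, genome, cfg)]
        counts, _ = np.histogram(starts, bins=np.linspace(0, 901, 11))
        _, p = stats.chisquare(counts)
        assert p > 0.01

    def test_excluded_regions_respected(self):
        genome = GenomeModel(
            {"chr1": 1000},
            excluded=PeakSet("ex", [GenomicInterval("chr1", 0, 500)]),
        )
        template = PeakSet("t", [GenomicInterval("chr1", 0, 100)], genome)
        cfg = RandomizationConfig(n_iterations=500, seed=7)
        for it in sample_random_regions(template, genome, cfg):
            assert it[0].start >= 500

    def test_determinism_bit_identical(self, toy_genome):
        template = random_peakset(np.random.default_rng(1), toy_genome, 10, label="t")
        cfg = RandomizationConfig(n_iterations=20, seed=99)
        a = sample_random_regions(template, toy_genome, cfg)
        b = sample_random_regions(template, toy_genome, cfg)
        assert [[iv.key() for iv in it] for it in a] == [[iv.key() for iv in it] for it in b]


class TestPerPeakSignificance:
    def test_b_covering_genome_gives_p_one(self):
        genome = GenomeModel({"chr1": 1000})
        b = PeakSet("b", [GenomicInterval("chr1", 0, 1000)], genome)
        a = PeakSet("a", [GenomicInterval("chr1", 100, 200),
                          GenomicInterval("chr1", 300, 450)], genome)
        pp = per_peak_overlap_significance(a, b, genome, RandomizationConfig(100, seed=0))
        assert (pp.table["observed_fraction"] == 1.0).all()
        assert (pp.table["empirical_p"] == 1.0).all()

    def test_empirical_p_never_zero_and_in_unit_interval(self, toy_genome):
        rng = np.random.default_rng(2)
        a = random_peakset(rng, toy_genome, 15, label="a")
        b = random_peakset(rng, toy_genome, 50, label="b")
        pp = per_peak_overlap_significance(a, b, toy_genome, RandomizationConfig(50, seed=3))
        p = pp.table["empirical_p"]
        assert (p > 0).all() and (p <= 1).all()

    def test_empirical_p_matches_exhaustive_enumeration(self):
        """On a tiny genome every placement can be enumerated; Monte-Carlo
        empirical p must approach the exact placement p."""
        genome = GenomeModel({"chr1": 20})
        b = PeakSet("b", [GenomicInterval("chr1", 12, 18)], genome)
        a = PeakSet("a", [GenomicInterval("chr1", 13, 17)], genome)  # length 4
        L = 4
        # exact: all starts 0..16, P(fraction >= observed)
        obs = 4 / 4
        fracs = np.array([
            max(0, min(s + L, 18) - max(s, 12)) / L for s in range(0, 20 - L + 1)
        ])
        exact_p = (fracs >= obs).mean()
        n = 20_000
        pp = per_peak_overlap_significance(a, b, genome, RandomizationConfig(n, seed=11))
        emp = pp.table["empirical_p"].iloc[0]
        assert abs(emp - exact_p) < 2 / np.sqrt(n) + 1e-3


class TestYates:
    def test_balanced_table_zero(self):
        stat, p = chi_square_yates([[10, 10], [10, 10]])
        assert stat == 0.0 and p == 1.0

    def test_hand_computed_value(self):
        # E = [[30,20],[30,20]]; |O-E| = 10 -> (9.5^2/30 + 9.5^2/20) * 2
        stat, p = chi_square_yates([[20, 30], [40, 10]])
        assert stat == pytest.approx(15.042, abs=0.001)
        assert p == pytest.approx(1.05e-4, rel=0.01)

    def test_correction_clamps_at_zero(self):
        stat, p = chi_square_yates([[1, 0], [0, 1]])
        assert stat == 0.0 and p == 1.0

    def test_zero_marginal_error(self):
        with pytest.raises(ValueError, match="marginal"):
            chi_square_yates([[0, 0], [5, 5]])

    def test_matches_reference_implementation_on_random_tables(self):
        rng = np.random.default_rng(4)
        for _ in range(1000):
            t = rng.integers(1, 200, size=(2, 2))
            stat, p = chi_square_yates(t)
            ref = chi2_contingency(t, correction=True)
            assert stat == pytest.approx(ref.statistic, rel=1e-9, abs=1e-12)
            assert p == pytest.approx(ref.pvalue, rel=1e-9, abs=1e-300)


def _structured_b(genome: GenomeModel, seed: int) -> PeakSet:
    """Variable-length tiling so per-peak overlap fractions are continuous."""
    rng = np.random.default_rng(seed)
    ivs, pos = [], 0
    G = genome.chromosomes["chr1"]
    while True:
        s = pos + int(rng.integers(50, 400))
        L = int(rng.integers(100, 500))
        if s + L + 50 >= G:
            break
        ivs.append(GenomicInterval("chr1", s, s + L))
        pos = s + L
    return PeakSet("b", ivs, genome, allow_duplicates=True)


class TestMedianOverlapChisq:
    def test_saturated_case_highly_significant(self):
        # a == b: every observed fraction 1, random fractions near 0
        genome = GenomeModel({"chr1": 1_000_000})
        rng = np.random.default_rng(5)
        starts = np.sort(rng.choice(999_000, size=30, replace=False))
        a = PeakSet("a", [GenomicInterval("chr1", int(s), int(s) + 500) for s in starts],
                    genome, allow_duplicates=True)
        pp = per_peak_overlap_significance(a, a, genome, RandomizationConfig(200, seed=6))
        sig = median_overlap_chisq(pp)
        assert sig.status == "ok"
        assert sig.observed_ge_median == len(a)
        assert sig.expected_ge_median < 2
        assert sig.chisq_p < 0.01
        # closed-form check of the reported table
        assert sig.chisq_stat == pytest.approx(chi_square_yates(sig.table)[0])

    def test_single_peak_degenerate(self):
        genome = GenomeModel({"chr1": 10_000})
        a = PeakSet("a", [GenomicInterval("chr1", 0, 100)], genome)
        b = PeakSet("b", [GenomicInterval("chr1", 50, 150)], genome)
        pp = per_peak_overlap_significance(a, b, genome, RandomizationConfig(50, seed=0))
        sig = median_overlap_chisq(pp)
        assert sig.status.startswith("degenerate")

    def test_null_calibration_type_i_error(self):
        """Peak set drawn from the null sampler: per-peak p super-uniform,
        chi-square type-I error <= 0.07 at alpha 0.05 over 200 datasets."""
        genome = GenomeModel({"chr1": 1_000_000})
        b = _structured_b(genome, seed=0)
        rng = np.random.default_rng(1)
        template = PeakSet(
            "t",
            [GenomicInterval("chr1", 0, int(L)) for L in rng.integers(300, 800, 20)],
            genome, allow_duplicates=True,
        )
        rejections, pvals = 0, []
        n_sims = 200
        for sim in range(n_sims):
            a = sample_random_regions(
                template, genome, RandomizationConfig(1, seed=5000 + sim)
            )[0]
            pp = per_peak_overlap_significance(
                a, b, genome, RandomizationConfig(200, seed=1000 + sim)
            )
            pvals.extend(pp.table["empirical_p"])
            sig = median_overlap_chisq(pp)
            assert sig.status == "ok"
            if sig.chisq_p <= 0.05:
                rejections += 1
        assert rejections / n_sims <= 0.07
        p = np.asarray(pvals)
        for alpha in (0.01, 0.05, 0.1):
            bound = alpha + 3 * np.sqrt(alpha * (1 - alpha) / p.size)
            assert (p <= alpha).mean() <= bound


class TestRepeatEnrichment:
    def test_no_repeats_all_ns(self, toy_genome):
        peaks = random_peakset(np.random.default_rng(6), toy_genome, 10)
        empty = PeakSet("r", [], toy_genome)
        result = repeat_enrichment(peaks, empty, toy_genome,
                                   RandomizationConfig(100, seed=0))
        assert (result.per_family["direction"] == "ns").all()
        assert (result.per_family["observed_fraction"] == 0).all()

    def test_default_pool_size_is_10000(self, toy_genome):
        peaks = random_peakset(np.random.default_rng(7), toy_genome, 5)
        rep = PeakSet("r", [GenomicInterval("chr1", 0, 100, name="fam")], toy_genome)
        result = repeat_enrichment(peaks, rep, toy_genome)
        assert result.n_random == 10_000

    def test_planted_enrichment_and_unplanted_ns(self, bundle):
        cfg = RandomizationConfig(n_iterations=10_000, seed=5)
        result = repeat_enrichment(bundle["atac"], bundle["repeats"],
                                   bundle["genome"], cfg)
        per = result.per_family.set_index("family")
        enriched = bundle["truth"].enriched_family
        assert per.loc[enriched, "direction"] == "enriched"
        assert per.loc[enriched, "p"] < 1e-10
        assert per.loc["B1_fam", "direction"] == "ns"

    def test_planted_depletion_detected(self):
        from peaklink.synth import make_annotations, make_genome

        genome = make_genome(seed=3)
        peaks = random_peakset(np.random.default_rng(8),
                               GenomeModel(genome.chromosomes), 80, max_len=500)
        peaks = PeakSet("peaks", peaks.intervals, genome, allow_duplicates=True)
        _, repeats, _ = make_annotations(
            genome, repeat_families={"dense_fam": 0.5},
            enriched_family=None, depleted_family="dense_fam",
            depleted_in=peaks, seed=4,
        )
        result = repeat_enrichment(peaks, repeats, genome,
                                   RandomizationConfig(10_000, seed=9))
        per = result.per_family.set_index("family")
        assert per.loc["dense_fam", "direction"] == "depleted"
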