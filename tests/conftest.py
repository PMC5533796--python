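import numpy as np
import pytest

from peaklink.intervals import GenomeModel, GenomicInterval, PeakSet
from peaklink import synth


# ---------------------------------------------------------------------------
# Independent per-base / brute-force oracles (never share code with the
# implementation under test)
# ---------------------------------------------------------------------------

def perbase_masks(peaks: PeakSet, genome: GenomeModel) -> dict[str, np.ndarray]:
    masks = {c: np.zeros(L, dtype=bool) for c, L in genome.chromosomes.items()}
    for iv in peaks:
        masks[iv.chrom][iv.start:iv.end] = True
    return masks


def oracle_pair_overlap(a: GenomicInterval, b: GenomicInterval) -> int:
    """Per-base overlap of two intervals via boolean membership."""
    if a.chrom != b.chrom:
        return 0
    lo, hi = min(a.start, b.start), max(a.end, b.end)
    ma = np.zeros(hi - lo, dtype=bool)
    mb = np.zeros(hi - lo, dtype=bool)
    ma[a.start - lo:a.end - lo] = True
    mb[b.start - lo:b.end - lo] = True
    return int((ma & mb).sum())


def oracle_intersect_pairs(a: PeakSet, b: PeakSet, min_bp: int) -> set:
    pairs = set()
    for i, ia in enumerate(a):
        for j, ib in enumerate(b):
            ov = oracle_pair_overlap(ia, ib)
            if ov >= min_bp:
                pairs.add((i, j, ov))
    return pairs


def oracle_overlaps_set(iv: GenomicInterval, other: PeakSet, min_bp: int) -> bool:
    return any(oracle_pair_overlap(iv, ob) >= min_bp for ob in other)


def random_peakset(
    rng: np.random.Generator,
    genome: GenomeModel,
    n: int,
    max_len: int = 2000,
    label: str = "rand",
) -> PeakSet:
    chroms = list(genome.chromosomes)
    ivs = []
    for _ in range(n):
        chrom = chroms[rng.integers(0, len(chroms))]
        L = int(rng.integers(1, max_len))
        L = min(L, genome.chromosomes[chrom])
        s = int(rng.integers(0, genome.chromosomes[chrom] - L + 1))
        ivs.append(GenomicInterval(chrom, s, s + L))
    return PeakSet(label, ivs, genome, allow_duplicates=True)


@pytest.fixture(scope="session")
def toy_genome() -> GenomeModel:
    return GenomeModel({"chr1": 100_000, "chr2": 60_000})


@pytest.fixture(scope="session")
def bundle():
    """Default synthetic study bundle shared across tests."""
    return synth.default_bundle(seed=17)
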