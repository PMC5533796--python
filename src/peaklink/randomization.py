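"""Randomized-null overlap significance and repeat-element enrichment.

Implements the two-step overlap test used for ChIP-seq vs ATAC-seq peak
comparisons: (1) per-peak empirical p-values against length-matched random
regions, (2) a Yates-corrected chi-square asking whether more peaks reach
the observed median percentage overlap than expected under the random
null. Also the repeat-family enrichment/depletion test against a pool of
randomly placed regions of equivalent size.

All randomness flows through a single :class:`numpy.random.Generator`
seeded from :class:`RandomizationConfig`; identical config + inputs
reproduce every random region and p-value bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import GenomeModel, GenomicInterval, PeakSet

__all__ = [
    "RandomizationConfig",
    "CoverageIndex",
    "OverlapSignificance",
    "PerPeakOverlap",
    "RepeatEnrichment",
    "sample_random_regions",
    "per_peak_overlap_significance",
    "median_overlap_chisq",
    "chi_square_yates",
    "repeat_enrichment",
]

_PLACEMENTS = {"genome_uniform", "chromosome_matched"}


@dataclass
class RandomizationConfig:
    """Parameters of the random-region null.

    ``placement="genome_uniform"`` picks a chromosome with probability
    proportional to its number of valid start positions, then a uniform
    start; ``"chromosome_matched"`` keeps each region on its template's
    chromosome. ``respect_excluded`` rejects placements overlapping the
    genome's excluded regions.
    """

    n_iterations: int = 1000
    seed: int = 0
    placement: str = "genome_uniform"
    respect_excluded: bool = True

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.placement not in _PLACEMENTS:
            raise ValueError(f"placement must be one of {_PLACEMENTS}")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


class CoverageIndex:
    """Merged per-chromosome coverage of a peak set for fast overlap-bp queries."""

    def __init__(self, peaks: PeakSet) -> None:
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for iv in peaks:
            by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
        self._index: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, spans in by_chrom.items():
            spans.sort()
            merged: list[list[int]] = []
            for s, e in spans:
                if merged and s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            starts = np.array([m[0] for m in merged], dtype=np.int64)
            ends = np.array([m[1] for m in merged], dtype=np.int64)
            cum = np.concatenate([[0], np.cumsum(ends - starts)])
            self._index[chrom] = (starts, ends, cum)

    def overlap_bp(self, chrom: str, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
        """Vectorized covered bp within each query ``[start, end)`` on ``chrom``."""
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        if chrom not in self._index:
            return np.zeros(starts.shape, dtype=np.int64)
        ms, me, cum = self._index[chrom]
        # first merged span ending after query start / starting before query end
        lo = np.searchsorted(me, starts, side="right")
        hi = np.searchsorted(ms, ends, side="left")
        full = cum[np.maximum(hi, lo)] - cum[lo]
        # correct partial overlap at the two boundary spans
        lo_c = np.minimum(lo, len(ms) - 1)
        hi_c = np.maximum(hi - 1, 0)
        trim_left = np.where(hi > lo, np.maximum(starts - ms[lo_c], 0), 0)
        trim_right = np.where(hi > lo, np.maximum(me[hi_c] - ends, 0), 0)
        return np.maximum(full - trim_left - trim_right, 0)


@dataclass
class PerPeakOverlap:
    """Per-peak observed overlap fractions and their matched-size null."""

    table: pd.DataFrame           # peak, chrom, start, end, observed_fraction, empirical_p
    null_fractions: np.ndarray    # shape (n_peaks, n_iterations)
    config: RandomizationConfig


@dataclass
class OverlapSignificance:
    """Median-overlap chi-square summary of a peak-set comparison."""

    per_peak: pd.DataFrame
    median_fraction: float
    observed_ge_median: int
    expected_ge_median: float
    table: list[list[int]] | None
    chisq_stat: float | None
    chisq_p: float | None
    status: str = "ok"


@dataclass
class RepeatEnrichment:
    per_family: pd.DataFrame
    random_baseline: float
    n_random: int


# ---------------------------------------------------------------------------
# Random placement
# ---------------------------------------------------------------------------

def _placement_matrix(
    template: PeakSet,
    genome: GenomeModel,
    config: RandomizationConfig,
    rng: np.random.Generator,
    n: int,
) -> tuple[list[str], np.ndarray, list[np.ndarray]]:
    """Draw ``n`` placements per template interval.

    Returns (chrom names, lengths, [per-interval arrays of (chrom_idx, start)])
    packed as a list of (n, 2) int arrays.
    """
    chrom_names = list(genome.chromosomes)
    chrom_lens = np.array([genome.chromosomes[c] for c in chrom_names], dtype=np.int64)
    excluded = None
    if config.respect_excluded and genome.excluded is not None and len(genome.excluded):
        excluded = CoverageIndex(genome.excluded)

    lengths = np.array([iv.length for iv in template], dtype=np.int64)
    placements: list[np.ndarray] = []
    for iv, L in zip(template, lengths):
        if config.placement == "chromosome_matched":
            cand = np.array([chrom_names.index(iv.chrom)])
        else:
            cand = np.flatnonzero(chrom_lens >= L)
        if cand.size == 0 or not np.any(chrom_lens[cand] >= L):
            raise ValueError(f"interval {iv.key()} is longer than every chromosome")
        n_valid = (chrom_lens[cand] - L + 1).astype(np.float64)
        weights = n_valid / n_valid.sum()

        out = np.empty((n, 2), dtype=np.int64)
        todo = np.arange(n)
        for _attempt in range(1000):
            k = todo.size
            ci = cand[rng.choice(cand.size, size=k, p=weights)]
            starts = (rng.random(k) * (chrom_lens[ci] - L + 1)).astype(np.int64)
            out[todo, 0] = ci
            out[todo, 1] = starts
            if excluded is None:
                todo = np.array([], dtype=np.int64)
                break
            bad = np.zeros(k, dtype=bool)
            for c in np.unique(ci):
                m = ci == c
                ov = excluded.overlap_bp(chrom_names[c], starts[m], starts[m] + L)
                bad[m] = ov > 0
            todo = todo[bad]
            if todo.size == 0:
                break
        if todo.size:
            raise ValueError(
                f"no valid placement found for interval {iv.key()} "
                "outside excluded regions"
            )
        placements.append(out)
    return chrom_names, lengths, placements


def sample_random_regions(
    template: PeakSet, genome: GenomeModel, config: RandomizationConfig
) -> list[PeakSet]:
    """One random :class:`PeakSet` per iteration, length-matched to ``template``.

    Each iteration contains one region per template interval with the same
    length, placed uniformly among valid start positions. Regions within an
    iteration may overlap one another (no rejection), matching naive
    random-region generation.
    """
    rng = config.rng()
    chrom_names, lengths, placements = _placement_matrix(
        template, genome, config, rng, config.n_iterations
    )
    iterations = []
    for it in range(config.n_iterations):
        ivs = [
            GenomicInterval(chrom_names[placements[j][it, 0]],
                            int(placements[j][it, 1]),
                            int(placements[j][it, 1] + lengths[j]))
            for j in range(len(template))
        ]
        iterations.append(
            PeakSet(f"{template.label}_rand{it}", ivs, genome, allow_duplicates=True)
        )
    return iterations


# ---------------------------------------------------------------------------
# Two-step overlap significance
# ---------------------------------------------------------------------------

def per_peak_overlap_significance(
    a: PeakSet, b: PeakSet, genome: GenomeModel, config: RandomizationConfig
) -> PerPeakOverlap:
    """Per-peak overlap fractions of ``a`` vs ``b`` with empirical p-values.

    For each a-interval the null sample is the overlap fraction of
    ``n_iterations`` random placements of a same-length region; the
    empirical p uses the add-one convention
    ``p = (1 + #{null >= observed}) / (1 + n_iterations)`` and is never 0.
    """
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both peak sets must be non-empty")
    b_cov = CoverageIndex(b)
    rng = config.rng()
    chrom_names, lengths, placements = _placement_matrix(
        a, genome, config, rng, config.n_iterations
    )

    n_peaks, n_iter = len(a), config.n_iterations
    observed = np.empty(n_peaks)
    null = np.empty((n_peaks, n_iter))
    for j, iv in enumerate(a):
        obs_bp = b_cov.overlap_bp(iv.chrom, np.array([iv.start]), np.array([iv.end]))[0]
        observed[j] = obs_bp / iv.length
        ci, starts = placements[j][:, 0], placements[j][:, 1]
        frac = np.empty(n_iter)
        for c in np.unique(ci):
            m = ci == c
            frac[m] = b_cov.overlap_bp(chrom_names[c], starts[m], starts[m] + lengths[j]) / lengths[j]
        null[j] = frac

    emp_p = (1 + (null >= observed[:, None]).sum(axis=1)) / (1 + n_iter)
    table = pd.DataFrame(
        {
            "peak": [iv.name if iv.name is not None else f"{a.label}_{j}" for j, iv in enumerate(a)],
            "chrom": [iv.chrom for iv in a],
            "start": [iv.start for iv in a],
            "end": [iv.end for iv in a],
            "observed_fraction": observed,
            "empirical_p": emp_p,
        }
    )
    return PerPeakOverlap(table=table, null_fractions=null, config=config)


def chi_square_yates(table: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Yates continuity-corrected chi-square on a 2x2 table of counts.

    ``statistic = sum(max(|O - E| - 0.5, 0)^2 / E)`` with expected counts
    from the marginals; p from chi-square with 1 df. The correction clamps
    at zero when ``|O - E| < 0.5``.
    """
    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2):
        raise ValueError("chi_square_yates requires a 2x2 table")
    if np.any(obs < 0):
        raise ValueError("counts must be non-negative")
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    if np.any(row == 0) or np.any(col == 0):
        raise ValueError("all marginals must be > 0")
    expected = np.outer(row, col) / obs.sum()
    adj = np.maximum(np.abs(obs - expected) - 0.5, 0.0)
    stat = float((adj ** 2 / expected).sum())
    p = float(stats.chi2.sf(stat, df=1))
    return stat, p


def median_overlap_chisq(
    per_peak: PerPeakOverlap, include_zero: bool = True
) -> OverlapSignificance:
    """Test whether more peaks reach the median observed overlap than expected.

    The threshold is the median observed per-peak fraction (over all peaks
    by default; ``include_zero=False`` takes it over peaks with nonzero
    overlap). The expected count is the mean, over random iterations, of
    regions reaching that threshold, rounded to the nearest integer for
    the 2x2 Yates chi-square ``[[obs_ge, obs_lt], [exp_ge, exp_lt]]``.
    """
    observed = per_peak.table["observed_fraction"].to_numpy()
    null = per_peak.null_fractions
    n = observed.size
    pool = observed if include_zero else observed[observed > 0]

    def degenerate(reason: str, thr: float, obs_ge: int, exp_ge: float) -> OverlapSignificance:
        return OverlapSignificance(
            per_peak=per_peak.table, median_fraction=thr,
            observed_ge_median=obs_ge, expected_ge_median=exp_ge,
            table=None, chisq_stat=None, chisq_p=None, status=f"degenerate: {reason}",
        )

    if n < 2 or pool.size == 0:
        thr = float(np.median(pool)) if pool.size else float("nan")
        return degenerate("fewer than 2 peaks", thr, int(n), float(n))
    thr = float(np.median(pool))
    obs_ge = int((observed >= thr).sum())
    exp_ge = float((null >= thr).sum(axis=0).mean())
    exp_ge_int = int(round(exp_ge))
    table = [[obs_ge, n - obs_ge], [exp_ge_int, n - exp_ge_int]]
    try:
        stat, p = chi_square_yates(table)
    except ValueError as exc:
        return degenerate(str(exc), thr, obs_ge, exp_ge)
    return OverlapSignificance(
        per_peak=per_peak.table, median_fraction=thr,
        observed_ge_median=obs_ge, expected_ge_median=exp_ge,
        table=table, chisq_stat=stat, chisq_p=p,
    )


# ---------------------------------------------------------------------------
# Repeat enrichment
# ---------------------------------------------------------------------------

def repeat_enrichment(
    peaks: PeakSet,
    repeats: PeakSet,
    genome: GenomeModel,
    config: RandomizationConfig | None = None,
    alpha: float = 0.05,
) -> RepeatEnrichment:
    """Repeat-family enrichment/depletion of a peak set vs random regions.

    The null is a single pool of ``config.n_iterations`` (default 10,000)
    random regions with lengths resampled from the peak lengths. For each
    repeat family (interval ``name``) and for all repeats pooled
    (``any_repeat``), the counts of peak vs random regions overlapping at
    least one repeat form a 2x2 Yates chi-square; ``direction`` flags
    enrichment or depletion at ``alpha``.
    """
    if len(peaks) == 0:
        raise ValueError("peak set must be non-empty")
    if config is None:
        config = RandomizationConfig(n_iterations=10000)
    rng = config.rng()
    n_rand = config.n_iterations

    # random pool: lengths resampled from peak lengths, one placement each
    lengths = np.array(peaks.lengths(), dtype=np.int64)
    pool_lengths = lengths[rng.integers(0, lengths.size, size=n_rand)]
    template = PeakSet(
        "pool",
        [GenomicInterval("_tmp", 0, int(L)) for L in pool_lengths],
        genome=None, allow_duplicates=True,
    )
    # borrow the placement machinery: one iteration of the whole pool
    # (pool regions have no meaningful template chromosome, so placement is
    # always genome-uniform here)
    pool_config = RandomizationConfig(
        n_iterations=config.n_iterations, seed=config.seed,
        placement="genome_uniform", respect_excluded=config.respect_excluded,
    )
    chrom_names, tmpl_lengths, placements = _placement_matrix(
        template, genome, pool_config, rng, 1
    )
    rand_chroms = [chrom_names[placements[j][0, 0]] for j in range(n_rand)]
    rand_starts = np.array([placements[j][0, 1] for j in range(n_rand)], dtype=np.int64)
    rand_ends = rand_starts + pool_lengths

    families = sorted({iv.name for iv in repeats if iv.name is not None})
    groups: dict[str, PeakSet] = {
        fam: PeakSet(fam, [iv for iv in repeats if iv.name == fam], allow_duplicates=True)
        for fam in families
    }
    if len(repeats):
        groups["any_repeat"] = PeakSet("any_repeat", list(repeats), allow_duplicates=True)

    def overlap_count(cov: CoverageIndex) -> tuple[int, int]:
        obs = 0
        for iv in peaks:
            if cov.overlap_bp(iv.chrom, np.array([iv.start]), np.array([iv.end]))[0] > 0:
                obs += 1
        rand = 0
        for c in set(rand_chroms):
            m = np.array([rc == c for rc in rand_chroms])
            ov = cov.overlap_bp(c, rand_starts[m], rand_ends[m])
            rand += int((ov > 0).sum())
        return obs, rand

    rows = []
    baseline = 0.0
    for fam, fam_set in groups.items():
        cov = CoverageIndex(fam_set)
        obs, rand = overlap_count(cov)
        obs_frac = obs / len(peaks)
        rand_frac = rand / n_rand
        table = [[obs, len(peaks) - obs], [rand, n_rand - rand]]
        try:
            stat, p = chi_square_yates(table)
        except ValueError:
            stat, p = 0.0, 1.0
        if p <= alpha and obs_frac > rand_frac:
            direction = "enriched"
        elif p <= alpha and obs_frac < rand_frac:
            direction = "depleted"
        else:
            direction = "ns"
        if fam == "any_repeat":
            baseline = rand_frac
        rows.append(
            {
                "family": fam,
                "observed_count": obs,
                "observed_fraction": obs_frac,
                "null_mean": rand_frac * len(peaks),
                "random_fraction": rand_frac,
                "chisq_stat": stat,
                "p": p,
                "direction": direction,
            }
        )
    if not rows:  # no repeats annotated at all
        rows.append(
            {
                "family": "any_repeat", "observed_count": 0, "observed_fraction": 0.0,
                "null_mean": 0.0, "random_fraction": 0.0, "chisq_stat": 0.0,
                "p": 1.0, "direction": "ns",
            }
        )
    return RepeatEnrichment(
        per_family=pd.DataFrame(rows), random_baseline=baseline, n_random=n_rand
    )
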