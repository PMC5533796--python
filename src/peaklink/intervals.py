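"""Genomic interval data model, standard-format I/O and peak-set algebra.

Coordinates are 0-based half-open (BED convention) throughout. narrowPeak
-log10 q-values are converted to the linear scale on ingest and back on
output. Strand is carried but ignored by all overlap operations, which is
appropriate for unstranded accessibility / occupancy peaks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

__all__ = [
    "GenomicInterval",
    "PeakSet",
    "GenomeModel",
    "read_chrom_sizes",
    "read_intervals",
    "write_intervals",
    "intersect_sets",
    "consensus_peaks",
    "subtract_peaks",
    "classify_multiway",
    "overlap_bp",
]

_STRANDS = {"+", "-", "."}


@dataclass
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` with optional metadata.

    ``score`` carries signal intensity (e.g. FPKM-scaled peak intensity);
    ``q_value`` is the peak caller's FDR-adjusted significance on the
    *linear* scale in (0, 1].
    """

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None
    q_value: float | None = None
    strand: str | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:[{self.start},{self.end}): "
                "require 0 <= start < end"
            )
        if self.q_value is not None and not (0.0 < self.q_value <= 1.0):
            raise ValueError(f"linear q-value must be in (0,1], got {self.q_value}")
        if self.strand is not None and self.strand not in _STRANDS:
            raise ValueError(f"strand must be one of {_STRANDS}, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def key(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)


def overlap_bp(a: GenomicInterval, b: GenomicInterval) -> int:
    """Base pairs shared by two intervals (0 if different chromosomes)."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


@dataclass
class GenomeModel:
    """Chromosome name -> length table defining the sampling workspace.

    ``excluded`` optionally lists regions barred from random placement.
    """

    chromosomes: dict[str, int]
    excluded: "PeakSet | None" = None

    def __post_init__(self) -> None:
        for name, length in self.chromosomes.items():
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")
        if self.excluded is not None:
            for iv in self.excluded:
                if iv.chrom not in self.chromosomes:
                    raise ValueError(f"excluded region on unknown chromosome {iv.chrom!r}")
                if iv.end > self.chromosomes[iv.chrom]:
                    raise ValueError(f"excluded region {iv.key()} exceeds chromosome length")

    @property
    def total_size(self) -> int:
        return sum(self.chromosomes.values())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenomeModel):
            return NotImplemented
        return self.chromosomes == other.chromosomes

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chromosomes


class PeakSet:
    """An ordered, labelled collection of :class:`GenomicInterval`.

    Duplicate coordinates are rejected unless ``allow_duplicates=True``.
    When a :class:`GenomeModel` is attached, every interval must lie within
    its chromosome's bounds.
    """

    def __init__(
        self,
        label: str,
        intervals: Iterable[GenomicInterval],
        genome: GenomeModel | None = None,
        allow_duplicates: bool = False,
    ) -> None:
        self.label = label
        self.intervals: list[GenomicInterval] = list(intervals)
        self.genome = genome
        self.allow_duplicates = allow_duplicates
        if not allow_duplicates:
            seen: set[tuple[str, int, int]] = set()
            for iv in self.intervals:
                k = iv.key()
                if k in seen:
                    raise ValueError(
                        f"duplicate interval {k} in peak set {label!r} "
                        "(pass allow_duplicates=True to permit)"
                    )
                seen.add(k)
        if genome is not None:
            for iv in self.intervals:
                if iv.chrom not in genome.chromosomes:
                    raise ValueError(f"interval on unknown chromosome {iv.chrom!r}")
                if iv.end > genome.chromosomes[iv.chrom]:
                    raise ValueError(
                        f"interval {iv.key()} exceeds {iv.chrom} length "
                        f"{genome.chromosomes[iv.chrom]}"
                    )

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __getitem__(self, i: int) -> GenomicInterval:
        return self.intervals[i]

    def __repr__(self) -> str:
        return f"PeakSet({self.label!r}, n={len(self)})"

    def sorted(self) -> "PeakSet":
        ivs = sorted(self.intervals, key=lambda iv: iv.key())
        return PeakSet(self.label, ivs, self.genome, allow_duplicates=True)

    def with_label(self, label: str) -> "PeakSet":
        return PeakSet(label, self.intervals, self.genome, allow_duplicates=True)

    def lengths(self) -> list[int]:
        return [iv.length for iv in self.intervals]

    def trees(self) -> dict[str, IntervalTree]:
        """Per-chromosome interval trees; tree data is the interval index."""
        trees: dict[str, IntervalTree] = {}
        for i, iv in enumerate(self.intervals):
            trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, i)
        return trees


def _check_same_genome(*sets: PeakSet) -> None:
    genomes = [s.genome for s in sets if s.genome is not None]
    for g in genomes[1:]:
        if g != genomes[0]:
            raise ValueError("peak sets refer to different genomes")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_chrom_sizes(path: str | Path) -> GenomeModel:
    """Read a UCSC-style two-column chrom.sizes TSV."""
    chroms: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 tab-separated columns")
            chroms[parts[0]] = int(parts[1])
    return GenomeModel(chroms)


def _parse_score(tok: str) -> float | None:
    if tok in (".", ""):
        return None
    return float(tok)


def read_intervals(
    path: str | Path,
    dialect: str = "bed",
    genome: GenomeModel | None = None,
    label: str | None = None,
    dedup: bool = False,
) -> PeakSet:
    """Read a BED, ENCODE narrowPeak or headered TSV interval file.

    narrowPeak q-values (column 9, -log10) are converted to the linear
    scale; a sentinel value of -1 becomes a missing q-value. With
    ``dedup=True`` duplicate (chrom, start, end) records are silently
    collapsed to the first occurrence.
    """
    path = Path(path)
    label = label if label is not None else path.stem
    intervals: list[GenomicInterval] = []

    if dialect == "tsv":
        df = pd.read_csv(path, sep="\t")
        required = {"chrom", "start", "end"}
        if not required.issubset(df.columns):
            raise ValueError(f"{path}: TSV dialect requires columns {sorted(required)}")
        for lineno, row in enumerate(df.itertuples(index=False), 2):
            try:
                intervals.append(
                    GenomicInterval(
                        chrom=str(row.chrom),
                        start=int(row.start),
                        end=int(row.end),
                        name=str(row.name) if "name" in df.columns and pd.notna(row.name) else None,
                        score=float(row.score) if "score" in df.columns and pd.notna(row.score) else None,
                        q_value=float(row.q_value)
                        if "q_value" in df.columns and pd.notna(row.q_value)
                        else None,
                        strand=str(row.strand) if "strand" in df.columns and pd.notna(row.strand) else None,
                    )
                )
            except (ValueError, TypeError) as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    else:
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                try:
                    if dialect == "bed":
                        if len(parts) < 3:
                            raise ValueError("BED requires >= 3 columns")
                        iv = GenomicInterval(
                            chrom=parts[0],
                            start=int(parts[1]),
                            end=int(parts[2]),
                            name=parts[3] if len(parts) > 3 and parts[3] != "." else None,
                            score=_parse_score(parts[4]) if len(parts) > 4 else None,
                            strand=parts[5] if len(parts) > 5 else None,
                        )
                    elif dialect == "narrowPeak":
                        if len(parts) != 10:
                            raise ValueError(f"narrowPeak requires 10 columns, got {len(parts)}")
                        neglog_q = float(parts[8])
                        q = None if neglog_q < 0 else 10.0 ** (-neglog_q)
                        iv = GenomicInterval(
                            chrom=parts[0],
                            start=int(parts[1]),
                            end=int(parts[2]),
                            name=parts[3] if parts[3] != "." else None,
                            score=_parse_score(parts[6]),  # signalValue
                            q_value=q,
                            strand=parts[5] if parts[5] != "." else None,
                        )
                    else:
                        raise ValueError(f"unknown dialect {dialect!r}")
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: {exc}") from exc
                intervals.append(iv)

    if dedup:
        seen: set[tuple[str, int, int]] = set()
        unique = []
        for iv in intervals:
            if iv.key() not in seen:
                seen.add(iv.key())
                unique.append(iv)
        intervals = unique
    return PeakSet(label, intervals, genome=genome, allow_duplicates=dedup)


def write_intervals(peaks: PeakSet, path: str | Path, dialect: str = "bed") -> None:
    """Write a :class:`PeakSet` as BED6 or ENCODE narrowPeak.

    Round-trips every field that the dialect retains bit-exactly (q-values
    are stored as -log10 in narrowPeak with 17 significant digits).
    """
    with open(path, "w") as fh:
        for iv in peaks:
            name = iv.name if iv.name is not None else "."
            strand = iv.strand if iv.strand is not None else "."
            if dialect == "bed":
                score = repr(iv.score) if iv.score is not None else "."
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{strand}\n")
            elif dialect == "narrowPeak":
                signal = repr(iv.score) if iv.score is not None else "0"
                neglog_q = repr(-math.log10(iv.q_value)) if iv.q_value is not None else "-1"
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{strand}"
                    f"\t{signal}\t-1\t{neglog_q}\t-1\n"
                )
            else:
                raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Peak-set algebra
# ---------------------------------------------------------------------------

def intersect_sets(a: PeakSet, b: PeakSet, min_bp: int = 1) -> pd.DataFrame:
    """Report every (a, b) interval pair overlapping by at least ``min_bp``.

    Returns a table with a/b indices and coordinates, overlap in bp and
    the overlap as a fraction of the a-interval's length. Swapping the
    arguments yields the same pairs with roles reversed.
    """
    if min_bp < 1:
        raise ValueError("min_bp must be >= 1")
    _check_same_genome(a, b)
    b_trees = b.trees()
    rows = []
    for ai, iv in enumerate(a):
        tree = b_trees.get(iv.chrom)
        if tree is None:
            continue
        for hit in sorted(tree.overlap(iv.start, iv.end)):
            ov = min(iv.end, hit.end) - max(iv.start, hit.begin)
            if ov >= min_bp:
                rows.append(
                    {
                        "a_index": ai,
                        "b_index": hit.data,
                        "chrom": iv.chrom,
                        "a_start": iv.start,
                        "a_end": iv.end,
                        "b_start": hit.begin,
                        "b_end": hit.end,
                        "overlap_bp": ov,
                        "fraction_a": ov / iv.length,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "a_index", "b_index", "chrom", "a_start", "a_end",
            "b_start", "b_end", "overlap_bp", "fraction_a",
        ],
    )


def _overlaps_any(iv: GenomicInterval, trees: Mapping[str, IntervalTree], min_bp: int) -> bool:
    tree = trees.get(iv.chrom)
    if tree is None:
        return False
    for hit in tree.overlap(iv.start, iv.end):
        if min(iv.end, hit.end) - max(iv.start, hit.begin) >= min_bp:
            return True
    return False


def consensus_peaks(replicates: Sequence[PeakSet], min_bp: int = 1) -> PeakSet:
    """Replicate-consistent peaks.

    Returns the intervals of the first (reference) replicate that overlap,
    by at least ``min_bp``, at least one interval in *every* other
    replicate. Coordinates are the reference replicate's, not merged spans.
    """
    if len(replicates) < 2:
        raise ValueError("consensus requires >= 2 replicates")
    _check_same_genome(*replicates)
    ref = replicates[0]
    other_trees = [r.trees() for r in replicates[1:]]
    kept = [
        iv for iv in ref
        if all(_overlaps_any(iv, trees, min_bp) for trees in other_trees)
    ]
    return PeakSet(f"{ref.label}_consensus", kept, ref.genome, allow_duplicates=True)


def subtract_peaks(target: PeakSet, background: PeakSet, min_bp: int = 1) -> PeakSet:
    """Whole-interval subtraction.

    Removes every target interval that overlaps any background interval by
    at least ``min_bp``; surviving intervals keep their exact coordinates
    (no clipping).
    """
    _check_same_genome(target, background)
    bg_trees = background.trees()
    kept = [iv for iv in target if not _overlaps_any(iv, bg_trees, min_bp)]
    return PeakSet(f"{target.label}_minus_{background.label}", kept, target.genome,
                   allow_duplicates=True)


def classify_multiway(sets: Sequence[PeakSet], min_bp: int = 1) -> dict[str, PeakSet]:
    """Venn-style classification of the first set against one or two others.

    Each interval of the first set is assigned to exactly one category
    based on which of the other sets it overlaps (>= ``min_bp``):
    ``unique``, ``shared_with_<label>`` and, with three sets,
    ``shared_with_all``. Categories partition the first set.
    """
    if not (2 <= len(sets) <= 3):
        raise ValueError("classify_multiway supports exactly 2 or 3 peak sets")
    _check_same_genome(*sets)
    first, others = sets[0], sets[1:]
    other_trees = [s.trees() for s in others]

    categories: dict[str, list[GenomicInterval]] = {"unique": []}
    for s in others:
        categories[f"shared_with_{s.label}"] = []
    if len(others) == 2:
        categories["shared_with_all"] = []

    for iv in first:
        flags = tuple(_overlaps_any(iv, trees, min_bp) for trees in other_trees)
        if not any(flags):
            categories["unique"].append(iv)
        elif all(flags) and len(others) == 2:
            categories["shared_with_all"].append(iv)
        else:
            hit = [s.label for s, f in zip(others, flags) if f]
            # with 2 sets, any(flags) implies exactly one partner label
            categories[f"shared_with_{hit[0]}"].append(iv)
    return {
        name: PeakSet(f"{first.label}_{name}", ivs, first.genome, allow_duplicates=True)
        for name, ivs in categories.items()
    }
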