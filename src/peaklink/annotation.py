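"""Peak-to-gene annotation by nearest TSS and regulatory-element labelling.

Peaks are linked to the transcription start site minimizing the distance
from the peak midpoint on the same chromosome; links farther than the
window (default +/-100 kb) are flagged and excluded from downstream gene
sets. Regulatory-element classification uses histone-mark *peak overlap*
(H3K4me1 = enhancer-like, H3K4me3 = promoter-like, H3K27ac = active) as a
discrete proxy for read-density profiles.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .intervals import PeakSet, _check_same_genome, _overlaps_any

__all__ = [
    "TSSRecord",
    "read_tss",
    "annotate_nearest_tss",
    "distance_distribution",
    "classify_regulatory_element",
    "DEFAULT_WINDOW",
    "DEFAULT_DISTANCE_BINS",
]

DEFAULT_WINDOW = 100_000
# 0-5 kb (promoter-proximal), 5-50 kb, 50-100 kb, beyond the window
DEFAULT_DISTANCE_BINS = [0, 5_000, 50_000, 100_000, np.inf]


@dataclass(frozen=True)
class TSSRecord:
    gene: str
    chrom: str
    position: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.position < 0:
            raise ValueError(f"TSS position must be >= 0, got {self.position}")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"TSS strand must be + or -, got {self.strand!r}")


def read_tss(path: str | Path) -> list[TSSRecord]:
    """Read a TSS table: 4-column TSV (gene, chrom, position, strand) with
    header, or BED6 (chrom, start, end, gene, score, strand; TSS = start)."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline().rstrip("\n").split("\t")
    if first[:2] == ["gene", "chrom"]:
        df = pd.read_csv(path, sep="\t")
        return [
            TSSRecord(str(r.gene), str(r.chrom), int(r.position), str(r.strand))
            for r in df.itertuples(index=False)
        ]
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValueError(f"{path}:{lineno}: BED6 TSS requires 6 columns")
            records.append(TSSRecord(parts[3], parts[0], int(parts[1]), parts[5]))
    return records


def annotate_nearest_tss(
    peaks: PeakSet,
    tss: Sequence[TSSRecord],
    window: int | None = DEFAULT_WINDOW,
    anchor: str = "midpoint",
) -> pd.DataFrame:
    """Link each peak to its nearest TSS on the same chromosome.

    The anchor is the peak midpoint ``floor((start+end)/2)`` (or the
    nearest peak edge with ``anchor="edge"``). Distance is signed and
    strand-oriented: negative means upstream of the TSS. Ties between
    equidistant TSSs break toward the lexicographically smallest gene
    identifier. Peaks on chromosomes without any TSS get a null link.
    ``window=None`` disables the window flag (all links within_window).
    """
    if not tss:
        raise ValueError("TSS list must be non-empty")
    if window is not None and window <= 0:
        raise ValueError("window must be positive")
    if anchor not in {"midpoint", "edge"}:
        raise ValueError("anchor must be 'midpoint' or 'edge'")

    by_chrom: dict[str, list[TSSRecord]] = {}
    for rec in tss:
        by_chrom.setdefault(rec.chrom, []).append(rec)
    # sort by (position, gene) so equidistant ties resolve deterministically
    sorted_chrom: dict[str, tuple[np.ndarray, list[TSSRecord]]] = {}
    for chrom, recs in by_chrom.items():
        recs = sorted(recs, key=lambda r: (r.position, r.gene))
        sorted_chrom[chrom] = (np.array([r.position for r in recs]), recs)

    rows = []
    for i, iv in enumerate(peaks):
        anchor_pos = iv.midpoint
        entry = {
            "peak": iv.name if iv.name is not None else f"{peaks.label}_{i}",
            "chrom": iv.chrom, "start": iv.start, "end": iv.end,
            "anchor": anchor_pos, "gene": None, "tss_position": np.nan,
            "tss_strand": None, "distance": np.nan, "abs_distance": np.nan,
            "within_window": False,
        }
        if iv.chrom in sorted_chrom:
            positions, recs = sorted_chrom[iv.chrom]
            if anchor == "midpoint":
                dists = np.abs(positions - anchor_pos)
            else:
                # distance from the nearest peak edge (0 if the TSS is inside)
                dists = np.maximum(
                    np.maximum(iv.start - positions, positions - (iv.end - 1)), 0
                )
            best_d = dists.min()
            candidates = [recs[j] for j in np.flatnonzero(dists == best_d)]
            best = min(candidates, key=lambda r: r.gene)
            signed = anchor_pos - best.position
            if best.strand == "-":
                signed = -signed
            entry.update(
                gene=best.gene, tss_position=best.position, tss_strand=best.strand,
                distance=float(signed), abs_distance=float(best_d),
                within_window=(window is None) or (best_d <= window),
            )
        rows.append(entry)
    return pd.DataFrame(rows)


def distance_distribution(
    links: pd.DataFrame, bins: Sequence[float] = DEFAULT_DISTANCE_BINS
) -> pd.DataFrame:
    """Histogram of |distance to nearest TSS| over annotated links.

    Bin edges must be strictly increasing; bins are half-open
    ``[lo, hi)``. Fractions are over annotated links and sum to 1.
    """
    bins = list(bins)
    if any(b2 <= b1 for b1, b2 in zip(bins, bins[1:])):
        raise ValueError("bin edges must be strictly increasing")
    d = links.loc[links["gene"].notna(), "abs_distance"].to_numpy(dtype=float)
    if d.size == 0:
        raise ValueError("no annotated links to bin")
    counts, _ = np.histogram(d, bins=np.asarray(bins, dtype=float))
    # np.histogram closes the last bin; with an inf edge this is immaterial
    labels = [
        f"[{lo:g},{hi:g})" if np.isfinite(hi) else f">={lo:g}"
        for lo, hi in zip(bins, bins[1:])
    ]
    return pd.DataFrame(
        {"bin": labels, "count": counts, "fraction": counts / d.size}
    )


_CATEGORIES = [
    "active_promoter", "putative_promoter",
    "active_enhancer", "putative_enhancer", "unclassified",
]


def classify_regulatory_element(
    peaks: PeakSet,
    h3k4me1: PeakSet,
    h3k4me3: PeakSet,
    h3k27ac: PeakSet,
    min_bp: int = 1,
) -> pd.DataFrame:
    """Label peaks by histone-mark peak overlap.

    Rule order (deterministic, mutually exclusive, exhaustive):
    overlaps H3K4me3 -> promoter; else overlaps H3K4me1 -> enhancer; else
    unclassified. The ``active_`` prefix is added when the peak also
    overlaps H3K27ac.
    """
    _check_same_genome(peaks, h3k4me1, h3k4me3, h3k27ac)
    t1, t3, tac = h3k4me1.trees(), h3k4me3.trees(), h3k27ac.trees()
    rows = []
    for i, iv in enumerate(peaks):
        me1 = _overlaps_any(iv, t1, min_bp)
        me3 = _overlaps_any(iv, t3, min_bp)
        ac = _overlaps_any(iv, tac, min_bp)
        if me3:
            label = "active_promoter" if ac else "putative_promoter"
        elif me1:
            label = "active_enhancer" if ac else "putative_enhancer"
        else:
            label = "unclassified"
        rows.append(
            {
                "peak": iv.name if iv.name is not None else f"{peaks.label}_{i}",
                "chrom": iv.chrom, "start": iv.start, "end": iv.end,
                "h3k4me1": me1, "h3k4me3": me3, "h3k27ac": ac, "label": label,
            }
        )
    df = pd.DataFrame(rows)
    df["label"] = pd.Categorical(df["label"], categories=_CATEGORIES)
    return df
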