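"""Direct-target calling: ChIP peaks x accessibility x differential expression.

A gene is a candidate direct target when at least one ChIP peak links to
it as nearest TSS within the window (default +/-100 kb) *and* the gene is
derepressed past both thresholds (default fold change >= 1.5 at nominal
P <= 0.05). ChIP peaks are further dichotomized by ATAC-peak overlap into
accessible vs inaccessible sites, and the two classes contrasted on TSS
distance, peak intensity and motif content with Welch t-tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import DEFAULT_WINDOW, TSSRecord, annotate_nearest_tss
from .expression import TTestResult, t_test
from .intervals import PeakSet, _check_same_genome, _overlaps_any

__all__ = [
    "DERecord",
    "TargetCall",
    "read_de_table",
    "call_target_genes",
    "classify_peak_accessibility",
    "accessibility_contrasts",
    "crosstab_peak_sets",
]


@dataclass
class DERecord:
    """One gene's differential-expression summary.

    ``fold_change`` is a linear ratio (condition / reference, e.g.
    mutant / wild-type, so derepressed repressor targets have fc > 1);
    ``rank_score`` is a signed ranking statistic (DiffScore-like).
    """

    gene: str
    fold_change: float
    p_value: float
    adj_p: float | None = None
    rank_score: float | None = None

    def __post_init__(self) -> None:
        if self.fold_change <= 0:
            raise ValueError(f"fold_change must be > 0, got {self.fold_change}")
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError(f"p_value must be in (0,1], got {self.p_value}")


@dataclass
class TargetCall:
    gene: str
    fold_change: float
    p_value: float
    supporting_peaks: pd.DataFrame  # nearest-TSS links backing the call
    accessibility: str = "unknown"  # accessible | inaccessible | mixed | unknown


def read_de_table(path: str | Path) -> list[DERecord]:
    """Read a DE table TSV: gene, fold_change, p_value[, adj_p, rank_score]."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene", "fold_change", "p_value"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: DE table requires columns {sorted(required)}")
    return [
        DERecord(
            gene=str(r.gene),
            fold_change=float(r.fold_change),
            p_value=float(r.p_value),
            adj_p=float(r.adj_p) if "adj_p" in df.columns and pd.notna(r.adj_p) else None,
            rank_score=float(r.rank_score)
            if "rank_score" in df.columns and pd.notna(r.rank_score) else None,
        )
        for r in df.itertuples(index=False)
    ]


def call_target_genes(
    chip_peaks: PeakSet,
    tss: Sequence[TSSRecord],
    de: Sequence[DERecord],
    window: int = DEFAULT_WINDOW,
    min_fc: float = 1.5,
    max_p: float = 0.05,
    use_adj_p: bool = False,
    direction: str = "up",
    atac_peaks: PeakSet | None = None,
    min_bp: int = 1,
) -> list[TargetCall]:
    """Call candidate direct target genes.

    A gene qualifies iff (a) at least one ChIP peak has it as nearest TSS
    within ``window`` bp and (b) it passes the expression filter:
    ``fold_change >= min_fc`` (``direction="up"``) or
    ``fold_change <= 1/min_fc`` (``direction="down"``), with nominal
    ``p_value <= max_p`` (or ``adj_p`` when ``use_adj_p``). Output is
    deduplicated by gene and sorted by gene identifier. When
    ``atac_peaks`` is given, each call's accessibility reflects its
    supporting peaks: all accessible, all inaccessible, or mixed.
    """
    if min_fc <= 0 or max_p <= 0:
        raise ValueError("thresholds must be positive")
    if direction not in {"up", "down"}:
        raise ValueError("direction must be 'up' or 'down'")
    seen = [r.gene for r in de]
    if len(set(seen)) != len(seen):
        dupes = sorted({g for g in seen if seen.count(g) > 1})
        raise ValueError(f"duplicate gene rows in DE table: {', '.join(dupes)}")
    de_by_gene = {r.gene: r for r in de}

    links = annotate_nearest_tss(chip_peaks, tss, window=window)
    linked = links[links["within_window"] & links["gene"].notna()]

    peak_access: dict[str, bool] = {}
    if atac_peaks is not None:
        atac_trees = atac_peaks.trees()
        for i, iv in enumerate(chip_peaks):
            name = iv.name if iv.name is not None else f"{chip_peaks.label}_{i}"
            peak_access[name] = _overlaps_any(iv, atac_trees, min_bp)

    calls: list[TargetCall] = []
    for gene, sub in linked.groupby("gene", sort=True):
        rec = de_by_gene.get(str(gene))
        if rec is None:
            continue
        p = rec.adj_p if use_adj_p else rec.p_value
        if p is None:
            raise ValueError(f"gene {gene!r} lacks an adjusted p-value")
        passes_fc = rec.fold_change >= min_fc if direction == "up" \
            else rec.fold_change <= 1.0 / min_fc
        if passes_fc and p <= max_p:
            accessibility = "unknown"
            if atac_peaks is not None:
                flags = {peak_access[name] for name in sub["peak"]}
                accessibility = (
                    "mixed" if len(flags) == 2
                    else ("accessible" if True in flags else "inaccessible")
                )
            calls.append(
                TargetCall(
                    gene=str(gene), fold_change=rec.fold_change,
                    p_value=rec.p_value, supporting_peaks=sub.reset_index(drop=True),
                    accessibility=accessibility,
                )
            )
    return calls


def classify_peak_accessibility(
    chip_peaks: PeakSet, atac_peaks: PeakSet, min_bp: int = 1
) -> tuple[PeakSet, PeakSet]:
    """Partition ChIP peaks into accessible vs inaccessible by ATAC overlap.

    Accessible = overlapping at least one ATAC peak by ``min_bp``;
    inaccessible = the remainder. The partition is exhaustive and
    disjoint.
    """
    _check_same_genome(chip_peaks, atac_peaks)
    atac_trees = atac_peaks.trees()
    acc, inacc = [], []
    for iv in chip_peaks:
        (acc if _overlaps_any(iv, atac_trees, min_bp) else inacc).append(iv)
    return (
        PeakSet(f"{chip_peaks.label}_accessible", acc, chip_peaks.genome,
                allow_duplicates=True),
        PeakSet(f"{chip_peaks.label}_inaccessible", inacc, chip_peaks.genome,
                allow_duplicates=True),
    )


def _class_values(
    peaks: PeakSet,
    tss: Sequence[TSSRecord],
    motif_counts: Mapping[str, int] | None,
) -> dict[str, np.ndarray]:
    links = annotate_nearest_tss(peaks, tss, window=None)
    out = {
        "distance": links.loc[links["gene"].notna(), "abs_distance"].to_numpy(float),
    }
    scores = [iv.score for iv in peaks]
    out["score"] = (
        np.array([s for s in scores if s is not None], dtype=float)
        if any(s is not None for s in scores) else np.array([])
    )
    if motif_counts is not None:
        out["motif_count"] = np.array(
            [motif_counts.get(iv.name, 0) for iv in peaks], dtype=float
        )
    return out


def accessibility_contrasts(
    accessible: PeakSet,
    inaccessible: PeakSet,
    tss: Sequence[TSSRecord],
    motif_counts: Mapping[str, int] | None = None,
) -> dict[str, dict]:
    """Contrast accessible vs inaccessible ChIP peaks with Welch t-tests.

    Three two-tailed heteroscedastic comparisons: |distance to nearest
    TSS|, peak score (intensity), and per-peak motif count (when
    provided). Classes of size < 2 yield a ``degenerate`` status for the
    affected contrast.
    """
    if len(accessible) == 0 or len(inaccessible) == 0:
        raise ValueError("both accessibility classes must be non-empty")
    va = _class_values(accessible, tss, motif_counts)
    vb = _class_values(inaccessible, tss, motif_counts)

    report: dict[str, dict] = {}
    for key in va:
        a, b = va[key], vb[key]
        entry = {
            "mean_accessible": float(a.mean()) if a.size else np.nan,
            "mean_inaccessible": float(b.mean()) if b.size else np.nan,
            "n_accessible": int(a.size), "n_inaccessible": int(b.size),
        }
        if a.size < 2 or b.size < 2:
            entry.update(t=np.nan, df=np.nan, p=np.nan, status="degenerate")
        else:
            res: TTestResult = t_test(a, b, variance_mode="heteroscedastic")
            entry.update(t=res.t, df=res.df, p=res.p, status=res.status)
        report[key] = entry
    return report


def crosstab_peak_sets(
    chip_peaks: PeakSet,
    others: Mapping[str, PeakSet],
    min_bp: int = 1,
) -> pd.DataFrame:
    """Count ChIP peaks overlapping each comparison set and neither.

    When the comparison sets are mutually disjoint the rows partition the
    ChIP set; peaks hitting several sets are counted in each (and in
    ``multiple``).
    """
    for other in others.values():
        _check_same_genome(chip_peaks, other)
    trees = {label: s.trees() for label, s in others.items()}
    counts = {label: 0 for label in others}
    counts["neither"] = 0
    counts["multiple"] = 0
    for iv in chip_peaks:
        hits = [label for label, t in trees.items() if _overlaps_any(iv, t, min_bp)]
        if not hits:
            counts["neither"] += 1
        else:
            for label in hits:
                counts[label] += 1
            if len(hits) > 1:
                counts["multiple"] += 1
    return pd.DataFrame(
        {"set": list(counts), "count": list(counts.values()),
         "fraction": [c / len(chip_peaks) if len(chip_peaks) else np.nan
                      for c in counts.values()]}
    )
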