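"""Differentially accessible region (DAR) calling from per-replicate peaks.

A region is differentially accessible in condition A when it is detected
at stringent significance (q <= cutoff, default 1e-5) in *every* A
replicate and does not overlap any peak called in condition B at the
default calling threshold. This is presence/absence-based differential
accessibility, not a read-count model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .annotation import TSSRecord, annotate_nearest_tss
from .expression import TTestResult, t_test
from .intervals import PeakSet, consensus_peaks, subtract_peaks

__all__ = ["DARResult", "call_dars", "dar_distance_contrast"]

_EXCLUDE_MODES = {"union", "consensus"}


@dataclass
class DARResult:
    """Condition-specific high-confidence DARs with calling provenance."""

    condition_a_dars: PeakSet
    condition_b_dars: PeakSet
    q_cutoff: float
    provenance: pd.DataFrame  # per-DAR: condition, coords, per-replicate q
    params: dict

    @property
    def counts(self) -> dict[str, int]:
        return {
            self.condition_a_dars.label: len(self.condition_a_dars),
            self.condition_b_dars.label: len(self.condition_b_dars),
        }


def _filter_q(reps: Sequence[PeakSet], q_cutoff: float) -> list[PeakSet]:
    out = []
    for rep in reps:
        for iv in rep:
            if iv.q_value is None:
                raise ValueError(
                    f"peak {iv.key()} in replicate {rep.label!r} has no q-value"
                )
        kept = [iv for iv in rep if iv.q_value <= q_cutoff]
        out.append(PeakSet(rep.label, kept, rep.genome, allow_duplicates=True))
    return out


def _union(reps: Sequence[PeakSet], label: str) -> PeakSet:
    ivs = [iv for rep in reps for iv in rep]
    genome = reps[0].genome if reps else None
    return PeakSet(label, ivs, genome, allow_duplicates=True)


def _one_side(
    own_reps: Sequence[PeakSet],
    other_reps: Sequence[PeakSet],
    q_cutoff: float,
    min_bp: int,
    exclude_mode: str,
    label: str,
) -> PeakSet:
    stringent = _filter_q(own_reps, q_cutoff)
    cons = consensus_peaks(stringent, min_bp=min_bp)
    if exclude_mode == "union":
        other = _union(other_reps, "other_union")
    else:
        other = consensus_peaks(list(other_reps), min_bp=min_bp)
    dars = subtract_peaks(cons, other, min_bp=min_bp)
    return dars.with_label(label)


def call_dars(
    cond_a_reps: Sequence[PeakSet],
    cond_b_reps: Sequence[PeakSet],
    q_cutoff: float = 1e-5,
    min_bp: int = 1,
    exclude_mode: str = "union",
    labels: tuple[str, str] = ("A", "B"),
) -> DARResult:
    """Call condition-specific DARs from two sets of replicate peak calls.

    Condition-A DARs are the consensus (reference-replicate coordinates) of
    A peaks passing ``q <= q_cutoff`` in every A replicate, minus any
    interval overlapping the union of all B peaks (unfiltered) by
    ``min_bp``; symmetric for B. ``exclude_mode="consensus"`` instead
    excludes against the other condition's unfiltered consensus (the more
    permissive reading).
    """
    if len(cond_a_reps) < 2 or len(cond_b_reps) < 2:
        raise ValueError("each condition requires >= 2 replicates")
    if not (0.0 < q_cutoff < 1.0):
        raise ValueError(f"q_cutoff must be in (0,1), got {q_cutoff}")
    if exclude_mode not in _EXCLUDE_MODES:
        raise ValueError(f"exclude_mode must be one of {_EXCLUDE_MODES}")

    dars_a = _one_side(cond_a_reps, cond_b_reps, q_cutoff, min_bp, exclude_mode,
                       f"{labels[0]}_dars")
    dars_b = _one_side(cond_b_reps, cond_a_reps, q_cutoff, min_bp, exclude_mode,
                       f"{labels[1]}_dars")

    rows = []
    for cond, dars, reps in ((labels[0], dars_a, cond_a_reps), (labels[1], dars_b, cond_b_reps)):
        from .intervals import intersect_sets  # local import to avoid cycle at module load

        rep_hits = [intersect_sets(dars, rep, min_bp=min_bp) for rep in reps] if len(dars) else []
        for i, iv in enumerate(dars):
            row = {"condition": cond, "chrom": iv.chrom, "start": iv.start,
                   "end": iv.end, "q_value_ref": iv.q_value}
            for r, (rep, hits) in enumerate(zip(reps, rep_hits)):
                sub = hits[hits["a_index"] == i]
                qs = [rep[int(bi)].q_value for bi in sub["b_index"]]
                row[f"rep{r + 1}_min_q"] = min(qs) if qs else np.nan
            rows.append(row)
    provenance = pd.DataFrame(rows)
    return DARResult(
        condition_a_dars=dars_a,
        condition_b_dars=dars_b,
        q_cutoff=q_cutoff,
        provenance=provenance,
        params={"min_bp": min_bp, "exclude_mode": exclude_mode,
                "reference_replicate": 0},
    )


def dar_distance_contrast(
    dars_a: PeakSet,
    dars_b: PeakSet,
    tss: Sequence[TSSRecord],
) -> dict:
    """Compare DAR-to-nearest-TSS distances between two DAR sets.

    Computes |midpoint - nearest TSS| for each DAR and contrasts the two
    samples with a two-tailed homoscedastic (pooled-variance) t-test.
    Degenerate zero-variance inputs are flagged rather than returning NaN.
    """
    if len(dars_a) == 0 or len(dars_b) == 0:
        raise ValueError("both DAR sets must be non-empty")
    if not tss:
        raise ValueError("TSS table must be non-empty")

    def distances(peaks: PeakSet) -> np.ndarray:
        links = annotate_nearest_tss(peaks, tss, window=None)
        d = links.loc[links["gene"].notna(), "abs_distance"].to_numpy(dtype=float)
        if d.size == 0:
            raise ValueError(f"no DAR in {peaks.label!r} has a TSS on its chromosome")
        return d

    da, db = distances(dars_a), distances(dars_b)
    result: TTestResult = t_test(da, db, variance_mode="homoscedastic")
    return {
        "mean_a": float(da.mean()),
        "mean_b": float(db.mean()),
        "n_a": int(da.size),
        "n_b": int(db.size),
        "t": result.t,
        "df": result.df,
        "p": result.p,
        "status": result.status,
    }
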