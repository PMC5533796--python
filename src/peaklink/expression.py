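"""Expression-side statistics.

Two-sample t-tests (pooled-variance and Welch), k-means clustering of
temporal expression profiles, pre-ranked gene-set enrichment with a
gene-tag permutation null and permutation FWER, and relative qPCR
quantification by the 2^-ddCt method.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

__all__ = [
    "TTestResult",
    "t_test",
    "KMeansResult",
    "kmeans_profiles",
    "EnrichmentReport",
    "enrichment_score",
    "preranked_enrichment",
    "delta_delta_ct",
]


# ---------------------------------------------------------------------------
# t-tests
# ---------------------------------------------------------------------------

@dataclass
class TTestResult:
    t: float
    df: float
    p: float
    status: str = "ok"


def t_test(
    sample_a: Sequence[float],
    sample_b: Sequence[float],
    variance_mode: str = "homoscedastic",
) -> TTestResult:
    """Two-sided two-sample t-test.

    ``homoscedastic`` uses the pooled variance with ``df = n1 + n2 - 2``;
    ``heteroscedastic`` is Welch's t with Welch-Satterthwaite df. Inputs
    where both samples have zero variance are flagged ``degenerate``
    instead of producing NaN: equal means give t=0, p=1; unequal means an
    infinite t with p=0.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs n >= 2")
    if variance_mode not in {"homoscedastic", "heteroscedastic"}:
        raise ValueError("variance_mode must be homoscedastic or heteroscedastic")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        if a.mean() == b.mean():
            return TTestResult(t=0.0, df=float(a.size + b.size - 2), p=1.0,
                               status="degenerate")
        sign = 1.0 if a.mean() > b.mean() else -1.0
        return TTestResult(t=sign * np.inf, df=float(a.size + b.size - 2), p=0.0,
                           status="degenerate")
    res = stats.ttest_ind(a, b, equal_var=(variance_mode == "homoscedastic"))
    return TTestResult(t=float(res.statistic), df=float(res.df),
                       p=float(res.pvalue))


# ---------------------------------------------------------------------------
# k-means on expression profiles
# ---------------------------------------------------------------------------

@dataclass
class KMeansResult:
    assignments: pd.Series      # gene -> cluster id
    centroids: np.ndarray       # k x n_timepoints (in standardized space if used)
    within_ss: float
    cluster_fractions: dict[int, float]


def _row_standardize(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=0, keepdims=True)
    sd = np.where(sd == 0, 1.0, sd)
    return (x - mu) / sd


def kmeans_profiles(
    profiles: pd.DataFrame,
    k: int,
    seed: int = 0,
    n_restarts: int = 10,
    standardize: bool = True,
) -> KMeansResult:
    """Cluster temporal expression profiles (genes x timepoints) with k-means.

    Profiles are row-standardized (per-gene z-score across timepoints) by
    default so clusters reflect profile *shape* rather than absolute
    level. Lloyd's algorithm, Euclidean distance, best of ``n_restarts``
    by within-cluster sum of squares; deterministic given ``seed``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(profiles):
        raise ValueError(f"k={k} exceeds number of profiles {len(profiles)}")
    x = profiles.to_numpy(dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("profiles contain non-finite values")
    if standardize:
        x = _row_standardize(x)
    km = KMeans(
        n_clusters=k, n_init=n_restarts, random_state=seed, algorithm="lloyd"
    ).fit(x)
    labels = pd.Series(km.labels_, index=profiles.index, name="cluster")
    fracs = {int(c): float((km.labels_ == c).mean()) for c in range(k)}
    return KMeansResult(
        assignments=labels,
        centroids=km.cluster_centers_,
        within_ss=float(km.inertia_),
        cluster_fractions=fracs,
    )


# ---------------------------------------------------------------------------
# Pre-ranked gene-set enrichment
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentReport:
    gene_set: str
    es: float
    nes: float | None
    nominal_p: float
    fwer_p: float | None
    leading_edge: list[str]
    n_hits: int


def enrichment_score(
    genes: Sequence[str],
    scores: np.ndarray,
    member: np.ndarray,
    weight: float = 1.0,
) -> tuple[float, int]:
    """Weighted Kolmogorov-Smirnov enrichment score.

    ``member`` is a boolean hit indicator aligned with the descending
    ranked list. Hits increment by |score|^weight (normalized to sum 1);
    misses decrement by 1/(N - Nh). Returns (ES, index of the extreme
    deviation). ES is the running-sum value of largest magnitude.
    """
    n = len(genes)
    nh = int(member.sum())
    if nh == 0 or nh == n:
        raise ValueError("gene set must hit the ranked list but not cover it")
    w = np.abs(scores) ** weight
    hit_w = np.where(member, w, 0.0)
    total = hit_w.sum()
    if total == 0:  # all hit scores are exactly 0 (possible with weight>0)
        hit_w = member.astype(float)
        total = float(nh)
    inc = hit_w / total
    dec = np.where(member, 0.0, 1.0 / (n - nh))
    running = np.cumsum(inc - dec)
    i = int(np.argmax(np.abs(running)))
    return float(running[i]), i


def preranked_enrichment(
    ranked: pd.DataFrame,
    gene_sets: Mapping[str, set] | set,
    weight: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
) -> list[EnrichmentReport]:
    """Pre-ranked GSEA with a gene-tag permutation null.

    ``ranked`` has columns ``gene`` and ``score``; rows are sorted by
    score descending (ties keep their original order). The null draws
    random same-size gene sets from the ranked genes; NES divides ES by
    the mean |null ES| of the same sign; nominal p uses the add-one
    convention over same-sign null ES values. When several sets are
    tested together, the FWER p compares each |NES| against the
    permutation distribution of the maximum |NES| across sets.
    """
    if isinstance(gene_sets, (set, frozenset)):
        gene_sets = {"gene_set": set(gene_sets)}
    genes = [str(g) for g in ranked["gene"]]
    if len(set(genes)) != len(genes):
        raise ValueError("ranked list contains duplicate genes")
    scores = ranked["score"].to_numpy(dtype=float)
    order = np.argsort(-scores, kind="stable")  # descending, stable for ties
    genes = [genes[i] for i in order]
    scores = scores[order]
    n = len(genes)
    gene_index = {g: i for i, g in enumerate(genes)}
    rng = np.random.default_rng(seed)

    observed: dict[str, tuple[float, int, np.ndarray]] = {}
    for label, members in gene_sets.items():
        hit_idx = sorted(gene_index[g] for g in members if g in gene_index)
        if not hit_idx:
            raise ValueError(f"gene set {label!r} is disjoint from the ranked list")
        if len(hit_idx) == n:
            raise ValueError(f"gene set {label!r} covers the whole ranked list")
        member = np.zeros(n, dtype=bool)
        member[hit_idx] = True
        es, peak = enrichment_score(genes, scores, member, weight)
        observed[label] = (es, peak, member)

    # permutation null: random gene tags, one draw per (set, permutation)
    null_es = {label: np.empty(n_perm) for label in gene_sets}
    for label, members in gene_sets.items():
        nh = int(observed[label][2].sum())
        for j in range(n_perm):
            member = np.zeros(n, dtype=bool)
            member[rng.choice(n, size=nh, replace=False)] = True
            null_es[label][j], _ = enrichment_score(genes, scores, member, weight)

    def normalize(es: float, null: np.ndarray) -> float | None:
        same = null[null >= 0] if es >= 0 else null[null < 0]
        if same.size == 0:
            return None
        denom = float(np.abs(same).mean())
        return es / denom if denom > 0 else None

    nes_null: dict[str, np.ndarray] = {}
    reports: list[EnrichmentReport] = []
    for label in gene_sets:
        es, peak, member = observed[label]
        null = null_es[label]
        pos_mean = np.abs(null[null >= 0]).mean() if np.any(null >= 0) else np.nan
        neg_mean = np.abs(null[null < 0]).mean() if np.any(null < 0) else np.nan
        with np.errstate(invalid="ignore", divide="ignore"):
            nn = np.where(null >= 0, null / pos_mean, null / np.where(neg_mean > 0, neg_mean, np.nan))
        nes_null[label] = nn
        same = null[null >= 0] if es >= 0 else null[null < 0]
        nominal_p = (1 + int((np.abs(same) >= abs(es)).sum())) / (1 + same.size) \
            if same.size else 1.0
        hit_positions = np.flatnonzero(member)
        leading = [genes[i] for i in hit_positions[hit_positions <= peak]] if es >= 0 \
            else [genes[i] for i in hit_positions[hit_positions >= peak]]
        reports.append(
            EnrichmentReport(
                gene_set=label, es=es, nes=normalize(es, null),
                nominal_p=float(nominal_p), fwer_p=None,
                leading_edge=leading, n_hits=int(member.sum()),
            )
        )

    # FWER over the max-|NES| null across all sets tested together
    stacked = np.vstack([nes_null[label] for label in gene_sets])
    with np.errstate(invalid="ignore"):
        max_null = np.nanmax(np.abs(stacked), axis=0)
    for report in reports:
        if report.nes is not None:
            exceed = int(np.nansum(max_null >= abs(report.nes)))
            report.fwer_p = (1 + exceed) / (1 + n_perm)
    return reports


# ---------------------------------------------------------------------------
# qPCR 2^-ddCt
# ---------------------------------------------------------------------------

def delta_delta_ct(
    records: pd.DataFrame,
    reference_group: str,
    reference_gene: str = "Actb",
) -> pd.DataFrame:
    """Relative qPCR quantification by the 2^-ddCt method.

    ``records`` columns: sample, group, gene, ct. Per sample,
    ``dCt = Ct(target) - Ct(reference_gene)``; per target gene and group,
    ``ddCt = mean dCt(group) - mean dCt(reference_group)`` and
    ``fold = 2^-ddCt``. Group differences in dCt are tested with the
    two-tailed homoscedastic t-test. Fold changes are invariant to any
    per-sample additive Ct shift applied to both target and reference.
    """
    required = {"sample", "group", "gene", "ct"}
    if not required.issubset(records.columns):
        raise ValueError(f"records require columns {sorted(required)}")
    if reference_group not in set(records["group"]):
        raise ValueError(f"reference group {reference_group!r} not present")

    ref_ct = (
        records[records["gene"] == reference_gene]
        .set_index("sample")["ct"]
    )
    targets = records[records["gene"] != reference_gene].copy()
    missing = sorted(set(targets["sample"]) - set(ref_ct.index))
    if missing:
        raise ValueError(
            f"sample(s) missing a {reference_gene} Ct: {', '.join(missing)}"
        )
    targets["dct"] = targets["ct"].to_numpy() - ref_ct.loc[targets["sample"]].to_numpy()

    rows = []
    for gene, sub in targets.groupby("gene", sort=True):
        ref_dct = sub.loc[sub["group"] == reference_group, "dct"].to_numpy()
        if ref_dct.size == 0:
            raise ValueError(f"gene {gene!r} has no measurements in the reference group")
        for group, grp in sub.groupby("group", sort=True):
            dct = grp["dct"].to_numpy()
            ddct = float(dct.mean() - ref_dct.mean())
            fold = float(2.0 ** (-ddct))
            if group != reference_group and dct.size >= 2 and ref_dct.size >= 2:
                tt = t_test(dct, ref_dct, variance_mode="homoscedastic")
                t, p, status = tt.t, tt.p, tt.status
            else:
                t, p, status = np.nan, np.nan, "not_tested"
            sem = float(dct.std(ddof=1) / np.sqrt(dct.size)) if dct.size > 1 else np.nan
            rows.append(
                {
                    "gene": gene, "group": group, "n": int(dct.size),
                    "mean_dct": float(dct.mean()), "sem_dct": sem,
                    "ddct": ddct, "fold_change": fold,
                    "t": t, "p": p, "status": status,
                }
            )
    return pd.DataFrame(rows)
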