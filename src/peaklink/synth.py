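"""Synthetic data with planted ground truth for every pipeline stage.

Generates toy genomes, two-condition replicated peak experiments,
TSS/repeat annotations, differential-expression tables with planted
peak-linked targets, temporal expression profiles from two archetypes,
and peak sequences with motifs inserted at known per-class rates. Every
generator is deterministic given (parameters, seed) and records its
planted structure in a :class:`GroundTruth` manifest sufficient to
recompute every expected pipeline output.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import GenomeModel, GenomicInterval, PeakSet
from .motif import ALPHABET, PWM
from .randomization import CoverageIndex

__all__ = [
    "GroundTruth",
    "make_genome",
    "make_peak_experiment",
    "make_annotations",
    "make_expression_and_targets",
    "make_sequences_with_motif",
    "default_pwm",
    "default_bundle",
]


@dataclass
class GroundTruth:
    """Manifest of everything the generators planted."""

    seed: int
    params: dict = field(default_factory=dict)
    shared_regions: list = field(default_factory=list)        # (chrom, start, end)
    a_only_regions: list = field(default_factory=list)
    b_only_regions: list = field(default_factory=list)
    repeat_background_fraction: float | None = None
    enriched_family: str | None = None
    enriched_rate: float | None = None
    depleted_family: str | None = None
    target_genes: list = field(default_factory=list)
    decoy_genes: list = field(default_factory=list)
    cluster_membership: dict = field(default_factory=dict)    # gene -> cluster
    motif_positions: dict = field(default_factory=dict)       # peak -> [offsets]
    motif_rates: dict = field(default_factory=dict)           # class -> rate

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=str)


def make_genome(
    lengths: Sequence[int] = (5_000_000, 5_000_000),
    seed: int = 0,
    excluded_fraction: float = 0.0,
) -> GenomeModel:
    """A toy genome of chr1..chrN with optional random excluded regions."""
    if not lengths:
        raise ValueError("lengths must be non-empty")
    chroms = {f"chr{i + 1}": int(L) for i, L in enumerate(lengths)}
    excluded = None
    if excluded_fraction > 0:
        rng = np.random.default_rng(seed)
        block = 10_000
        ivs = []
        for chrom, L in chroms.items():
            n_blocks = int(round(excluded_fraction * L / block))
            starts = rng.choice(L // block, size=n_blocks, replace=False) * block
            ivs.extend(GenomicInterval(chrom, int(s), int(s) + block) for s in sorted(starts))
        excluded = PeakSet("excluded", ivs, allow_duplicates=True)
    return GenomeModel(chroms, excluded=excluded)


def _place_nonoverlapping(
    rng: np.random.Generator,
    genome: GenomeModel,
    n: int,
    length: int,
    margin: int,
    occupied: list[tuple[str, int, int]],
) -> list[tuple[str, int, int]]:
    """Place n regions of ``length`` bp, pairwise separated by >= margin."""
    chrom_names = list(genome.chromosomes)
    chrom_lens = np.array([genome.chromosomes[c] for c in chrom_names], dtype=float)
    weights = chrom_lens / chrom_lens.sum()
    placed: list[tuple[str, int, int]] = []
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for c, s, e in occupied:
        by_chrom.setdefault(c, []).append((s, e))
    attempts = 0
    while len(placed) < n:
        attempts += 1
        if attempts > 200 * max(n, 1):
            raise ValueError(
                f"genome too small to place {n} non-overlapping regions of {length} bp"
            )
        ci = rng.choice(len(chrom_names), p=weights)
        chrom = chrom_names[ci]
        max_start = genome.chromosomes[chrom] - length
        if max_start <= 0:
            continue
        s = int(rng.integers(0, max_start))
        e = s + length
        clash = any(
            s - margin < oe and os_ < e + margin for os_, oe in by_chrom.get(chrom, [])
        )
        if clash:
            continue
        placed.append((chrom, s, e))
        by_chrom.setdefault(chrom, []).append((s, e))
        occupied.append((chrom, s, e))
    return placed


def make_peak_experiment(
    genome: GenomeModel,
    n_shared: int = 120,
    n_a_only: int = 40,
    n_b_only: int = 40,
    n_replicates: int = 2,
    peak_length: int = 400,
    replicate_jitter: int = 20,
    q_params: Mapping[str, tuple[float, float]] | None = None,
    seed: int = 0,
    labels: tuple[str, str] = ("A", "B"),
) -> tuple[dict[str, list[PeakSet]], GroundTruth]:
    """Two-condition, replicated peak calls with planted shared and
    condition-specific regions.

    Shared regions appear in all replicates of both conditions;
    condition-only regions only in that condition's replicates. Replicate
    boundaries jitter by up to ``replicate_jitter`` bp per edge;
    q-values are drawn log-uniformly from class-specific ranges
    (defaults: condition-specific [1e-9, 1e-6], clear of the 1e-5 DAR
    cutoff; shared [1e-8, 1e-3], straddling it).
    """
    if q_params is None:
        q_params = {"shared": (1e-8, 1e-3), "a_only": (1e-9, 1e-6),
                    "b_only": (1e-9, 1e-6)}
    rng = np.random.default_rng(seed)
    occupied: list[tuple[str, int, int]] = []
    margin = 2 * replicate_jitter + 100
    shared = _place_nonoverlapping(rng, genome, n_shared, peak_length, margin, occupied)
    a_only = _place_nonoverlapping(rng, genome, n_a_only, peak_length, margin, occupied)
    b_only = _place_nonoverlapping(rng, genome, n_b_only, peak_length, margin, occupied)

    def draw_q(cls: str) -> float:
        lo, hi = q_params[cls]
        return float(10 ** rng.uniform(np.log10(lo), np.log10(hi)))

    def jitter(v: int) -> int:
        if replicate_jitter == 0:
            return v
        return v + int(rng.integers(-replicate_jitter, replicate_jitter + 1))

    conditions: dict[str, list[PeakSet]] = {}
    for cond, regions in ((labels[0], [("shared", shared), ("a_only", a_only)]),
                          (labels[1], [("shared", shared), ("b_only", b_only)])):
        reps = []
        for r in range(n_replicates):
            ivs = []
            for cls, coords in regions:
                for k, (chrom, s, e) in enumerate(coords):
                    s2 = max(0, jitter(s))
                    e2 = min(genome.chromosomes[chrom], jitter(e))
                    if e2 <= s2:
                        s2, e2 = s, e
                    ivs.append(
                        GenomicInterval(
                            chrom, s2, e2, name=f"{cls}_{k}",
                            score=float(rng.uniform(5, 50)), q_value=draw_q(cls),
                        )
                    )
            reps.append(PeakSet(f"{cond}_rep{r + 1}", ivs, genome, allow_duplicates=True))
        conditions[cond] = reps

    truth = GroundTruth(
        seed=seed,
        params={
            "n_shared": n_shared, "n_a_only": n_a_only, "n_b_only": n_b_only,
            "n_replicates": n_replicates, "peak_length": peak_length,
            "replicate_jitter": replicate_jitter,
            "q_params": {k: list(v) for k, v in q_params.items()},
        },
        shared_regions=shared, a_only_regions=a_only, b_only_regions=b_only,
    )
    return conditions, truth


def make_annotations(
    genome: GenomeModel,
    n_genes: int = 500,
    repeat_families: Mapping[str, float] | None = None,
    repeat_length: int = 150,
    enriched_family: str | None = "ERV_fam",
    enriched_rate: float = 0.6,
    enriched_in: PeakSet | None = None,
    depleted_family: str | None = None,
    depleted_in: PeakSet | None = None,
    seed: int = 1,
    truth: GroundTruth | None = None,
) -> tuple[list, PeakSet, GroundTruth]:
    """Uniform TSS annotation plus a RepeatMasker-style repeat track.

    ``repeat_families`` maps family name to the fraction of random
    ~peak-sized regions expected to overlap that family genome-wide (the
    background rate). ``enriched_family`` additionally gets one insertion
    inside each of a ``enriched_rate`` fraction of ``enriched_in`` peaks;
    ``depleted_family`` background copies are rejected from
    ``depleted_in`` peaks, planting depletion below background.
    """
    from .annotation import TSSRecord

    if repeat_families is None:
        repeat_families = {"B1_fam": 0.05, "ERV_fam": 0.05}
    rng = np.random.default_rng(seed)
    chrom_names = list(genome.chromosomes)
    chrom_lens = np.array([genome.chromosomes[c] for c in chrom_names], dtype=float)
    weights = chrom_lens / chrom_lens.sum()
    G = float(chrom_lens.sum())

    tss = []
    for i in range(n_genes):
        ci = rng.choice(len(chrom_names), p=weights)
        pos = int(rng.integers(0, chrom_lens[ci]))
        strand = "+" if rng.random() < 0.5 else "-"
        tss.append(TSSRecord(f"gene{i:04d}", chrom_names[ci], pos, strand))

    avoid = CoverageIndex(depleted_in) if (depleted_in is not None and len(depleted_in)) else None
    repeats: list[GenomicInterval] = []
    region_len = 400  # nominal query-region size the background rate refers to
    for fam, bg_rate in repeat_families.items():
        # number of copies so that P(random region overlaps >=1 copy) ~ bg_rate
        n_copies = int(round(-np.log(max(1 - bg_rate, 1e-12)) * G
                             / (repeat_length + region_len)))
        placed = 0
        guard = 0
        while placed < n_copies:
            guard += 1
            if guard > 100 * max(n_copies, 1):
                raise ValueError(f"infeasible repeat density for family {fam!r}")
            ci = rng.choice(len(chrom_names), p=weights)
            s = int(rng.integers(0, chrom_lens[ci] - repeat_length))
            if fam == depleted_family and avoid is not None:
                ov = avoid.overlap_bp(chrom_names[ci], np.array([s]),
                                      np.array([s + repeat_length]))[0]
                if ov > 0:
                    continue
            repeats.append(
                GenomicInterval(chrom_names[ci], s, s + repeat_length, name=fam)
            )
            placed += 1
        if fam == enriched_family and enriched_in is not None:
            for iv in enriched_in:
                if rng.random() < enriched_rate:
                    lo = iv.start
                    hi = max(iv.end - repeat_length, lo + 1)
                    s = int(rng.integers(lo, hi))
                    e = min(s + repeat_length, genome.chromosomes[iv.chrom])
                    repeats.append(GenomicInterval(iv.chrom, s, e, name=fam))

    repeat_set = PeakSet("repeats", repeats, genome, allow_duplicates=True)
    if truth is None:
        truth = GroundTruth(seed=seed)
    truth.params.update(
        {"n_genes": n_genes, "repeat_families": dict(repeat_families),
         "repeat_length": repeat_length}
    )
    truth.repeat_background_fraction = (
        repeat_families.get(enriched_family, 0.0) if enriched_family else None
    )
    truth.enriched_family = enriched_family
    truth.enriched_rate = enriched_rate if enriched_family else None
    truth.depleted_family = depleted_family
    return tss, repeat_set, truth


def make_expression_and_targets(
    tss: Sequence,
    genome: GenomeModel,
    n_targets: int = 30,
    n_decoys: int = 30,
    n_background_peaks: int = 60,
    window: int = 100_000,
    fc_range: tuple[float, float] = (1.6, 4.0),
    p_range: tuple[float, float] = (1e-5, 0.04),
    peak_length: int = 300,
    noise_sd: float = 0.2,
    n_timepoints: int = 4,
    seed: int = 2,
    truth: GroundTruth | None = None,
) -> tuple[PeakSet, list, pd.DataFrame, GroundTruth]:
    """Plant ChIP-linked derepressed target genes in a DE table.

    Each of ``n_targets`` genes gets a ChIP peak placed within the window
    of its TSS *and* verifiably nearest to it, with fold change drawn in
    ``fc_range`` (>= 1.5) and p in ``p_range`` (<= 0.05). ``n_decoys``
    genes pass both expression thresholds but have no ChIP peak within
    the window. All other genes draw fold changes near 1 and null
    p-values. Temporal profiles for target genes come from two archetypes
    (stem-state high / differentiation-induced) plus Gaussian noise.

    Returns (chip_peaks, profiles, DE table, truth).
    """
    rng = np.random.default_rng(seed)
    genes = list(tss)
    if n_targets + n_decoys > len(genes):
        raise ValueError("not enough genes for requested targets and decoys")
    order = rng.permutation(len(genes))

    by_chrom: dict[str, list] = {}
    for rec in genes:
        by_chrom.setdefault(rec.chrom, []).append(rec)

    def nearest_gene(chrom: str, pos: int) -> str:
        recs = by_chrom[chrom]
        best = min(recs, key=lambda r: (abs(r.position - pos), r.gene))
        return best.gene

    # choose targets whose TSS admits a peak that is nearest to them
    chip_ivs: list[GenomicInterval] = []
    target_genes: list[str] = []
    idx = 0
    while len(target_genes) < n_targets and idx < len(order):
        rec = genes[order[idx]]
        idx += 1
        ok = False
        for _ in range(50):
            d = int(rng.integers(1_000, 80_000)) * (1 if rng.random() < 0.5 else -1)
            mid = rec.position + d
            s = mid - peak_length // 2
            if s < 0 or s + peak_length > genome.chromosomes[rec.chrom]:
                continue
            if nearest_gene(rec.chrom, mid) == rec.gene:
                ok = True
                break
        if not ok:
            continue
        chip_ivs.append(
            GenomicInterval(
                rec.chrom, s, s + peak_length,
                name=f"chip_{len(target_genes):03d}",
                score=float(rng.uniform(5, 80)),
            )
        )
        target_genes.append(rec.gene)
    if len(target_genes) < n_targets:
        raise ValueError("not enough genes admit a nearest peak within the window")

    # non-functional background occupancy: peaks whose nearby genes stay
    # unchanged in expression (decoy selection below avoids them)
    chrom_names = list(genome.chromosomes)
    chrom_lens = np.array([genome.chromosomes[c] for c in chrom_names], dtype=float)
    cweights = chrom_lens / chrom_lens.sum()
    for k in range(n_background_peaks):
        ci = int(rng.choice(len(chrom_names), p=cweights))
        s = int(rng.integers(0, chrom_lens[ci] - peak_length))
        chip_ivs.append(
            GenomicInterval(
                chrom_names[ci], s, s + peak_length, name=f"chipbg_{k:03d}",
                score=float(rng.uniform(5, 80)),
            )
        )

    # decoys: pass thresholds but no peak within window of their TSS
    chip_cov = CoverageIndex(PeakSet("chip_tmp", chip_ivs, allow_duplicates=True))
    decoy_genes: list[str] = []
    for j in order[idx:]:
        if len(decoy_genes) >= n_decoys:
            break
        rec = genes[j]
        lo = max(0, rec.position - window - peak_length)
        hi = min(genome.chromosomes[rec.chrom], rec.position + window + peak_length)
        if chip_cov.overlap_bp(rec.chrom, np.array([lo]), np.array([hi]))[0] == 0:
            decoy_genes.append(rec.gene)
    if len(decoy_genes) < n_decoys:
        raise ValueError("not enough peak-free genes for the requested decoys")

    special = set(target_genes) | set(decoy_genes)
    rows = []
    for rec in genes:
        if rec.gene in special:
            fc = float(10 ** rng.uniform(np.log10(fc_range[0]), np.log10(fc_range[1])))
            p = float(10 ** rng.uniform(np.log10(p_range[0]), np.log10(p_range[1])))
        else:
            fc = float(2 ** rng.normal(0.0, 0.1))       # near 1
            p = float(rng.uniform(0.2, 1.0))            # clearly non-significant
        score = float(-10 * np.log10(p) * np.sign(np.log2(fc)))
        rows.append(
            {"gene": rec.gene, "fold_change": fc, "p_value": p,
             "adj_p": min(1.0, p * len(genes) / 10), "rank_score": score}
        )
    de = pd.DataFrame(rows)

    # temporal profiles for target genes from two archetypes
    t = np.linspace(0, 1, n_timepoints)
    archetypes = {0: 1.0 - 2.0 * t, 1: -1.0 + 2.0 * t}  # stem-high vs induced
    membership: dict[str, int] = {}
    profiles = {}
    for g in target_genes:
        c = int(rng.integers(0, 2))
        membership[g] = c
        profiles[g] = archetypes[c] + rng.normal(0.0, noise_sd, size=n_timepoints)
    profile_df = pd.DataFrame(profiles).T
    profile_df.columns = [f"t{j}" for j in range(n_timepoints)]
    profile_df.index.name = "gene"

    chip_peaks = PeakSet("chip", chip_ivs, genome, allow_duplicates=True)
    if truth is None:
        truth = GroundTruth(seed=seed)
    truth.params.update(
        {"n_targets": n_targets, "n_decoys": n_decoys,
         "n_background_peaks": n_background_peaks, "window": window,
         "fc_range": list(fc_range), "p_range": list(p_range),
         "noise_sd": noise_sd, "n_timepoints": n_timepoints}
    )
    truth.target_genes = sorted(target_genes)
    truth.decoy_genes = sorted(decoy_genes)
    truth.cluster_membership = membership
    return chip_peaks, profile_df, de, truth


DEFAULT_PWM_CONSENSUS = "GAAAGTGAAAG"


def default_pwm(name: str = "synthetic_motif", info: float = 0.9) -> PWM:
    """A synthetic high-information 11-bp PWM used by the sequence generator.

    Each position gives probability ``info`` to the consensus base and
    splits the remainder evenly; this is a made-up stand-in motif, not a
    matrix taken from any database.
    """
    rows = []
    for base in DEFAULT_PWM_CONSENSUS:
        row = [(1.0 - info) / 3.0] * 4
        row["ACGT".index(base)] = info
        rows.append(row)
    return PWM(name=name, matrix=np.array(rows))


def make_sequences_with_motif(
    peaks: PeakSet,
    pwm: PWM,
    rate_per_class: Mapping[str, float],
    class_of_peak: Mapping[str, str],
    background_gc: float = 0.5,
    seed: int = 3,
    truth: GroundTruth | None = None,
) -> tuple[dict[str, str], GroundTruth]:
    """Per-peak sequences with consensus motifs planted at class rates.

    Background is i.i.d. with the given GC fraction; each peak receives
    ``Poisson(rate)`` insertions of the PWM consensus at non-overlapping
    random offsets (rate taken from its class). Planted offsets are
    recorded in the truth manifest.
    """
    rng = np.random.default_rng(seed)
    p_bg = np.array([(1 - background_gc) / 2, background_gc / 2,
                     background_gc / 2, (1 - background_gc) / 2])
    consensus = pwm.consensus()
    L = pwm.length
    seqs: dict[str, str] = {}
    positions: dict[str, list[int]] = {}
    for i, iv in enumerate(peaks):
        name = iv.name if iv.name is not None else f"{peaks.label}_{i}"
        length = iv.length
        cls = class_of_peak[name]
        rate = rate_per_class[cls]
        if length < L and rate > 0:
            raise ValueError(f"peak {name!r} shorter than the motif")
        seq = list("".join(rng.choice(list(ALPHABET), size=length, p=p_bg)))
        n_ins = int(rng.poisson(rate)) if rate > 0 else 0
        placed: list[int] = []
        for _ in range(n_ins):
            for _try in range(100):
                off = int(rng.integers(0, length - L + 1))
                if all(abs(off - q) >= L for q in placed):
                    placed.append(off)
                    seq[off:off + L] = list(consensus)
                    break
        seqs[name] = "".join(seq)
        positions[name] = sorted(placed)
    if truth is None:
        truth = GroundTruth(seed=seed)
    truth.motif_positions = positions
    truth.motif_rates = dict(rate_per_class)
    truth.params.update({"background_gc": background_gc, "pwm_consensus": consensus})
    return seqs, truth


def default_bundle(seed: int = 17, out_dir: str | Path | None = None) -> dict:
    """The default synthetic study: genome, peaks, annotations, DE table,
    profiles and motif sequences, with one merged ground-truth manifest.

    With ``out_dir`` set, writes chrom.sizes, narrowPeak replicates, TSS
    TSV, repeat TSV, DE TSV, profile TSV, FASTA, MEME motif and
    ground_truth.json.
    """
    rng = np.random.default_rng(seed)
    s1, s2, s3, s4 = (int(x) for x in rng.integers(0, 2**31 - 1, size=4))

    genome = make_genome(seed=s1)
    conditions, truth = make_peak_experiment(genome, seed=s1)

    # accessibility: condition-A consensus regions are the "open" set
    from .intervals import consensus_peaks

    atac = consensus_peaks(conditions["A"])
    tss, repeats, truth = make_annotations(
        genome, enriched_in=atac, seed=s2, truth=truth
    )
    chip, profiles, de, truth = make_expression_and_targets(
        tss, genome, seed=s3, truth=truth
    )
    pwm = default_pwm()
    from .targets import classify_peak_accessibility

    # plant a ~2:1 accessible:inaccessible split of the ChIP peaks by
    # adding an open-chromatin region over each designated accessible peak
    chip_cov = CoverageIndex(atac)
    extra_open: list[GenomicInterval] = []
    class_of_peak: dict[str, str] = {}
    for i, iv in enumerate(chip):
        already = chip_cov.overlap_bp(
            iv.chrom, np.array([iv.start]), np.array([iv.end])
        )[0] > 0
        if already or i % 3 != 2:
            class_of_peak[iv.name] = "accessible"
            if not already:
                pad = 100
                s = max(0, iv.start - pad)
                e = min(genome.chromosomes[iv.chrom], iv.end + pad)
                extra_open.append(GenomicInterval(iv.chrom, s, e, name=f"open_{iv.name}"))
        else:
            class_of_peak[iv.name] = "inaccessible"
    atac_full = PeakSet(
        "atac_open", list(atac) + extra_open, genome, allow_duplicates=True
    )
    acc, inacc = classify_peak_accessibility(chip, atac_full)
    truth.params["accessibility_classes"] = dict(class_of_peak)
    seqs, truth = make_sequences_with_motif(
        chip, pwm, {"accessible": 1.0, "inaccessible": 3.0}, class_of_peak,
        seed=s4, truth=truth,
    )
    truth.seed = seed

    bundle = {
        "genome": genome, "conditions": conditions, "atac": atac,
        "atac_full": atac_full, "tss": tss, "repeats": repeats, "chip": chip,
        "profiles": profiles, "de": de, "pwm": pwm, "sequences": seqs,
        "truth": truth, "accessible": acc, "inaccessible": inacc,
    }
    if out_dir is not None:
        _write_bundle(bundle, Path(out_dir))
    return bundle


def _write_bundle(bundle: dict, out: Path) -> None:
    from .intervals import write_intervals
    from .motif import write_fasta, write_meme

    out.mkdir(parents=True, exist_ok=True)
    genome: GenomeModel = bundle["genome"]
    with open(out / "chrom.sizes", "w") as fh:
        for chrom, length in genome.chromosomes.items():
            fh.write(f"{chrom}\t{length}\n")
    for cond, reps in bundle["conditions"].items():
        for rep in reps:
            write_intervals(rep, out / f"{rep.label}.narrowPeak", dialect="narrowPeak")
    write_intervals(bundle["atac"], out / "atac_consensus.bed")
    write_intervals(bundle["atac_full"], out / "atac_open.bed")
    write_intervals(bundle["chip"], out / "chip_peaks.bed")
    with open(out / "tss.tsv", "w") as fh:
        fh.write("gene\tchrom\tposition\tstrand\n")
        for rec in bundle["tss"]:
            fh.write(f"{rec.gene}\t{rec.chrom}\t{rec.position}\t{rec.strand}\n")
    with open(out / "repeats.tsv", "w") as fh:
        fh.write("chrom\tstart\tend\tname\n")
        for iv in bundle["repeats"]:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\n")
    bundle["de"].to_csv(out / "de_table.tsv", sep="\t", index=False)
    bundle["profiles"].to_csv(out / "profiles.tsv", sep="\t")
    write_fasta(bundle["sequences"], out / "peak_sequences.fa")
    write_meme([bundle["pwm"]], out / "motif.meme")
    bundle["truth"].to_json(out / "ground_truth.json")
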