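# Methods

This note documents the statistical procedures implemented in peaklink,
their assumptions, the parameters that matter, and the design choices made
where the procedure admits more than one reasonable reading.

## Coordinates and interval algebra

All coordinates are 0-based half-open (BED convention); narrowPeak −log10
q-values are converted to linear on ingest (a sentinel of −1 means
missing). Overlap operations ignore strand — all peak data handled here is
unstranded. The default minimum overlap is `min_bp = 1` ("any overlap");
it is exposed everywhere as a flag because replicate-consensus pipelines
differ on this point and no single convention is canonical.

`consensus_peaks` keeps the *reference replicate's* coordinates (replicate
1 by default, recorded in the output) rather than merged spans: merged
coordinates would grow with replicate count and complicate the exact
recovery guarantees used in testing. `subtract_peaks` removes whole
intervals that touch the background at `min_bp`, never clipping
coordinates — appropriate for discarding non-specific peaks (e.g. peaks
also called in a knockout control), where a partial peak has no meaning.

All four algebra operations are tested for exact agreement with an
independent per-base boolean-array oracle on randomized instances.

## DAR calling

Differential accessibility is presence/absence based, not count based. A
condition-A DAR must (a) pass `q ≤ q_cutoff` (default 1 × 10⁻⁵, the
stringent peak-caller threshold) in **every** A replicate, taking the
consensus coordinates, and (b) overlap **no** peak of condition B. For
(b) the default excludes against the union of all B peaks at their
default calling threshold — the strictest reading, because a region
accessible in even one B replicate at ordinary significance is not
convincingly condition specific. `exclude_mode="consensus"` relaxes the
exclusion to B's replicate-consistent peaks. Both conditions are filtered
at the same cutoff before consensus; the exclusion step uses unfiltered
peaks. DAR counts are monotone in `q_cutoff` by construction.

## Randomized-null overlap significance

The two-step procedure for deciding whether two peak sets overlap more
than chance expects:

1. **Per-peak empirical p.** For each query peak, its observed overlap
   fraction against the comparison set is ranked within the overlap
   fractions of `n_iterations` (default 1,000) random placements of a
   region of identical length. Placement is uniform over valid start
   positions, chromosome chosen proportionally to its number of valid
   starts (`chromosome_matched` placement is available because some
   randomization tools condition on chromosome; the text this follows
   does not say). Empirical p uses the add-one (permutation) convention,
   `(1 + #{null ≥ obs}) / (1 + n)`, so it is never 0. Random regions may
   overlap one another within an iteration (no rejection), matching naive
   random-region generation.
2. **Median-overlap χ².** The threshold is the median observed per-peak
   fraction; the observed count of peaks at or above it is compared with
   the expected count — the mean across random iterations, rounded to
   the nearest integer for the 2×2 table — by a Yates-corrected
   chi-square. The mean (not median) is used as the expectation estimator
   for unbiasedness; the estimator is recorded in the output. Tables with
   a zero marginal (e.g. a single peak, or a median of 0 that every
   region trivially reaches) return an explicit `degenerate` status
   rather than a p-value.

The median threshold makes the test meaningful only for comparisons with
substantial, continuously distributed overlap: if most query peaks have
zero overlap the median is 0 and the table degenerates. The calibration
simulations therefore use a comparison set of variable-length intervals
tiling roughly half the toy genome, so every random query overlaps
partially and fractions are continuous. Under this null the per-peak
p-values are uniform and the χ² step is conservative (observed type-I
error ≈ 0 at α = 0.05 over 200 simulated datasets, bounded at 0.07 in the
acceptance test) — conservatism comes from the continuity correction and
the integer rounding of the expected count.

**Yates chi-square.** `statistic = Σ (max(|O−E|−0.5, 0))²/E` over the four
cells with expectations from the marginals, p from χ²₁. The correction is
clamped at zero when |O−E| < 0.5 (so exact independence and the
[[1,0],[0,1]] boundary case both give statistic 0). This matches scipy's
continuity-corrected `chi2_contingency`, which serves as the independent
reference in tests.

## Repeat-family enrichment

The null is a single pool of `n` (default 10,000) random regions whose
lengths are resampled with replacement from the query peak lengths —
"random regions of equivalent size". For each repeat family (and all
repeats pooled), the 2×2 table of (overlaps ≥ 1 repeat / does not) ×
(observed peaks / random regions) is tested with the Yates chi-square;
`direction` is `enriched` or `depleted` by comparing the two fractions at
α = 0.05, else `ns`. A single-test p is reported per family (no
cross-family multiplicity correction) — the analysis is per designated
family, not a genome-wide screen.

## Nearest-TSS annotation

Distance is measured from the peak midpoint `floor((start+end)/2)`
(midpoint chosen for symmetry; an `edge` anchor is available). Each peak
links to the TSS minimizing |midpoint − position| on its chromosome; ties
break toward the lexicographically smallest gene identifier so the result
is deterministic and order independent. Links beyond the window (default
±100 kb) are flagged and excluded from downstream gene sets; signed
distances are strand oriented (negative = upstream). The default distance
histogram bins are 0–5 kb, 5–50 kb, 50–100 kb, > 100 kb, reflecting the
promoter-proximal / distal-enhancer reporting convention.

Enhancer/promoter labelling is a discrete peak-overlap proxy for
read-density heatmap inspection (no BAM/signal processing is in scope):
H3K4me3 overlap ⇒ promoter, else H3K4me1 ⇒ enhancer, else unclassified,
with an `active_` prefix when H3K27ac also overlaps. The promoter rule
deliberately wins when both marks are present, since H3K4me3 dominance is
the conventional promoter signature.

## Target integration

A candidate direct target is a gene with ≥ 1 ChIP peak linking to it
(nearest TSS within ±100 kb) whose expression is derepressed at fold
change ≥ 1.5 and nominal P ≤ 0.05 (fold change is condition/reference —
mutant/wild-type for a repressor — so targets have fc > 1; a `direction`
flag gives the symmetric query, and adjusted-p filtering is available).
Nominal p is the default because the 1.5-fold/0.05 filter is convention-
ally applied to unadjusted p in this kind of candidate screen.

ChIP peaks are dichotomized into accessible/inaccessible by ATAC-peak
overlap (binary, not read-density quantiles; an optional `mixed` class is
off by default), and the two classes contrasted on |distance to nearest
TSS|, peak score and per-peak motif count with two-tailed Welch t-tests
(heteroscedastic, since the classes differ in size and spread by
construction).

## Motif scanning

Scores are log2-odds of the PWM (pseudocount 10⁻⁴ applied as
`(p + c)/(1 + 4c)`) against an i.i.d. background. The exact null
distribution of the score is computed by dynamic programming over scores
discretized to 10⁻³ bits — small enough that discretization error is far
below the p-value granularity at the 10⁻⁴ cutoff; the DP is verified
against exhaustive enumeration of all 4^L words for L ≤ 8. Scanning
reports every window with exact p ≤ cutoff on both strands (reverse
strand scores the reverse-complement matrix; the same null distribution
applies because the default backgrounds are complement-symmetric);
windows containing N are skipped and overlapping hits are all reported
(raw occurrence counting, no greedy masking).

## Expression statistics

- **t-tests:** pooled-variance (df = n₁+n₂−2) and Welch
  (Welch–Satterthwaite df) via scipy, wrapped so that zero-variance
  inputs return an explicit `degenerate` status instead of NaN.
- **k-means:** profiles are row-standardized (per-gene z-score across
  timepoints) by default so clusters reflect temporal shape, not level;
  Lloyd's algorithm, Euclidean distance, best of `n_restarts` by
  within-cluster SS (scikit-learn), deterministic given the seed.
- **Pre-ranked enrichment:** weighted KS running sum — hits increment by
  |score|^w (normalized), misses by 1/(N−N_h); ES is the extreme running
  value. The null permutes gene *tags* (random same-size sets), the only
  permutation scheme available for pre-ranked input. NES divides ES by
  the mean |null ES| of the same sign; nominal p is add-one within the
  same-sign null; FWER p compares |NES| against the permutation
  distribution of the maximum |NES| across all sets tested together.
  Score ties keep their original list order (stable sort). Default
  weight 1 (weight 0 gives the classic unweighted KS statistic).
- **2^−ΔΔCt:** per sample ΔCt = Ct(target) − Ct(reference gene, default
  Actb); per group ΔΔCt = mean ΔCt(group) − mean ΔCt(reference group);
  fold = 2^−ΔΔCt, with mean ± SEM of ΔCt and a pooled-variance t-test
  between groups. Fold changes are invariant to any per-sample additive
  Ct shift applied to both target and reference.

## Synthetic data: what it emulates and what it does not

The generators produce a two-condition, two-replicate peak experiment on
a toy genome (default 2 × 5 Mb — large enough that planted regions
placed with a separation margin never collide, small enough that the full
closure pipeline runs in seconds), with 120 shared and 40 + 40
condition-specific ~400 bp regions, ±20 bp replicate boundary jitter, and
q-values drawn log-uniformly: condition-specific in [10⁻⁹, 10⁻⁶] (clearly
past the 10⁻⁵ cutoff) and shared in [10⁻⁸, 10⁻³] (straddling it, so
cutoff monotonicity is exercised). Annotations add ~500 uniform TSSs and
RepeatMasker-style families whose background density is parameterized by
the fraction of random regions expected to overlap them (default 5%),
with one family additionally inserted into 60% of a designated peak set
(or excluded from one, to plant depletion). The expression generator
plants 30 target genes — each with a ChIP peak verifiably *nearest* to
its TSS within ±100 kb and fold change in [1.6, 4] at p in [10⁻⁵, 0.04] —
plus 30 decoy genes that pass the expression filter with no nearby peak,
60 background occupancy peaks, and two-archetype temporal profiles
(monotone down = stem-state expressed, monotone up =
differentiation-induced) with Gaussian noise (sd 0.2). Sequences are
i.i.d. at a chosen GC (default 0.5) with Poisson-distributed consensus
insertions at per-class rates (default 1 per accessible, 3 per
inaccessible peak). The shipped 11-bp PWM is synthetic — a made-up
high-information matrix, not a database motif.

What the generators do **not** emulate: read-level noise (fragment
models, Tn5 insertion bias, duplicate reads), peak-caller behaviour on
marginal signal, correlated q-values across replicates, microarray
probe-level noise, clustered TSS/gene structure, or realistic repeat
sequence content. Passing the closure tests therefore demonstrates that
the *analysis logic* is correct under its stated assumptions — exact
recovery of planted structure when classes are well separated — not that
the upstream assays or callers behave well on real data.

## Numerical and degeneracy conventions

Empirical p-values use the add-one convention and are never 0. The
median-overlap test, t-tests on zero-variance samples, and single-peak
inputs return explicit `degenerate` statuses. The expected count in the
median-overlap 2×2 table is rounded to the nearest integer; the Yates
correction clamps at zero. k-means empty clusters are handled by
scikit-learn's re-initialization. Problem sizes in the test and
acceptance runs (toy genomes of 1–10 Mb, 200 calibration simulations with
200 iterations each, 10,000-region repeat pools) were chosen so the full
suite exercises every statistic at meaningful resolution while remaining
quick on a single CPU.
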