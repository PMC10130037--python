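# Methods

`starrscreen` analyzes in vivo STARR-seq enhancer screens delivered by AAV to
brain tissue: a sheared-fragment library tiling a few megabases of genome is
packaged, injected, and read out as self-transcribed reporter RNA in several
animals alongside sequencing of the input DNA library. Enhancer activity at a
locus is the excess of RNA fragment abundance over what the input abundance
predicts. This note records the models, the defaults and why, the synthetic
data the tests rely on, and the known limits of both.

## Coordinates, fragments and coverage

All intervals are 0-based half-open (BED convention); 1-based formats must be
converted at the boundary. The atomic unit is the *fragment*: one mapped
library insert with its full span, sample of origin, MAPQ and multiplicity.
Fragments below MAPQ 3 are discarded at load time, matching the common
`samtools -q 3` filter for uniquely mapped pairs. Duplicate removal collapses
identical (chrom, start, end, sample) records to multiplicity 1 and is
sample-scoped. Coverage is fragment-level (the whole insert contributes) and
normalized to fragments per million: depth × 1,000,000 / total mapped
fragments, so tracks from libraries of different depth are comparable.

Cross-sample agreement is summarized on 1 kb bins (mean normalized signal per
bin, Pearson matrix). Activity tracks are per-base
log2((RNA + pc)/(DNA + pc)); the pseudocount defaults to 1 normalized unit
and positions covered in neither sample are masked rather than zero-filled,
so bin means and interval averages are taken over defined bases only.

## The window caller

Candidate enhancers are detected on sliding windows of 500 bp stepped by
100 bp. Full-width windows are tiled from each region start; when they leave
a tail of the region uncovered, one trailing partial window is appended
provided it is at least half the nominal width (shorter partials carry
high-variance counts and are dropped; a region shorter than one window
yields none). A fragment increments every window it overlaps by at least
1 bp, weighted by its multiplicity.

The background model asks what RNA count a window would show if transcription
were purely basal and input-proportional:

    log E[r] = β0 + β1·log(d + 1) + β2·gc

fit by a Poisson GLM (IRLS) on windows with input count d ≥ `min_input`
(default 10), where gc is the window G+C fraction among unambiguous bases.
Residual overdispersion is captured as NB2 dispersion
α = max(0, Σ[(r − μ)² − μ] / Σμ²), and each window's upper-tail probability
is evaluated under NB(μ, α) (Poisson when α = 0). Benjamini–Hochberg runs
jointly over all windows; windows below `min_input` are untestable and get
p = 1. Windows with q ≤ 0.05 and observed/expected fold ≥ 1.5 merge into
peaks when they overlap (configurable gap); the peak score is max(−log10 q)
and the summit is the center of the lowest-p member window, ties resolved
leftmost.

Robustness of the fit matters more than its efficiency: enhancer windows are
*in* the data being fit, and at realistic enhancer density (10–20 % of
windows touched) they can inflate α enough to mask themselves entirely. The
pipeline therefore fits twice: a first pass excluding the top 15 % of RNA
counts, then a refit that drops the blanket trim and instead holds out only
the windows the first pass flagged (q < 0.1). The refit keeps the null
dispersion essentially unbiased — a single-pass heavy trim underestimates α
and is anticonservative — while remaining immune to planted signal. The
`fit_background` function itself exposes `trim_top` (default 0.01) for
callers that want a single-pass fit on cleaner data.

A quadratic GC term is available but off by default; RNA secondary structure
is not modeled as a covariate (it would require an external folding engine,
and GC absorbs most of the compositional effect at window scale).

## Consensus filtering

Reproducibility is the screen's central quality argument and is implemented
as two rounds of single-linkage clustering by ≥ 1 bp overlap. Within an
animal, peaks are called once per input-DNA technical replicate and clusters
supported by ≥ 2 of 3 replicate calls are kept (union interval, mean score).
Across animals, clusters supported by all five animals form the final
consensus. Support counts distinct source sets, so several peaks from one
set count once. With `min_support=1` the operation degenerates to the merged
union of all sets, and the support histogram over clusters yields the
headline reproducibility number: the fraction of clusters seen in every
animal among clusters seen in any.

## Shuffled nulls and enrichment

Every overlap and conservation question is answered against a positional
null: 1000 random repositionings of the peak set *within the tiled regions*,
each preserving interval lengths and pairwise disjointness. Placement is
uniform over feasible start positions (a region is chosen with probability
proportional to its feasible-start count, then a start uniformly), with
rejection sampling against already-placed intervals up to `max_tries`
attempts. Trial t is seeded with t², so any single trial is reproducible
without generating the others.

The observed statistic is the number of peaks overlapping ≥ 1 feature
interval (per-peak hit counts are retained so a total-count summary can be
produced instead). The Z-score is moment-matched against the null sample;
the empirical p uses the add-one estimator (1 + #{null ≥ obs})/(N + 1),
which is never zero, and is reported in the direction of the deviation so
depletion (e.g. of retrotransposon classes) is detected symmetrically.
Feature tracks are not clipped to the tiled regions by default, mirroring
the use of genome-wide annotation against universe-restricted peaks; a clip
option exists for sensitivity checks.

Conservation is compared as per-peak mean base scores versus pooled
per-shuffled-interval means with the Wilcoxon rank-sum test: exact null when
both samples have ≤ 8 untied values, tie-corrected normal approximation
otherwise, p = 1 when everything is tied. ECDF curves of both samples are
returned for plotting.

An important caveat for interpreting Z against this null: the real peak
configuration is a single fixed object, so Z-scores computed for many
feature tracks against the same peak set are mutually correlated. Z is only
marginally standard normal across independent peak-set/feature pairs, which
is how the calibration tests sample it.

## Reporter validation arm

The validation assay expresses candidate sequences upstream of a minimal
promoter driving nuclear fluorescent reporters, co-packaged with a
CMV-driven reference so that per-cell normalization cancels transduction
copy number. From per-cell mean intensities and per-image background
statistics the module computes: positivity (intensity strictly greater than
background mean + k·SD, k = 3 by default), per-construct validation scores
(median log10 of the construct/reference intensity ratio over
reference-positive cells; an "all cells with nonzero reference" policy is
available since the published choice is ambiguous), cortical layer
distributions and co-labeling percentages (both aggregated as mean ± SD
across images, the replication unit), and the Pearson correlation between
screen signal (mean log2 fold-change over each validation region) and
validation scores, with the two-sided p from the t transform at n − 2
degrees of freedom.

## The synthetic screen generator

The generator produces screens with the statistical structure the analysis
assumes, plus a ground-truth manifest, so every stage is testable without
external data. Defaults define the desk-scale study conditions — a linear
~10× shrink of the design it mimics:

| parameter | default | rationale |
|---|---|---|
| regions | 9 × 30 kb | nine tiled loci; full scale is 9 × ~300 kb (~3 Mb) |
| library fragments | 50,000 | ~10× shrink of ~5·10⁵ unique transcripts/animal |
| fragment length | truncated normal, mean 742 bp, sd 110, bounds [500, 1000] | size-selected shearing; truncated mean stays within 1 bp of 742 |
| clonal abundance | log-normal, σ = 1.0 | typical library clone-size spread |
| positional bias field | log-sd 0.6, 5 kb correlation length | shared shearing/GC/clone-pool coverage structure |
| basal activity field | log-sd 0.4 clipped at ±2σ, 2 kb length | mild intrinsic transcribability differences, shared across animals |
| input replicates / animals | 3 / 5 | the screen design |
| DNA / RNA depth | 200,000 / 50,000 per sample | input deeper than RNA, as observed |
| enhancers (recovery config) | 20 × 8-fold, 1 kb, core fraction 0.5 | strong, unambiguous ground truth |

DNA replicate counts are Multinomial(depth, abundance); RNA counts per
animal are Multinomial(depth, abundance × activity), drawn independently per
animal, so fixed depths make count-conservation tests sharp. Fragment
activity is basal × exp(activity field at the fragment midpoint) × (1 +
Σ(effect − 1)·w), where w ramps linearly with enhancer overlap and saturates
at `core_fraction` of the enhancer width.

Two calibration choices deserve explanation. First, clonal abundance alone
produces far too little shared bin-level structure: without the positional
bias field, RNA–DNA bin correlation sits near 0.15 instead of the 0.8–0.9 a
real screen shows, because planted-enhancer bins dominate the raw-scale
variance. The bias field restores the shared coverage structure real
libraries have. Second, the activity field is what makes per-animal
fold-change tracks correlate (~0.92) *above* the RNA–DNA correlation
(~0.8–0.9), reproducing the screen's characteristic ordering; it is clipped
at ±2σ because unbounded Gaussian extremes are genuine activation that the
caller correctly and reproducibly detects in every animal — in this
generator, activation beyond mild bounded basal variation is by definition
an enhancer and must appear in the truth manifest, not in the background.

The annotation generator emits feature tracks (a planted interval per
enhancer with configurable sensitivity and jitter plus Poisson-scattered
background), a conservation track (Gaussian baseline noise plus a flat bump
over enhancers) and repeat tracks (scattered intervals optionally avoiding
enhancers, so the class reads out as depleted). The reporter-cell generator
draws zero-truncated Poisson vector copies shared across co-packaged
constructs, a per-cell log-normal imaging scale that cancels in ratios,
per-channel log-normal measurement noise that does not, additive Gaussian
background, biased layer assignment and independent binary marker channels.

What the generator does *not* emulate: sequence-dependent mappability and
alignment artifacts, GC-dependent amplification interacting with activity,
chromatin or episome copy dynamics, cell-type mixtures in the RNA pool,
spatial intensity gradients within images, and segmentation errors. Passing
tests therefore demonstrate the statistical machinery is correct under the
stated model, not that the model captures every failure mode of real data.

## Numerical choices

- q-values are floored at 1e-300 before −log10 for peak scores.
- Ties in window p are broken by coordinate (leftmost) for summit selection.
- Pearson entries are NaN when a pair shares fewer than two defined bins or
  either side is constant; the matrix is exactly symmetric with unit
  diagonal.
- GLM convergence: IRLS tolerance 1e-8, max 100 iterations; a constant GC
  column (or otherwise singular design) drops the covariate with a warning.
- Dispersion α is floored at 0; α ≤ 0 means Poisson tails.
- Empirical p is bounded below by 1/(N+1) by construction.
- Seeds: every sample and field draws from a child stream derived from the
  config seed and a fixed label (FNV-style hash, kept below 2³¹), so adding
  a sample never perturbs another sample's draw.

## Problem sizes used by the test suite

The default test and acceptance runs use the desk-scale configuration above
(9 × 30 kb, 50 k fragments, 2,664 windows, 8 samples), chosen so a full
screen simulation plus peak calling completes in a few seconds and the
complete suite in minutes on one core; `full_scale_config()` provides the
full-size version for slower, more faithful runs. Null calibration uses 20
screens, z calibration 25 screens × 4 feature tracks, and the shuffle
contract 1000 sets over 50 peaks — matching the sizes quoted in the package
guarantees.

## Known limitations

- The caller's NB tail assumes the gamma-Poisson mixture; heavy-tailed
  (log-normal) biological noise can exceed it slightly in the far tail.
- Consensus intervals are unions of member peaks; a different merge geometry
  (e.g. intersection) would give systematically narrower peaks. Union was
  chosen as the simplest reading consistent with per-peak support counts;
  sensitivity to this choice is untested.
- The shuffle places intervals independently subject to disjointness; it
  does not match GC or length-dependent placement preferences, so
  enrichment against strongly GC-biased features should be read with care.
- With very small universes or very long peaks, rejection sampling can fail;
  the error names the offending interval and callers may relax disjointness.
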