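# Methods

`retpoise` re-implements, on synthetic desk-scale data, the computational
chain that links nascent-transcription maps of regulatory elements to a
clinical expression statistic: counting conventions for run-on sequencing,
refinement of transcriptional regulatory elements (TREs) through an imputed
accessibility signal, a negative-binomial differential-transcription test,
motif enrichment against a GC-matched background, and the RET-ligand
"outlier score" with its responder comparison. This note records the models,
the defaults and their rationale, the numerical choices, and what the
synthetic data does and does not establish.

## Counting conventions (`retpoise.tracks`)

Run-on sequencing (PRO-seq style) maps each engaged RNA polymerase to a
single base — the 3' end of the nascent RNA — on the transcribed strand.
All coordinates are 0-based half-open; the TSS of a minus-strand gene is
`end − 1`. Three conventions drive every downstream statistic:

- **Gene bodies** are counted on the sense strand only, from 1,000 bp
  downstream of the TSS to the annotation end, excluding the
  promoter-proximal pause so body counts measure productive elongation.
  Sense-only counting is the field's convention for polymerase abundance in
  gene bodies and is adopted here as an explicit assumption; genes shorter
  than the offset are excluded with a warning.
- **TRE windows** are counted on both strands over the element interval,
  since enhancers and promoters transcribe divergently.
- **Normalization** is RPKM: count / (length/10³) / (depth/10⁶). The library
  depth is carried in a sidecar rather than recomputed from in-memory
  arrays, because a real library's depth includes reads outside the loaded
  chromosomes.

Minus-strand bedGraph files store magnitudes; the strand lives in the file
name. This resolves a common dialect ambiguity at load time.

## Synthetic data (`retpoise.synthdata`)

The generator produces every input the pipeline consumes, with the
statistical structure the analysis assumes. All randomness descends from one
integer seed through named `SeedSequence` children (tags hashed with CRC32
for cross-run stability), so reruns are bit-identical and sub-generators are
independent.

**Genome and tracks.** A single 1 Mb chromosome (configurable) holds
non-overlapping genes (3–8 kb, ≥ 2 kb so the body window is non-empty) and
300 bp TREs placed by a stars-and-bars scheme with a 400 bp margin;
infeasible packings raise an explicit error. Every gene carries a promoter
TRE at its TSS; enhancers are intergenic. Tracks are Poisson draws around an
expected-rate profile: gene bodies at `body_density` (0.05 reads/bp),
divergent pause peaks (Gaussian, 15 bp SD) with the plus-strand apex
downstream and minus-strand apex upstream of the TRE center, separated
uniformly 60–300 bp — geometry drawn once per genome so conditions share
it — at apex rate `pause_height` (2 reads/bp) for promoters and
`enhancer_height` (1) for enhancers. A fraction `diff_fraction` (0.2) of
genes and enhancers carries a ±`planted_fc` (2 in log2) fold change applied
in condition B; promoter TREs inherit their gene's fold change, since their
signal is generated from it.

**Accessibility target.** A Gaussian bump (height 10, SD 75 bp) at each
active TRE center over a zero baseline — a smooth stand-in for DNase-I
signal used to train the imputer. It emulates the feature that matters for
the method (peaks centered on regulatory elements) and none of the
chromatin-biology detail (hypersensitivity magnitude variation, footprints).

**Feature-level counts.** Negative-binomial via a gamma–Poisson mixture with
dispersion `nb_dispersion` = 0.02, the level typical of clonal cell-line
sequencing replicates; per-feature base means are log-normal around 100.

**Expression cohorts.** Two styles share one machinery. `tcga` emulates a
large tumor cohort (n = 925 after no filtering; ~79% ER+); `letrozole` a
small treated cohort (n = 52; 31 responders, 13 non-responders, 8 not
assessable; optionally 3 biopsy time points per sample sharing a mean with
5% log-normal noise). Four ligand genes (GDNF, NRTN, ARTN, PSPN) have a
deliberately *bounded* baseline, `x = scale·exp(−σ|z|)` with σ = 0.5: most
samples sit below a detection-like ceiling, emulating ligands detectable in
only a fraction of tumors. A planted high component — log-normal at
`scale·e^1.0`, σ = 0.3 — holds `ligand_tail_fraction` (0.13) of samples in
the tail of ≥ 1 ligand (GDNF most often, weights 0.5/0.2/0.2/0.1; 1–3
ligands per tail sample). The bounded baseline is a design decision forced
by the threshold rule's geometry: for any near-symmetric baseline,
`Q50 + 2.5(Q50−Q25)` flags ~5% of baseline samples per gene (~17% for
any-of-4), which would swamp a 13% planted fraction; with the ceiling, the
threshold lands between baseline and tail and the recovered fraction tracks
the planted one. The empirical distribution family of real tumor RPKMs is
not prescribed anywhere; these mixture parameters are configurable.
RET and GFRA1 correlate with an ESR1-like gene through a Gaussian copula
with latent correlation `2·sin(π·ρₛ/6)` targeting Spearman ρₛ = 0.5.
`responder_shift` is defined in units of expected tail memberships: each
non-responder's per-ligand tail probability increases by `shift/4` (capped),
so shift 0 makes labels exchangeable exactly, and shift 0.5 (default) adds
half an expected membership. At that effect size the 13-vs-31 rank-sum test
has roughly 50% power per cohort — a moderate, not overwhelming, planted
signal.

What passing tests on these cohorts show: the transform, threshold and test
machinery recover planted structure of the stated form. What they do not
show: robustness to real-platform artifacts (probe saturation, batch
effects, zero-inflation from alignment, tumor purity).

## TRE refinement (`retpoise.refine`)

Candidate TREs (here: true TREs plus signal-free decoy windows) are refined
by imputing an accessibility-like signal from nascent-transcription features
and peak-calling the result.

- **Features**: per 10 bp bin, read counts in centered windows at
  {10, 50, 150, 500} bp on each strand, over the candidate extended ±200 bp.
  The 150 bp scale is this package's addition to the classic multi-scale
  set; it matches the width of typical accessibility peaks and measurably
  improves holdout correlation. Counts are divided by depth (reads per
  million); each window whose maximum exceeds a cap — frozen at training
  time as the 90th percentile of training-example values — is rescaled so
  its maximum equals the cap. The same per-window rule applies at training
  and prediction (an inconsistency here silently destroys the learned
  mapping).
- **Imputer**: ε-SVR with Gaussian kernel (scikit-learn), preceded by an
  internal standardizer so the kernel length scale is meaningful across
  feature scales. Training positions are sampled inside candidate regions
  plus an equal weight of background windows so the model is calibrated
  off-peak. Feature scales are selected greedily, maximizing Pearson r on a
  30% validation split; kernel width γ ∈ {0.03, 0.1, 0.3, 1} and
  ε ∈ {0.05, 0.2} are tuned on the same split; C = 50; up to 2,000 training
  positions. Predictions are clipped at zero.
- **Peak calling**: a cubic smoothing spline (FITPACK, smoothing factor =
  the first free parameter) is fitted per contiguous non-zero signal
  segment; local maxima with spline height ≥ the intensity threshold (second
  free parameter) become peaks. A peak's extent is the interval where the
  spline stays above half its local maximum, stopping at intervening
  valleys, minimum one bin — a parameter-free extent rule chosen because no
  published definition of peak boundaries exists for this procedure.
- **Tuning**: both free parameters are grid-optimized (smoothness
  {0, 2, 10, 50, 200, 800} × threshold {0.5 … 5}) for maximal sensitivity
  subject to empirical FDR ≤ 10%, matching peaks to truth by any overlap
  (center-within-truth available); ties resolve toward the higher threshold,
  then the lower smoothness. If no grid point satisfies the constraint the
  tuner returns none along with the full diagnostics table.
- **Divergent-pause refinement**: within a TRE-scale window, the interval
  between the maximal minus-strand and maximal plus-strand positions
  (leftmost on ties) when the geometry is divergent; otherwise the region is
  returned unrefined and flagged.

On fresh synthetic genomes (400 kb, 20 genes, 12 enhancers; train on one
seed, evaluate on another) the tuned pipeline reaches sensitivity ≥ 0.87 at
FDR ≤ 0.06 across seeds, and holdout imputation r ≈ 0.85–0.90.

## Differential transcription (`retpoise.diffexpr`)

A two-group negative-binomial Wald test specified completely in this
package, so every number is reproducible from the code alone:

- size factors by median-of-ratios over features positive in all samples,
  geometric-mean-normalized;
- per-feature dispersion α by method of moments on normalized counts,
  pooled within groups (df = n − 2), floored at 10⁻⁸, with no shrinkage —
  transparency was preferred over the small-n efficiency of shrinkage
  estimators, and this is the main expected source of divergence from
  shrinkage-based packages at tiny replicate numbers;
- the log2 fold change is the log ratio of per-group means of normalized
  counts. This estimator (rather than a full GLM MLE) makes the size-factor
  cancellation exact: rescaling one sample's counts together with its size
  factor changes nothing. The Wald SE comes from the NB variance function
  `Var = μ + αμ²` via the delta method; all-zero groups are floored at half
  a read over the group's summed size factor;
- the Wald statistic is referred to a **t distribution with n − 2 degrees of
  freedom**. With moment-estimated dispersion at 4-vs-4 the normal reference
  is anticonservative (type-I ≈ 0.09 at nominal 0.05); the t reference
  restores nominal size (measured 0.033–0.055 over seeds) and converges to
  the normal as replicates grow;
- Benjamini–Hochberg FDR over tested features (statsmodels); features with
  all-zero counts are untested.

Classification follows the study conventions: *changed* at FDR < 0.01;
*unchanged* — the motif-enrichment background pool — at |log2FC| < 0.25 and
raw p > 0.2 (raw, not adjusted, taken literally). Sample clustering uses
Spearman correlation of gene-body counts with average linkage on 1 − ρ,
columns pre-sorted by name so equal-height merges are deterministic. The
gene-set shift statistic codes membership up = +1 / down = −1 and reports
Spearman ρ against log2FC — one of several possible pairings; it is the
documented, configurable choice.

## Motif enrichment (`retpoise.motifs`)

PWMs (pseudocount 0.01 per cell) are scanned as natural-log odds against a
third-order Markov background with add-one smoothing, estimated from the
pooled TRE sequences themselves (no training corpus is prescribed; the
pooled sequences are the neutral choice). A window is a hit at log-odds
≥ 7.5; the reverse strand is scanned with the reverse-complement PPM at the
same cutoff, sharing the forward-strand background term (backgrounds are
treated as strand-symmetric); positions with N never score; bases with fewer
than three predecessors back off to the longest available context. For the
per-TRE indicator, hits on both strands at one offset count once.

Enrichment of changed vs unchanged TREs uses a one-sided Fisher's exact
test (enrichment direction fixed; the one-sided choice is flagged as an
assumption) with Bonferroni correction over the motif-set size (the study
scale is 622 clustered specificities; the set is an input). The background
is a GC-matched stratified sample of unchanged TREs: 20 GC bins, demand
proportional to the changed set's histogram, total ≥ 1,500 at study scale
(configurable down for desk-scale runs); bins short of supply borrow from
the nearest bins with a warning, and an undersized pool is an error.

## RET-ligand outlier score (`retpoise.ligandscore`)

Per ligand, expression is median-centered and scaled by the lower tail
(quartiles 0–50): `score = (x − median)/s` with
`s = sqrt(mean{x ≤ median}((x − median)²))` — a one-sided RMS analogue of
the standard deviation, chosen because the verbal description ("scaled
based on the lower tail") admits several estimators; `(median − Q25)/0.6745`
is available as an option. High expression never inflates its own
denominator. The four per-ligand scores sum to the outlier score (exactly;
a missing ligand is an error, never imputed).

The ligand-high threshold is `Q50 + 2.5·(Q50 − Q25)` with type-7
(linear-interpolation) quantiles — documented because small-n thresholds
depend on the quantile rule. The anchor of the 2.5× range is ambiguous in
the verbal rule; the median anchor is the default, with Q25 and zero
anchors available. Zeros participate in quantiles (no detectability
filter). A sample is ligand-high when strictly above the threshold; the
cohort fraction counts samples high in ≥ 1 ligand once.

Repeated biopsy time points are averaged per sample (mean over available
time points) before scoring. The responder comparison is a one-sided
Wilcoxon rank-sum (non-responders higher, fixed a priori): exact
enumeration when the pooled size is ≤ 20 with no ties, otherwise the normal
approximation with tie and continuity corrections (SciPy). Expression
enters the transform on its given scale; a log option exists.

## Orchestration and problem sizes

`run_all` executes synthdata → counting → differential/clustering →
refinement → motifs → scoring from one schema-validated config (unknown
keys rejected), writing each table plus a manifest of output checksums,
seed and versions; deterministic stages re-run bit-identically. The demo
uses a 400 kb genome with 20 genes and 12 enhancers, three replicate tracks
per condition (so the t-referenced test has df = 4), an 800-position
imputer budget and a 50-element motif background, and completes in a few
seconds. The test suite and the acceptance script use the same desk scales
(2,000-feature null tables, 500-feature planted tables at 4 vs 4, 925-sample
cohorts, five train/evaluate genome pairs); these sizes were chosen so each
statistical property is measured with adequate precision while the whole
study remains reproducible on a laptop.

## Known limitations

- No read-level simulation (FASTQ, mappability, GC bias of reads), no
  alignment, and no bigWig write path; bedGraph is the reference dialect.
- The NB test supports two groups only; no multi-factor designs or batch
  correction. Exact numerical parity with shrinkage-based differential
  packages is a non-goal; agreement is asserted at the call level on
  synthetic truth.
- Motif clustering into representative specificities and TF-expression-based
  representative selection are out of scope; the motif set is an input.
- The cohort generator's mixture is a stand-in for real tumor expression;
  conclusions about real platforms require real data.
- KS-based uniformity checks of discrete rank-test p-values carry the
  intrinsic ~5% false-alarm rate of the check itself.
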