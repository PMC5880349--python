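# retpoise

Nascent-transcription analysis of regulatory elements and RET-ligand
outlier scoring of expression cohorts, exercised end-to-end on synthetic
data.

## The scientific problem

Most ER+ breast cancers already express the RET receptor tyrosine kinase
and its co-receptor GFRα1 — both correlate with *ESR1* — so the RET
signaling pathway is poised for growth-factor-driven endocrine resistance;
what is normally missing is the ligand. A minority of tumors expresses a
RET ligand (GDNF, NRTN, ARTN or PSPN) at outlier levels, and those tumors
are candidates for intrinsic resistance to endocrine therapy such as
tamoxifen or letrozole.

Detecting and quantifying this requires a chain of computation that this
package implements as a library for computational biologists:

1. **Run-on sequencing conventions** (`retpoise.tracks`) — strand-specific
   single-base 3'-end tracks; sense-strand gene-body counting from TSS+1 kb
   to the annotation end; both-strand counting over regulatory-element
   windows; RPKM normalization; signal matrices around binding sites.
2. **Regulatory-element refinement** (`retpoise.refine`) — an ε-SVR with
   Gaussian kernel imputes a DNase-I-like accessibility signal from
   multi-scale binned nascent-transcription features; a cubic smoothing
   spline plus local-maxima calling turns it into peaks, with the two free
   parameters (spline smoothness, intensity threshold) grid-tuned to a
   <10% empirical false discovery rate; a divergent-pause rule refines each
   element to the interval between opposing paused-polymerase maxima.
3. **Differential transcription** (`retpoise.diffexpr`) — a fully specified
   two-group negative-binomial Wald test (median-of-ratios size factors,
   moment dispersion, t-referenced Wald statistic, Benjamini–Hochberg FDR),
   with changed TREs called at FDR < 0.01 and "unchanged" TREs
   (|log2FC| < 0.25, p > 0.2) reserved as an enrichment background.
4. **Motif enrichment** (`retpoise.motifs`) — PWM scanning at a natural-log
   odds cutoff of 7.5 against a third-order Markov background, one-sided
   Fisher's exact test of changed vs GC-matched unchanged TREs with
   Bonferroni correction.
5. **The RET-ligand outlier score** (`retpoise.ligandscore`) — per ligand,

       score_i = (x_i − median(x)) / s,   s = sqrt( mean_{x_j ≤ median} (x_j − median)² )

   a median-centered transform scaled by the *lower* tail of the
   distribution (quartiles 0–50), so the high-expression outliers being
   scored never inflate the denominator. The four ligand scores are summed
   per sample; a ligand-high cutoff sits at Q50 + 2.5·(Q50 − Q25); and the
   summed score of treatment non-responders is compared with responders by
   a one-sided Wilcoxon rank-sum test.

A first-class synthetic-data module (`retpoise.synthdata`) generates every
input with the structure the analysis assumes — planted promoter/enhancer
architecture with divergent pausing, smooth accessibility truth,
negative-binomial count tables with planted fold changes, and expression
cohorts with heavy right ligand tails, receptor–ESR1 correlation and a
planted non-responder shift — so every statistical property of the pipeline
is testable against known ground truth.

## Worked example

Score a simulated letrozole-style cohort (52 samples, three biopsy time
points each, 13% of samples planted in a ligand high-expression tail,
non-responders shifted upward):

```python
from retpoise.synthdata import SimParams, gen_expression_cohort
from retpoise.ligandscore import RetLigandScoreModel

cohort, truth = gen_expression_cohort(SimParams(seed=1), style="letrozole",
                                      n_timepoints=3)
result = RetLigandScoreModel(cohort).fit()
print(result.summary())
```

```
RET-ligand outlier score
========================================
samples: 52
transform: lower-tail rms; threshold anchor: median

ligand     threshold  n high
GDNF           6.407       5
NRTN           5.524       2
ARTN           5.763       3
PSPN           5.746       4

samples with >= 1 ligand high: 12 (23.1%)
one-sided rank-sum p (non-responders higher): 0.0118
```

Time points are averaged per sample, each ligand is transformed and
thresholded on its own cohort distribution, and 12 of 52 samples (23.1%)
exceed at least one ligand's cutoff — this cohort carries the planted 13%
tail plus the elevated non-responder memberships, and the ground-truth table
confirms 23.1% of samples are in a planted tail. The rank-sum p of 0.0118
says non-responders score significantly higher, recovering the planted
direction. `result.plot_scores()` draws the responder/non-responder
boxplots; `result.to_frame()` returns per-sample scores and flags.

The whole synthetic study — tracks, counting, differential calls,
refinement, motif enrichment, scoring — runs from one config:

```sh
retpoise run --config examples/demo.yaml
```

which writes every table plus `manifest.json` (checksums, seed, versions)
into `demo_run/`; re-running is bit-identical. Individual stages are also
exposed (`retpoise simulate|count|diff|motifs|score|refine`).

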