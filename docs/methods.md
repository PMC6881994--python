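# Methods

## Problem and overall design

The pipeline discovers genes hypermethylated in ovarian carcinoma relative
to normal controls across three methylome platforms, verifies candidates by
pooled-DNA qMSP, and converts per-gene qMSP readouts from cervical
scrapings into a logistic risk score. Each stage is a pure function of its
inputs plus explicit thresholds; the orchestration layer
(`papmeth.pipeline`) only sequences stages and freezes training-derived
quantities before testing data is read.

## Stage models

### Tissue MBD-seq (`mbdseq`)

Methylation of a gene is the fraction of a sample's uniquely mapped read
starts inside a promoter window, default TSS ± 1000 bp (2000 bp total).
Coordinates are 0-based half-open; a read belongs to a window when its
start position does (length-independent and deterministic). Windows for
minus-strand genes swap the up/downstream flanks, which for the symmetric
default yields the same interval. Sex-chromosome genes and non-coding
(NR-accession) records are excluded up front.

Raw per-sample fractions are of order 1e-6, so a fixed "HDM level > 0.2"
threshold is only meaningful after rescaling. The default is per-gene
min–max scaling to [0, 1] across samples (constant genes map to 0); a rank
transform and pass-through are available, and the chosen mode is carried in
the result object. The HDM level is the difference of group medians on the
scaled level — consistent with the nonparametric test, and robust to the
scaling's tail behavior. A gene passes with *P* < 0.01 (two-sided
Mann–Whitney), HDM level > 0.2 and AUC > 0.85, and only in the
hypermethylated direction.

### Bead arrays (`beadarray`)

Probe QC removes probes failing detection (*p* > 0.01) in **any** sample
(configurable to "all" — the stricter "any" is the default because one
failed hybridization invalidates the probe-wise comparison), probes with
annotated SNPs (count ≥ 1; SNPs under the probe corrupt β — the retain-style
reading of a "SNP ≥ 2" rule contradicts standard array QC and is treated as
an exclusion, configurable), non-NM genes and sex chromosomes. For the
individual-sample stage a probe is HDM when the case–control median β
difference exceeds 0.15 with *P* < 0.05 and AUC > 0.75; a gene is called
when at least three of its promoter probes pass. For the pooled-scraping
stage (2–3 equal-mass five-specimen pools per group) no test is computed —
with so few pools a rank test is vacuous — and a probe passes when the
mean-of-case-pools minus mean-of-control-pools β exceeds 0.015, with the
same ≥ 3 promoter-probe aggregation. Missing β values are handled
probe-wise complete-case.

### Candidate selection (`candidates`)

The three gene sets are intersected; the intersection's tissue methylation
profiles (all samples, both groups) are clustered by complete-linkage
agglomerative clustering on Euclidean distance and the tree is cut at
k = 4. Genes are pre-sorted lexicographically so tie merges are
deterministic, and cluster labels are canonicalized by each cluster's
smallest gene id, making membership invariant to input order. Within each
cluster larger than five genes the top ⌈0.10 · size⌉ genes by HDM level are
selected (ceiling, because a handful of picks from dozens of genes implies
rounding up); smaller clusters keep all members. Literature-novelty triage
is intentionally manual: the table carries ranks, not verdicts.

### qMSP (`qmsp`)

ΔCp = Cp(gene) − Cp(COL2A1); the reference is methylation-independent, so
the difference normalizes DNA input, and lower ΔCp means more methylated
template. A reference Cp above 36 cycles marks absent template and voids
the record; an undetected target with a valid reference is right-censored
at ΔCp = 12 cycles (above any plausible observed value, preserving rank
order without inventing precision). Technical duplicates are averaged over
valid wells. The pooled verification gate passes a gene when at least one
tumor tissue pool and *all* tumor scraping pools lie strictly below the
normal pools — "below the normals" compares to their minimum by default
(strictest reading; mean available). Final panel picks take up to two
verified genes per cluster, ranked by the normal-minus-tumor pooled ΔCp
gap. A per-gene assay-stability flag is an input, not an inference.

### ROC machinery (`rocstats`)

AUC is the rank statistic (ties count ½); direction is an explicit argument
everywhere (`lower_is_positive` for ΔCp) so no ROC can silently invert.
The cutoff minimizes (1 − sensitivity)² + (1 − specificity)² over midpoints
of adjacent sorted unique values plus ±∞ (closest-topleft); ties resolve
toward higher sensitivity, then the lower cutoff; a value exactly at the
cutoff is called positive. Confidence intervals are percentile bootstrap
with 200 iterations, stratified within class so every resample contains
both classes; sensitivity/specificity CIs are computed at the cutoff frozen
on the full sample. The Mann–Whitney test uses the exact null distribution
when both groups have ≤ 8 observations and no ties, otherwise the normal
approximation with continuity and tie correction. Kruskal–Wallis (with tie
correction) compares ≥ 3 groups; when significant at 0.05, Dunn's z tests
on mean ranks with Holm adjustment flag pairs — Dunn–Holm is a documented
default, chosen for being the standard rank-based posthoc, not an inference
about any particular prior analysis.

### Risk model (`riskscore`)

The score is affine in the per-gene ΔCp: ε + Σ βᵢΔCpᵢ, classified positive
at score ≥ cutoff. Fitting repeats stratified 10-fold cross-validation 200
times; every training fold contributes one maximum-likelihood logistic fit
(IRLS with a 1e-6 ridge on slopes only, present solely so Newton steps stay
solvable under complete separation in small folds; separation is flagged in
provenance). Final coefficients are the mean over all 2000 fold fits
(median stored alongside — the aggregate choice is genuinely open and both
are kept). The cutoff is closest-topleft on the aggregated model's
in-sample training scores; the published model uses its published cutoff
verbatim. Note the published intercept (6.38) is far from zero even though
an intercept "expected to be zero" is a natural prior for a balanced
design; the implementation simply treats ε as the fitted intercept.

The sample-size planner solves the two-sided Hanley–McNeil problem: find
the smallest n with z₁₋α/₂·√V(θ₀,n) + z_power·√V(θ₁,n) ≤ θ₁ − θ₀, where
V(θ,n) = [θ(1−θ) + (n−1)(Q₁−θ²) + (nR−1)(Q₂−θ²)]/(n²R), Q₁ = θ/(2−θ),
Q₂ = 2θ²/(1+θ). For θ₁ = 0.75, α = 0.05, power 0.8, R = 1 this gives
n = 20 per group, whereas the cohort arithmetic that the planner's
`plan_study` reproduces (test n + 2, train round(1.5 n) + 2, half-up
rounding so 28.5 → 29) starts from n = 19; commercial calculators differ in
the variance form and the discrepancy is reported, not hidden.

## Synthetic cohorts (`simulate`)

One latent methylation fraction per gene and specimen drives every
platform, which is exactly what makes a cross-platform intersection
meaningful: a marker gene is shifted upward in disease specimens everywhere.
No distributional model is imposed by the underlying assays, so the
generator families are implementation choices, documented here:

* **Gene universe** — genes spaced 100 kb apart on 22 autosomes, 4 % on
  chrX and 2 % NR-accession to exercise the annotation filters; baseline
  methylation Uniform(0.15, 0.45); specimen-level wobble sd 0.05.
* **Tissue sequencing** — window read count ~ Poisson(depth · rate ·
  latent) with depth 1e5 and rate 0.002 per unit methylation (mean ~60
  reads per window at baseline: enough that Poisson noise does not drown a
  0.3 latent shift at 50 v 6); remaining reads scatter uniformly outside
  windows so window counts stay exactly Poisson.
* **Arrays** — probe β ~ Beta centered on the latent with precision 200
  (per-probe sd ≈ 0.03, the scale of replicate noise on modern arrays) plus
  a fixed per-probe offset (sd 0.03) that cancels in group differences;
  each gene has at least 5 promoter probes plus Poisson(3) extras (450K
  promoters typically carry several probes; the ≥ 3-probe rule makes genes
  with very few probes uncallable by construction, so the floor matters);
  5 % of probes carry SNP annotations and 1 % a failed detection *p* to
  give QC work.
* **Pools** — equal-mass DNA pooling averages latent fractions (β mode) and
  mixes template quantities on the 2^−Cp scale (Cp mode):
  pooled Cp = −log₂(mean 2^−Cpᵢ).
* **qMSP** — Cp(gene) = ref_mean + baseline_g − 5·latent + N(0, 1.5) per
  well against Cp(ref) ~ N(27, 0.3), two wells per sample; 5 cycles per
  unit methylation spans the observed 0–8 ΔCp range. Per-gene baselines and
  group latent centers are solved so generated group medians land on
  requested targets (the shipped defaults are the validation cohorts'
  reported group medians); per-sample latent sd 0.15 puts single-gene AUCs
  in the high 0.8s/low 0.9s at 21 + 21, matching the reported performance
  band. A configurable fraction of samples gets reference Cp > 36 to
  exercise QC.
* **Verification pools** — markers carry a strong latent contrast (0.9 vs
  0.1) as befits candidates that already survived three discovery filters;
  pools of five, duplicate wells, pooling before measurement noise.
* **Logistic cohorts** — ΔCp Gaussian around given means, labels Bernoulli
  from a known (β, ε): the generating truth for coefficient-recovery
  checks.

What the generator does **not** emulate: batch effects, probe
cross-reactivity, bisulfite conversion failure, cellular heterogeneity of
scrapings, correlated probes within a CpG island, or assay-specific PCR
efficiency differences. Passing tests therefore demonstrate the pipeline's
statistical machinery and its operating characteristics under a faithful
signal model — not clinical performance on real specimens.

## Numerical and degenerate-input choices

* Constant features: Mann–Whitney on all-equal data returns p = 1; min–max
  scaling of a constant gene yields zeros; Kruskal–Wallis on identical
  groups returns H = 0, p = 1.
* Exactly-at-cutoff classifies positive (≥), fixed and documented.
* Windows below position 0 clamp to 0 with a warning; samples with zero
  mapped reads are dropped with a warning; probes missing one whole group
  are dropped with a warning; an empty QC result or empty intersection
  warns instead of raising.
* Clustering imputes missing profile entries with the gene median; ties
  break lexicographically; quota rounding is ceiling.
* All randomness flows through `numpy.random.default_rng` seeded per stage
  from a single study seed, so every artifact is reproducible
  byte-for-byte.

## Problem sizes used in checks

Unit tests run the generators at reduced sizes (40–60 genes, read depth
2e4) — the statistical properties under test are size-stable, and the suite
stays quick. The end-to-end acceptance checks run the study-shaped
conditions: 500 genes with 10 planted markers at effects 0.3/0.2/0.05
across 50 v 6, 79 v 6 and 3 v 2-pool cohorts (10 seeds), a ≥ 500-gene null
control, and 50-seed risk-model runs at 31+31/21+21 with 10-fold × 200-rep
fitting.

## Known limitations

* The discovery thresholds are fixed rules, not FDR-controlling
  procedures; calibration of the whole pipeline is demonstrated empirically
  on null simulations rather than guaranteed analytically.
* The pooled-scraping stage has no inferential test; its 0.015 threshold is
  only meaningful at the generator's noise scale and on real data would
  need re-tuning against technical replicates.
* The IRLS ridge (1e-6) bounds but does not remove coefficient blow-up on
  separable folds; separable training sets yield large (flagged)
  coefficients whose magnitudes should not be interpreted, though the
  induced ranking and classifications remain stable.
* Censoring undetected targets at ΔCp = 12 is adequate for rank statistics
  but biases means; median-based summaries are used throughout.
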