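# Methods

## Chromosome dosage from relative expression

For sample $s$ and chromosome $c$ the relative expression is

$$R(s, c) = \frac{\sum_{g \in c} n_{gs}}{\sum_{g\ \text{assigned}} n_{gs}}$$

computed per replicate on raw counts (genes without a chromosome assignment
are excluded from numerator and denominator, so fractions sum to 1), then
averaged over a line's replicates. Library-depth differences cancel exactly
in this statistic, so no size-factor correction is applied here.

A trisomic chromosome with no dosage compensation multiplies its per-copy
output by $\lambda = 3/2$; because the extra reads also enter the
denominator, the expected ratio against a euploid reference is
$\lambda / (1 + (\lambda - 1) f)$ with $f$ the chromosome's baseline share —
1.46–1.48 for chromosomes holding 3–5% of the transcriptome. This
renormalization is also why *every other* chromosome of an aneuploid line
sits slightly *below* its reference value.

**Reference construction.** Each analysed line is compared against the
remaining lines (leave-one-out). The reference fraction is the **median**
across reference lines (configurable to the mean): in a five-line cohort in
which two lines share a trisomy of the same chromosome, a mean reference is
contaminated by the second aneuploid line and drags the expected ratio from
~1.48 down to ~1.29, below the call threshold; the median of four reference
values is robust to one aneuploid member.

**Significance.** Per (line, chromosome), a paired t-test across the
chromosome's genes: for each gene, the mean over the candidate line's
replicates of $\log_2(\text{rpm}+1)$ is paired with the mean over all
reference-line replicates. Pairing by gene absorbs the (large) gene-to-gene
expression differences, which is what makes the test powerful at two
replicates per line. p-values are Benjamini–Hochberg-adjusted across
chromosomes within each line (each line is an independent karyotype
question). A **gain** is called when ratio ≥ 1.3 *and* adjusted p ≤ 0.01;
both gates matter — the ratio threshold supplies effect-size specificity
(chromosome fractions are so precise that trivial deviations are
"significant"), the test guards against single-gene artifacts. Loss calls
(ratio ≤ 1/1.3) are symmetric but off by default.

**Sex chromosomes are excluded from trisomy calling.** X dosage is
confounded by sex and X-inactivation state — a biactive-X female reads as
~1.7× against a mixed cohort and would be miscalled as a gain — and Y by sex
alone. Both are analysed by the X-status model instead; `include_x` /
`include_y` re-enable them for single-sex cohorts.

## X-inactivation classification

Three per-line quantities: the mean rpm per X-linked gene (XIST excluded —
it marks the *inactive* X and would distort the dosage average), XIST rpm,
and total Y-linked rpm. Sex comes from metadata when recorded, otherwise
from Y expression (male if ≥ 1 rpm summed over Y genes). Classes:

| class | rule |
|---|---|
| `male_single_X` | male |
| `female_XIST_pos_Xi` | female, XIST ≥ 100 rpm |
| `female_XIST_neg_biactive` | female, XIST ≤ 10 rpm and X fold vs cohort ≥ 1.3 |
| `ambiguous` | anything else |

The thresholds sit roughly an order of magnitude away from observed values
on both sides (XIST-positive lines run at many hundreds of rpm, negative
ones below ~5; the biactive X fold is ~1.6–1.7), so calls tolerate ±10×
threshold shifts. The X fold compares a line's X-linked average rpm with
the mean of the other analysed lines; against a mixed cohort of male and
Xi-female lines the biactive line's expected fold is
$2 / (1 + \bar{e}/2) \approx 1.67$ at an average escape fraction
$\bar e = 0.4$ (slightly deflated in rpm units because single-X libraries
are smaller). A paired t-test on X (the dosage test with chromosome = X)
accompanies the classification as a significance readout.

## The synthetic cohort generator

Each gene has a *per-copy mean* (expected reads per library per expressed
copy at reference depth) drawn log-normal ($\sigma = 1.0$ in natural log)
and scaled so the expected disomic non-Y library equals the configured
library size. Counts are negative binomial via gamma–Poisson mixing,
variance $\mu + \alpha\mu^2$. Effective copies: autosomes carry their
configured copy number (no dosage compensation); male X = 1; biactive
female X = 2; Xi female X = $1 + e$ per gene ($e$ = escape fraction 0.4,
or 2 for genes flagged as full escapees); Y silent in females. XIST is a
single dedicated X gene whose expectation is injected directly from the
karyotype's rpm target — a controlled parameter, deliberately exempt from
line-level expression jitter.

Two nuisance layers exercise normalization and clustering: per-replicate
depth jitter (log-normal, σ = 0.1) and per-line per-gene expression
individuality (log-normal, σ = 0.1, shared by a line's replicates) — real
cell lines differ gene-by-gene; replicates of one line do not.

Defaults (the study-design scale): 20 autosomes of 250 genes, except
autosomes 19 and 20 at 150 genes so each carries ~3% of expression — the
smallest chromosomes, and the trisomy targets of the default scenarios;
X 250 genes (one of them XIST), Y 20; 2×10⁶ expected reads per replicate;
2 replicates per line; dispersion α = 0.02, typical of homogeneous
cell-line biological replicates. The default `study_design` scenario is
five ES-like lines — male +19+20, Xi female +20 (XIST target 945 rpm), Xi
female euploid (851 rpm), male euploid, biactive female euploid (XIST
2 rpm) — plus a female fibroblast outgroup with the pluripotency programme
silenced, FGF5 active, and broad log-normal (σ = 1) rewiring of the rest of
its transcriptome. Male lines carry a 0.5-rpm XIST background: background
transcription is nonzero in real data (males are observed *below* a 3-rpm
bound, not at zero), and an identically-zero target would make that bound
vacuous.

### Parameter choices worth recording

* **Expression spread σ = 1.0.** At desk scale (150–250 genes per
  chromosome instead of thousands) a broader spread lets single genes
  dominate a chromosome's read share (effective gene number
  $n/e^{\sigma^2}$), making per-line chromosome fractions wobble 5–7% —
  an artifact real chromosomes do not show. σ = 1.0 keeps desk-scale
  chromosome shares as stable across lines (~2%) as real ones, which is
  the regime in which trisomies stand out cleanly at ~1.5-fold.
* **Line-effect σ = 0.1** (~10% per-gene individuality): enough for
  replicates to cluster by line and for thousands of genes to differ
  measurably between lines, while keeping chromosome-share noise well
  under the 1.3 call threshold.
* **Escape fraction 0.4**: gives the biactive line a ~1.67× X fold against
  a two-male/two-Xi-female cohort, matching the ~1.7× regime the
  classifier is built for.

## What the generator does **not** emulate

No read-level features (FASTQ, mapping, GC/length bias), no splicing or
isoforms, no batch effects, no sub-chromosomal CNVs, no allele-specific
expression, and gene counts per chromosome are two orders of magnitude
below a real annotation — per-gene rpm values are correspondingly inflated
even though all *ratios* (dosage folds, X folds) are on the real scale.
Passing tests therefore demonstrate the correctness and calibration of the
statistics under the stated generative model, not robustness to mapping
artifacts or batch structure in real data.

## Numerical and procedural choices

* Chromosome labels are compared after stripping an optional `chr` prefix.
* rpm uses raw library totals; profiling (PCA, clustering, DE, markers)
  uses $\log_2(\text{size-factor-normalized} + 1)$.
* Size factors: median-of-ratios against the per-gene geometric mean over
  genes positive in all samples, with the median taken on the log scale
  (the reference estimator's convention; matters only for even counts of
  usable genes), normalized to geometric mean 1. No pseudo-reference
  fallback: a matrix without any all-positive gene is an error.
* The paired dosage test returns (t, p) = (0, 1) when candidate and
  reference are identical (zero differences); fewer than 3 usable genes on
  a chromosome is an error.
* PCA centers genes; a constant matrix is an error, while *identical*
  samples (zero centered variance, but a non-constant matrix) return
  all-zero coordinates and zero variance fractions.
* Hierarchical clustering: average linkage on 1 − Pearson r (configurable
  linkage).
* Differential expression uses a Welch t-test on log2 values — deliberately
  not a negative-binomial GLM with dispersion shrinkage. At n = 2–3
  replicates the Welch degrees of freedom (~2–4) bound attainable
  FDR-adjusted significance: complete recovery of every planted effect
  among ~10³ genes is not achievable, and measured power is ≥ 7 of 10
  four-fold effects with essentially no false candidates (the fold-change
  gate suppresses them). Real-study candidate counts from shrinkage-based
  tools are not reproduction targets.
* End-to-end runs are deterministic given the seed; `summary.json` is
  byte-identical across repeated runs of one configuration.

## Problem sizes

Monte-Carlo suites use 100 simulated cohorts for calibration means, call
recovery, specificity and classifier recovery, 20–30 for the slower
profiling checks; each cohort is ~5 × 10³ genes × 10–12 samples at 2 × 10⁶
reads — chosen as comfortable desk-scale sizes at which the Monte-Carlo
standard errors (≲ 0.5% on dosage ratios) are far tighter than the
acceptance bands.
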