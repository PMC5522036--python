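# Methods

## The SEM model

A stochastic epigenetic mutation (SEM) is defined per locus and per
sample: the sample's beta value lies strictly outside the Tukey fences
`[Q1 − k·IQR, Q3 + k·IQR]` of a reference population at that locus, with
fence multiplier `k = 3` ("extreme" outliers; `k = 1.5` marks ordinary
ones). The definition is purely distributional — no error model is fit —
so three numerical choices matter and are all explicit parameters:

* **Quantile definition.** `quantile_method="linear"` (the default) uses
  linear interpolation of order statistics, equivalent to R's default
  `quantile(type = 7)`; `"tukey"` uses boxplot hinges (the median of each
  half, halves including the median for odd n). Both are implemented
  because boxplot-based software mixes the two conventions; the method
  used is recorded on the `ReferenceFences` object. Calls can differ
  between the conventions only when the fence lands between two order
  statistics, which the oracle-equivalence tests exercise for both.
* **Strictness at the fence.** Values exactly at a fence are *not* called
  — the outlier must lie strictly outside. This is an exact-arithmetic
  contract; fences such as 0.3 + 3·(0.3 − 0.2) carry ordinary binary
  floating-point representation error, so boundary behavior is only
  meaningful (and only tested) on dyadic inputs.
* **Degenerate spread.** When IQR = 0 the faithful rule makes any
  deviation a call. A `min_iqr` floor is available but defaults to 0
  (faithful); real array data essentially never ties, synthetic data can.

Case and control samples are scored against fences fit on the **full**
reference. Reference subjects are never scored against fences containing
themselves: each is held out and compared to the remaining N−1 subjects
(leave-one-out), which is what makes the reference burden an unbiased
noise floor. Probes with fewer than `min_support = 8` non-missing
reference values are excluded from fitting and calling (not imputed) and
logged. Direction (hyper/hypo) is recorded per call even though burden
summaries use totals, because the shared-gene analysis needs the
promoter-up / body-down pattern and the BED export carries direction in
its name field.

## Preprocessing

Filtering reproduces standard 450K practice on beta matrices with
detection p-values. A beta value is unreliable when its detection p-value
is *not below* the threshold `T = 0.05` — read literally, `p ≥ T` is
unreliable, so the boundary is masked. Stages, in the default order:

1. **Flag filter**: SNP-overlapping probes removed first, then
   sex-chromosome probes; a probe with both flags counts under SNP. The
   order is fixed so the two counts in the report are reproducible.
2. **Greedycut**: iteratively remove the probe or sample with the largest
   fraction of unreliable entries until none remain. The scoring
   (fraction per row/column) and tie-break (probe first, then lowest
   index) are this package's own deterministic choices, since published
   descriptions of the procedure leave them open. Dimension floors
   (keep ≥ 50% of samples; keep ≥ 10 probes, capped at half the input for
   tiny matrices) prevent pathological full erosion; hitting a floor is
   logged and leaves the matrix dirty rather than empty.
3. **Masking**: remaining unreliable entries set to missing. Missing
   values propagate pairwise-complete through every downstream mean and
   quantile.

Whether Greedycut should run before or after the flag filter is not
dictated by anything in the data; the pipeline default is flags-first,
and the order is configurable. Intensity-level corrections (background
subtraction, probe-type normalization) are out of scope: the package
consumes beta matrices, not raw idat files.

## Differential methylation

Site level: per-probe paired t-test on per-pair differences, with
`delta = mean(control) − mean(case)` so that loss of methylation in the
tumor is positive. `method="moderated"` shrinks per-probe variances
toward a pooled prior (scaled-inverse-chi-square; prior df and scale
estimated by matching the moments of log s² via the trigamma function,
and posterior df = residual + prior df). This is the standard
empirical-Bayes construction; numerical equality with any particular
microarray package is not claimed or tested — with prior weight 0 the
moderated test reduces exactly to the plain one, which is the tested
contract. Probes whose differences have zero variance are flagged
degenerate and reported at p = 1 rather than producing infinite
statistics.

Adjustment defaults to Benjamini-Hochberg (Bonferroni by flag). Region
p-values combine member-site p-values by Fisher's method (−2Σln p against
χ² with 2m df) or Stouffer's z; site p-values of exactly 0 are clamped to
the smallest positive float (logged), and an all-ones region combines to
exactly 1 under both methods (Stouffer's z = −∞ is guarded through the
normal survival function). Significance counts use strict inequalities at
both the alpha and the |delta| threshold.

Exploratory summaries: hierarchical clustering of samples on the top-k
most significant sites (Euclidean distance, average linkage, 2-cluster
cut; misclassification minimized over the two cluster-to-label mappings)
and classical Torgerson MDS (double-centered squared-distance matrix,
eigendecomposition, negative eigenvalues clipped). The pipeline default
is k = 200 on the default 2,000-probe panel — the same "strongest decile"
role that k = 1000 plays on a ~485k-probe array; k is configurable.

## Burden association

Burden counts are large and right-skewed, so the default response is
`log10(count + 1)` in a Gaussian OLS, adjusted for age; `identity` is
available. The distribution family of the original analysis is not
recoverable from its description, and on multiplicative effects the log
link makes coefficients directly interpretable (0.301 = doubling).
Categorical predictors are dummy-coded against fixed reference levels
(viral status `none`, grade `I`, Child-Pugh `A`) so coefficient signs are
stable across runs; rank-deficient designs raise an error naming the
aliased terms. Bonferroni adjustment is applied across the predictor
terms of a model. Group comparisons use Shapiro-Wilk per group followed
by the two-sided Wilcoxon rank-sum test — exact for small tie-free
groups, otherwise the tie-corrected normal approximation (flagged).

FAMD (factor analysis of mixed data) standardizes continuous variables
(population sd), one-hot encodes categorical ones with indicators scaled
by 1/√(level proportion) and centered, and takes the SVD of the joint
matrix divided by √n. Each continuous variable contributes inertia 1 and
a categorical with L levels contributes L − 1, so explained variances sum
to the total inertia (tested). This is the textbook construction; no
rotation-matching against any specific implementation is attempted, and
only rotation-invariant quantities (explained-variance fractions,
variable-dimension association strengths) are treated as meaningful.

## Shared-SEM candidate genes

A probe is a shared-SEM candidate iff it is epimutated in strictly more
than `fraction = 0.90` of case samples **and** in zero control samples.
Both conditions are deliberately absolute: exactly 90% prevalence fails,
and one control carrier excludes a probe. Selected probes map to genes
through the annotation; per gene, mean methylation over promoter and
gene-body probes is reported per tissue group, which is where the
characteristic promoter-hypermethylation / body-hypomethylation signature
of recurrently epimutated genes becomes visible.

## The synthetic cohort generator

The generator exists so that every downstream stage has ground truth. It
emulates the three-population design — reference, peritumoral, tumor —
with these components:

* **Baseline**: each probe draws from a three-class Beta mixture, hypo ≈
  Beta(2, 18), hemi ≈ Beta(10, 10), hyper ≈ Beta(18, 2), in proportions
  0.4 / 0.2 / 0.4 — the bimodal-with-shoulder shape of real 450K data.
  Gene promoters are forced hypo and gene bodies hyper (the canonical
  genic pattern). Probe positions, tiling windows (100 kb), genes,
  promoters (doubling as CpG islands) and SNP/sex-chromosome flags are
  laid out deterministically from the seed.
* **Epimutation injection**: per-sample burdens are drawn from a negative
  binomial (configurable dispersion, default size 8) whose mean depends
  on tissue class, multiplied by an exponential age effect (default
  1.02 per year, a free parameter — the age-burden relationship is
  qualitative, not a calibration target) and by per-level clinical
  factors (defaults: HBV ×2.0, HCV ×1.6, HBV+HCV ×2.5, grade II ×1.2,
  III ×1.8). An injection displaces the baseline value to fence ±
  `spike_magnitude` (default 0.15), clipped to [0, 1]; a probe without
  headroom is skipped and logged, never silently mis-recorded. Every
  injection is asserted to lie strictly outside the fences at generation
  time, which is what makes 100% recovery a meaningful acceptance check
  rather than a tautology about tolerances.
* **Default scale**: 2,000 probes, 114 reference subjects, 20 pairs. The
  burden means (tumor 320, peritumoral 25 expected injections; reference
  0 — its burden is the ambient fence-tail noise recovered by
  leave-one-out calling) are the published full-array burden medians
  scaled down proportionally to the panel size, so group ratios carry
  over even though absolute counts do not.
* **Shared genes**: listed genes (default: the first two panel genes) are
  epimutated in strictly more than `shared_fraction = 0.95` of tumors
  and in zero peritumoral samples, promoter probes displaced up and body
  probes down.
* **Global differential methylation**: a fraction (default 0.8) of the
  call-free probes — those whose fences already extend beyond [0, 1], in
  practice the hemimethylated class — receive a consistent per-probe
  shift in every tumor sample (magnitude U(0.10, 0.30), 80% losses).
  Restricting the shift to call-free probes keeps the SEM truth table
  exact: planted differential methylation can never convert into an
  unrecorded outlier call, so the false-positive calibration against the
  Monte-Carlo fence-tail estimate remains valid.
* **Detection p-values**: Uniform(0, 0.01) for reliable entries; a small
  planted fraction (default 0.002) of entries get Uniform(0.05, 1) to
  exercise Greedycut and masking. Injected epimutations are never marked
  unreliable, so preprocessing cannot silently delete planted truth.
* **Clinical covariates** are sampled from fixed frequency tables
  matching a published HCC case series (76.8% male, 59.5% HCV, 85.6%
  grade II, etc.); reference subjects get neutral clinical values.

What the generator does **not** emulate: probe-type (I/II) chemistry
bias, batch/chip effects, spatial correlation along the genome, raw
intensity artifacts. Passing tests therefore demonstrate correctness of
the statistical machinery under the stated generative assumptions, not
robustness to array artifacts — on real data, preprocessing quality and
reference-population match will dominate.

## Determinism and problem sizes

All randomness flows through `numpy.random.default_rng` seeded from the
spec/config seed; identical configuration yields byte-identical outputs.
The shipped test and acceptance workloads use the default synthetic scale
(2,000 probes, 114 + 2×20 samples; the parameter-recovery simulation uses
50 replicates of 69 subjects, and the fence-tail Monte-Carlo 10⁶ draws
per probe class), which the package's own test-size policy keeps to
seconds per suite while leaving every statistical check adequately
powered.

## Known limitations

* The fence rule is the sole epimutation definition; no secondary
  outlier test is implemented for confirmation, and no per-locus
  significance is attached to individual SEM calls.
* Exact numerical replication of any specific microarray pipeline
  (moderated tests, region combination internals) is a non-goal; the
  package's own definitions are documented above and tested against
  closed forms and brute-force oracles instead.
* Allele-specific methylation is invisible to array beta values and out
  of scope.
* The Gaussian-on-log10 burden model is a pragmatic default; counts with
  many zeros (tiny panels, low burdens) would warrant a count model.
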