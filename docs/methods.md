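# Methods

This note documents the statistical models implemented in `episig`,
the choices made where the design was genuinely open, and what the
synthetic-data generator does and does not emulate.

## Probe quality control

Six exclusion rules are applied in a fixed order: detection failures,
SNP-adjacent probes, cross-reactive probes, extreme raw betas, non-CpG
probes, sex-chromosome probes. Because the rule categories overlap on
real arrays (a cross-reactive probe may also sit on chrX), the
`FilterReport` records two counts per rule: *matched* (all probes
satisfying the rule, computed on the input) and *removed* (probes newly
excluded given the rules applied before it). Only the removed counts
sum to the total; the final probe set is independent of rule order.

Defaults: a probe fails detection when its detection p-value exceeds
0.01 in at least one sample (both threshold and sample fraction
configurable); SNP exclusion uses MAF strictly greater than 0.01;
"raw beta of 0 or 1" is tested by exact equality after parsing
(tolerance configurable, default 0) in strictly more than 0.25% of
samples; non-CpG means manifest probe class other than `cg`; sex
chromosomes match `X, Y, chrX, chrY`. Sample-level QC based on raw
array intensities cannot be computed from beta values and is out of
scope; samples are excluded by editing the sample sheet.

## Cell-type deconvolution

Whole blood is modeled as a linear mixture of cell-type methylation
profiles. Given a reference panel `R` (deconvolution CpGs × cell
types, default CD4T/CD8T/NK/Bcell/Mono/Neu), each sample's composition
solves

    min_pi || beta_s - R pi ||^2   s.t.  pi >= 0,  sum(pi) = 1.

The solver is non-negative least squares on a system augmented with a
sum-to-one row weighted 1e4, followed by exact renormalization; this
is deterministic, satisfies the simplex constraints to ~1e-8 before
renormalization, and recovers noise-free mixtures to 1e-6. Probes of
the panel missing from a sample are dropped per sample; at least as
many overlapping CpGs as cell types are required and the panel must be
full rank. For use as model covariates one cell type is dropped
(neutrophils by default, the dominant type) to avoid the sum-to-one
collinearity with the intercept.

## Epigenetic clock

The clock is a linear model on a fixed CpG panel predicting a
transformed age. The transform is logarithmic before the knot
`adult_age` (default 20 years) and linear after:

    T(a) = log(a + 1) - log(a0 + 1)      if a <= a0
         = (a - a0) / (a0 + 1)           otherwise

It is continuous and strictly increasing, with the exact inverse used
to map the linear predictor back to years. Ages are stored as reals
(a 2-day-old is 2/365.25 years) because the transform needs continuous
age. Clock CpGs absent from a matrix are tolerated up to 5% of the
panel and imputed with the cohort mean (with a warning); more is an
error.

Age acceleration is DNAm age minus chronological age. The *DNAm-age
residual* — the covariate used by the differential model — is the
residual from an ordinary least-squares regression of DNAm age on
chronological age. The fitting set defaults to the samples entering
the differential model (discovery cases + controls); this is
configurable, since a controls-only fit is also defensible.

Group comparisons use a paired Wilcoxon signed-rank test (DNAm vs
chronological age within a group) and a Mann-Whitney U test
(acceleration between groups), both two-sided. Exact null
distributions are used for the signed-rank test at n ≤ 25 non-zero
untied pairs and for the U test at min(n, m) ≤ 8 without ties;
otherwise normal approximations with continuity (and tie) corrections.
These switchover points are configurable constants; the tests
themselves are delegated to scipy behind this policy and are verified
against full enumeration in the test suite.

## Differential methylation and signature selection

Models are fitted per CpG on the **beta scale**, because the selection
thresholds are defined on beta differences; an M-value option exists
but is off by default. The design is: intercept, group (case = 1),
age, sex (M = 1), five cell proportions, DNAm-age residual. Rank
deficiency is detected at design construction and reported with the
offending columns (e.g. a single-sex cohort).

Probes with missing values are fitted on complete cases with reduced
residual degrees of freedom; probes left with df ≤ 0 are flagged and
excluded from moderation. Variance moderation follows the standard
empirical-Bayes construction: residual variances are shrunk toward a
scaled inverse-chi-square prior (d0, s0²),

    s~_g^2 = (d0 s0^2 + d_g s_g^2) / (d0 + d_g),

with (d0, s0²) estimated by the method of moments on log s_g²
(digamma/trigamma matching; trigamma inverted by Newton iteration).
Probes with zero variance are excluded from hyperparameter estimation.
The moderated t uses d0 + d_g degrees of freedom; d0 = 0 reproduces
the ordinary t and d0 = ∞ pools every probe to s0². The implementation
agrees with Bioconductor limma's `eBayes` to ~1e-10 on shared
fixtures (see `tests/test_limma_crosscheck.py`).

Δβ is the raw difference in group mean beta (case − control) over the
discovery samples, missing values skipped per group. The signature is
the set of CpGs with BH-adjusted p strictly below 0.05 **and** |Δβ|
strictly above 0.10, sorted by q, then |Δβ| descending, then probe id
(a deterministic tie-break).

Enrichment uses one-sided upper-tail hypergeometric tests: for CpG
island/shore membership (foreground = signature, background = post-QC
probe set) and for gene sets over a gene universe, with BH across
terms. CpGs map to every annotated gene span within 10 kb of the
probe position, measured to the nearest span edge and inclusive at the
boundary (a gene starting exactly 10,000 bp away is mapped). Reported
terms need at least 3 gene hits and q < 0.05. Ontology-graph
propagation and web enrichment services are out of scope.

## Classification

Signature CpGs are pruned before training: while any pair of remaining
features has |Pearson r| ≥ 0.90 over the *training* samples (never the
scoring samples, to avoid leakage), the pair with the largest |r| is
found (ties broken lexicographically by probe-id pair) and the member
with the larger mean absolute correlation to the other remaining
features is removed (ties broken by removing the lexicographically
larger id). The post-condition — no kept pair at or above the cutoff —
is asserted in tests.

The classifier is a support-vector machine on the pruned CpGs,
standardized by training mean/SD. Kernel, cost and calibration are
open choices; the defaults are a linear kernel with cost 1, and Platt
sigmoid calibration P(case | f) = 1/(1 + exp(Af + B)) fitted on
out-of-fold decision values from a seeded stratified 5-fold split,
using Platt's smoothed targets. Calibration is implemented in-package
so the trained model serializes to plain JSON (features, scaler,
weights or support vectors, sigmoid parameters, seed) and scoring is
exactly reproducible from the file. Missing feature values are imputed
with training-control means; a sample missing more than 20% of model
features is flagged unscoreable. Scores above 0.5 are called *high*
(case-like); exactly 0.5 — undefined by the > 0.5 / < 0.5 convention —
is called low with a warning. Cohort evaluation reports sensitivity
(expected-case cohorts) and specificity (expected-control cohorts)
with per-cohort score ranges.

## Synthetic data

The generator emits everything a study needs (beta matrix, sample
sheet, manifest, cell reference, clock, truth tables), deterministic
given one seed. Defaults encode the target study design: 8 discovery
cases vs 26 discovery controls, 6 validation cases, 100 validation
controls, planted |Δβ| ∈ [0.10, 0.25] with half hyper- and half
hypomethylated signature CpGs, a six-type Dirichlet blood composition
dominated by neutrophils, a +14.4-year mean case age acceleration, and
island/shore fractions of 0.55 among signature CpGs vs 0.37 in the
background.

Per probe and sample:

* background probes are `expit(logit(m) + cell effect + e)`, with
  bimodal baseline means m (mostly-methylated / mostly-unmethylated,
  as on real arrays), a sparse cell-composition loading on 10% of
  background probes, and Gaussian noise e on the logit scale
  (`noise_sd`, default 0.05 — roughly 0.01 on the beta scale at
  mid-methylation, typical technical noise);
* signature probes add, in case-like samples, a logit shift calibrated
  so the realized mean beta difference equals the configured Δβ
  exactly at the baseline: shift = logit(m + Δβ) − logit(m), with
  baselines kept mid-range so m + Δβ stays inside (0, 1);
* deconvolution probes are `R pi_s` plus beta-scale noise (sd 0.01) —
  mixtures of cell profiles are linear in beta, so these probes are
  generated on that scale;
* clock probes are `mu_p + a_p T(effective age)` plus beta-scale noise
  (sd 0.003), with weights arranged so the clock's linear predictor
  equals the transformed effective age exactly; effective age is
  chronological age plus the planted acceleration (cases) plus an
  inter-individual deviation.

The planted case acceleration is drawn per case from N(14.4, 6²)
years, and every sample receives an N(0, 4²) inter-individual clock
deviation. This spread is essential, not cosmetic: with a constant
offset the DNAm-age-residual covariate becomes an exact linear
function of the group indicator, the design degenerates, and the group
effect is unestimable — real cohorts show acceleration spanning
roughly +2 to +20 years. Truth tables record the per-sample effective
ages, so "recovery" means the clock estimate matches the planted
per-sample value (the clock measurement error is ~0.1 year at these
noise levels); the between-case spread itself is not measurement
error.

An optional second signature on a disjoint CpG set generates
"other-syndrome" cohorts: epigenetically abnormal samples that carry
no case signature and must score low (the specificity condition).
`simulate_test_samples` draws fresh case-like, control-like or
other-signature samples from the same generative state.

What the generator does **not** emulate, and what that implies for the
tests: Illumina type I/II chemistry, batch/chip effects, and
cell-type-specific differential effects are absent; noise is
homoscedastic on the logit scale rather than the U-shaped
beta-variance of real arrays; and — most consequentially — the planted
effect is identical in every case, so signature CpGs are nearly
perfectly pairwise correlated across training samples. The |r| ≥ 0.90
pruning therefore collapses a synthetic signature to very few SVM
features, whereas real cohorts (with heterogeneous per-individual
effects) retain most of theirs. Passing end-to-end tests demonstrates
that the pipeline's statistics, thresholds and bookkeeping behave
correctly under the declared generative model, not that real-data
performance (effect sizes, pruning ratios, score margins) is
reproduced.

## Numerical and policy details

* Problem sizes: unit tests use 2,000–5,000-probe cohorts; the
  end-to-end acceptance simulation uses 20,000 probes × 140 samples,
  which exercises every stage in a few seconds.
* BH adjustment delegates to statsmodels; hypergeometric tails to
  scipy. Both are checked against brute-force definitions in tests.
* Degenerate inputs: single-sample cohorts report SD = 0 with a flag;
  all-zero-difference rank tests return p = 1 with a warning; empty
  signatures are allowed (warned) everywhere except direction
  summaries and enrichment, which error.
* All tie-breaks (signature sorting, pruning pair and victim choice)
  are lexicographic on probe ids, making every output order
  deterministic.
* Seeds: one integer seed drives the generator; the classifier's
  calibration folds take their own seed recorded inside the serialized
  model. Same seed, same bytes.
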