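# Methods

## Model and test

For one (gene, gRNA) pair in n cells, let X_i ∈ {0,1} indicate gRNA
presence, Y_i the gene's UMI count, and Z_i ∈ R^d the cell's technical
covariates. The null hypothesis is conditional independence,
Y ⊥ X | Z. The conditional randomization test resamples the treatment
from its (estimated) conditional law given Z — X~_i ~ Bernoulli(pi_i)
with pi_i = P[X_i = 1 | Z_i] — holding Y and Z fixed, and compares the
observed test statistic with its resampling distribution. Validity
requires only that the propensity model for X | Z is adequate; the
expression model enters solely through the choice of statistic, so
misspecifying it costs power, not type-I error. This is the property
the calibration study exercises.

### Test statistic: distilled NB z-score

The statistic is the Wald z of the gRNA coefficient in the NB
regression log mu_i = beta0 + X_i·beta + Z_i'gamma with fixed
dispersion alpha (convention Var = mu + alpha·mu²). Refitting the full
GLM for every resample would dominate the cost, so the statistic is
distilled into two stages:

1. **Reduced fit** (once per gene): IRLS fit of the covariate-only
   model; the fitted linear predictor o_i = beta0 + Z_i'gamma is frozen
   as an offset.
2. **Univariate refit** (once per resample): MLE of the scalar beta in
   log mu_i = X_i·beta + o_i. Cells with X_i = 0 contribute a
   beta-free constant to this likelihood, so the refit uses only the
   carrier cells. The z-value is beta_hat / SE with the SE from the
   observed information of the univariate likelihood,
   I(beta) = Σ_{i: X_i=1} mu_i (1 + alpha·Y_i) / (1 + alpha·mu_i)².

The univariate solve is a guarded scalar Newton iteration (closed-form
Poisson-style start beta = log(ΣY / Σe^o) over carriers, steps clipped
at ±3, tolerance 1e-10, max 100 iterations); all B resamples are
solved simultaneously with segment sums. The package retains the
all-cells formulation of the same likelihood as an independent code
path, and tests assert both routes agree to 1e-6; the joint-GLM Wald z
is retained separately as the plain parametric comparison method and
is checked to lie within 0.1 of the distilled z on well-conditioned
data.

Degenerate refits — a resample with no carriers, or carrier counts
summing to zero (beta → −∞) — yield no z-value; they are dropped from
the null sample with a logged count rather than imputed.

### Propensity model and resampling

pi_i is estimated by logistic regression of X on Z (MLE via IRLS).
Separation — plausible for rare gRNAs crossed with small batches — is
detected by non-convergence or coefficients exceeding 30 on
standardized covariates and handled by refitting with a small ridge
penalty (lambda = 1e-4 on standardized covariates), flagged in the
result. Fitted probabilities are clipped to [1e-8, 1−1e-8] so
diagnostic logs stay finite. The fit depends only on (X, Z), so one
fit per gRNA is cached and reused for every gene paired with it.
Resampling draws B independent Bernoulli vectors from pi_hat;
B = 500 by default.

### Skew-t null smoothing

An Azzalini skew-t (location xi, scale omega, slant, degrees of
freedom nu) is fit to the B resampled z-scores by maximum likelihood:
bound-constrained L-BFGS-B over (xi, log omega, slant, log nu), with
moment-based initialization (median, sample SD, 3×sample skewness
clipped to ±5, nu = 10) and bounds slant ∈ [−50, 50],
nu ∈ [0.5, 300]. The family contains the Student t (slant 0) and, at
the nu bound, is numerically indistinguishable from a skew-normal /
normal, so near-Gaussian resampling distributions sit comfortably at
the boundary. The CDF is evaluated by adaptive quadrature of the
density over the nearer tail, which keeps extreme tail probabilities
accurate. Left, right, and two-sided (2·min, capped at 1) p-values are
read off the fitted CDF.

If the fit fails — fewer than 50 usable resamples, zero variance, or a
non-finite optimum — the engine falls back to the add-one empirical
p-value p = (1 + #{b: z_b ≤ z}) / (B + 1), which is strictly positive
and super-uniform under the null. Tests check the smoothed and
empirical p-values agree within a factor of two whenever both exceed
0.02.

The default tail is **left**: in CRISPRi screens of candidate
enhancers a true regulatory effect represses the target gene. The
calibration study uses two-sided p-values (its null is symmetric and
QQ-plot practice is two-sided); both are configurable.

### Dispersion estimation

Per-gene dispersions are pooled across genes: (i) method-of-moments
raw estimate alpha_g = max(0.01, (s² − m)/m²) per gene; (ii)
Nadaraya–Watson regression of log raw dispersion on log mean
expression with a Gaussian kernel and Silverman rule-of-thumb
bandwidth (overridable); (iii) each gene's final dispersion is the
trend value at its mean. Method-of-moments is used for the raw pass
because it is closed-form and feeds a pooled trend that absorbs its
variance; the floor keeps downstream likelihoods defined for under-
dispersed genes. A single shared dispersion can be forced
(`fixed_dispersion`), which is how the calibration study fixes
alpha = 1.

### Pair construction and discovery calling

Candidate *cis* pairs join each protein-coding gene with each
candidate-enhancer gRNA whose target-site midpoint lies within 1 Mb of
the gene's TSS, inclusive at the boundary, same chromosome only.
Coordinates are 0-based; gRNA sites are interval midpoints; strand is
ignored for distances. In-silico negative controls take gRNAs strictly
more than 1 Mb from every transcription-factor TSS on their
chromosome, pair them with non-TF genes on other chromosomes, and
downsample uniformly (seeded) to 500 genes per gRNA. Calibration on a
pair family is assessed by the one-sample KS test against Uniform(0,1)
with Bonferroni flagging at alpha/G across G groups; discoveries are
called by BH step-up at FDR 0.1 over the candidate family alone —
positive controls are excluded because BH becomes anticonservative
when enriched-for-signal hypotheses are folded in.

## Synthetic data

Each simulated screen has two confounders per cell: batch
Z1 ~ Bernoulli(0.5) and log-depth Z2 = log of a lognormal with
log-mean 8.9 and log-sd 0.3 (≈ 7,300 median UMIs, a realistic droplet
depth). gRNA presence follows the logistic model with
tau = (−7, −2, 0.5); expression follows a zero-inflated NB with
beta = (−2.5, −2, 0.5): log mu = beta0 + Z'beta (+ X·effect for power
studies; effect = 0 is the null). The depth parameters were calibrated
once, by closed-form calculation confirmed with Monte Carlo, so the
design's two stated properties hold: mean gRNA presence probability
≈ 0.04 and mean expression ≈ 4 across cells. NB draws use the
gamma–Poisson mixture with shape 1/alpha, matching the
Var = mu + alpha·mu² convention exactly.

The calibration study crosses four (lambda, alpha_true) settings —
(0,1), (0,5), (0,0.2), (0.25,1) — with the analysis dispersion fixed
at 1, n = 1000 cells, B = 500 resamples, and 500 repetitions per
setting. Only setting 1 is correctly specified for the parametric NB
z-test; the CRT is expected to stay calibrated in all four.

What the generator does *not* emulate: multi-gene count correlation,
per-gene dispersion heterogeneity within one screen, gRNA
cross-contamination, variable MOI per cell, mitochondrial content, or
the empirical batch/depth distributions of any real screen. Passing
tests therefore demonstrate the method's statistical properties under
its assumed structure — confounded treatment assignment with
misspecified count models — not end-to-end fidelity to any particular
dataset.

## Numerical and reproducibility choices

- GLM fits: statsmodels IRLS, max 100 iterations, deviance tolerance
  1e-8; non-convergence is flagged and surfaced as a per-pair error
  code, never a silent p-value.
- gRNA assignment threshold: UMI count ≥ 5, inclusive, configurable. A
  conservative default against ambient gRNA noise, not a claim about
  any published dataset.
- Cells with zero total UMIs are dropped with a logged count before
  covariate computation (log-transforms are undefined there).
- Batch enters the design one-hot with a dropped reference level;
  fitted means are invariant to the reference choice (tested).
- min_treated = 10 carrier cells by default before a pair is tested;
  below that the pair is flagged, not silently skipped.
- Per-pair randomness derives from blake2b(master_seed | gene_id |
  grna_id) → an independent Generator per pair, making batch results
  bit-identical across worker counts, chunk sizes, and pair orderings
  (tested). Batch parallelism uses joblib over cached per-gene and
  per-gRNA fits.
- Study sizes used by the shipped checks: the four-setting calibration
  study runs at its design size (500 repetitions, B = 500, n = 1000,
  ~3 minutes); the CRT-validity check under a deliberately wrong
  dispersion uses 500 repetitions with the true propensities; design-
  property checks use 100,000 cells.

## Known limitations

- No effect-size estimation or confidence intervals: the test reports
  evidence against conditional independence only.
- One gRNA at a time: the propensity model is marginal per gRNA; joint
  modelling of gRNA co-occurrence is out of scope.
- The skew-t df upper bound (300) means extremely heavy-shouldered but
  near-symmetric nulls are represented as effectively normal; this is
  by construction adequate for z-statistics.
- The ridge fallback's penalty is fixed, not tuned; it exists to keep
  rare-gRNA fits finite, not to optimize shrinkage.
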