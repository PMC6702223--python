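# Methods

This note documents the models, algorithms, numerical choices and
limitations of `twinconn`, in the order data flows through the package.

## Synthetic twin cohorts

`simulate_twin_phenotypes` draws each pair's phenotypes from a bivariate
normal with variance `total_var` and within-pair covariance
`(a2 + d2 + c2) * total_var` for MZ and `(a2/2 + d2/4 + c2) * total_var`
for DZ pairs, via the Cholesky factor of the 2×2 pair covariance. The
latent A/D/C/E variables are never materialized individually: only their
implied covariance matters for every estimator in the package, so the
pair covariance is the minimal sufficient structure. `d2` and `c2` may
not both be positive in one spec, mirroring the identification limit of
the MZ/DZ design.

Defaults are chosen to emulate a healthy young-adult twin cohort:
phenotype variance 1 and mean 0 (the underlying studies do not report
the phenotype's scale, so unit variance is the convention); ages uniform
on 22–36 years shared within pair; MZ twins same-sex, DZ sexes
independent; mean frame-wise displacement (FD) normal with mean 0.17 mm,
SD 0.05 mm, floored at 0, and within-pair FD correlation 0.36 for *both*
zygosities — motion similarity is familial but shows no extra MZ
resemblance, so motion heritability cannot masquerade as phenotype
heritability in simulated data.

`simulate_discordant_cohort` generates three ordered groups —
control twins (g = 0, n = 32), discordant-DZ cotwins (g = 1, n = 30),
discordant-MZ cotwins (g = 2, n = 10) by default — with group means
(0, 0.5, 1.0) in residual-SD units plus age/sex/FD covariate effects and
Gaussian residuals. The 0.5-SD-per-step default is consistent with the
one-tailed powers of the design's pairwise contrasts at these group
sizes (~0.7 for 10 vs 30 at d ≈ 0.8; ~0.9 for 10 vs 32 at d ≈ 1.0).
Group demographics (age means/SDs, sex ratios, FD) default to values
typical of a middle-aged discordant-cotwin sample.

## Synthetic multi-paradigm time series

`simulate_multiparadigm_timeseries` builds node signals as mixtures of
latent factors:

    x = sqrt(sw) * ( W_b f_b  +  sqrt(lam * cw) * W_c f_c )
        + sqrt(spw) * W_p g  +  noise_sd * eps

* `W_b` (backbone) is shared by all subjects and paradigms — the stable
  connectome scaffold that dominates every paradigm's first component;
* `W_c` (circuit) is a low-rank subnetwork whose variance is scaled per
  subject by `lam = loading_base + loading_slope * z(phenotype)`, an
  affine map of the twin phenotype floored at 0.05;
* `W_p` is paradigm-specific; `eps` is white observation noise.

All mixing matrices have unit-norm rows, so the implied covariance has a
node-constant diagonal and the population correlation is an affine image
of the planted edge patterns. Factor series are *exactly whitened*
(rows demeaned and rotated so the sample factor covariance is the
identity); consequently at `noise_sd = 0` the sample correlation matrix
equals the planted pattern exactly, which makes noiseless recovery tests
sharp rather than approximate. Whitening requires
`n_timepoints > 2*n_factors + n_circuit_factors` (validated).

Separating backbone and circuit matters: a subject loading that scaled
the *whole* shared pattern would be normalized away by the correlation
and by the unit-norm SVD loadings, leaving the network score insensitive
to the phenotype. With a constant backbone the circuit's contribution
to the first component varies nearly linearly in `lam`, and the score
over the circuit's top positive edges tracks the latent phenotype at
r ≈ 0.98 under the default settings (shared weight 1.0, specific 0.3,
noise SD 0.5, circuit weight 0.4, slope 0.3, 8 paradigms × 200
timepoints, 50 nodes).

What the generator does **not** emulate: hemodynamic response and
autocorrelated BOLD noise, scanner drift and physiological spectra,
spatial structure of atlas nodes, distance-dependent motion artifacts,
non-Gaussian phenotypes. Passing recovery tests therefore demonstrate
correctness of the estimators under the stated generative model, not
robustness to every property of real fMRI.

## Connectivity stage

Per run: OLS nuisance regression, then zero-phase temporal filtering,
then Pearson correlation; session matrices are averaged entrywise.

* The design is intercept + task regressors (supplied pre-convolved;
  no HRF modeling here) + WM + CSF + the 24-parameter motion expansion
  (6 rigid-body series, backward-difference derivatives with first row
  0, squares of both) + FD. Exactly collinear columns are dropped
  deterministically in a left-to-right scan (the later column loses),
  with a logged warning; a design with as many retained columns as
  timepoints is an error naming the design.
* The filter is a 4th-order Butterworth applied forward-backward
  (`sosfiltfilt`), high-pass 0.008 Hz for task runs and band-pass
  0.008–0.1 Hz for rest by default. Only the band edges are contractual;
  the family/order is this package's choice of a common fMRI default.
  Regression precedes filtering; a joint regression of filter basis and
  nuisance is intentionally out of scope.
* Correlation matrices are averaged directly across sessions (the
  default preserves the plain-average convention); Fisher-z averaging is
  available behind `fisher_z=True`.

## CPC extraction and scoring

Edge vectorization uses a fixed canonical order: upper triangle,
`i < j`, row-major, 0-based node indices — masks and edge lists are
portable only because this order never changes. `compute_cpc` stacks
one subject's paradigm edge vectors (k × E), takes the SVD *without*
edge-wise centering (centering available behind a flag), and returns the
first right-singular vector as loadings, `σ_c²/Σσ²` as variance
explained, and the row projections as paradigm scores. SVD sign is
fixed deterministically: flip so the paradigm scores sum positive; on an
exact zero sum, make the largest-magnitude loading positive. The
network score is the unweighted mean of loadings over the masked edges
(sum and weighted mean selectable); the mean is scale-stable across mask
sizes.

## Biometric models

`fit_biometric_model` supports ADE, ACE, AE, CE, DE and E. Parameters
are one grand mean plus one path per component; variances are squared
paths, so components are non-negative by construction and boundary
solutions (e.g. d → 0) are interior points of the parameterization. The
likelihood is evaluated from per-zygosity sufficient statistics (sums,
squares, cross-products), making each evaluation O(1) in the number of
pairs. Optimization: L-BFGS-B with finite-difference gradients from 8
deterministic starts (Falconer-style moment estimates clipped to the
admissible region, fixed rescalings of them, an equal split, and
near-boundary starts), followed by a Nelder-Mead polish; non-convergence
is flagged on the returned fit, never silent. The saturated reference
(per zygosity: 2 means, 2 variances, 1 covariance; 10 parameters) has a
closed-form ML solution.

The intraclass correlation is the double-entry Pearson correlation (each
pair enters in both orders), invariant to within-pair labeling; the
one-way ANOVA ICC(1) serves as an independent oracle in tests only.

AIC uses the degrees-of-freedom convention `−2LL − 2(n_obs − k)`
(`convention="classic"` gives `−2LL + 2k`). Likelihood-ratio tests use
the naive χ² reference at Δdf = Δk with no 50:50 boundary-mixture
correction, so a component fixed at its boundary yields p = 1 rather
than 0.5. Model selection minimizes AIC among structured fits with ties
broken toward fewer parameters.

Heritability CIs are profile-likelihood intervals on the standardized
genetic fraction h². For the profile, the grand mean and total variance
are concentrated out in closed form (GLS mean with per-zygosity weight
1/(1+r_z); ML variance as the weighted mean square), leaving at most a
one-dimensional inner optimization over the free split (a²/d² in ADE,
c² in ACE); endpoints solve `profile −2LL = min + 3.84` by Brent's
method to 1e-8. This concentration is a reparameterization of the same
likelihood, not a different estimator. For CE/E models the genetic
fraction is structurally zero and the interval degenerates to [0, 0].
Simulation at 85 + 52 pairs shows 93–96% empirical coverage of the 95%
interval.

MZ-vs-DZ mean and variance screens use a two-sample t test and Levene's
test on subject-level values; both ignore pair clustering, a documented
limitation of this screen (not of the ML fits, which model it).

## Risk analysis

Genetic proximity enters the OLS regression as an equally spaced numeric
regressor 0/1/2 (an orthogonal ordinal contrast is available but not the
default), with age, sex and FD always adjusted and a cohort indicator
added when samples are pooled. The two-sided p is default; the
directional hypothesis (proximity increases the phenotype) can be tested
one-sided by flag. Rank-deficient designs fail with the offending
column named. Levene's W uses group-mean absolute deviations. Power
for two-sample contrasts uses the noncentral-t distribution with
noncentrality `d * sqrt(n1*n2/(n1+n2))`; the effect size d is always an
explicit input, never inferred silently. Twin-pair non-independence in
pooled control samples is not modeled.

## Pipeline driver and formats

All tables are TSV with header rows; matrices and time series are
whitespace-delimited text with a single `#` header line carrying
subject/paradigm/session metadata. Node indices are 0-based everywhere.
Every output file written by `run_pipeline` carries the SHA-256 hash of
the configuration and the seed, and a rerun from the same configuration
is byte-identical. Subjects with mean FD ≥ 0.5 mm are excluded at read
time (threshold overridable); the exclusion count is logged and equals
the rows dropped downstream.

## Problem sizes

Tests and the acceptance script scale the study down where full size
adds nothing: parameter recovery uses 2000 + 2000 pairs; coverage uses
500 replicates at the study's 85 + 52 pairs; the imaging branch uses 50
nodes (not an atlas-scale 270) with the full 8-paradigm × 2-session
protocol and 200 timepoints; calibration suites use 2000 replicates at
40–60 subjects per group, where t-based p-values are exact under
normality anyway. The acceptance script reports cohort-level statistics
as Monte Carlo means (medians for p-values) over 25 replicate cohorts
(4 for the imaging branch) so that reported values reflect the sampling
distribution under the stated conditions rather than a single draw.

## Known limitations

* The CPC scalar reduction (mean loading over a supplied mask) is one
  reasonable convention; other reductions change the phenotype's scale
  but not the twin-correlation logic.
* Biometric means are a single grand mean (no covariate-adjusted means
  inside the SEM); pre-residualizing the phenotype before fitting is the
  supported alternative.
* No multivariate twin models, extended pedigrees, or mixed-effects
  handling of pair clustering in the regression branch.
* The DE model is fit when requested but rarely interpretable on its
  own; it exists to complete the nested family.
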