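# Methods

This package benchmarks three linear regressors for brain-age prediction —
support vector regression (SVR), expectation-maximisation relevance vector
regression (EM-RVR) and Gaussian process regression (GPR) — on two feature
representations of structural morphometry: ~101 region-level volumes and a
high-dimensional "voxel" vector, the latter optionally reduced to 150
principal components by incremental PCA.  Because the population-imaging
data such analyses are usually run on cannot be redistributed, the package
ships a seeded synthetic-cohort generator that reproduces the *statistical
structure* of a two-site study at desk scale; everything downstream (CV
protocol, metrics, statistics) is data-agnostic.

## The synthetic cohorts

**Demographics.** Integer ages on [47, 73] (uniform, exactly balanced, or
weighted), near-balanced sex, one site label per cohort.  A second site is
sampled from the same feature law with its age weights tilted linearly so the
mean age rises by `site_age_shift` (default 1.1 years, site 2 older), at
roughly 1/5-scale sizes (2,000 vs 350 subjects).

**Region features.** Volume of region *r* for subject *i*:

    v_ir = [ a_r + b_r (age_i + u_i − 60) + c_r 1[sex_i = F] + ε_ir ] · (TIV_i / TIV_ref)

with intercepts `a_r ~ U(5, 50)` (arbitrary volume units), per-year slopes
`b_r` equal to 0.15–0.45% of `a_r` (negative for ~90% of regions — linear
atrophy; the remainder grow slightly), small sex effects, independent noise
`ε_ir` with SD 2% of `a_r`, and lognormal total intracranial volume that
scales the whole profile (so dividing by TIV removes head size exactly).
A fraction `outlier_rate` (default 1%) of entries is shifted by ±5 noise SDs,
a heavy-tailed contamination that shows up as RMSE > MAE.

**The biological brain-age latent.** `u_i ~ N(0, brain_age_sd²)` (4.5 years
for regions, 3.0 for voxels) shifts *every* feature of a subject coherently,
as if the brain were a few years older or younger than the calendar age.
This is the design choice that matters most: with 101 regions carrying
independent noise, averaging would drive prediction error toward zero and
every benchmark comparison would saturate.  A shared latent caps the
attainable MAE at `E|u| = brain_age_sd·√(2/π)` (≈3.6 y regions, ≈2.4 y
voxels), which keeps desk-scale errors in the empirically plausible 2.5–4.5
year band and gives the voxel representation a genuine (configured) accuracy
advantage.  It is correlated Gaussian noise, not a new mechanism.

**Voxel features.** Low-rank-plus-noise: `X = L Q + σ_n E` with orthonormal
loading rows `Q` (default 200 latents × 10,000 voxels, fixed by a loading
seed shared across sites), nuisance latent SDs decaying as `j^(−1/2)`, one
age latent `∝ (age + u − 60)` carrying `age_signal_fraction` (default 0.3)
of the latent variance, and isotropic noise set to 35% of total variance.
PCA to 150 components therefore retains nearly all age-predictable variance
— emulating, qualitatively, the situation where 150 components explain most
of a registered image's variance.  The generator does **not** emulate
spatial smoothness, site-specific scanner effects on features, nonlinear
atrophy trajectories, or ethnicity/health heterogeneity; passing tests show
the *pipeline* behaves correctly under the assumed structure, not that these
models reach any particular accuracy on real images.

## Preprocessing

Region volumes are divided by TIV, then robust-scaled: `(x − median)/IQR`
per feature with training-fold statistics only (quantiles by linear
interpolation, type 7; a zero IQR leaves the feature unscaled with a
warning).  Voxel features enter incremental PCA *unscaled*; the 150
component scores are then robust-scaled.  Incremental PCA (batch size 400 >
n_components, enforced) keeps memory independent of the number of subjects;
each component's sign is fixed so its largest-magnitude loading is positive.
By default the scaler and PCA basis are refitted inside **every** CV training
fold (`pca_scope="fold"`); `"global"` reproduces the cheaper
fit-once variant at the cost of a technical leakage, which the audit (below)
will flag by design.

## The regressors

All models are linear in their input features; kernel fits are collapsed to
primal weights (`w = X_svᵀ dual`), so persisted models are a weight vector
plus transforms.

* **SVR** — ε-insensitive linear SVR with ε = 0, tolerance 1e-4, max 1,000
  iterations; `C` is the only tuned hyperparameter, selected per outer fold
  by a nested 5-fold age-stratified search over {2⁻⁷, 2⁻⁵, 2⁻³, 2⁻¹, 1, 2,
  2³, 2⁵, 2⁷} scored by MAE (ties to the smaller C).  Raw-voxel SVR uses a
  precomputed linear Gram matrix so cost scales with subjects, not voxels.
* **EM-RVR** — authored here from the update rules
  `Σ = (βΦᵀΦ + diag(α))⁻¹`, `μ = βΣΦᵀy`, `γᵢ = 1 − αᵢΣᵢᵢ`, `αᵢ ← γᵢ/μᵢ²`,
  `β ← (N − Σγᵢ)/‖y − Φμ‖²`, with basis functions pruned at αᵢ > 1e9 and at
  most 5,000 iterations.  Convergence is declared at max |Δ log α| < 1e-3
  (the tolerance is configurable; a looser/tighter value trades iterations
  for weight precision).  Initialisation: α = 1e-6, β = 1/var(y) — a weak,
  standard sparse-Bayesian start.  No bias basis function is added; instead
  target and features are centred internally (an unpenalised intercept at
  the training mean).  Without this, a linear-kernel basis over
  column-centred features cannot represent the ~60-year mean target and the
  EM collapses — the centring is the package's resolution of that
  degeneracy.  If every basis function is pruned the fit degenerates to the
  training mean age (raised as an error by `fit_rvr`; substituted as a
  constant predictor by the CV engine).  A fit with fewer relevance vectors
  than 600/9,432 ≈ 6.4% of its training set is flagged *underfitted* — the
  fraction, not the absolute count, so desk-scale runs behave comparably.
* **GPR** — dot-product kernel (inhomogeneity σ₀ optimised by maximising the
  log marginal likelihood, one L-BFGS run by default) with observation
  jitter 1e-10.  With this kernel the posterior mean coincides with Bayesian
  linear regression, which is the closed-form cross-check in the tests.  GPR
  on raw voxels is not offered: its cost scales with the voxel count and the
  linear-kernel information is already available through the Gram-matrix
  models.

## Evaluation protocol

10-times repeated 10-fold CV, stratified by integer age (ages with fewer
members than folds are merged with the nearest age first), yields k·r = 100
fold scores per model; all models share the fold assignments of each
repetition — a paired design.  Per fold we record MAE, weighted MAE
(MAE / observed age range of the evaluation set), RMSE, Pearson r,
prediction R² (1 − SS_res/SS_tot on held-out data; may be negative), and the
age bias (Spearman correlation of age with BrainAGE = predicted − true age,
average ranks for ties; "not available" when predictions are constant).
Summaries are mean (SD) over the 100 records.

Pairwise model differences in MAE use the variance-corrected paired t-test
for repeated k-fold CV:

    t = d̄ / √( s_d² (1/(k·r) + n_test/n_train) ),   df = k·r − 1

with the fold-derived ratio n_test/n_train = (n/k)/(n − n/k).  The inflation
term compensates for the dependence of fold scores under overlapping
training sets, which makes the classical paired t-test anti-conservative —
the calibration test simulates exactly this null.  Eight models give 28
pairs; the Bonferroni threshold is .05/28 ≈ .0018.  Two-sided p-values
throughout.

**Generalisation.** Every one of the 100 trained instances (with its own
fold scaler/PCA) predicts the full independent site; per-instance metrics
are aggregated as mean (SD) and compared with the same corrected test,
retaining the CV fold ratio: the models are unchanged and only the
evaluation sample differs, so reusing the fold-derived ratio is the
package's documented choice for this setting (no canonical value exists).  Site age
distributions are compared with Welch's two-sample t-test (unequal n and
variances; a pooled-variance option exists).

**Leakage audit.** Every scaler/PCA fit records the subject ids it saw;
`assert_no_leakage` verifies the intersection with each fold's validation
ids (and, structurally, the independent site) is empty.

## Learning curves and chance level

Bootstrap training samples are drawn with replacement in a balanced design —
`c` men and `c` women per integer age, `c` = 1…20, i.e. 54-subject steps up
to 1,080 for 27 ages — disjoint from a balanced validation set (default 40
per age, 20/20 by sex = 1,080 subjects).  Each replicate refits the model
(including SVR's nested C search) and scores the training sample, the
validation set and optionally the full independent site; 95% CIs are Efron
percentile intervals, and "above chance" is the smallest size whose
validation CI upper bound lies below chance.  PCA models run only at sizes
exceeding the component count.  Desk default: 200 replicates (the original
design's 1,000 is a config change).

Chance level is the *uniform-SD convention*: predicting the mean of uniform
ages is assigned an error of range/√12 = 7.5 years for [47, 73].  The exact
mean absolute deviation of a uniform variable is range/4 = 6.5 years; the
package follows the 7.5 convention for comparability and exposes
`uniform_mean_absolute_deviation` so the discrepancy is explicit and tested.

## Numerical and design choices

* Ages are integers: stratification, balancing and the bootstrap design are
  defined "per age".
* β is capped at 1e12 and residual norms floored at 1e-12 in the EM, so
  noise-free targets converge instead of overflowing; a constant target
  degenerates immediately to the mean.
* Robust-scaler quantiles use the type-7 (linear interpolation) convention.
* PCA fold scope is the leakage-safe default; the global variant exists for
  cost parity with fit-once pipelines.
* The CV engine scores each fold by running the persisted model object on
  the raw validation sub-cohort (same code path as independent-site
  scoring), so "site 2 = copy of a validation fold" reproduces fold metrics
  bitwise.
* Desk-scale defaults used by the test-suite and the acceptance script:
  1,000-subject site 1, 2,000 synthetic voxels, one repetition of 10-fold
  CV for the eight-model comparison; 500 subjects with 10×10 CV for the
  record-count check; 50–200 bootstrap replicates for curves.  Full-scale
  settings are plain configuration changes.

## Known limitations

* The linear-atrophy region model and single age latent are assumptions of
  convenience; real volume trajectories bend with age and the age signal is
  spatially structured.
* Chance-level and weighted-MAE conventions assume a bounded, roughly
  uniform age range; neither transfers to strongly non-uniform cohorts.
* The corrected t-test's variance inflation is itself an approximation; its
  calibration band in the tests (rejection rate in [0.01, 0.12] at α = .05)
  reflects that it is conservative rather than exact.
* No age-bias correction is applied to predictions (deliberately out of
  scope); the reported Spearman age-bias quantifies, not removes, regression
  to the mean.
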