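# Methods

## Problem and scope

`specstack` estimates leaf dry matter content (DM, % of fresh mass,
DM = 100·m_dry/m_fresh) from full-spectrum leaf reflectance sampled at
1 nm from 350 to 2500 nm (2151 bands).  DM is a spectrally diffuse
trait: cellulose, hemicellulose and lignin produce broad, overlapping
SWIR absorption complexes rather than an isolated line, and water —
DM's complement in fresh mass — dominates the same region.  The package
therefore implements the full modeling ladder for this problem:
narrow-band index baselines, full-spectrum latent-variable and machine
learning regressions, and a candidate-level stacked ensemble, together
with permutation-based spectral attribution.

## Data model and splitting

Spectra live in a wide table (one row per leaf; columns `R350..R2500`)
with reflectance as a unitless fraction.  The train/test split is a
seeded uniform permutation with train size floor(frac·n); per-sample
membership is not expected to match any external study's split (R and
NumPy RNG streams are not interchangeable), only distributional
comparability matters.  Comparability is checked the way chemometric
practice does: Shapiro–Wilk normality per cohort, Fligner–Killeen
variance homogeneity and the Wilcoxon rank-sum location test across
cohorts.  Skewness is reported in the bias-corrected (adjusted
Fisher–Pearson) form and kurtosis as bias-corrected excess; standard
deviations use the n−1 denominator throughout.  These estimator choices
are recorded in the `CohortStats.estimator_note` field because
references differ in which variant they print.

## Synthetic leaf generator

No public leaf DM/reflectance data accompany the problem, so the
generator is a first-class module with a fully known trait→spectrum
mechanism:

* **Trait law.**  DM ~ shift + Gamma(k, θ) with (k, θ, shift) =
  (1.90, 4.75, 7.08), obtained by method of moments (skew = 2/√k,
  sd = θ√k, mean = shift + kθ) from the target cohort statistics
  mean 16.11 %, sd 6.55, skew 1.45.  Samples are clipped to (0, 100).
* **Template.**  An analytic leaf shape: VIS trough with a Gaussian
  green bump at 550 nm, logistic red edge at ~715 nm, NIR plateau at
  0.48, and a smooth SWIR decline.  No radiative-transfer code is used;
  the template is exact and fast, which the oracle tests rely on.
* **Absorption features.**  Gaussians subtracted from the template:
  water features at 1450 and 1940 nm with depth proportional to the
  latent water fraction, and dry-matter features at 1720, 2100 and
  2300 nm with depth proportional to DM/100.  Water fraction is
  negatively linked to DM (water = 1 − 0.01·DM + noise), so water bands
  carry indirect DM signal, as in real leaves.  Feature widths
  (28–45 nm) are realistic for liquid-water and biochemical overtones;
  a consequence is that feature tails extend beyond ±50 nm, so strict
  "zero signal" holds only a few widths away from each centre (the
  locality tests probe at > 250 nm).
* **Noise.**  Low-order Legendre baseline wiggle (sd 0.004),
  multiplicative scatter (sd 0.01) and additive white noise (sd 0.002),
  then clipping to (0.001, 1) so logarithmic and ratio indices are
  always defined.
* **Modes.**  `linear`: observed DM = structural DM (+ optional label
  noise); the structural DM is an exact linear functional of the
  noiseless spectrum.  `nonlinear`: adds a quadratic interaction of the
  water-1940 and dm-2100 feature depths.  `null`: labels permuted — the
  negative control.
* **Oracle noise level.**  "Noise for oracle R²" is label measurement
  noise with sd = sd_structural·√(1/R² − 1); a regression of observed
  DM on the stored latent feature depths then attains the target R² in
  expectation, giving every downstream learner a computable ceiling.

What the generator does **not** emulate: instrument-specific noise
spectra, detector-junction artifacts, species-level structural
variation (leaf mesophyll scattering differences), specular/geometry
effects, or any radiative-transfer physics.  Passing tests therefore
demonstrate the correctness and statistical behaviour of the modeling
machinery under a controlled mechanism, not field performance on real
leaves.

## Preprocessing

Screening flags spectra with reflectance outside [0, max], absolute
first differences above a step threshold, or non-finite values.
Savitzky–Golay smoothing (quadratic, windows 7/9/11/13) is available
but **off by default** — on high-SNR laboratory spectra it tends to
blunt subtle SWIR features; edges are mirror-padded so the grid length
is preserved.  Standardization is per-band mean/sd from training data
only; bands with sd ≤ 1e−12 are dropped as constant (this also guards
against double-precision cancellation noise being amplified to
unit variance in noise-free synthetic data) with wavelength identity
preserved for reporting.  PCA is computed by SVD of the standardized
training matrix; the component budget K_max is the smallest K whose
cumulative explained variance reaches the target (default 0.99), and
loading signs are fixed so each component's largest-magnitude element
is positive.  Preprocessing is refit inside every CV training fold by
default (`PrepConfig.refit_per_fold`); fitting once on the full
training set is available but is the leakier reading.

## Index library

The registry ships 24 definitions: 23 printed narrow-band indices (ND,
ratio, composite, log-ND and linear-combination kinds) plus the
numerator-swapped NWI 900/970 variant that appears separately in index
combination reports.  Sources describing this index set count 26
members; three definitions are not printed anywhere we can verify, so
the registry documents the gap and stays user-extensible
(`register_index`) rather than inventing them.  NDLI uses log10 — the
base cancels in the ratio, a tested identity.  Zero denominators yield
NaN values that exclude the affected samples from that index's
regression instead of aborting.  The elastic-net baseline standardizes
indices with training statistics and tunes (λ, α) by seeded K-fold CV.

## Base learners and tuning

Seven families: PCR, PLSR, elastic net, random forest, XGBoost,
LightGBM, and Gaussian process regression.  All except PLSR consume the
first `num_comp` PCA scores (num_comp ≤ K_max); PLSR consumes the
standardized full spectrum and tunes its own latent dimension.  Search
bounds are (PCR 10–150 components, PLSR
2–120, elastic net λ ∈ [1e−6, 1] log / α ∈ [0, 1], RF trees 500–2000 /
mtry 5–150 / min_n 2–20, XGBoost and LightGBM tree, depth 3–8 and
log-scaled learning-rate bounds, GPR σ ∈ [1e−3, 10] log).  Boosting min_n, mtry and the row/column subsampling rates have no
established reference bounds; we reuse the RF bounds and [0.5, 1.0].

Sampling is an evenly spaced integer grid for single-dimension families
and a seeded Latin hypercube otherwise (log-scaled where bounds span
decades); budget = 1 degenerates to the (geometric) midpoint.  GPR uses
a two-stage search — stage 1 tunes num_comp at the log-midpoint
σ ≈ 0.1, stage 2 tunes σ at the stage-1 winner — with the kernlab
bandwidth convention k(x,x′) = exp(−σ‖x−x′‖²), standardized inputs and
a fixed 1e−6 jitter.

Tuning is repeated K-fold CV (default 10 folds × 3 repeats, seeded).
Per configuration: cv_rmse_mean is the mean of the folds×repeats
held-out RMSEs, and the SE is their sd/√(folds·repeats) — the
conventional resample SE.  Held-out predictions are retained per
candidate; each training sample is predicted exactly once per repeat.
A configuration that fails to fit is recorded and excluded, never
fatal.  The one-SE rule selects, among configurations within one SE of
the minimum (the SE of the best configuration), the simplest by the
documented order: fewer components, then shallower depth, fewer trees,
larger min_n, smaller mtry, larger λ; ties break by mean RMSE then a
deterministic configuration hash.  Test metrics are RMSE and
R² = 1 − SS_res/SS_tot with the test-set mean.

## Stacking

The candidate library keeps the top-m (default 20) configurations per
family, named `family_rank` (e.g. `gpr_4`).  The OOF matrix averages
each candidate's held-out predictions over repeats (averaging reduces
meta-design noise); candidates evaluated under different resample seeds
are rejected outright, since mixing them would leak fit information
into the meta-design.  The meta-learner minimizes

    (1/2n)·Σᵢ (yᵢ − b − Σ_c w_c·oof_ic)² + λ·Σ_c w_c ,  w ≥ 0

with λ = 1e−6 fixed and the intercept unpenalized.  Because w ≥ 0 makes
the L1 term linear, cyclic coordinate descent with clipping solves the
problem exactly; the implementation centers columns (equivalent under
an unpenalized intercept) and stops when the largest per-sweep weight
change falls below 1e−8 (cap 1e5 sweeps).  No sum-to-one constraint is
imposed — blend weights need not be convex combinations.  Duplicate
OOF columns are kept; coordinate order resolves the tie
deterministically.  Members with positive weight are refit on the full
training set; the stack predicts b + Σ w_c·member_c(x).  Tests verify
the solver against an exact active-set enumeration oracle, projected
gradient, and scipy NNLS at λ = 0, plus the dominance property (the
feasible set contains every single-column solution, so the blend's
meta-fit RMSE cannot exceed the best column's).

## Interpretation

Band permutation importance tiles the grid into contiguous blocks
(default 10 nm; the 2151-band grid leaves a 1 nm final block, kept and
flagged).  For each block and repeat, one shared row permutation is
applied jointly to all raw-reflectance columns in the block — before
standardization/PCA, so importance propagates through the whole
pipeline, and jointly, so within-block correlation is preserved
(independent per-band shuffles would overstate importance).  ΔRMSE is
reported as mean ± sd over repeats (default 10).  Residual diagnostics
report observed − predicted against predicted with a tri-cube local
linear (LOESS) smoother, default span 0.75, evaluated on a uniform grid.

## Numerical choices and degenerate inputs

* Constant trait cohorts: skewness/kurtosis flagged NaN, comparability
  tests skipped with a warning (n < 8 likewise).
* Zero-variance spectral bands: dropped from standardization/PCA with a
  warning; wavelength bookkeeping keeps importance profiles aligned.
* num_comp values above the fold's K_max (or a PLS rank limit) are
  clipped at fit time; the candidate keeps its nominal configuration.
* Elastic-net index baseline with all-zero coefficients returns the
  intercept-only model with a warning.
* A meta-fit that retains no members raises rather than silently
  predicting the mean.

## Problem sizes used by the shipped checks

The package's own validation runs use reduced-but-faithful sizes chosen
to keep the full chain cheap on a single core: n = 500 synthetic leaves
(80/20 split), 5-fold × 1-repeat CV, 4–8 configurations per family,
top-5 candidate libraries, and 3–10 permutation repeats.  The reference
defaults (10 × 3 CV, budget 60, top-20) remain the package defaults and
are exercised through the same code paths.

## Known limitations

* The synthetic mechanism is additive-Gaussian in feature depths;
  real SWIR absorption saturates nonlinearly with water thickness.
* GPR uses a single isotropic RBF bandwidth on standardized scores;
  no ARD.
* The stack serializes its CV record but not fitted estimator state;
  CLI stages that need a fitted stack refit it deterministically from
  the stored candidates.
* Permutation importance on n < ~30 test samples is noisy; profiles
  should be read with their sd band.
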