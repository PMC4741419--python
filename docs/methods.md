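# Methods

## The two-tissue mixture model

A deep gray matter nucleus is modeled as a mixture of two tissue pools with
region-global characteristic T1 values, `μ_GM > μ_WM` (ms), and a local GM
concentration `c_i ∈ [0, 1]` per voxel:

    y_i = μ_GM c_i + μ_WM (1 − c_i) + ε_i,   ε_i ~ N(0, σ).

The two-tissue closure (`C_WM = 1 − C_GM`) is an assumption: CSF and lesion
tissue are not classes. Lesions are handled by exclusion (normal-appearing
tissue only); voxels dominated by CSF would violate the model and should be
kept out of the label volume.

### Why the likelihood must marginalize the concentrations

Profiling the concentrations out of the least-squares objective is
degenerate: for any bracket `[μ_WM, μ_GM]` covering the data range, setting
`c_i = (y_i − μ_WM)/(μ_GM − μ_WM)` reproduces every voxel exactly, so the
profiled residual sum of squares is identically zero on an unbounded
plateau and the naive alternation of clamped concentrations and ordinary
least squares drifts outward without converging to anything meaningful
(measured on simulations: ≈ −100 ms bias on μ_WM at N = 5000, σ = 50 ms).
The fit therefore treats the concentrations as latent variables with a
uniform prior on [0, 1] and maximizes the marginal likelihood

    p(y_i | μ_GM, μ_WM, σ) = [Φ((y_i−μ_WM)/σ) − Φ((y_i−μ_GM)/σ)] / (μ_GM − μ_WM).

The width penalty `1/(μ_GM − μ_WM)` restores identifiability. For
noise-free data the maximizer collapses onto the tightest bracket covering
the data, which equals the true pair exactly when the region contains
(near-)pure voxels of both tissues — without such anchors, no estimator can
recover the characteristic values from noise-free data, because any wider
bracket with rescaled concentrations fits equally well.

### Estimation

1. **Alternation (default 10 iterations)** from the standard 3T
   initialization (1350/850 ms). Step 1 computes the posterior mean and
   variance of each `c_i` (truncated normal on [0, 1]); as σ → 0 the
   posterior mean reduces to the clamped ratio
   `clip((y_i − μ_WM)/(μ_GM − μ_WM), 0, 1)`. Step 2 solves the
   variance-corrected 2×2 normal equations for (μ_GM, μ_WM) and updates σ.
   These are EM steps, so the marginal negative log-likelihood recorded
   after each iteration (`objective_trace`) is non-increasing. An optional
   early-stop tolerance on the parameter change is off by default.
2. **Polish**: bounded L-BFGS on (μ_WM, log width, log σ) with analytic
   gradients, with σ floored at 10⁻³ of the data span.
3. **Noise-free boundary**: the marginal likelihood has a degenerate
   σ → 0 attractor in which the bracket collapses onto the data hull. In
   low-information samples (small N, large σ relative to the bracket) this
   degenerate solution can even dominate the interior optimum — the
   variance split between "narrow mixture plus noise" and "wide noise-free
   mixture" is then weakly identified. As is standard for collapse-prone
   mixture likelihoods, the fit keeps the non-degenerate interior solution
   and follows the boundary only when the bounded descent itself rides σ
   down to the floor, i.e. when the data are consistent with a noise-free
   mixture. In that collapsed regime a derivative-free bracket search runs
   at the floor and the result is canonicalized to the exact σ → 0 limit
   (the data hull); concentrations are then the hard-clip limit and the
   reported σ is the conditional residual SD (zero for exactly noise-free
   data). `PVEFitResult.sigma_marginal` preserves the noise scale at which
   the final objective value holds.

Degenerate inputs raise rather than guess: constant regions (every voxel
maps to one concentration), rank-deficient Step-2 designs, and final
estimates violating `μ_GM > μ_WM`. If the initial bracket misses the data
range entirely (all voxels would clamp to one pure tissue), the fit
restarts from the data hull instead of failing, so true values anywhere in
600–1800 ms are reachable from the fixed initialization. Non-finite or
non-positive T1 voxels inside a region are dropped with a logged count;
regions below a minimum size (default 20 voxels after lesion exclusion) are
rejected.

Measured behavior under the reference conditions: noise-free recovery is exact
to < 10⁻³ ms for true pairs spanning 600–1800 ms and 11–5000 voxels;
absolute bias of both characteristic values is < 1 ms at N = 5000 voxels
and σ = 50 ms; the final objective matches a brute-force 1-ms grid search
to better than 10⁻⁶ relative.

## Per-subject features

Per region and subject: `μ_GM`, `μ_WM`, the concentration ratio
`C_GM/C_WM`, and the global mean T1. The ratio is the ratio of ROI-mean
concentrations (one scalar per region), not a mean of voxelwise ratios,
which are unbounded where the WM fraction vanishes. Both analysis arms use
the same lesion-excluded voxel set, so they differ only in the statistic.
Failed regions become missing values with a logged reason; subjects are
dropped pairwise per region in the statistics.

A known attenuation: with noisy data the posterior-mean concentration field
shrinks toward ½, which biases the ratio feature toward 1 relative to the
underlying mixture (e.g. a true region ratio of 0.62 appears as ≈ 0.87 at
σ = 50 ms). The shrinkage depends on σ/(μ_GM − μ_WM), which is shared
between groups, so group contrasts on the ratio remain valid; absolute
ratio values should not be read as unbiased mixture fractions.

## Group statistics

* **Multivariate arm** — multivariate linear model of the feature triple on
  group + age + sex; Pillai's trace with its standard F approximation
  (exact for a single-degree-of-freedom hypothesis). Implemented directly
  (verified against statsmodels MANOVA to 10⁻¹³ and against the pooled
  t-test to 10⁻¹⁵ in the 1-feature, no-covariate case, where the reduction
  is algebraic).
* **Component tests** — two-tailed permutation two-sample t-tests.
  Covariates are regressed out of the feature first; group labels of the
  residuals are permuted (10 000 permutations by default, mandatory seed;
  exhaustive enumeration automatically when the number of distinct splits
  is ≤ 20 000, giving exact p-values). `p = (1 + #{|t*| ≥ |t|})/(1 + n)`,
  so p-values are never zero. Constant features yield t = 0, p = 1 with a
  warning.
* **Global arm** — t-test of the group coefficient in an ordinary linear
  model, which reduces exactly to the classical pooled two-sample t-test
  without covariates.
* **Multiplicity** — families are the regions for the multivariate and
  global arms and the three components within a region for the component
  tests. Bonferroni by default; optionally a single-step max-statistic
  permutation FWE procedure that shares the permutation draws with the raw
  component tests (guaranteeing corrected ≥ raw per instance).

Null calibration, measured: the component test's type-I error at α = 0.05
over 1000 null cohorts at the default group sizes (19 vs 43, with age/sex
covariates) is 0.045.

## Synthetic data

The generator emulates a case-control imaging study's data layer: four
ellipsoidal nuclei on a
64³ grid at 1 mm (scaled for other grids), per-subject characteristic
values drawn from group distributions, the forward mixture model plus
Gaussian noise, spherical T1-hyperintense lesions in patients only, and a
cohort table with group/age/sex. Defaults are the package's reference
study conditions:

* 19 controls vs 43 patients; ages 33 ± 9.3 vs 35.2 ± 10 years; sex ratios
  11 F/8 M vs 27 F/16 M.
* Thalamus: μ_GM 1389 ± 47 vs 1427 ± 40 ms, μ_WM 912 ± 18 vs 918 ± 14 ms,
  ratio 0.62 ± 0.08 vs 0.61 ± 0.07 (control vs patient).
* Caudate, putamen, pallidum: region-typical values with identical
  distributions in both groups (no reference per-tissue values are
  established for them); they act as built-in null regions.
* Voxel noise σ = 50 ms — a round value on the scale of quantitative T1
  mapping residuals in deep gray matter, matching the estimator's
  characterization conditions.
* Lesions: Poisson-distributed count (mean 3 per patient across regions),
  radius 2 voxels, T1 elevated 25 % — enough that forgetting the exclusion
  visibly shifts features, mimicking a low lesion load.

The thalamic concentration field is a center-bright radial profile
parametrized in the ellipsoidal volume fraction, `c ∝ (1 − r³)^γ`, rescaled
so border and center anchors (0 and 1) are attained exactly on the voxel
lattice; γ is solved per subject so the region-mean GM fraction matches the
drawn concentration ratio. At γ = 1 the voxelwise concentration
distribution is exactly uniform — the estimator's reference condition. The
full [0, 1] span gives every subject pure-tissue anchors, which is what
makes per-subject characteristic values identifiable; the other nuclei use
narrow near-homogeneous spans (qualitatively matching their flat
appearance) and consequently have only weakly identified per-subject
values — acceptable because they carry no group effect. Subject-level
variation enters through the characteristic intensities and the target
ratio, not through the spatial pattern shape, with a truth manifest
recording every drawn value. All randomness flows from one seed through
per-subject child streams, so cohorts are bit-reproducible and truth draws
do not depend on which regions are materialized.

What the generator does **not** emulate: realistic anatomy or texture,
spatial noise correlation, B1/inversion-efficiency effects, registration
or segmentation error, and CSF partial volume at region borders. Passing
tests therefore validate the estimator and the statistical machinery under
the stated model, not robustness to those real-data effects.

## Validation problem sizes

The test suite and the acceptance script size their simulations to run on
one CPU in minutes while keeping each check meaningful: recovery checks use
11–5000 voxels; bias uses 200 replications at N = 5000; calibration uses
1000 null cohorts with 999 permutations each; the end-to-end group
comparison uses 100 simulated cohorts of 62 subjects (thalamus only, ≈ 1500
voxels per subject) with 499 permutations per component family. The
brute-force oracle evaluates every ordered 1-ms pair in 600–1800 ms.

## Known limitations

* Two tissue classes only; no spatial regularization of the concentration
  field (each voxel's concentration depends on its own intensity alone).
* The ratio feature is attenuation-biased under noise (see above).
* Characteristic values of regions without near-pure voxels are
  hull-limited rather than true tissue values; between-group contrasts
  remain valid when the concentration span is shared across groups.
* At small voxel counts with large σ relative to the GM–WM separation, the
  marginal likelihood only weakly separates noise from mixture width; the
  interior-solution policy keeps estimates stable but they inherit
  small-sample bias in that regime.
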