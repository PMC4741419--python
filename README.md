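# dgmpv — partial-volume analysis of deep gray matter on quantitative T1 maps

Deep gray matter nuclei (thalamus, caudate, putamen, pallidum) are mixtures
of gray-matter tissue (neurons, glia) and traversing white-matter fibers, so
the T1 value of a voxel reflects an unknown blend of both. Classical
region-of-interest analyses average the signal over a nucleus and can detect
*that* something changed between patients and controls, but not *which*
tissue pool changed. `dgmpv` implements a partial-volume decomposition of
quantitative T1 maps that separates the two contributions, and the
statistical framework to compare them across groups — e.g. early
relapsing-remitting multiple sclerosis patients against healthy controls.

## Model

Within one nucleus, every voxel value is modeled as a two-tissue linear
mixture with Gaussian noise:

```
y_i = μ_GM · C_GM,i + μ_WM · C_WM,i + ε_i ,   C_GM,i + C_WM,i = 1 ,   ε_i ~ N(0, σ)
```

where `μ_GM > μ_WM` are region-global characteristic T1 values (the T1 of
100 % gray and 100 % white matter, in ms) and `C_GM,i ∈ [0, 1]` is the local
GM concentration of voxel *i*. Treating the concentrations as free
parameters makes least squares degenerate, so the fit maximizes the marginal
likelihood with the concentrations integrated out under a uniform prior on
[0, 1]:

```
p(y_i | μ_GM, μ_WM, σ) = [Φ((y_i−μ_WM)/σ) − Φ((y_i−μ_GM)/σ)] / (μ_GM − μ_WM)
```

Estimation alternates two steps from the standard 3T initialization
(μ_GM = 1350 ms, μ_WM = 850 ms): **Step 1** estimates the concentration map
given the characteristic values (posterior mean; the hard limit is
`clip((y−μ_WM)/(μ_GM−μ_WM), 0, 1)`); **Step 2** re-estimates μ_GM, μ_WM and
σ by variance-corrected least squares. Ten iterations are followed by a
direct likelihood polish. Per subject and region this yields the feature
triple (μ_GM, μ_WM, C_GM/C_WM) plus the classical global mean T1 over the
same normal-appearing (lesion-excluded) voxels.

Group comparison runs two arms per region:

* **partial-volume arm** — Pillai's-trace multivariate test of
  (μ_GM, μ_WM, C_GM/C_WM) on group with age/sex covariates, followed by
  two-tailed permutation two-sample t-tests per component
  (residual-permutation scheme, exhaustive when feasible);
* **global-averaging arm** — covariate-adjusted two-sample t-test on mean
  T1.

Multiplicity is controlled by Bonferroni or a max-statistic permutation
family-wise-error procedure.

## Worked example

No imaging data ships with the package; the synthetic module generates
cohorts whose group structure defaults to the package's reference study
conditions
(19 controls vs 43 patients; thalamic μ_GM 1389 ± 47 vs 1427 ± 40 ms,
μ_WM 912 ± 18 vs 918 ± 14 ms, concentration ratio 0.62 ± 0.08 vs
0.61 ± 0.07; 50 ms voxel noise; lesions in patients only):

```
$ cat spec.yaml
grid: 48
regions:
  thalamus: {}

$ dgmpv simulate --spec spec.yaml --out sim --seed 7
62 subjects -> sim
$ dgmpv fit --cohort sim/cohort.csv --out fit --regions thalamus
features for 62 subjects -> fit/features.csv
$ dgmpv compare --features fit/features.csv --cohort sim/cohort.csv \
      --out cmp --regions thalamus --n-perm 9999 --seed 7
Group comparison report
=======================

[thalamus]
  pv_manova     all      stat=  +0.1262 p= 0.05450 p_corr= 0.05450 (bonferroni)
  pv_component  mu_gm    stat=  +2.2334 p= 0.02940 p_corr= 0.08820 (bonferroni)
  pv_component  mu_wm    stat=  +1.5016 p= 0.14140 p_corr= 0.42420 (bonferroni)
  pv_component  ratio    stat=  -1.0275 p= 0.30820 p_corr= 0.92460 (bonferroni)
  global_mean   mean_t1  stat=  +1.9312 p= 0.05835 p_corr= 0.05835 (bonferroni)
```

Reading the report: the multivariate test on the partial-volume triple and
the global-mean test both flag a thalamic difference at roughly the same
strength, but only the partial-volume arm attributes it — the GM
characteristic T1 carries the smallest component p-value (here t = +2.23,
patients higher), while the WM pool and the concentration ratio do not
differ. `fit` also writes per-subject GM concentration maps
(`cgm_<subject>.nii.gz`) whose thalamic values increase from the border to
the center of the nucleus.

`simulate` records every drawn ground-truth parameter in `truth.json`, so
estimated features can be compared against the values that generated them.

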