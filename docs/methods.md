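# Methods

## Models

### Mixed-effects w-score (core method)

Each of the K ROIs is fitted independently. The model is a random-intercept
regression: biological covariates (age in years, sex coded 0 = female /
1 = male, years of education, intracranial volume in mm³ — all in raw units)
as fixed effects, the center as an exchangeable random intercept
(`b_jk ~ N(0, d_k)`, scalar variance per ROI), homoscedastic Gaussian
residuals. Only CN scans enter the fit; patients are scored against the CN
normative surface.

Estimation is two-stage, the standard reading of mixed-model fitting:

1. `(d_k, σ²_k)` maximize the restricted log-likelihood profiled over the
   fixed effects,

   `l = −½ [ Σ_j log|Σ_j| + r'Σ⁻¹r + log|X'Σ⁻¹X| + (n−p−1) log 2π ]`,

   with `Σ_j = σ² I + d 11'` per center and `r` the GLS residual at
   `(d, σ²)`.
2. `(α_k, β_k)` are the GLS solution at the estimated variances; per-center
   intercepts are BLUPs `b̂_j = d̂ · Σr_j / (σ̂² + n_j d̂)`.

The compound-symmetry structure gives closed forms for every determinant and
inverse, so the implementation works entirely from per-center sufficient
statistics (X'X, X'y, y'y) — no n×n matrix is ever built — and one objective
evaluation costs O(J·p²). A dense-matrix implementation (explicit Σ) exists
in the test suite as an independent oracle and agrees to 1e-8 relative; the
fit is also cross-checked against `statsmodels.MixedLM`.

Optimization is quasi-Newton (L-BFGS-B) on `(log d, log σ²)` from five
starts on a variance-ratio grid `d/(d+σ²) ∈ {0.05, 0.25, 0.5, 0.75, 0.95}`,
plus the `d = 0` boundary candidate whose ReML optimum is closed form
(`σ̂² = RSS/(n−p−1)`); an unconverged winner gets one Nelder-Mead polish.
Estimated `d` below 1e-10 collapses to the boundary. Degenerate parameter
corners (e.g. `d → ∞`, where the GLS matrix approaches the centering matrix)
return a large finite penalty rather than raising. Objective tolerance is
ftol = 1e-13; the fitted optimum is asserted (in tests) to dominate every
optimizer iterate.

Because ICV is of order 1.3×10⁶ mm³ while sex is 0/1, the design matrix is
rescaled column-wise (root-mean-square scaling) before any solve; returned
coefficients and objective values are always in original units (the
determinant correction for the rescaling is applied analytically). Rank
deficiency is detected by SVD up front and reported with the implicated
columns.

The w-score scale `s_k` is the SD (ddof = 1) of the conditional CN training
residuals pooled over all centers — unlike the per-dataset method, the
mixed-model w-score has a single scale per ROI.

**Unseen centers.** Scoring a center absent from training uses the marginal
mean (`b = 0`) by default; a `strict` policy raises instead, and a
`blup-from-data` policy estimates the center's intercept from the scoring
rows themselves with all parameters frozen. Marginal is the default because
the motivating use case is an external scan set with no CN reference at all.
`add_center` registers a new center from its CN rows by the frozen-parameter
BLUP; fixed effects, variance components and all existing centers' scores
are untouched (bit-identical), which is what makes incremental growth cheap.

**Missing education.** Rows without education are dropped at fit time; at
score time education is imputed with the scoring center's CN median when
available, else the global CN median stored in the model. Some policy is
unavoidable for external cohorts that do not record education; this one is
the package's choice and is stated here rather than hidden.

### Protocol-specific w-score (Self-W)

Per dataset and ROI, a robust regression of thickness on the four covariates
over that dataset's CN scans: IRLS with Tukey bisquare weights (tuning
constant 4.685, ≈95% Gaussian efficiency), MAD scale, at most 50 iterations,
tolerance 1e-8 — delegated to `statsmodels.RLM`. Whether the original
formulation used bisquare or Huber weights is not documented anywhere we
know of; on clean data the choice is immaterial (the suite bounds the
IRLS-vs-OLS gap), and bisquare is the common default. The w-score divides
the residual by the plain SD (ddof = 1) of the dataset's CN residuals — not
the robust scale — so that CN training scores have SD exactly 1. Datasets
with fewer than p+2 = 6 complete CN rows are skipped with a warning: the
structural limitation of per-site normative modeling. Unseen datasets cannot
be scored, by construction.

### ComBat

Location/scale batch adjustment with parametric Empirical Bayes, following
the classical formulation: least squares with one intercept per batch plus
shared covariate effects; grand mean = per-subject-weighted (n_j/N) average
of batch intercepts; pooled residual SD with denominator N; per-batch
moments of the standardized residuals shrunk by a normal prior on the
additive effect and an inverse-gamma prior on the squared multiplicative
effect, hyperparameters by method of moments, conditional posterior means
iterated to a fixed point (tolerance 1e-6, max 500 iterations; an
independent heavily-damped iteration serves as the test oracle). Output is
harmonized thickness in mm (covariate effects and grand mean restored), not
a standardized score.

Two deliberate choices: the fit uses CN rows only, so all three harmonizers
share the same normative reference (the classical formulation fits on all
rows); and at least 2 ROIs are required because the EB priors pool across
ROIs. The implementation reproduces Bioconductor `sva::ComBat` to ~1e-7 on
matched input, and the suite keeps that comparison as a cross-check.

## Synthetic cohorts

The generator produces per-scan thickness as

```
y = base_k + X·β[:,k] + a_{jk} + severity_i · atrophy_{dx,k} + u_i + scale_{jk}·ε_ik
```

* `a_jk` — additive center effect, drawn N(0, d_k) (default SD 0.1 mm) or
  fixed by the caller; `scale_jk` multiplies only the noise (default
  U(0.9, 1.1)), mirroring the multiplicative batch model.
* `u_i` — a global per-subject offset (default SD 0.1 mm) shared by all
  ROIs: inter-individual "overall thickness" variation. It is part of each
  per-ROI residual (each ROI's marginal model is exactly the harmonizers'
  model), cancels in paired designs, and keeps covariate-direction contrasts
  from being unrealistically separable in 68 dimensions.
* `severity_i` — gamma-distributed per-patient atrophy multiplier (mean 1,
  default SD 0.6, capped at 2.5): disease-stage heterogeneity. Without it
  every patient carries an identical shift and CN-vs-patient classification
  saturates near 100%, far from the ~80–90% regime reported for real
  cohorts.
* Randomness is laid out in per-center counter-based substreams of one
  global seed, so adding a center never perturbs existing centers' draws —
  required by the scalability experiment. Same config ⇒ byte-identical
  cohort.
* A conservative worst-case positivity check (3σ bounds, severity at its
  cap) rejects configurations that could produce non-positive thickness
  before anything is sampled.

Three packaged presets define the study conditions:

* `default_discovery_config()` — ten centers with the demographic profile of
  a typical multi-cohort discovery set (group sizes 25–2907 CN per center,
  one dominant center, one Parkinson-only patient center; ages ~64–76,
  education 9–17 years, ICV ~1.2–1.6×10⁶ mm³; education varies by center,
  confounding center with demographics). Covariate effects: age ≈ −0.008,
  sex ≈ −0.03, education ≈ +0.01, ICV ≈ +2e-8 (mm per unit), each modulated
  ±30% across ROIs; baselines recentred so a typical subject's observed
  thickness lies in 2–3 mm. AD atrophy: −0.12 mm (−0.17 entorhinal) on ten
  temporal/parietal ROIs; PD atrophy: 80% of −0.10 mm on eight
  fusiform/precuneus/supramarginal/temporal ROIs.
* `two_center_config()` — the center-effect-removal benchmark: two CN-only
  centers with identical demographics and fixed ±0.15 mm offsets.
* `confounded_disease_config()` — eight CN/AD centers with education
  confounded with center (means 10→17 years), demographics matched within
  center, balanced-ish group composition, additive center effects SD
  0.15 mm. Composition balance matters: when one center dominates one
  diagnostic class, its offset becomes a shortcut class signal that
  *inflates* pooled raw-thickness accuracy — the generator for the
  disease-preservation experiment deliberately avoids that regime so center
  effects act as nuisance, which is the phenomenon harmonization addresses.

What the generator does **not** emulate: nonlinear or covariate-interacting
protocol effects, rich multi-mode anatomical covariance between ROIs,
longitudinal repeat scans, and scanner physics. Consequences worth stating
plainly: within a single dataset of this linear world, the w-score is raw
thickness minus covariate information, so raw can never be *systematically*
worse than harmonized scores inside one dataset — the advantage of
harmonization shows in pooled/merged analyses and unseen-center scoring,
which is where the experiments look for it. Passing tests therefore
demonstrate correctness of the estimators and the pooled-analysis benefits,
not every empirical ordering that richer real data can produce.

## Evaluation protocol

PCA-LDA classification: per repeat, the majority class is undersampled
without replacement to the minority size; features are centered on the
undersampled set; PCA retains the smaller of the 95%-cumulative-variance
component count and **10 components** (further capped at n−2); LDA is fitted
on the projected data and — deliberately — evaluated on the same training
set, 30 repeats by default. The in-sample protocol is the point: if even the
optimal in-sample discriminator cannot separate two centers, the center
effect is gone. The 10-component cap exists because with ~60 retained
components the in-sample null accuracy of LDA at these sample sizes is
~0.63, which would swamp the chance-level reading; with the cap the null sits
at ~0.53–0.55 (and ~0.67 for very small pairs, which is why small-pair cells
read high). A stratified 70/30 holdout mode is available behind a flag for
general use. Sensitivity/specificity use patient as the positive class.

Center prediction runs every unordered center pair on CN scans (pairs with
fewer than 3 usable scans are skipped with a warning); the grand mean is
over unordered pairs. Disease classification runs CN-vs-patient per dataset
plus a merged set that pools every AD-bearing dataset (PD-only centers are
excluded from the merge). The intrasubject comparison scales raw thickness
by a reference center's CN SD per ROI, takes whole-brain means per subject
and center, and applies a two-sided paired t-test on both scales (the test
is the package's choice; only p-values are protocol-specified upstream),
reporting the percent reduction in mean |between-center difference|. The
scalability experiment refits the mixed model on every subset of the
non-test datasets (optionally a random cap per subset size), scores the test
dataset marginally, and reports RMSE against the all-centers reference
w-scores normalized by the IQR of the reference scores pooled over subjects
× ROIs; single-dataset training sets are fitted at the `d = 0` boundary
(the random intercept is unidentifiable from one center).

## Problem sizes used by the test suite

The suite's simulation studies run at sizes chosen to make their conclusions
statistically meaningful at desk scale: oracle checks on ≤60-row problems;
variance-component recovery on 20 seeds of 20 centers × 100 CN (the cohort's
`d̂`/`σ̂²` are averaged over its 4 ROIs before the 15% median-error check —
a single ROI's ReML estimate from 20 centers has ~24% sampling error, so the
cohort-level average is the honest estimator of the shared component);
center-effect removal on 2 × 300 CN; Self-W reference behavior on 3 × 5000
CN (the training-mean w-score has scale 1/√n, so 3 SE sits below the 0.05
band only for n ≳ 3600); disease preservation on 10 seeds of the confounded
preset; scalability on 10 seeds of a 0.15-scaled discovery preset with 12
ROIs and ≤2 subsets per size; the intrasubject design with two 3000-CN
reference centers and 24 ROIs (a center's BLUP cannot be distinguished from
its subjects' mean anatomy, so the residual paired bias shrinks as
`subject_sd·√2/√n_center`; 3000 scans — the size of the dominant center in
the emulated discovery set — keep it well below the paired test's noise).

## Known limitations

* One model per ROI; no spatial pooling, random slopes, or per-center
  residual variances.
* The marginal policy leaves an unseen center's true offset in its w-scores;
  `blup-from-data` absorbs it but biases scores if the scoring set contains
  patients.
* ComBat's CN-only fit deviates from the classical all-rows fit; on strongly
  imbalanced cohorts the two differ.
* The generator's linearity means some orderings reported on real data
  (e.g. harmonized scores beating raw *within* a single dataset) are not
  reproducible in simulation; see the generator section for why.
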