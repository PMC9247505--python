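# lmewscore

Harmonization of multicenter regional cortical-thickness data with a
mixed-effects w-score, plus the two standard comparators (protocol-specific
w-score and ComBat) and the evaluation toolkit used to verify that center
effects are removed while disease effects are preserved.

## The problem

Mean cortical thickness per region of interest (ROI) is a workhorse feature
in neurodegeneration research, but thickness measured at different imaging
centers is systematically biased by scanner vendor, field strength and
acquisition protocol — the *center effect*. Pooling multicenter data without
correction lets a classifier learn the scanner instead of the disease, and
classical per-site normative models cannot score a center that lacks its own
cognitively normal (CN) reference sample.

## The model

For each ROI *k*, thickness is modeled as a linear mixed-effects regression
with the biological covariates (age, sex, years of education, intracranial
volume) as fixed effects and the center as an exchangeable random intercept:

```
y_ik = α_k + X_i β_k + b_{j(i),k} + ε_ik,    b_jk ~ N(0, d_k),   ε_ik ~ N(0, σ²_k)
```

Variance components `(d_k, σ²_k)` are estimated by restricted maximum
likelihood (ReML) on CN scans, fixed effects by generalized least squares at
the estimated variances, and per-center intercepts as BLUPs. The harmonized
score is a covariate-adjusted z-score,

```
w_ik = (y_ik − ŷ_ik) / s_k,
```

with `ŷ` the conditional mean (including the center's BLUP) for centers seen
at training and the marginal mean (`b = 0`) for unseen centers, and `s_k` the
pooled SD of the conditional training residuals. Because the center is a
random effect, the model can score scans from centers never seen at training
and can register a new center from its CN scans alone (`add_center`) without
refitting — the two capabilities the per-dataset w-score and ComBat lack.

The package also provides:

* `fit_selfw` / `score_selfw` — per-dataset robust (Tukey-bisquare IRLS)
  normative w-score, the per-site reference method;
* `fit_combat` / `apply_combat` — ComBat location/scale harmonization with
  parametric Empirical-Bayes shrinkage (cross-checked against Bioconductor's
  `sva::ComBat`);
* `synthetic` — a seeded multicenter cohort generator with known ground
  truth (covariate effects, additive/multiplicative center effects,
  region-specific AD/PD atrophy with per-patient severity);
* `evaluation` — the PCA-LDA center-prediction and CN-vs-patient
  experiments, paired intrasubject comparison, and the leave-one-dataset-out
  scalability curve.

## Worked example

```python
import numpy as np
import lmewscore as lw

cfg = lw.default_discovery_config(scale=0.25, seed=42)   # 10-center preset
cohort = lw.generate_cohort(cfg).cohort
print(f"cohort: {len(cohort)} scans, {len(cohort.centers)} centers, {cohort.n_rois} ROIs")

model = lw.fit_lme(cohort)                                # CN rows only
print(f"random-intercept SD (mean over ROIs): {np.sqrt(model.d).mean():.3f} mm")
print(f"residual SD (mean over ROIs):        {np.sqrt(model.sigma2).mean():.3f} mm")

w = lw.score_lme(model, cohort)
res = lw.center_prediction_experiment(
    {"raw": cohort.thickness(), "lme_w": w.scores()},
    cohort.df["center_id"], cohort.df["diagnosis"], n_repeats=30, seed=42)
for name, r in res.items():
    print(f"{name}: mean pairwise center-prediction accuracy = {r.grand_mean:.3f}")

rep = lw.atrophy_report(w)
print(rep[rep.diagnosis == "AD"].head(5).to_string(index=False))
```

prints

```
cohort: 1144 scans, 10 centers, 68 ROIs
random-intercept SD (mean over ROIs): 0.099 mm
residual SD (mean over ROIs):        0.144 mm
raw: mean pairwise center-prediction accuracy = 1.000
lme_w: mean pairwise center-prediction accuracy = 0.647
diagnosis                 roi  mean_wscore   n
       AD       lh_entorhinal    -1.087974 203
       AD       rh_entorhinal    -1.059269 203
       AD   rh_middletemporal    -0.935913 203
       AD lh_inferiortemporal    -0.894331 203
       AD         rh_fusiform    -0.817483 203
```

The generator injected additive center effects with SD 0.10 mm and residual
noise totalling ~0.14 mm per ROI; the fit recovers both scales. Raw
thickness identifies a scan's center almost perfectly, while on harmonized
w-scores the in-sample classifier drops far toward chance (the residual
optimism comes from the smallest center pairs, which undersample to a
handful of scans per class). The most negative group-mean w-scores land
exactly on the ROIs that carry the generator's Alzheimer atrophy
(entorhinal, temporal, fusiform, inferior-parietal).

A command-line interface mirrors the library:

```
lmewscore simulate --scale 0.25 --seed 42 --out cohort.csv --truth truth.json
lmewscore fit --method lme --cohort cohort.csv --model lme.json
lmewscore score --model lme.json --cohort cohort.csv --out wscores.csv
lmewscore add-center --model lme.json --new-cn new_center.csv --out lme2.json
lmewscore evaluate center-effect --cohort cohort.csv --scores wscores.csv --out report/
```

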