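"""Seeded evaluation procedures for residual site effects and disease signal.

Four experiments, each reusable on any feature block (raw thickness or any
harmonized score matrix):

* PCA-LDA classification with class-balancing undersampling, repeated with
  fresh undersamples; the default evaluates on the training set itself — the
  deliberately optimistic probe: if even the in-sample discriminator cannot
  separate two centers, the center effect is gone.
* Pairwise center-prediction over all center pairs (CN scans only).
* CN-vs-patient classification per dataset plus a merged AD set.
* Paired intrasubject comparison and the leave-one-dataset-out scalability
  curve for the mixed-effects harmonizer.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .cohort import CohortTable, WScoreTable
from .lme import LMEModel, fit_lme, score_lme

__all__ = [
    "ClassificationResult",
    "CenterPredictionResult",
    "DiseaseClassificationResult",
    "PairedComparisonResult",
    "ScalabilityResult",
    "pca_lda_classify",
    "center_prediction_experiment",
    "disease_classification_experiment",
    "intrasubject_comparison",
    "scalability_experiment",
    "atrophy_report",
]

#: Retained principal components: the smaller of the 95%-cumulative-variance
#: count and this cap (further limited by n - 2).  The cap keeps the
#: in-sample LDA optimism of the null case near chance level.
MAX_COMPONENTS = 10
VAR_THRESHOLD = 0.95


@dataclass
class ClassificationResult:
    """Aggregated repeated PCA-LDA performance (positive class = patient)."""

    per_repeat_accuracy: np.ndarray
    per_repeat_sensitivity: np.ndarray
    per_repeat_specificity: np.ndarray
    n_per_class: int
    seed: int
    positive_label: object

    @property
    def accuracy(self) -> float:
        return float(np.mean(self.per_repeat_accuracy))

    @property
    def sensitivity(self) -> float:
        return float(np.mean(self.per_repeat_sensitivity))

    @property
    def specificity(self) -> float:
        return float(np.mean(self.per_repeat_specificity))

    @property
    def accuracy_sd(self) -> float:
        return float(np.std(self.per_repeat_accuracy, ddof=1)) \
            if len(self.per_repeat_accuracy) > 1 else 0.0


def _n_components(Z: np.ndarray, max_components: int) -> int:
    n = len(Z)
    cap = max(1, min(max_components, n - 2, Z.shape[1]))
    pca = PCA(n_components=min(n - 1, Z.shape[1])).fit(Z)
    q95 = int(np.searchsorted(np.cumsum(pca.explained_variance_ratio_), VAR_THRESHOLD) + 1)
    return max(1, min(cap, q95))


def pca_lda_classify(
    features: np.ndarray,
    labels,
    n_repeats: int = 30,
    seed: int = 0,
    positive_label=None,
    max_components: int = MAX_COMPONENTS,
    holdout: bool = False,
) -> ClassificationResult:
    """Repeated class-balanced PCA-LDA classification.

    Each repeat undersamples the majority class (without replacement) to the
    minority size, centers the features on the undersampled set, fits PCA then
    LDA, and — by default — evaluates on that same training set.  With
    ``holdout`` a stratified 70/30 split is evaluated instead (the sane
    general-use mode).
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError(f"exactly two classes required, got {list(classes)}")
    if positive_label is None:
        non_cn = [c for c in classes if str(c) != "CN"]
        positive_label = non_cn[-1] if non_cn else classes[-1]
    negative_label = classes[classes != positive_label][0]
    idx_pos = np.flatnonzero(labels == positive_label)
    idx_neg = np.flatnonzero(labels == negative_label)
    m = min(len(idx_pos), len(idx_neg))
    if m < 3:
        raise ValueError(f"minority class has {m} < 3 members")
    rng = np.random.default_rng(seed)
    acc = np.empty(n_repeats)
    sen = np.empty(n_repeats)
    spe = np.empty(n_repeats)
    for r in range(n_repeats):
        take_pos = rng.choice(idx_pos, size=m, replace=False)
        take_neg = rng.choice(idx_neg, size=m, replace=False)
        idx = np.concatenate([take_pos, take_neg])
        assert len(np.unique(idx)) == len(idx)  # each scan used at most once
        y = np.concatenate([np.ones(m, dtype=int), np.zeros(m, dtype=int)])
        Xb = features[idx]
        if holdout:
            perm_pos = rng.permutation(m)
            perm_neg = rng.permutation(m)
            cut = max(2, int(round(0.7 * m)))
            tr = np.concatenate([perm_pos[:cut], m + perm_neg[:cut]])
            te = np.concatenate([perm_pos[cut:], m + perm_neg[cut:]])
            if len(te) == 0:
                raise ValueError("holdout split left no test rows")
        else:
            tr = te = np.arange(2 * m)
        mu = Xb[tr].mean(axis=0)
        Ztr, Zte = Xb[tr] - mu, Xb[te] - mu
        q = _n_components(Ztr, max_components)
        pca = PCA(n_components=q).fit(Ztr)
        lda = LinearDiscriminantAnalysis().fit(pca.transform(Ztr), y[tr])
        pred = lda.predict(pca.transform(Zte))
        truth = y[te]
        acc[r] = float(np.mean(pred == truth))
        sen[r] = float(np.mean(pred[truth == 1] == 1)) if (truth == 1).any() else np.nan
        spe[r] = float(np.mean(pred[truth == 0] == 0)) if (truth == 0).any() else np.nan
    return ClassificationResult(acc, sen, spe, m, seed, positive_label)


@dataclass
class CenterPredictionResult:
    """Pairwise center-prediction accuracies for one feature type."""

    matrix: pd.DataFrame          # centers x centers, NaN off the computed pairs
    skipped_pairs: list[tuple[str, str]] = field(default_factory=list)

    @property
    def grand_mean(self) -> float:
        """Mean accuracy over unordered center pairs."""
        vals = self.matrix.to_numpy()
        iu = np.triu_indices_from(vals, k=1)
        v = vals[iu]
        return float(np.nanmean(v))


def center_prediction_experiment(
    scores: dict[str, np.ndarray],
    centers,
    diagnosis=None,
    cn_only: bool = True,
    n_repeats: int = 30,
    seed: int = 0,
    min_per_center: int = 3,
) -> dict[str, CenterPredictionResult]:
    """For each feature table, PCA-LDA accuracy of every unordered center pair.

    ``scores`` maps a method name (raw / selfw / combat / lme ...) to an
    (n, K) feature matrix aligned with ``centers`` (and ``diagnosis`` when
    ``cn_only``).  Pairs in which either center has fewer than
    ``min_per_center`` usable scans are skipped with a warning.
    """
    centers = np.asarray(centers)
    if diagnosis is not None:
        diagnosis = np.asarray(diagnosis)
    if cn_only:
        if diagnosis is None:
            raise ValueError("cn_only requires diagnosis labels")
        keep = diagnosis == "CN"
    else:
        keep = np.ones(len(centers), dtype=bool)
    unique_centers = list(dict.fromkeys(centers))
    if len(unique_centers) < 2:
        raise ValueError("need at least 2 centers")
    ss = np.random.SeedSequence(seed)
    pair_seeds = {
        pair: int(s.generate_state(1)[0] % (2**31))
        for pair, s in zip(
            itertools.combinations(unique_centers, 2),
            ss.spawn(math.comb(len(unique_centers), 2)),
        )
    }
    out: dict[str, CenterPredictionResult] = {}
    for method, feats in scores.items():
        feats = np.asarray(feats, dtype=float)
        mat = pd.DataFrame(
            np.full((len(unique_centers),) * 2, np.nan),
            index=unique_centers, columns=unique_centers,
        )
        skipped = []
        for ca, cb in itertools.combinations(unique_centers, 2):
            sel = keep & np.isin(centers, (ca, cb))
            labs = centers[sel]
            if min((labs == ca).sum(), (labs == cb).sum()) < min_per_center:
                skipped.append((ca, cb))
                warnings.warn(f"pair ({ca}, {cb}) skipped: too few CN scans")
                continue
            res = pca_lda_classify(
                feats[sel], labs, n_repeats=n_repeats, seed=pair_seeds[(ca, cb)],
                positive_label=cb,
            )
            mat.loc[ca, cb] = mat.loc[cb, ca] = res.accuracy
        out[method] = CenterPredictionResult(mat, skipped)
    return out


@dataclass
class DiseaseClassificationResult:
    per_dataset: dict[str, ClassificationResult]
    merged: ClassificationResult | None
    skipped: list[str] = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        rows = {
            ds: (r.accuracy, r.sensitivity, r.specificity)
            for ds, r in self.per_dataset.items()
        }
        if self.merged is not None:
            rows["merged_AD"] = (
                self.merged.accuracy, self.merged.sensitivity, self.merged.specificity,
            )
        return pd.DataFrame.from_dict(
            rows, orient="index", columns=["accuracy", "sensitivity", "specificity"]
        )


def disease_classification_experiment(
    features: np.ndarray,
    diagnosis,
    centers,
    n_repeats: int = 30,
    seed: int = 0,
    merged: bool = True,
    min_group: int = 3,
) -> DiseaseClassificationResult:
    """CN-vs-patient PCA-LDA per dataset, plus a merged set pooling every
    AD-bearing dataset (PD-only datasets are excluded from the merge)."""
    features = np.asarray(features, dtype=float)
    diagnosis = np.asarray(diagnosis)
    centers = np.asarray(centers)
    is_patient = (diagnosis != "CN") & (diagnosis != "UNKNOWN")
    unique_centers = list(dict.fromkeys(centers))
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(len(unique_centers) + 1)]
    per_dataset: dict[str, ClassificationResult] = {}
    skipped = []
    for i, ds in enumerate(unique_centers):
        m = centers == ds
        n_cn = int((m & (diagnosis == "CN")).sum())
        n_pt = int((m & is_patient).sum())
        if n_cn < min_group or n_pt < min_group:
            skipped.append(ds)
            continue
        sel = m & ((diagnosis == "CN") | is_patient)
        labs = np.where(is_patient[sel], "patient", "CN")
        per_dataset[ds] = pca_lda_classify(
            features[sel], labs, n_repeats=n_repeats, seed=seeds[i],
            positive_label="patient",
        )
    merged_res = None
    if merged:
        ad_datasets = [
            ds for ds in unique_centers
            if ((centers == ds) & (diagnosis == "AD")).sum() > 0
        ]
        sel = np.isin(centers, ad_datasets) & ((diagnosis == "CN") | (diagnosis == "AD"))
        if sel.sum() and (diagnosis[sel] == "AD").sum() >= min_group:
            labs = np.where(diagnosis[sel] == "AD", "patient", "CN")
            merged_res = pca_lda_classify(
                features[sel], labs, n_repeats=n_repeats, seed=seeds[-1],
                positive_label="patient",
            )
    return DiseaseClassificationResult(per_dataset, merged_res, skipped)


@dataclass
class PairedComparisonResult:
    """Intrasubject two-center comparison on the raw-scaled and w-score scales."""

    per_subject: pd.DataFrame     # subject_id, raw_a, raw_b, raw_diff, w_a, w_b, w_diff
    p_raw: float
    p_wscore: float
    percent_reduction: float      # of mean |difference|, raw-scaled -> w-score


def intrasubject_comparison(
    raw_pair: CohortTable,
    w_pair: WScoreTable,
    ref_sd: np.ndarray,
) -> PairedComparisonResult:
    """Whole-brain paired comparison of the same subjects scanned at two centers.

    Raw thickness is scaled per ROI by ``ref_sd`` (the reference-center CN
    thickness SD) so that both scales are dimensionless; each subject's
    whole-brain mean per center is compared with a two-sided paired t-test.
    """
    ref_sd = np.asarray(ref_sd, dtype=float)
    if ref_sd.shape != (raw_pair.n_rois,):
        raise ValueError("ref_sd must have one entry per ROI")
    df_r = raw_pair.df
    df_w = w_pair.df
    cents = list(dict.fromkeys(df_r["center_id"]))
    if len(cents) != 2:
        raise ValueError(f"expected exactly 2 centers, got {cents}")
    ca, cb = cents
    counts = df_r.groupby(["subject_id", "center_id"]).size().unstack(fill_value=0)
    bad = counts[(counts.get(ca, 0) != 1) | (counts.get(cb, 0) != 1)].index.tolist()
    if bad:
        raise ValueError(f"subjects without exactly one scan per center: {bad}")
    subj = sorted(counts.index)

    def _means(df: pd.DataFrame, vals: np.ndarray, scale) -> pd.DataFrame:
        g = pd.DataFrame(vals / scale)
        g["subject_id"] = df["subject_id"].to_numpy()
        g["center_id"] = df["center_id"].to_numpy()
        wide = g.groupby(["subject_id", "center_id"]).mean().mean(axis=1).unstack()
        return wide.loc[subj]

    raw_m = _means(df_r, raw_pair.thickness(), ref_sd)
    w_m = _means(df_w, w_pair.scores(), 1.0)
    raw_diff = raw_m[ca] - raw_m[cb]
    w_diff = w_m[ca] - w_m[cb]
    p_raw = float(sps.ttest_rel(raw_m[ca], raw_m[cb]).pvalue)
    p_w = float(sps.ttest_rel(w_m[ca], w_m[cb]).pvalue)
    mean_abs_raw = float(np.mean(np.abs(raw_diff)))
    reduction = 100.0 * (1.0 - float(np.mean(np.abs(w_diff))) / mean_abs_raw) \
        if mean_abs_raw > 0 else 0.0
    per_subject = pd.DataFrame({
        "subject_id": subj,
        "raw_a": raw_m[ca].to_numpy(), "raw_b": raw_m[cb].to_numpy(),
        "raw_diff": raw_diff.to_numpy(),
        "w_a": w_m[ca].to_numpy(), "w_b": w_m[cb].to_numpy(),
        "w_diff": w_diff.to_numpy(),
    })
    return PairedComparisonResult(per_subject, p_raw, p_w, reduction)


@dataclass
class ScalabilityResult:
    """IQR-normalized w-score RMSE against the all-centers reference model,
    by number of training datasets."""

    test_dataset: str
    per_size_mean: dict[int, float]
    per_subset: pd.DataFrame      # n_train, subset, rmse_normalized
    reference_iqr: float
    failed_subsets: list[tuple[str, ...]] = field(default_factory=list)


def scalability_experiment(
    cohort: CohortTable,
    test_dataset: str,
    reference: LMEModel,
    max_subsets_per_size: int | None = None,
    seed: int = 0,
) -> ScalabilityResult:
    """Leave-one-dataset-out scalability curve of the mixed-effects harmonizer.

    For subsets S of the non-test datasets, refit the harmonizer on S (CN
    only), score the test dataset with the marginal (unseen-center) policy,
    and compare with the reference model's w-scores via RMSE over all test
    rows and ROIs, normalized by the IQR of the reference w-scores.  With
    ``max_subsets_per_size`` set, at most that many random subsets are drawn
    per size (capped enumeration for large center counts).
    """
    all_centers = cohort.centers
    if test_dataset not in all_centers:
        raise KeyError(f"unknown test dataset {test_dataset!r}")
    others = [c for c in all_centers if c != test_dataset]
    if len(others) < 2:
        raise ValueError("need at least 3 datasets")
    test_mask = (cohort.df["center_id"] == test_dataset).to_numpy()
    test_rows = cohort.subset(test_mask)
    ref_w = score_lme(reference, test_rows).scores()
    q75, q25 = np.percentile(ref_w, [75, 25])
    iqr = float(q75 - q25)
    rng = np.random.default_rng(seed)
    records = []
    failed = []
    for size in range(1, len(others) + 1):
        total = math.comb(len(others), size)
        if max_subsets_per_size is not None and total > max_subsets_per_size:
            chosen = set()
            while len(chosen) < max_subsets_per_size:
                chosen.add(tuple(sorted(rng.choice(len(others), size, replace=False))))
            subsets = [tuple(others[i] for i in c) for c in sorted(chosen)]
        else:
            subsets = list(itertools.combinations(others, size))
        for S in subsets:
            sub = cohort.subset(cohort.df["center_id"].isin(S).to_numpy())
            try:
                model = fit_lme(sub, allow_single_center=True)
                w = score_lme(model, test_rows, unseen_center_policy="marginal").scores()
            except Exception as exc:
                failed.append(S)
                warnings.warn(f"subset {S} failed: {exc}")
                continue
            rmse = float(np.sqrt(np.mean((w - ref_w) ** 2)))
            records.append({"n_train": size, "subset": S, "rmse_normalized": rmse / iqr})
    per_subset = pd.DataFrame.from_records(records)
    per_size = {
        int(s): float(g["rmse_normalized"].mean())
        for s, g in per_subset.groupby("n_train")
    }
    return ScalabilityResult(test_dataset, per_size, per_subset, iqr, failed)


def atrophy_report(wscores: WScoreTable, groups=("AD", "PD")) -> pd.DataFrame:
    """Group-mean w-score per ROI per diagnosis, most atrophic first.

    Long-format frame (diagnosis, roi, mean_wscore, n) sorted ascending by
    mean within each group — the tabular counterpart of a cortical atrophy
    map.
    """
    df = wscores.df
    present = [g for g in dict.fromkeys(df["diagnosis"]) if g in groups]
    if not any((df["diagnosis"] == g).any() for g in present):
        raise ValueError("no patient rows to report")
    out = []
    for g in present:
        sub = df.loc[df["diagnosis"] == g, list(wscores.roi_names)]
        means = sub.mean(axis=0).sort_values()
        out.append(pd.DataFrame({
            "diagnosis": g, "roi": means.index, "mean_wscore": means.to_numpy(),
            "n": len(sub),
        }))
    return pd.concat(out, ignore_index=True)
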