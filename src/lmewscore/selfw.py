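"""Protocol-specific (per-dataset) w-score harmonizer.

Within each dataset's cognitively normal group, thickness is regressed on the
four biological covariates by robust iteratively reweighted least squares
(IRLS, Tukey bisquare); the w-score is the residual standardized by the SD of
the CN residuals of that dataset.  By construction the CN training mean of
every dataset is ~0 per ROI, which is why this score acts as the per-dataset
reference ("gold standard") — at the cost of needing enough CN scans in every
dataset and of being unable to score a dataset it has never seen.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .cohort import COVARIATE_NAMES, CohortTable, WScoreTable

__all__ = ["SelfWModel", "fit_selfw", "score_selfw", "DegenerateResidualError"]

#: Tukey bisquare tuning constant (95% Gaussian efficiency) and IRLS controls.
TUKEY_C = 4.685
IRLS_MAXITER = 50
IRLS_TOL = 1e-8


class DegenerateResidualError(ValueError):
    """Residual variance is numerically zero for some dataset/ROI."""


@dataclass
class SelfWModel:
    method: str
    covariate_names: tuple[str, ...]
    roi_names: tuple[str, ...]
    datasets: tuple[str, ...]
    alpha: np.ndarray   # (J, K) mm
    beta: np.ndarray    # (J, p, K) mm per covariate unit
    s: np.ndarray       # (J, K) mm, CN residual SD
    n_cn: dict[str, int]
    edu_median_by_dataset: dict[str, float]
    edu_median_global: float
    skipped: tuple[str, ...] = ()

    def dataset_index(self, dataset: str) -> int:
        try:
            return self.datasets.index(dataset)
        except ValueError:
            raise KeyError(
                f"dataset {dataset!r} has no fitted sub-model; the protocol-"
                "specific w-score cannot score unseen datasets"
            ) from None

    def education_fill(self) -> dict[str, float]:
        fills = dict(self.edu_median_by_dataset)
        fills["__global__"] = self.edu_median_global
        return fills

    def to_dict(self) -> dict:
        return {
            "covariate_names": list(self.covariate_names),
            "roi_names": list(self.roi_names),
            "datasets": list(self.datasets),
            "alpha": self.alpha,
            "beta": self.beta,
            "s": self.s,
            "n_cn": self.n_cn,
            "edu_median_by_dataset": self.edu_median_by_dataset,
            "edu_median_global": self.edu_median_global,
            "skipped": list(self.skipped),
        }

    @classmethod
    def from_dict(cls, data: dict) -> "SelfWModel":
        return cls(
            method="selfw",
            covariate_names=tuple(data["covariate_names"]),
            roi_names=tuple(data["roi_names"]),
            datasets=tuple(data["datasets"]),
            alpha=np.asarray(data["alpha"], dtype=float),
            beta=np.asarray(data["beta"], dtype=float),
            s=np.asarray(data["s"], dtype=float),
            n_cn={k: int(v) for k, v in data["n_cn"].items()},
            edu_median_by_dataset={
                k: float(v) for k, v in data["edu_median_by_dataset"].items()
            },
            edu_median_global=float(data["edu_median_global"]),
            skipped=tuple(data.get("skipped", ())),
        )


def _irls_fit(Xd: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Robust regression coefficients via IRLS with Tukey bisquare weights."""
    res = sm.RLM(y, Xd, M=sm.robust.norms.TukeyBiweight(c=TUKEY_C)).fit(
        maxiter=IRLS_MAXITER, tol=IRLS_TOL, scale_est="mad"
    )
    return np.asarray(res.params)


def fit_selfw(cohort: CohortTable, min_cn: int | None = None) -> SelfWModel:
    """Fit per-dataset robust normative regressions on CN rows.

    Datasets with fewer than ``min_cn`` complete CN rows (default p + 2) are
    skipped with a warning — the structural limitation of the per-dataset
    approach: a center without enough CN scans gets no model at all.
    """
    p = len(COVARIATE_NAMES)
    if min_cn is None:
        min_cn = p + 2
    cn = cohort.cn_only().drop_missing_education()
    fitted, skipped = [], []
    for ds in cohort.centers:
        n = int((cn.df["center_id"] == ds).sum())
        if n >= min_cn:
            fitted.append(ds)
        else:
            skipped.append(ds)
            warnings.warn(
                f"dataset {ds!r} has only {n} complete CN rows (< {min_cn}); skipped"
            )
    if not fitted:
        raise ValueError("no dataset has enough CN rows to fit")
    K = cohort.n_rois
    J = len(fitted)
    alpha = np.empty((J, K))
    beta = np.empty((J, p, K))
    s = np.empty((J, K))
    n_cn = {}
    for j, ds in enumerate(fitted):
        sub = cn.subset((cn.df["center_id"] == ds).to_numpy())
        X = sub.covariates()
        Y = sub.thickness()
        n_cn[ds] = len(sub)
        # column scaling keeps the IRLS inner solves well conditioned for
        # raw-unit ICV
        Xd = np.column_stack([np.ones(len(X)), X])
        scales = np.sqrt(np.mean(Xd**2, axis=0))
        scales[scales <= 0] = 1.0
        Xs = Xd / scales
        for k in range(K):
            coef = _irls_fit(Xs, Y[:, k]) / scales
            resid = Y[:, k] - Xd @ coef
            sd = float(np.std(resid, ddof=1))
            if not np.isfinite(sd) or sd <= 1e-12:
                raise DegenerateResidualError(
                    f"zero residual variance for dataset {ds!r}, "
                    f"ROI {cohort.roi_names[k]!r}"
                )
            alpha[j, k], beta[j, :, k], s[j, k] = coef[0], coef[1:], sd
    edu = cn.df.groupby("center_id")["education"].median()
    return SelfWModel(
        method="selfw",
        covariate_names=tuple(COVARIATE_NAMES),
        roi_names=tuple(cohort.roi_names),
        datasets=tuple(fitted),
        alpha=alpha, beta=beta, s=s, n_cn=n_cn,
        edu_median_by_dataset={d: float(edu.get(d, np.nan)) for d in fitted},
        edu_median_global=float(cn.df["education"].median()),
        skipped=tuple(skipped),
    )


def score_selfw(model: SelfWModel, cohort: CohortTable) -> WScoreTable:
    """w = (y - alpha_j - X beta_j) / s_j per dataset and ROI.

    Every row's dataset must have a fitted sub-model; patients are scored
    against their dataset's CN normative fit.
    """
    if tuple(cohort.roi_names) != tuple(model.roi_names):
        raise ValueError("cohort ROI set does not match the model")
    X = cohort.covariates(education_fill=model.education_fill())
    Y = cohort.thickness()
    W = np.empty_like(Y)
    center_ids = cohort.df["center_id"].to_numpy()
    for ds in dict.fromkeys(center_ids):
        j = model.dataset_index(ds)
        m = center_ids == ds
        pred = model.alpha[j] + X[m] @ model.beta[j]
        W[m] = (Y[m] - pred) / model.s[j]
    out = cohort.df.copy()
    out[list(cohort.roi_names)] = W
    return WScoreTable(out, cohort.roi_names)
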