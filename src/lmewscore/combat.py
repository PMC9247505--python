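"""ComBat location/scale harmonization with parametric Empirical Bayes.

The model per ROI ``k`` is

    y_ijk = alpha_k + X_ij beta_k + gamma_jk + delta_jk eps_ijk,

with an additive (gamma) and a multiplicative (delta) effect per dataset.
After removing covariate effects and standardizing by the pooled residual SD,
per-dataset location/scale estimates are shrunk by parametric Empirical Bayes
(normal prior on gamma, inverse-gamma prior on delta^2, hyperparameters by
method of moments, conditional posterior means iterated to a fixed point).
The harmonized output is thickness in mm — covariate effects are removed,
batch effects divided out, then covariate effects and the grand mean are
restored — not a standardized score.

Fitting uses CN rows only so that the batch parameters are estimated on the
same normative reference as the other harmonizers; the classical formulation
fits on all rows, a deliberate divergence documented in the methods note.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort import COVARIATE_NAMES, CohortTable

__all__ = ["ComBatModel", "fit_combat", "apply_combat", "eb_fixed_point"]

EB_TOL = 1e-6
EB_MAXITER = 500


@dataclass
class ComBatModel:
    method: str
    covariate_names: tuple[str, ...]
    roi_names: tuple[str, ...]
    datasets: tuple[str, ...]
    alpha: np.ndarray        # (K,) mm, grand intercept
    beta: np.ndarray         # (p, K)
    pooled_sd: np.ndarray    # (K,) mm
    gamma_star: np.ndarray   # (J, K), standardized additive batch effect
    delta_star: np.ndarray   # (J, K) > 0, multiplicative batch effect (SD ratio)
    gamma_bar: np.ndarray    # (J,) EB normal-prior mean
    tau2: np.ndarray         # (J,) EB normal-prior variance
    lam: np.ndarray          # (J,) inverse-gamma shape
    theta: np.ndarray        # (J,) inverse-gamma scale
    n_cn: dict[str, int]
    edu_median_by_dataset: dict[str, float]
    edu_median_global: float

    def dataset_index(self, dataset: str) -> int:
        try:
            return self.datasets.index(dataset)
        except ValueError:
            raise KeyError(
                f"dataset {dataset!r} was not present at fit time; ComBat "
                "cannot harmonize unseen datasets"
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
            "pooled_sd": self.pooled_sd,
            "gamma_star": self.gamma_star,
            "delta_star": self.delta_star,
            "gamma_bar": self.gamma_bar,
            "tau2": self.tau2,
            "lam": self.lam,
            "theta": self.theta,
            "n_cn": self.n_cn,
            "edu_median_by_dataset": self.edu_median_by_dataset,
            "edu_median_global": self.edu_median_global,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "ComBatModel":
        return cls(
            method="combat",
            covariate_names=tuple(data["covariate_names"]),
            roi_names=tuple(data["roi_names"]),
            datasets=tuple(data["datasets"]),
            alpha=np.asarray(data["alpha"], dtype=float),
            beta=np.asarray(data["beta"], dtype=float),
            pooled_sd=np.asarray(data["pooled_sd"], dtype=float),
            gamma_star=np.asarray(data["gamma_star"], dtype=float),
            delta_star=np.asarray(data["delta_star"], dtype=float),
            gamma_bar=np.asarray(data["gamma_bar"], dtype=float),
            tau2=np.asarray(data["tau2"], dtype=float),
            lam=np.asarray(data["lam"], dtype=float),
            theta=np.asarray(data["theta"], dtype=float),
            n_cn={k: int(v) for k, v in data["n_cn"].items()},
            edu_median_by_dataset={
                k: float(v) for k, v in data["edu_median_by_dataset"].items()
            },
            edu_median_global=float(data["edu_median_global"]),
        )


def eb_fixed_point(
    z: np.ndarray,
    gamma_hat: np.ndarray,
    delta2_hat: np.ndarray,
    gamma_bar: float,
    tau2: float,
    lam: float,
    theta: float,
    tol: float = EB_TOL,
    max_iter: int = EB_MAXITER,
) -> tuple[np.ndarray, np.ndarray]:
    """Iterate the conditional posterior means for one batch to a fixed point.

    ``z`` is the (n, K) standardized data of the batch, ``gamma_hat`` /
    ``delta2_hat`` the per-ROI sample moments.  Updates:

        gamma* = (n tau2 gamma_hat + delta2* gamma_bar) / (n tau2 + delta2*)
        delta2* = (theta + 1/2 sum_i (z_i - gamma*)^2) / (n/2 + lam - 1)
    """
    n = len(z)
    g = gamma_hat.copy()
    d2 = delta2_hat.copy()
    for _ in range(max_iter):
        g_new = (n * tau2 * gamma_hat + d2 * gamma_bar) / (n * tau2 + d2)
        d2_new = (theta + 0.5 * ((z - g_new) ** 2).sum(axis=0)) / (n / 2 + lam - 1)
        change = max(
            np.max(np.abs(g_new - g) / (np.abs(g) + 1e-12)),
            np.max(np.abs(d2_new - d2) / (np.abs(d2) + 1e-12)),
        )
        g, d2 = g_new, d2_new
        if change < tol:
            break
    return g, d2


def _moments_priors(gamma_hat_j: np.ndarray, delta2_hat_j: np.ndarray):
    """Method-of-moments hyperparameters for one batch across ROIs."""
    gamma_bar = float(np.mean(gamma_hat_j))
    tau2 = float(np.var(gamma_hat_j, ddof=1))
    m = float(np.mean(delta2_hat_j))
    s2 = float(np.var(delta2_hat_j, ddof=1))
    if s2 <= 0:
        # all ROIs identical: an (arbitrarily) tight prior at the common value
        lam, theta = 2.0 + 1e6, (1e6 + 1.0) * m
    else:
        lam = (2 * s2 + m**2) / s2
        theta = (m * s2 + m**3) / s2
    return gamma_bar, tau2, lam, theta


def fit_combat(cohort: CohortTable) -> ComBatModel:
    """Estimate the ComBat standardization model and EB-shrunk batch effects.

    Requires >= 2 datasets, each with >= 2 complete CN rows, and >= 2 ROIs
    (the EB priors pool information across ROIs).
    """
    cn = cohort.cn_only().drop_missing_education()
    datasets = cn.centers
    if len(datasets) < 2:
        raise ValueError("ComBat needs at least 2 datasets")
    K = cohort.n_rois
    if K < 2:
        raise ValueError("parametric EB needs at least 2 ROIs to pool across")
    counts = cn.df["center_id"].value_counts()
    too_small = [d for d in datasets if counts.get(d, 0) < 2]
    if too_small:
        raise ValueError(f"datasets with < 2 complete CN rows: {too_small}")
    X = cn.covariates()
    Y = cn.thickness()
    N, p = len(X), X.shape[1]
    codes = np.searchsorted(np.array(sorted(datasets)), cn.df["center_id"].to_numpy())
    order = sorted(datasets)
    J = len(order)
    nj = np.bincount(codes, minlength=J)

    # Least squares with one intercept per batch plus covariates; batch means
    # are then combined with per-subject weights n_j/N into the grand mean.
    onehot = np.zeros((N, J))
    onehot[np.arange(N), codes] = 1.0
    M = np.column_stack([onehot, X])
    scales = np.sqrt(np.mean(M**2, axis=0))
    scales[scales <= 0] = 1.0
    Ms = M / scales
    coef, _, rank, _ = np.linalg.lstsq(Ms, Y, rcond=None)
    if rank < M.shape[1]:
        raise ValueError("rank-deficient ComBat design (collinear covariates)")
    coef = coef / scales[:, None]
    batch_means = coef[:J]          # (J, K)
    beta = coef[J:]                 # (p, K)
    alpha = (nj / N) @ batch_means  # (K,)

    fitted = M @ coef
    resid = Y - fitted
    pooled_var = (resid**2).mean(axis=0)
    if (pooled_var <= 1e-18).any():
        bad = [cohort.roi_names[k] for k in np.flatnonzero(pooled_var <= 1e-18)]
        raise ValueError(f"zero pooled residual variance on ROIs {bad}")
    pooled_sd = np.sqrt(pooled_var)

    Z = (Y - alpha - X @ beta) / pooled_sd
    gamma_star = np.empty((J, K))
    delta_star = np.empty((J, K))
    gamma_bar = np.empty(J)
    tau2 = np.empty(J)
    lam = np.empty(J)
    theta = np.empty(J)
    for j in range(J):
        zj = Z[codes == j]
        gamma_hat = zj.mean(axis=0)
        delta2_hat = zj.var(axis=0, ddof=1)
        if (delta2_hat <= 1e-18).any():
            bad = [cohort.roi_names[k] for k in np.flatnonzero(delta2_hat <= 1e-18)]
            raise ValueError(
                f"zero within-dataset variance for {order[j]!r} on ROIs {bad}"
            )
        gamma_bar[j], tau2[j], lam[j], theta[j] = _moments_priors(gamma_hat, delta2_hat)
        g, d2 = eb_fixed_point(
            zj, gamma_hat, delta2_hat, gamma_bar[j], tau2[j], lam[j], theta[j]
        )
        gamma_star[j] = g
        delta_star[j] = np.sqrt(d2)
    edu = cn.df.groupby("center_id")["education"].median()
    return ComBatModel(
        method="combat",
        covariate_names=tuple(COVARIATE_NAMES),
        roi_names=tuple(cohort.roi_names),
        datasets=tuple(order),
        alpha=alpha, beta=beta, pooled_sd=pooled_sd,
        gamma_star=gamma_star, delta_star=delta_star,
        gamma_bar=gamma_bar, tau2=tau2, lam=lam, theta=theta,
        n_cn={d: int(nj[j]) for j, d in enumerate(order)},
        edu_median_by_dataset={d: float(edu.get(d, np.nan)) for d in order},
        edu_median_global=float(cn.df["education"].median()),
    )


def apply_combat(model: ComBatModel, cohort: CohortTable) -> CohortTable:
    """Harmonized thickness: standardize, remove gamma*, divide by delta*,
    restore the grand mean and covariate effects.  Output stays in mm."""
    if tuple(cohort.roi_names) != tuple(model.roi_names):
        raise ValueError("cohort ROI set does not match the model")
    X = cohort.covariates(education_fill=model.education_fill())
    Y = cohort.thickness()
    covar_part = model.alpha + X @ model.beta
    Z = (Y - covar_part) / model.pooled_sd
    out_vals = np.empty_like(Y)
    center_ids = cohort.df["center_id"].to_numpy()
    for ds in dict.fromkeys(center_ids):
        j = model.dataset_index(ds)
        m = center_ids == ds
        out_vals[m] = (
            model.pooled_sd * (Z[m] - model.gamma_star[j]) / model.delta_star[j]
            + covar_part[m]
        )
    out = cohort.df.copy()
    out[list(cohort.roi_names)] = out_vals
    return CohortTable(out, cohort.roi_names)
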