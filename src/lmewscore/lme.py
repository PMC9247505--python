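"""Mixed-effects w-score harmonizer (the package's core method).

For each ROI ``k`` the model is a linear mixed-effects regression

    y_ik = alpha_k + X_i beta_k + b_{j(i),k} + eps_ik,
    b_jk ~ N(0, d_k),   eps_ik ~ N(0, sigma2_k),

with the four biological covariates as fixed effects and the center as an
exchangeable random intercept.  Variance components are estimated by
restricted maximum likelihood (ReML); the fixed effects follow by generalized
least squares at the estimated variances; per-center intercepts are BLUPs.
The harmonized score is

    w_ik = (y_ik - yhat_ik) / s_k,

where ``yhat`` is the conditional mean (including the center's BLUP) for
centers seen at fit time and the marginal mean (population regression only)
for unseen centers, and ``s_k`` is the pooled SD of the conditional training
residuals.  Because the center enters only as a random effect, the model can
score scans from centers absent at training and can register a new center
from its CN scans alone without refitting anything else.

The random-intercept structure makes every per-center covariance matrix
compound-symmetric, so all matrix algebra reduces to closed-form scalar
expressions; the implementation works from per-center sufficient statistics
(X'X, X'y, y'y) and never builds an n-by-n covariance.  Fixed-effect columns
are internally rescaled so that the solver is unaffected by the heterogeneous
covariate units (ICV is of order 1e6 while sex is 0/1); returned values are
always in original units.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize

from .cohort import COVARIATE_NAMES, CohortTable, WScoreTable

__all__ = [
    "LMEModel",
    "reml_objective",
    "beta_gls",
    "fit_lme",
    "score_lme",
    "add_center",
    "ConvergenceError",
    "RankDeficientDesignError",
]

_LOG2PI = float(np.log(2.0 * np.pi))

#: Variance-ratio grid d/(d+sigma2) used for quasi-Newton multi-starts.
MULTISTART_RATIOS = (0.05, 0.25, 0.5, 0.75, 0.95)


class ConvergenceError(RuntimeError):
    """ReML optimization failed for some ROI; carries per-start diagnostics."""


class RankDeficientDesignError(ValueError):
    """The fixed-effect design is rank deficient."""


# -- design handling -----------------------------------------------------------


def _design(X: np.ndarray) -> np.ndarray:
    """Prepend an intercept column."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D (n, p)")
    return np.column_stack([np.ones(len(X)), X])


def _column_scales(Xd: np.ndarray) -> np.ndarray:
    s = np.sqrt(np.mean(Xd**2, axis=0))
    s[s <= 0] = 1.0
    return s


def _check_rank(Xs: np.ndarray, names: Sequence[str]) -> None:
    _, sv, vt = np.linalg.svd(Xs, full_matrices=False)
    if sv[-1] <= 1e-10 * sv[0]:
        v = np.abs(vt[-1])
        cols = [("intercept",) + tuple(names)][0]
        implicated = [cols[i] for i in np.flatnonzero(v > 0.3)]
        raise RankDeficientDesignError(
            f"fixed-effect design is rank deficient; collinear columns: {implicated}"
        )


@dataclass
class _RoiStats:
    """Per-center sufficient statistics for one ROI (struct of arrays, J centers)."""

    nj: np.ndarray        # (J,)
    xtx: np.ndarray       # (J, q, q) on the scaled design
    xty: np.ndarray       # (J, q)
    yty: np.ndarray       # (J,)
    u: np.ndarray         # (J, q) = X' 1 per center
    ty: np.ndarray        # (J,) = 1' y per center
    xtx_sum: np.ndarray   # (q, q)
    xty_sum: np.ndarray   # (q,)
    yty_sum: float

    @classmethod
    def build(cls, Xs: np.ndarray, y: np.ndarray, codes: np.ndarray) -> "_RoiStats":
        J = codes.max() + 1
        q = Xs.shape[1]
        xtx = np.empty((J, q, q))
        xty = np.empty((J, q))
        yty = np.empty(J)
        nj = np.empty(J)
        for j in range(J):
            m = codes == j
            Xj, yj = Xs[m], y[m]
            xtx[j] = Xj.T @ Xj
            xty[j] = Xj.T @ yj
            yty[j] = yj @ yj
            nj[j] = m.sum()
        return cls(nj, xtx, xty, yty, xtx[:, :, 0].copy(), xty[:, 0].copy(),
                   xtx.sum(axis=0), xty.sum(axis=0), float(yty.sum()))


def _gls_pieces(d: float, sigma2: float, st: _RoiStats):
    """Assemble A = X' Sigma^-1 X, b = X' Sigma^-1 y, q = y' Sigma^-1 y and
    log|Sigma| using the compound-symmetry closed form
    Sigma_j^-1 = (I - c_j 1 1')/sigma2 with c_j = d/(sigma2 + n_j d)."""
    if d > 0:
        c = d / (sigma2 + st.nj * d)
        A = st.xtx_sum - np.einsum("j,ji,jl->il", c, st.u, st.u)
        b = st.xty_sum - (c * st.ty) @ st.u
        q = st.yty_sum - float(c @ st.ty**2)
    else:
        A, b, q = st.xtx_sum.copy(), st.xty_sum.copy(), st.yty_sum
    n = float(st.nj.sum())
    logdet_sigma = (n - len(st.nj)) * np.log(sigma2) + float(
        np.log(sigma2 + st.nj * d).sum()
    )
    return A / sigma2, b / sigma2, q / sigma2, logdet_sigma


def _reml_from_stats(
    d: float, sigma2: float, st: _RoiStats, n: int,
    logdet_scale_adj: float = 0.0,
) -> tuple[float, np.ndarray]:
    A, b, q, logdet_sigma = _gls_pieces(d, sigma2, st)
    try:
        beta = np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        # design rank is verified up front; a singular A here means the
        # optimizer probed a degenerate (d, sigma2) corner — reject the point
        return -np.inf, np.zeros(A.shape[0])
    quad = q - beta @ b
    sign, logdet_a = np.linalg.slogdet(A)
    if sign <= 0:
        return -np.inf, beta
    p1 = A.shape[0]
    ll = -0.5 * (
        logdet_sigma + quad + logdet_a + logdet_scale_adj + (n - p1) * _LOG2PI
    )
    return ll, beta


# -- public per-ROI operations -------------------------------------------------


def reml_objective(
    d: float, sigma2: float, y: np.ndarray, X: np.ndarray, centers: Sequence,
) -> float:
    """Restricted log-likelihood of one ROI, profiled over the fixed effects.

    ``X`` is the (n, p) covariate matrix (an intercept is added internally),
    ``centers`` the per-row center labels.  The value is the standard ReML
    restricted log-likelihood

        -1/2 [ sum_j log|Sigma_j| + r' Sigma^-1 r + log|X' Sigma^-1 X|
               + (n - p - 1) log 2 pi ]

    with ``r`` the GLS residual at (d, sigma2) and Sigma_j = sigma2 I + d 11'.
    """
    if sigma2 <= 0:
        raise ValueError("sigma2 must be > 0")
    if d < 0:
        raise ValueError("d must be >= 0")
    y = np.asarray(y, dtype=float)
    Xd = _design(X)
    scales = _column_scales(Xd)
    Xs = Xd / scales
    _check_rank(Xs, COVARIATE_NAMES[: Xd.shape[1] - 1] if Xd.shape[1] - 1 == 4 else
                [f"x{i}" for i in range(Xd.shape[1] - 1)])
    codes = np.unique(np.asarray(centers), return_inverse=True)[1]
    stats = _RoiStats.build(Xs, y, codes)
    adj = 2.0 * float(np.sum(np.log(scales)))
    ll, _ = _reml_from_stats(d, sigma2, stats, len(y), logdet_scale_adj=adj)
    return ll


def beta_gls(
    d: float, sigma2: float, y: np.ndarray, X: np.ndarray, centers: Sequence,
) -> tuple[float, np.ndarray]:
    """Generalized least-squares fixed effects at given variance components.

    Returns ``(alpha, beta)`` with the intercept separated from the p
    covariate coefficients.  Uses the compound-symmetry closed-form inverse
    per center and a solve (never an explicit matrix inverse); covariate
    columns are rescaled internally so the solution is stable for
    ICV-magnitude covariates.
    """
    if sigma2 <= 0:
        raise ValueError("sigma2 must be > 0")
    y = np.asarray(y, dtype=float)
    Xd = _design(X)
    scales = _column_scales(Xd)
    Xs = Xd / scales
    names = COVARIATE_NAMES if Xd.shape[1] - 1 == len(COVARIATE_NAMES) else [
        f"x{i}" for i in range(Xd.shape[1] - 1)
    ]
    _check_rank(Xs, names)
    codes = np.unique(np.asarray(centers), return_inverse=True)[1]
    stats = _RoiStats.build(Xs, y, codes)
    A, b, _, _ = _gls_pieces(d, sigma2, stats)
    beta_scaled = np.linalg.solve(A, b)
    coef = beta_scaled / scales
    return float(coef[0]), coef[1:]


# -- fitting -------------------------------------------------------------------


def _fit_roi(
    stats: _RoiStats, n: int, p1: int, logdet_scale_adj: float,
) -> dict:
    """Maximize the ReML objective for one ROI.

    Quasi-Newton (L-BFGS-B) on (log d, log sigma2) from a variance-ratio grid
    of starts, plus the boundary candidate d = 0 whose ReML optimum is closed
    form.  Returns a dict with the winning components and the full iterate
    trace for diagnostics.
    """

    def neg(theta: np.ndarray) -> float:
        # box the search region to keep exp() finite; a large finite penalty
        # is kinder to the quasi-Newton line search than inf
        if not np.all(np.isfinite(theta)) or np.any(np.abs(theta) > 46):
            return 1e12
        d, s2 = np.exp(theta)
        ll, _ = _reml_from_stats(d, s2, stats, n, logdet_scale_adj)
        return -ll if np.isfinite(ll) else 1e12

    # total-variance anchor from the d = 0 boundary (OLS) candidate
    ll0, beta0 = _reml_from_stats(0.0, 1.0, stats, n, logdet_scale_adj)
    A, b, q, _ = _gls_pieces(0.0, 1.0, stats)
    rss = max(q - beta0 @ b, 1e-12)
    v0 = rss / max(n - p1, 1)
    sigma2_bound = v0
    ll_bound, _ = _reml_from_stats(0.0, sigma2_bound, stats, n, logdet_scale_adj)

    best = {"d": 0.0, "sigma2": sigma2_bound, "ll": ll_bound, "converged": True}
    trace: list[float] = [ll_bound]
    n_ok = 0
    for ratio in MULTISTART_RATIOS:
        x0 = np.log([max(ratio * v0, 1e-10), max((1 - ratio) * v0, 1e-10)])
        path: list[float] = []

        def cb(theta, _path=path):
            _path.append(-neg(theta))

        res = optimize.minimize(
            neg, x0, method="L-BFGS-B", callback=cb,
            options={"ftol": 1e-13, "gtol": 1e-9, "maxiter": 500},
        )
        trace.extend(path)
        ll = -res.fun
        trace.append(ll)
        if np.isfinite(ll) and ll > -1e11:
            n_ok += 1
            if ll > best["ll"]:
                d_hat, s2_hat = np.exp(res.x)
                best = {"d": float(d_hat), "sigma2": float(s2_hat),
                        "ll": float(ll), "converged": bool(res.success),
                        "x": res.x}
    if n_ok == 0 and not np.isfinite(ll_bound):
        raise ConvergenceError(
            f"ReML optimization failed from all {len(MULTISTART_RATIOS)} starts"
        )
    # An unconverged winner (e.g. line-search breakdown) gets one polish run;
    # it counts as converged when no further improvement is possible.
    if not best["converged"] and "x" in best:
        res = optimize.minimize(
            lambda t: neg(t), best["x"], method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 400},
        )
        ll = -res.fun
        trace.append(ll)
        if np.isfinite(ll) and ll >= best["ll"] - 1e-9:
            d_hat, s2_hat = np.exp(res.x)
            if ll > best["ll"]:
                best.update(d=float(d_hat), sigma2=float(s2_hat), ll=float(ll))
            best["converged"] = bool(res.success) or (ll - best["ll"] < 1e-7)
    best.pop("x", None)
    # Collapse numerically-zero d to the boundary.
    if best["d"] < 1e-10:
        best["d"] = 0.0
        best["sigma2"] = sigma2_bound if best["ll"] <= ll_bound else best["sigma2"]
        best["ll"] = max(best["ll"], ll_bound)
    best["trace"] = trace
    return best


@dataclass
class LMEModel:
    """Fitted per-ROI mixed-effects harmonizer.

    Arrays are indexed by ROI (length K) except ``b`` which is (J centers, K).
    ``s`` is the pooled conditional-residual SD used as the w-score scale.
    """

    method: str
    covariate_names: tuple[str, ...]
    roi_names: tuple[str, ...]
    centers: tuple[str, ...]
    alpha: np.ndarray          # (K,) mm
    beta: np.ndarray           # (p, K) mm per covariate unit
    d: np.ndarray              # (K,) mm^2
    sigma2: np.ndarray         # (K,) mm^2
    b: np.ndarray              # (J, K) mm, per-center BLUP intercepts
    s: np.ndarray              # (K,) mm
    n_per_center: dict[str, int]
    edu_median_by_center: dict[str, float]
    edu_median_global: float
    converged: np.ndarray      # (K,) bool
    reml_value: np.ndarray     # (K,)
    fit_trace: dict = field(default_factory=dict, repr=False, compare=False)

    def center_index(self, center_id: str) -> int:
        try:
            return self.centers.index(center_id)
        except ValueError:
            raise KeyError(f"center {center_id!r} is not registered") from None

    def education_fill(self) -> dict[str, float]:
        fills = dict(self.edu_median_by_center)
        fills["__global__"] = self.edu_median_global
        return fills

    def to_dict(self) -> dict:
        return {
            "covariate_names": list(self.covariate_names),
            "roi_names": list(self.roi_names),
            "centers": list(self.centers),
            "alpha": self.alpha,
            "beta": self.beta,
            "d": self.d,
            "sigma2": self.sigma2,
            "b": self.b,
            "s": self.s,
            "n_per_center": self.n_per_center,
            "edu_median_by_center": self.edu_median_by_center,
            "edu_median_global": self.edu_median_global,
            "converged": self.converged.astype(bool).tolist(),
            "reml_value": self.reml_value,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "LMEModel":
        return cls(
            method="lme",
            covariate_names=tuple(data["covariate_names"]),
            roi_names=tuple(data["roi_names"]),
            centers=tuple(data["centers"]),
            alpha=np.asarray(data["alpha"], dtype=float),
            beta=np.asarray(data["beta"], dtype=float),
            d=np.asarray(data["d"], dtype=float),
            sigma2=np.asarray(data["sigma2"], dtype=float),
            b=np.asarray(data["b"], dtype=float),
            s=np.asarray(data["s"], dtype=float),
            n_per_center={k: int(v) for k, v in data["n_per_center"].items()},
            edu_median_by_center={
                k: float(v) for k, v in data["edu_median_by_center"].items()
            },
            edu_median_global=float(data["edu_median_global"]),
            converged=np.asarray(data["converged"], dtype=bool),
            reml_value=np.asarray(data["reml_value"], dtype=float),
        )


def fit_lme(cohort: CohortTable, allow_single_center: bool = False) -> LMEModel:
    """Fit the mixed-effects harmonizer on the cohort's CN rows.

    Rows with missing education are dropped from fitting (their centers still
    register if they contribute complete rows).  Requires at least 2 centers
    and total CN n > p + 3.  With ``allow_single_center`` a one-center cohort
    is fitted at the d = 0 boundary (the random intercept is unidentifiable
    from a single center); this supports the scalability experiments, which
    include one-dataset training sets.
    """
    cn = cohort.cn_only().drop_missing_education()
    centers = cn.centers
    if len(centers) < 2 and not allow_single_center:
        raise ValueError("fit_lme requires CN data from at least 2 centers")
    if not centers:
        raise ValueError("no complete CN rows to fit")
    p = len(COVARIATE_NAMES)
    if len(cn) <= p + 3:
        raise ValueError(f"too few CN rows ({len(cn)}) for {p} covariates")
    X = cn.covariates()
    Y = cn.thickness()
    n, K = Y.shape
    Xd = _design(X)
    scales = _column_scales(Xd)
    Xs = Xd / scales
    _check_rank(Xs, COVARIATE_NAMES)
    codes = np.searchsorted(
        np.array(sorted(centers)), cn.df["center_id"].to_numpy()
    )
    order = sorted(centers)
    adj = 2.0 * float(np.sum(np.log(scales)))

    # Per-center design cross-products are shared by every ROI.
    J, q_dim = len(order), Xd.shape[1]
    xtx = np.empty((J, q_dim, q_dim))
    xty_all = np.empty((J, q_dim, K))
    yty_all = np.empty((J, K))
    nj = np.empty(J)
    for j in range(J):
        m = codes == j
        Xj = Xs[m]
        xtx[j] = Xj.T @ Xj
        xty_all[j] = Xj.T @ Y[m]
        yty_all[j] = np.einsum("ik,ik->k", Y[m], Y[m])
        nj[j] = m.sum()
    xtx_sum = xtx.sum(axis=0)
    u_all = xtx[:, :, 0].copy()
    alpha = np.empty(K)
    beta = np.empty((p, K))
    d_hat = np.empty(K)
    s2_hat = np.empty(K)
    b_hat = np.empty((J, K))
    s_pool = np.empty(K)
    conv = np.empty(K, dtype=bool)
    llv = np.empty(K)
    traces = {}
    for k in range(K):
        stats = _RoiStats(
            nj=nj, xtx=xtx, xty=xty_all[:, :, k], yty=yty_all[:, k],
            u=u_all, ty=xty_all[:, 0, k],
            xtx_sum=xtx_sum, xty_sum=xty_all[:, :, k].sum(axis=0),
            yty_sum=float(yty_all[:, k].sum()),
        )
        if J == 1:
            # one center: d is unidentifiable (absorbed by the intercept);
            # pin it to the boundary and use the closed-form ReML variance
            ll0, beta0 = _reml_from_stats(0.0, 1.0, stats, n, adj)
            _, b0, q0, _ = _gls_pieces(0.0, 1.0, stats)
            rss = max(q0 - beta0 @ b0, 1e-12)
            s2_bound = rss / max(n - q_dim, 1)
            llb, _ = _reml_from_stats(0.0, s2_bound, stats, n, adj)
            best = {"d": 0.0, "sigma2": s2_bound, "ll": llb,
                    "converged": True, "trace": [llb]}
        else:
            best = _fit_roi(stats, n, q_dim, adj)
        d_k, s2_k = best["d"], best["sigma2"]
        ll, beta_scaled = _reml_from_stats(d_k, s2_k, stats, n, adj)
        coef = beta_scaled / scales
        alpha[k], beta[:, k] = coef[0], coef[1:]
        d_hat[k], s2_hat[k] = d_k, s2_k
        conv[k], llv[k] = best["converged"], best["ll"]
        traces[cohort.roi_names[k]] = best["trace"]
        sum_resid = stats.ty - stats.u @ beta_scaled
        b_hat[:, k] = (
            d_k * sum_resid / (s2_k + nj * d_k) if d_k > 0 else 0.0
        )
        resid = Y[:, k] - Xd @ coef - b_hat[codes, k]
        s_pool[k] = float(np.std(resid, ddof=1))
    if not conv.all():
        bad = [cohort.roi_names[k] for k in np.flatnonzero(~conv)[:5]]
        warnings.warn(f"ReML optimizer reported non-convergence for ROIs {bad}")
    edu = cn.df.groupby("center_id")["education"].median()
    return LMEModel(
        method="lme",
        covariate_names=tuple(COVARIATE_NAMES),
        roi_names=tuple(cohort.roi_names),
        centers=tuple(order),
        alpha=alpha, beta=beta, d=d_hat, sigma2=s2_hat, b=b_hat, s=s_pool,
        n_per_center={c: int(nj[j]) for j, c in enumerate(order)},
        edu_median_by_center={c: float(edu.get(c, np.nan)) for c in order},
        edu_median_global=float(cn.df["education"].median()),
        converged=conv, reml_value=llv, fit_trace=traces,
    )


# -- scoring -------------------------------------------------------------------


def _blup_for_rows(model: LMEModel, X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """BLUP intercept per ROI from a block of same-center rows, with the
    model's parameters frozen: b = d * sum(resid) / (sigma2 + n d)."""
    n = len(Y)
    marg = model.alpha + X @ model.beta
    sum_resid = (Y - marg).sum(axis=0)
    with np.errstate(invalid="ignore"):
        b = model.d * sum_resid / (model.sigma2 + n * model.d)
    return np.where(model.d > 0, b, 0.0)


def score_lme(
    model: LMEModel,
    cohort: CohortTable,
    unseen_center_policy: str = "marginal",
) -> WScoreTable:
    """Harmonized w-scores for every scan in the cohort.

    Registered centers are scored against the conditional mean
    (alpha + X beta + b_center); unregistered centers per policy:
    ``marginal`` uses the population mean (b = 0), ``blup-from-data``
    estimates the center intercept from the scoring rows themselves, and
    ``strict`` raises.
    """
    if unseen_center_policy not in ("marginal", "strict", "blup-from-data"):
        raise ValueError(f"unknown unseen_center_policy: {unseen_center_policy!r}")
    if tuple(cohort.roi_names) != tuple(model.roi_names):
        raise ValueError("cohort ROI set does not match the model")
    X = cohort.covariates(education_fill=model.education_fill())
    Y = cohort.thickness()
    yhat = model.alpha + X @ model.beta
    center_ids = cohort.df["center_id"].to_numpy()
    registered = set(model.centers)
    for cid in dict.fromkeys(center_ids):
        m = center_ids == cid
        if cid in registered:
            yhat[m] += model.b[model.center_index(cid)]
        elif unseen_center_policy == "strict":
            raise KeyError(f"center {cid!r} was not seen at fit time")
        elif unseen_center_policy == "blup-from-data":
            yhat[m] += _blup_for_rows(model, X[m], Y[m])
        # marginal: b = 0, nothing to add
    W = (Y - yhat) / model.s
    out = cohort.df.copy()
    out[list(cohort.roi_names)] = W
    return WScoreTable(out, cohort.roi_names)


def add_center(model: LMEModel, new_cn: CohortTable) -> LMEModel:
    """Register one new center from its CN scans without refitting.

    Fixed effects and variance components stay frozen; the new center's
    intercepts are BLUPs under the existing model, so all previously
    registered centers score bit-identically afterwards.
    """
    cn = new_cn.cn_only()
    cids = cn.centers
    if len(cids) != 1:
        raise ValueError("add_center expects rows from exactly one center")
    cid = cids[0]
    if cid in model.centers:
        raise ValueError(f"center {cid!r} is already registered")
    complete = cn.drop_missing_education()
    if len(complete) < 2:
        warnings.warn(
            f"center {cid!r} has < 2 complete CN rows; registering with "
            "marginal (b = 0) scoring"
        )
        b_new = np.zeros(len(model.roi_names))
        n_new = len(complete)
    else:
        X = complete.covariates()
        Y = complete.thickness()
        b_new = _blup_for_rows(model, X, Y)
        n_new = len(complete)
    edu_med = float(complete.df["education"].median()) if len(complete) else \
        model.edu_median_global
    return LMEModel(
        method="lme",
        covariate_names=model.covariate_names,
        roi_names=model.roi_names,
        centers=model.centers + (cid,),
        alpha=model.alpha, beta=model.beta, d=model.d, sigma2=model.sigma2,
        b=np.vstack([model.b, b_new[None, :]]),
        s=model.s,
        n_per_center={**model.n_per_center, cid: n_new},
        edu_median_by_center={**model.edu_median_by_center, cid: edu_med},
        edu_median_global=model.edu_median_global,
        converged=model.converged, reml_value=model.reml_value,
        fit_trace=model.fit_trace,
    )
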