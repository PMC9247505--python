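"""Synthetic multicenter cohort generator with known ground truth.

The generative model per scan ``i`` from center ``j`` on ROI ``k`` is

    thickness_ik = base_k + X_i . beta[:, k] + a_{jk} + atrophy_{dx(i), k}
                   + u_i + scale_{jk} * eps_ik

with ``X_i`` the four biological covariates (age, sex, education, ICV in raw
units), ``a_jk`` an additive center effect (drawn N(0, d_k) or user-fixed),
``atrophy`` a non-positive disease shift on selected ROIs, ``u_i`` a global
per-subject offset shared by all ROIs (inter-individual "overall thickness"
variation; it is part of each per-ROI residual and cancels in paired designs),
and ``eps_ik ~ N(0, noise_sd_k^2)`` measurement noise whose scale the center
multiplies — the multiplicative protocol effect.

Randomness is laid out in per-center substreams keyed off one global seed, so
adding a center to a configuration never perturbs the draws of existing
centers (required by the scalability experiments).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import COVARIATE_NAMES, DK_ROI_NAMES, CohortTable

__all__ = [
    "GroupSpec",
    "CenterSpec",
    "GeneratorConfig",
    "SyntheticCohort",
    "generate_cohort",
    "generate_paired_cohort",
    "default_discovery_config",
    "confounded_disease_config",
    "realized_center_effects",
    "AD_ATROPHY_ROIS",
    "PD_ATROPHY_ROIS",
]

#: Upper bound on the per-patient atrophy-severity multiplier.
SEVERITY_CAP = 2.5

#: ROIs carrying the Alzheimer atrophy preset (entorhinal/fusiform/temporal/
#: inferior-parietal pattern, both hemispheres).
AD_ATROPHY_ROIS = tuple(
    f"{h}_{r}" for h in ("lh", "rh")
    for r in ("entorhinal", "fusiform", "inferiortemporal", "middletemporal",
              "inferiorparietal")
)

#: ROIs carrying the Parkinson atrophy preset (fusiform/precuneus/
#: supramarginal/temporal pattern).
PD_ATROPHY_ROIS = tuple(
    f"{h}_{r}" for h in ("lh", "rh")
    for r in ("fusiform", "precuneus", "supramarginal", "superiortemporal")
)


@dataclass(frozen=True)
class GroupSpec:
    """Covariate distribution of one diagnostic group within one center."""

    age_mean: float
    age_sd: float
    male_frac: float
    edu_mean: float
    edu_sd: float
    icv_mean: float  # mm^3
    icv_sd: float    # mm^3


@dataclass(frozen=True)
class CenterSpec:
    center_id: str
    n_cn: int
    cn: GroupSpec
    n_patient: int = 0
    patient_dx: str = "AD"
    patient: GroupSpec | None = None
    education_recorded: bool = True


@dataclass
class GeneratorConfig:
    """Full specification of a synthetic multicenter cohort.

    ``center_additive``/``center_scale`` may be given explicitly (shape (J, K))
    to fix the center effects; otherwise additive effects are drawn
    N(0, d_true[k]) and scales uniformly from ``scale_range``, deterministically
    per center from ``seed``.
    """

    centers: list[CenterSpec]
    roi_names: tuple[str, ...] = DK_ROI_NAMES
    base_thickness: np.ndarray | None = None          # (K,) mm
    beta_true: np.ndarray | None = None               # (4, K) mm per unit
    d_true: np.ndarray | float = 0.01                 # mm^2, additive-effect variance
    scale_range: tuple[float, float] = (0.9, 1.1)
    center_additive: np.ndarray | None = None         # (J, K) mm, fixed override
    center_scale: np.ndarray | None = None            # (J, K), fixed override
    disease_atrophy: dict[str, np.ndarray] = field(default_factory=dict)  # dx -> (K,) mm, <= 0
    noise_sd: np.ndarray | float = 0.1                # mm
    subject_sd: float = 0.1                           # mm, global per-subject offset
    severity_sd: float = 0.6                          # SD of per-patient atrophy multiplier
    seed: int = 0

    def __post_init__(self) -> None:
        self.roi_names = tuple(self.roi_names)
        K = len(self.roi_names)
        if self.base_thickness is None:
            self.base_thickness = np.full(K, 2.5)
        self.base_thickness = np.asarray(self.base_thickness, dtype=float)
        if self.beta_true is None:
            self.beta_true = np.zeros((4, K))
        self.beta_true = np.asarray(self.beta_true, dtype=float)
        if self.beta_true.shape != (4, K):
            raise ValueError(f"beta_true must have shape (4, {K})")
        self.d_true = np.broadcast_to(np.asarray(self.d_true, dtype=float), (K,)).copy()
        self.noise_sd = np.broadcast_to(np.asarray(self.noise_sd, dtype=float), (K,)).copy()
        self.disease_atrophy = {
            dx: np.asarray(a, dtype=float) for dx, a in self.disease_atrophy.items()
        }
        for dx, a in self.disease_atrophy.items():
            if a.shape != (K,):
                raise ValueError(f"disease_atrophy[{dx!r}] must have shape ({K},)")
            if (a > 0).any():
                raise ValueError(f"disease_atrophy[{dx!r}] must be <= 0 (atrophy)")
        ids = [c.center_id for c in self.centers]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate center ids")
        self._validate_positivity()

    @property
    def n_rois(self) -> int:
        return len(self.roi_names)

    def center_index(self, center_id: str) -> int:
        for j, c in enumerate(self.centers):
            if c.center_id == center_id:
                return j
        raise KeyError(f"center {center_id!r} not in config")

    def _validate_positivity(self) -> None:
        # Conservative 3-sigma worst case (severity capped at 2.5): thickness
        # must stay > 0 for any plausible draw, checked before sampling.
        worst_cov = np.zeros(self.n_rois)
        for c in self.centers:
            for g in (c.cn, c.patient):
                if g is None:
                    continue
                lo_hi = {
                    "age": (max(g.age_mean - 3 * g.age_sd, 40.0), min(g.age_mean + 3 * g.age_sd, 100.0)),
                    "sex": (0.0, 1.0),
                    "education": (max(g.edu_mean - 3 * g.edu_sd, 0.0), min(g.edu_mean + 3 * g.edu_sd, 25.0)),
                    "icv": (max(g.icv_mean - 3 * g.icv_sd, 0.3 * g.icv_mean), g.icv_mean + 3 * g.icv_sd),
                }
                tot = np.zeros(self.n_rois)
                for p, name in enumerate(COVARIATE_NAMES):
                    lo, hi = lo_hi[name]
                    tot += np.minimum(self.beta_true[p] * lo, self.beta_true[p] * hi)
                worst_cov = np.minimum(worst_cov, tot)
        sev_max = SEVERITY_CAP if self.severity_sd > 0 else 1.0
        atro = np.zeros(self.n_rois)
        for a in self.disease_atrophy.values():
            atro = np.minimum(atro, sev_max * a)
        add = (
            -np.abs(self.center_additive).max(axis=0)
            if self.center_additive is not None
            else -3 * np.sqrt(self.d_true)
        )
        hi_scale = max(abs(s) for s in self.scale_range) if self.center_scale is None \
            else np.abs(self.center_scale).max()
        worst = (
            self.base_thickness + worst_cov + atro + add
            - 3 * (hi_scale * self.noise_sd + self.subject_sd)
        )
        if (worst <= 0).any():
            bad = [self.roi_names[k] for k in np.flatnonzero(worst <= 0)[:5]]
            raise ValueError(
                f"configuration admits non-positive thickness (worst-case) on ROIs {bad}"
            )

    def with_scaled_sizes(self, scale: float, min_group: int = 3) -> "GeneratorConfig":
        """Return a copy with all group sizes multiplied by ``scale``."""
        centers = [
            dataclasses.replace(
                c,
                n_cn=max(min_group, round(c.n_cn * scale)),
                n_patient=0 if c.n_patient == 0 else max(min_group, round(c.n_patient * scale)),
            )
            for c in self.centers
        ]
        return dataclasses.replace(self, centers=centers)


@dataclass
class SyntheticCohort:
    """A generated cohort plus the ground truth that produced it."""

    cohort: CohortTable
    truth: dict


def _rng(seed: int, center_idx: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(center_idx, stream))
    )


def realized_center_effects(config: GeneratorConfig) -> tuple[np.ndarray, np.ndarray]:
    """Per-center additive offsets (mm) and multiplicative noise scales.

    Deterministic given the config: fixed overrides are returned as-is, drawn
    effects depend only on (seed, center index).
    """
    J, K = len(config.centers), config.n_rois
    additive = np.empty((J, K))
    scale = np.empty((J, K))
    for j in range(J):
        rng = _rng(config.seed, j, 0)
        a = rng.normal(0.0, np.sqrt(config.d_true))
        s = rng.uniform(*config.scale_range, size=K)
        additive[j] = config.center_additive[j] if config.center_additive is not None else a
        scale[j] = config.center_scale[j] if config.center_scale is not None else s
    return additive, scale


def _draw_covariates(g: GroupSpec, n: int, rng: np.random.Generator) -> pd.DataFrame:
    age = np.clip(rng.normal(g.age_mean, g.age_sd, n), 40.0, 100.0)
    sex = (rng.random(n) < g.male_frac).astype(float)
    edu = np.clip(rng.normal(g.edu_mean, g.edu_sd, n), 0.0, 25.0)
    icv = np.clip(rng.normal(g.icv_mean, g.icv_sd, n), 0.3 * g.icv_mean, None)
    return pd.DataFrame({"age": age, "sex": sex, "education": edu, "icv": icv})


def _severity(config: GeneratorConfig, n: int, rng: np.random.Generator):
    """Per-patient atrophy multiplier: gamma with mean 1, SD ``severity_sd``.

    Disease stages vary across patients; a homogeneous shift would make the
    patient group unrealistically separable from CN.
    """
    if config.severity_sd <= 0:
        return 1.0
    shape = 1.0 / config.severity_sd**2
    sev = rng.gamma(shape, scale=config.severity_sd**2, size=(n, 1))
    return np.minimum(sev, SEVERITY_CAP)


def _assemble_rows(
    config: GeneratorConfig,
    j: int,
    group: GroupSpec,
    n: int,
    diagnosis: str,
    additive: np.ndarray,
    scale: np.ndarray,
    stream: int,
    subject_prefix: str,
) -> pd.DataFrame:
    rng = _rng(config.seed, j, stream)
    cov = _draw_covariates(group, n, rng)
    X = cov[list(COVARIATE_NAMES)].to_numpy()
    u = rng.normal(0.0, config.subject_sd, size=(n, 1))
    atrophy = np.asarray(config.disease_atrophy.get(diagnosis, 0.0))
    severity = _severity(config, n, rng) if np.any(atrophy != 0) else 1.0
    eps = rng.normal(0.0, 1.0, size=(n, config.n_rois)) * config.noise_sd
    thick = (
        config.base_thickness
        + X @ config.beta_true
        + additive[j]
        + severity * atrophy
        + u
        + scale[j] * eps
    )
    spec = config.centers[j]
    out = pd.DataFrame(thick, columns=list(config.roi_names))
    out.insert(0, "icv", cov["icv"])
    out.insert(0, "education", cov["education"] if spec.education_recorded else np.nan)
    out.insert(0, "sex", cov["sex"])
    out.insert(0, "age", cov["age"])
    out.insert(0, "diagnosis", diagnosis)
    out.insert(0, "center_id", spec.center_id)
    out.insert(0, "subject_id", [f"{subject_prefix}{i:05d}" for i in range(n)])
    return out


def generate_cohort(config: GeneratorConfig) -> SyntheticCohort:
    """Sample a full multicenter cohort from the configured model."""
    additive, scale = realized_center_effects(config)
    frames = []
    for j, spec in enumerate(config.centers):
        frames.append(
            _assemble_rows(
                config, j, spec.cn, spec.n_cn, "CN", additive, scale,
                stream=1, subject_prefix=f"{spec.center_id}_cn_",
            )
        )
        if spec.n_patient > 0:
            pgroup = spec.patient if spec.patient is not None else spec.cn
            frames.append(
                _assemble_rows(
                    config, j, pgroup, spec.n_patient, spec.patient_dx, additive,
                    scale, stream=2, subject_prefix=f"{spec.center_id}_pt_",
                )
            )
    df = pd.concat(frames, ignore_index=True)
    cohort = CohortTable(df, config.roi_names)
    truth = {
        "config": config,
        "center_additive": {
            c.center_id: additive[j] for j, c in enumerate(config.centers)
        },
        "center_scale": {c.center_id: scale[j] for j, c in enumerate(config.centers)},
    }
    return SyntheticCohort(cohort, truth)


def generate_paired_cohort(
    config: GeneratorConfig,
    n_subjects: int,
    center_a: str,
    center_b: str,
    diagnosis: str = "CN",
    stream: int = 7,
) -> SyntheticCohort:
    """Scan the same subjects at two centers (intrasubject design).

    Each subject appears twice with identical covariates and identical latent
    thickness (base + covariate effects + atrophy + subject offset); the two
    rows differ only through the centers' additive/multiplicative effects and
    independent measurement noise.
    """
    if n_subjects < 2:
        raise ValueError("paired statistics need at least 2 subjects")
    ja, jb = config.center_index(center_a), config.center_index(center_b)
    additive, scale = realized_center_effects(config)
    rng = _rng(config.seed, ja, stream)
    group = config.centers[ja].cn
    cov = _draw_covariates(group, n_subjects, rng)
    X = cov[list(COVARIATE_NAMES)].to_numpy()
    u = rng.normal(0.0, config.subject_sd, size=(n_subjects, 1))
    atrophy = np.asarray(config.disease_atrophy.get(diagnosis, 0.0))
    severity = _severity(config, n_subjects, rng) if np.any(atrophy != 0) else 1.0
    latent = (
        config.base_thickness
        + X @ config.beta_true
        + severity * atrophy
        + u
    )
    frames = []
    for j, cid in ((ja, center_a), (jb, center_b)):
        eps = rng.normal(0.0, 1.0, size=(n_subjects, config.n_rois)) * config.noise_sd
        thick = latent + additive[j] + scale[j] * eps
        out = pd.DataFrame(thick, columns=list(config.roi_names))
        out.insert(0, "icv", cov["icv"])
        out.insert(0, "education", cov["education"])
        out.insert(0, "sex", cov["sex"])
        out.insert(0, "age", cov["age"])
        out.insert(0, "diagnosis", diagnosis)
        out.insert(0, "center_id", cid)
        out.insert(0, "subject_id", [f"pair_{i:04d}" for i in range(n_subjects)])
        frames.append(out)
    df = pd.concat(frames, ignore_index=True)
    truth = {
        "config": config,
        "center_additive": {center_a: additive[ja], center_b: additive[jb]},
        "center_scale": {center_a: scale[ja], center_b: scale[jb]},
    }
    return SyntheticCohort(CohortTable(df, config.roi_names), truth)


# -- packaged 10-center preset -------------------------------------------------

# Per-center, per-group demographic parameters of the packaged discovery
# preset: (n, male_frac, age_mean, age_sd, edu_mean, edu_sd, icv_mean, icv_sd),
# ICV in units of 1e5 mm^3.  One center (D8) dominates in size and one (D10)
# contributes only Parkinson patients; education level varies systematically
# across centers, confounding center with demographics.
_DISCOVERY_DEMOGRAPHICS = {
    "D1": {"CN": (107, 0.51, 76.15, 4.56, 15.84, 3.01, 15.32, 1.54),
           "AD": (96, 0.51, 74.87, 7.84, 14.74, 3.21, 15.37, 1.85)},
    "D2": {"CN": (92, 0.39, 72.83, 5.67, 16.48, 2.67, 14.32, 1.18),
           "AD": (48, 0.60, 74.50, 8.15, 15.48, 2.91, 14.60, 1.65)},
    "D3": {"CN": (25, 0.72, 74.76, 3.57, 17.24, 2.20, 15.62, 1.18),
           "AD": (16, 0.44, 74.20, 9.20, 14.63, 3.30, 15.21, 1.69)},
    "D4": {"CN": (68, 0.43, 72.99, 6.04, 16.63, 2.44, 14.96, 2.18),
           "AD": (34, 0.47, 72.54, 7.12, 15.76, 2.88, 15.29, 2.34)},
    "D5": {"CN": (93, 0.45, 76.03, 5.79, 15.91, 2.76, 15.31, 1.73),
           "AD": (74, 0.49, 76.97, 7.20, 14.49, 3.39, 15.44, 1.78)},
    "D6": {"CN": (152, 0.50, 73.03, 6.40, 16.74, 2.50, 15.01, 1.56),
           "AD": (75, 0.60, 75.73, 8.09, 15.96, 2.58, 15.43, 1.65)},
    "D7": {"CN": (75, 0.28, 74.65, 7.92, 15.28, 2.73, 14.54, 1.59),
           "AD": (56, 0.52, 75.43, 6.55, 13.71, 2.83, 14.50, 1.70)},
    "D8": {"CN": (2907, 0.50, 64.12, 7.20, 12.76, 4.33, 12.48, 2.09),
           "AD": (351, 0.32, 71.21, 9.23, 9.17, 5.59, 13.87, 2.00)},
    "D9": {"CN": (51, 0.53, 64.24, 11.30, 11.80, 4.84, 13.99, 1.86),
           "AD": (64, 0.33, 66.33, 10.09, 8.96, 4.70, 13.82, 1.93)},
    "D10": {"CN": (71, 0.39, 65.89, 7.57, 12.79, 4.33, 12.24, 2.20),
            "PD": (120, 0.49, 64.70, 7.25, 10.70, 5.03, 13.08, 2.21)},
}


def _group(params) -> GroupSpec:
    n, male, am, asd, em, esd, im, isd = params
    return GroupSpec(am, asd, male, em, esd, im * 1e5, isd * 1e5)


def default_discovery_config(
    scale: float = 1.0,
    seed: int = 0,
    roi_names: Sequence[str] = DK_ROI_NAMES,
) -> GeneratorConfig:
    """The packaged 10-center discovery preset.

    Ten centers with heterogeneous demographics, one dominant in size, one
    carrying only Parkinson patients; additive center effects N(0, 0.01 mm^2),
    multiplicative noise scales U(0.9, 1.1), AD/PD atrophy presets on their
    canonical ROI sets.  ``scale`` multiplies every group size (ratios
    preserved; minimum 3 per non-empty group).
    """
    roi_names = tuple(roi_names)
    K = len(roi_names)
    centers = []
    for cid, groups in _DISCOVERY_DEMOGRAPHICS.items():
        dx = "PD" if "PD" in groups else "AD"
        centers.append(
            CenterSpec(
                center_id=cid,
                n_cn=groups["CN"][0],
                cn=_group(groups["CN"]),
                n_patient=groups[dx][0],
                patient_dx=dx,
                patient=_group(groups[dx]),
            )
        )
    # Deterministic per-ROI variation of baseline and covariate effects.  The
    # intercept is recentered so the observed thickness of a typical subject
    # (age 70, education 14 y, ICV 1.4e6 mm^3) lands in the 2-3 mm range.
    prng = np.random.default_rng(20220617)
    mod = prng.uniform(0.7, 1.3, size=(4, len(DK_ROI_NAMES)))
    beta_full = mod * np.array([[-0.008], [-0.03], [0.01], [2.0e-8]])
    x_ref = np.array([70.0, 0.5, 14.0, 1.4e6])
    base = prng.uniform(2.0, 3.0, size=len(DK_ROI_NAMES)) - x_ref @ beta_full
    idx = [DK_ROI_NAMES.index(r) if r in DK_ROI_NAMES else None for r in roi_names]
    if any(i is None for i in idx):
        base_k = np.full(K, 2.5)
        beta_k = np.broadcast_to(np.array([[-0.008], [-0.03], [0.01], [2.0e-8]]), (4, K)).copy()
    else:
        base_k = base[idx]
        beta_k = beta_full[:, idx]

    def _atrophy(roi_set: Sequence[str], depth: Mapping[str, float]) -> np.ndarray:
        a = np.zeros(K)
        for r in roi_set:
            if r in roi_names:
                a[roi_names.index(r)] = -depth.get(r.split("_", 1)[1], 0.10)
        return a

    atrophy = {
        "AD": _atrophy(AD_ATROPHY_ROIS, {"entorhinal": 0.15}),
        "PD": 0.8 * _atrophy(PD_ATROPHY_ROIS, {}),
    }
    cfg = GeneratorConfig(
        centers=centers,
        roi_names=roi_names,
        base_thickness=base_k,
        beta_true=beta_k,
        d_true=0.01,
        scale_range=(0.9, 1.1),
        disease_atrophy=atrophy,
        noise_sd=0.1,
        subject_sd=0.1,
        seed=seed,
    )
    if scale != 1.0:
        cfg = cfg.with_scaled_sizes(scale)
    return cfg


def confounded_disease_config(
    seed: int = 0,
    n_centers: int = 8,
    n_cn: int = 120,
    n_ad: int = 80,
) -> GeneratorConfig:
    """Multicenter CN/AD preset with education confounded with center.

    Each center contributes both groups in similar proportions, with CN and AD
    demographics matched within center, so center effects act as nuisance
    rather than as a shortcut class signal; mean education instead varies
    systematically across centers (10 to 17 years), reproducing the
    dataset-demographics confounding seen in multi-cohort studies.  Additive
    center effects have SD 0.15 mm.  This is the study condition for the
    disease-effect-preservation experiments: harmonization must keep the
    CN-vs-AD signal while removing the center and demographic nuisance that
    penalizes pooled raw-thickness classification.
    """
    K = len(DK_ROI_NAMES)
    edu_means = np.linspace(10.0, 17.0, n_centers)
    centers = [
        CenterSpec(
            f"C{j}", n_cn,
            GroupSpec(70.0, 7.0, 0.5, float(edu_means[j]), 2.5, 1.4e6, 1.6e5),
            n_patient=n_ad, patient_dx="AD", patient=None,
        )
        for j in range(n_centers)
    ]
    beta = np.vstack([
        np.full(K, -0.02),   # mm per year of age
        np.full(K, -0.06),   # mm, male vs female
        np.full(K, 0.01),    # mm per year of education
        np.full(K, 2.0e-8),  # mm per mm^3 ICV
    ])
    base = 2.8 - np.array([70.0, 0.5, 14.0, 1.4e6]) @ beta
    atrophy = np.zeros(K)
    for r in AD_ATROPHY_ROIS:
        atrophy[DK_ROI_NAMES.index(r)] = -0.17 if "entorhinal" in r else -0.12
    return GeneratorConfig(
        centers=centers,
        roi_names=DK_ROI_NAMES,
        base_thickness=base,
        beta_true=beta,
        d_true=0.15**2,
        scale_range=(0.9, 1.1),
        disease_atrophy={"AD": atrophy},
        noise_sd=0.08,
        subject_sd=0.1,
        seed=seed,
    )


def two_center_config(
    seed: int = 0,
    n_per_center: int = 300,
    offset: float = 0.15,
) -> GeneratorConfig:
    """Two CN-only centers with identical covariate distributions and fixed
    opposite additive offsets (+/- ``offset`` mm on every ROI, multiplicative
    scale 1).  The canonical center-effect-removal benchmark: raw thickness
    separates the centers almost perfectly, while a harmonizer that fully
    absorbs the offsets leaves in-sample center prediction near 50%."""
    K = len(DK_ROI_NAMES)
    g = GroupSpec(70.0, 6.0, 0.5, 14.0, 3.0, 1.4e6, 1.5e5)
    additive = np.vstack([np.full(K, offset), np.full(K, -offset)])
    return GeneratorConfig(
        centers=[CenterSpec("A", n_per_center, g), CenterSpec("B", n_per_center, g)],
        roi_names=DK_ROI_NAMES,
        center_additive=additive,
        center_scale=np.ones((2, K)),
        noise_sd=0.1,
        subject_sd=0.1,
        seed=seed,
    )
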