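"""Cohort data model and validated I/O.

A cohort is a flat table with one row per scan: subject/center identifiers, a
diagnosis label, four biological covariates (age in years, sex coded
0=female/1=male, years of education, intracranial volume in mm^3), and the mean
cortical thickness in mm for each region of interest (ROI).  The default ROI
set is the 68-region Desikan-Killiany parcellation (34 regions per hemisphere).

Covariates are kept in their raw units throughout: downstream solvers must be
robust to the resulting heterogeneous coefficient scales (ICV is of order
1.3e6 mm^3 while sex is 0/1).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DIAGNOSES",
    "DK_ROI_NAMES",
    "COVARIATE_NAMES",
    "ID_COLUMNS",
    "CohortTable",
    "WScoreTable",
    "CohortValidationError",
    "SchemaError",
    "read_cohort",
    "read_wscores",
    "write_cohort",
    "save_model",
    "load_model",
    "ARTIFACT_FORMAT_VERSION",
]

#: Recognised diagnosis labels.  CN (cognitively normal) subjects are the
#: normative reference for every harmonizer fit; AD/PD are patient groups.
DIAGNOSES = ("CN", "AD", "PD", "OTHER", "UNKNOWN")

_DK_REGIONS = (
    "bankssts", "caudalanteriorcingulate", "caudalmiddlefrontal", "cuneus",
    "entorhinal", "frontalpole", "fusiform", "inferiorparietal",
    "inferiortemporal", "insula", "isthmuscingulate", "lateraloccipital",
    "lateralorbitofrontal", "lingual", "medialorbitofrontal", "middletemporal",
    "paracentral", "parahippocampal", "parsopercularis", "parsorbitalis",
    "parstriangularis", "pericalcarine", "postcentral", "posteriorcingulate",
    "precentral", "precuneus", "rostralanteriorcingulate",
    "rostralmiddlefrontal", "superiorfrontal", "superiorparietal",
    "superiortemporal", "supramarginal", "temporalpole", "transversetemporal",
)

#: Desikan-Killiany cortical ROI names, left hemisphere then right (K = 68).
DK_ROI_NAMES: tuple[str, ...] = tuple(
    f"{hemi}_{r}" for hemi in ("lh", "rh") for r in _DK_REGIONS
)

#: Biological covariates, in model column order (p = 4).
COVARIATE_NAMES = ("age", "sex", "education", "icv")

#: Identifying / phenotype columns preceding the ROI block.
ID_COLUMNS = ("subject_id", "center_id", "diagnosis") + COVARIATE_NAMES


class CohortValidationError(ValueError):
    """A row or value violates the cohort invariants."""


class SchemaError(CohortValidationError):
    """A mandatory column is missing or mis-typed."""


def _check_positive(df: pd.DataFrame, col: str) -> None:
    vals = df[col].to_numpy(dtype=float)
    bad = ~np.isfinite(vals) | (vals <= 0)
    if bad.any():
        rows = np.flatnonzero(bad)[:10].tolist()
        raise CohortValidationError(
            f"column '{col}' must be finite and > 0; offending row indices {rows}"
        )


@dataclass
class CohortTable:
    """Validated per-scan table of covariates, center ids and ROI thickness.

    ``df`` holds one row per scan with columns ``ID_COLUMNS + roi_names``.
    The same ``subject_id`` may legitimately appear under two centers (the
    paired intrasubject design); (subject_id, center_id) identifies a scan.
    """

    df: pd.DataFrame
    roi_names: tuple[str, ...] = field(default=DK_ROI_NAMES)

    def __post_init__(self) -> None:
        self.roi_names = tuple(self.roi_names)
        if len(self.roi_names) < 1:
            raise CohortValidationError("at least one ROI is required")
        missing = [c for c in ID_COLUMNS if c not in self.df.columns]
        missing += [c for c in self.roi_names if c not in self.df.columns]
        if missing:
            raise SchemaError(f"missing mandatory column(s): {missing}")
        self.df = self.df.loc[:, list(ID_COLUMNS) + list(self.roi_names)].reset_index(
            drop=True
        )
        self._validate()

    def _validate(self) -> None:
        df = self.df
        bad_dx = set(df["diagnosis"].astype(str)) - set(DIAGNOSES)
        if bad_dx:
            raise CohortValidationError(f"unknown diagnosis labels: {sorted(bad_dx)}")
        if len(df):
            _check_positive(df, "age")
            _check_positive(df, "icv")
            sex = df["sex"].to_numpy(dtype=float)
            if not np.isin(sex, (0.0, 1.0)).all():
                raise CohortValidationError("sex must be coded 0 (female) / 1 (male)")
            thick = df[list(self.roi_names)].to_numpy(dtype=float)
            if not (np.isfinite(thick).all() and (thick > 0).all()):
                rows = np.flatnonzero(~(np.isfinite(thick) & (thick > 0)).all(axis=1))
                raise CohortValidationError(
                    f"thickness must be finite and > 0 mm; offending rows {rows[:10].tolist()}"
                )

    # -- convenience accessors -------------------------------------------------

    def __len__(self) -> int:
        return len(self.df)

    @property
    def n_rois(self) -> int:
        return len(self.roi_names)

    @property
    def centers(self) -> list[str]:
        """Center ids in first-appearance order."""
        return list(dict.fromkeys(self.df["center_id"].astype(str)))

    def thickness(self) -> np.ndarray:
        """(n, K) thickness matrix in mm, ROI order = ``roi_names``."""
        return self.df[list(self.roi_names)].to_numpy(dtype=float)

    def covariates(self, education_fill: Mapping[str, float] | float | None = None) -> np.ndarray:
        """(n, 4) covariate matrix [age, sex, education, icv] in raw units.

        ``education_fill`` imputes missing education: a scalar, or a mapping
        from center_id to fill value (missing centers fall back to the mapping
        key ``"__global__"``).  With ``None``, missing education raises.
        """
        X = self.df[list(COVARIATE_NAMES)].astype(float).copy()
        miss = X["education"].isna()
        if miss.any():
            if education_fill is None:
                rows = np.flatnonzero(miss)[:10].tolist()
                raise CohortValidationError(
                    f"missing education in rows {rows}; supply an imputation policy"
                )
            if isinstance(education_fill, Mapping):
                fills = self.df.loc[miss, "center_id"].map(
                    lambda c: education_fill.get(c, education_fill.get("__global__", np.nan))
                )
                X.loc[miss, "education"] = fills.to_numpy(dtype=float)
            else:
                X.loc[miss, "education"] = float(education_fill)
            if X["education"].isna().any():
                raise CohortValidationError("education imputation left missing values")
        return X.to_numpy(dtype=float)

    def subset(self, mask: np.ndarray | pd.Series) -> "CohortTable":
        return CohortTable(self.df.loc[np.asarray(mask)].reset_index(drop=True), self.roi_names)

    def cn_only(self) -> "CohortTable":
        return self.subset((self.df["diagnosis"] == "CN").to_numpy())

    def drop_missing_education(self) -> "CohortTable":
        return self.subset(self.df["education"].notna().to_numpy())


@dataclass
class WScoreTable:
    """Harmonized standardized scores, same row/ROI layout as the source cohort."""

    df: pd.DataFrame
    roi_names: tuple[str, ...] = field(default=DK_ROI_NAMES)

    def __post_init__(self) -> None:
        self.roi_names = tuple(self.roi_names)
        missing = [c for c in ID_COLUMNS if c not in self.df.columns]
        missing += [c for c in self.roi_names if c not in self.df.columns]
        if missing:
            raise SchemaError(f"missing mandatory column(s): {missing}")
        self.df = self.df.loc[:, list(ID_COLUMNS) + list(self.roi_names)].reset_index(
            drop=True
        )
        w = self.df[list(self.roi_names)].to_numpy(dtype=float)
        if len(self.df) and not np.isfinite(w).all():
            raise CohortValidationError("w-scores must be finite")

    def __len__(self) -> int:
        return len(self.df)

    def scores(self) -> np.ndarray:
        """(n, K) w-score matrix (dimensionless)."""
        return self.df[list(self.roi_names)].to_numpy(dtype=float)


# -- delimited-text I/O --------------------------------------------------------


def read_cohort(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    roi_names: Sequence[str] | None = None,
    sep: str = ",",
    education_policy: str = "keep",
) -> CohortTable:
    """Read a delimited cohort table and validate it.

    Parameters
    ----------
    schema
        Optional mapping from canonical column name (``subject_id`` ...) to the
        column name used in the file.
    roi_names
        ROI columns to load; by default every non-identifier column is treated
        as an ROI, falling back to the Desikan-Killiany set when all 68 are
        present.
    sep
        Field delimiter; pass ``"\\t"`` for TSV.
    education_policy
        ``"keep"`` retains missing education as NaN (models decide later),
        ``"drop"`` drops those rows, ``"impute_median"`` fills with the cohort
        CN median.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=sep)
    if schema:
        df = df.rename(columns={v: k for k, v in schema.items()})
    for col in ID_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"missing mandatory column: '{col}'")
    if roi_names is None:
        candidates = [c for c in df.columns if c not in ID_COLUMNS]
        if set(DK_ROI_NAMES) <= set(candidates):
            roi_names = list(DK_ROI_NAMES)
        else:
            roi_names = candidates
    df = df.copy()
    for col in roi_names:
        if col not in df.columns:
            raise SchemaError(f"missing ROI column: '{col}'")
        if not pd.api.types.is_numeric_dtype(df[col]):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = np.flatnonzero(coerced.isna() & df[col].notna())
            if len(bad):
                raise CohortValidationError(
                    f"non-numeric thickness in column '{col}', "
                    f"row indices {bad[:10].tolist()}"
                )
            df[col] = coerced.astype(float)
    if education_policy == "drop":
        df = df.loc[df["education"].notna()]
    elif education_policy == "impute_median":
        med = df.loc[df["diagnosis"] == "CN", "education"].median()
        df = df.copy()
        df["education"] = df["education"].fillna(med)
    elif education_policy != "keep":
        raise ValueError(f"unknown education_policy: {education_policy!r}")
    return CohortTable(df.reset_index(drop=True), tuple(roi_names))


def read_wscores(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    roi_names: Sequence[str] | None = None,
    sep: str = ",",
) -> WScoreTable:
    """Read a harmonized score table (no positivity constraint on values)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=sep)
    if schema:
        df = df.rename(columns={v: k for k, v in schema.items()})
    for col in ID_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"missing mandatory column: '{col}'")
    if roi_names is None:
        roi_names = [c for c in df.columns if c not in ID_COLUMNS]
    return WScoreTable(df, tuple(roi_names))


def write_cohort(table: CohortTable | WScoreTable, path: str | Path, sep: str = ",") -> None:
    """Write a cohort or w-score table with deterministic column order.

    Floats are written with full round-trip precision so that
    ``read_cohort(write_cohort(t))`` reproduces ``t`` exactly.
    """
    cols = list(ID_COLUMNS) + list(table.roi_names)
    table.df.loc[:, cols].to_csv(path, sep=sep, index=False, float_format=None)


# -- model artifact serialization ---------------------------------------------

ARTIFACT_FORMAT_VERSION = 1


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    return obj


def save_model(model, path: str | Path) -> None:
    """Serialize a fitted harmonizer to JSON.

    The model must expose ``method`` (str) and ``to_dict()``; the wrapper adds
    a format-version header so that incompatible files fail loudly.
    """
    payload = {
        "format_version": ARTIFACT_FORMAT_VERSION,
        "method": model.method,
        "model": _jsonify(model.to_dict()),
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path: str | Path):
    """Load a harmonizer saved by :func:`save_model`.

    Dispatches on the ``method`` field; the returned model scores identically
    to the in-memory original.
    """
    try:
        payload = json.loads(Path(path).read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise ValueError(f"cannot read model artifact {path}: {exc}") from exc
    if not isinstance(payload, dict) or "format_version" not in payload:
        raise ValueError(f"{path} is not a model artifact")
    if payload["format_version"] != ARTIFACT_FORMAT_VERSION:
        raise ValueError(
            f"incompatible artifact format {payload['format_version']} "
            f"(expected {ARTIFACT_FORMAT_VERSION})"
        )
    method = payload.get("method")
    from . import combat, lme, selfw  # deferred: avoid import cycle

    registry = {
        "selfw": selfw.SelfWModel,
        "combat": combat.ComBatModel,
        "lme": lme.LMEModel,
    }
    if method not in registry:
        raise ValueError(f"unknown harmonizer method in artifact: {method!r}")
    return registry[method].from_dict(payload["model"])
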