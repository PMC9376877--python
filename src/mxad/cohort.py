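"""Subject-level data model and preprocessing.

Holds one modality of regional measurements (cortical thickness +
subcortical volume, or amyloid-PET SUVR) for a set of subjects, together
with the covariates used downstream: age, sex, total intracranial volume
(TIV), CSF A-beta-42 and the diagnostic group.

Preprocessing implemented here:

* CSF A-beta-42 assay ceiling (values above 1700 pg/ml are replaced by
  1700 pg/ml) and the amyloid-positivity cutoff (< 976.6 pg/ml).
* TIV adjustment of subcortical volumes,
  ``adjusted_i = observed_i - beta * (TIV_i - mean TIV)``,
  with ``beta`` the least-squares slope of volume on TIV.
* Residualization of regional values on age and sex prior to network
  construction.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .atlas import AtlasSpec, default_atlas

#: Assay ceiling: the immunoassay is not validated above this level.
CSF_ABETA_CEILING = 1700.0
#: Amyloid positivity: CSF A-beta-42 strictly below this value (pg/ml).
ABETA_CUTOFF = 976.6

GRAY_MATTER = "gray_matter"
AMYLOID = "amyloid"
MODALITIES = (GRAY_MATTER, AMYLOID)

#: Diagnostic groups along the amyloid-positive disease continuum.
GROUPS = ("CN_Aneg", "CN_Apos", "MCI_Apos", "AD_Apos")
APOS_GROUPS = ("CN_Apos", "MCI_Apos", "AD_Apos")


class CohortValidationError(ValueError):
    """Raised when subject-level input data violate the data contract."""


def clamp_csf(value):
    """Apply the CSF A-beta-42 assay ceiling of 1700 pg/ml.

    Values above the ceiling are replaced by the ceiling; values at or
    below it pass through.  Accepts scalars or arrays.
    """
    arr = np.asarray(value, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise CohortValidationError("CSF A-beta-42 contains missing/non-finite values")
    if np.any(arr <= 0):
        raise CohortValidationError("CSF A-beta-42 must be strictly positive")
    out = np.minimum(arr, CSF_ABETA_CEILING)
    return float(out) if np.isscalar(value) else out


def classify_abeta(value):
    """Amyloid status from (clamped) CSF A-beta-42: Apos iff value < 976.6.

    Returns ``"Apos"``/``"Aneg"`` for scalars, an object array for arrays.
    """
    arr = np.asarray(value, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise CohortValidationError("CSF A-beta-42 contains missing/non-finite values")
    out = np.where(arr < ABETA_CUTOFF, "Apos", "Aneg")
    return str(out[()]) if np.isscalar(value) else out


def adjust_tiv(volumes, tiv, beta_source=None):
    """TIV-adjust one region's volumes across subjects.

    ``adjusted_i = observed_i - beta * (TIV_i - mean TIV)`` where ``beta``
    is the least-squares slope of volume on TIV estimated over
    ``beta_source`` (boolean mask or index array; default: all subjects)
    and ``mean TIV`` is the average over *all* subjects passed in.
    """
    volumes = np.asarray(volumes, dtype=float)
    tiv = np.asarray(tiv, dtype=float)
    if volumes.shape != tiv.shape or volumes.ndim != 1:
        raise CohortValidationError("volumes and tiv must be 1-D and aligned")
    if np.any(tiv <= 0):
        raise CohortValidationError("TIV must be strictly positive")
    if beta_source is None:
        beta_source = np.ones(len(tiv), dtype=bool)
    v_src = volumes[beta_source]
    t_src = tiv[beta_source]
    if len(t_src) < 3:
        raise CohortValidationError("need >= 3 subjects to estimate the TIV slope")
    t_c = t_src - t_src.mean()
    denom = np.dot(t_c, t_c)
    if denom == 0:
        raise CohortValidationError("zero TIV variance in beta_source: degenerate regression")
    beta = np.dot(t_c, v_src - v_src.mean()) / denom
    return volumes - beta * (tiv - tiv.mean())


def residualize(values, age, sex):
    """OLS residuals of regional values on [intercept, age, sex].

    Residuals have zero mean and zero sample correlation with both
    covariates; they are the inputs to partial-correlation edges.
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    age = np.asarray(age, dtype=float)
    sex = np.asarray(sex, dtype=float)
    n = values.shape[0]
    if age.shape != (n,) or sex.shape != (n,):
        raise CohortValidationError("age/sex must align with the subject axis")
    if n < 4:
        raise CohortValidationError("need >= 4 subjects to residualize on age and sex")
    for name, cov in (("age", age), ("sex", sex)):
        if np.ptp(cov) == 0:
            raise CohortValidationError(
                f"covariate '{name}' is constant: design matrix is rank-deficient"
            )
    X = np.column_stack([np.ones(n), age, sex])
    rank = np.linalg.matrix_rank(X)
    if rank < 3:
        raise CohortValidationError(
            "design matrix [intercept, age, sex] is rank-deficient "
            "(age and sex are collinear)"
        )
    coef, *_ = np.linalg.lstsq(X, values, rcond=None)
    return values - X @ coef


@dataclass
class RegionalCohort:
    """Subject x region measurements for one modality plus covariates."""

    subject_ids: np.ndarray
    values: np.ndarray  # (n_subjects, n_regions)
    modality: str
    region_names: tuple[str, ...]
    age: np.ndarray
    sex: np.ndarray  # {0, 1}
    csf_abeta42: np.ndarray
    group: np.ndarray
    tiv: np.ndarray | None = None  # required for volume-bearing modalities

    def __post_init__(self) -> None:
        self.subject_ids = np.asarray(self.subject_ids)
        self.values = np.asarray(self.values, dtype=float)
        self.age = np.asarray(self.age, dtype=float)
        self.sex = np.asarray(self.sex, dtype=float)
        self.csf_abeta42 = np.asarray(self.csf_abeta42, dtype=float)
        self.group = np.asarray(self.group)
        if self.tiv is not None:
            self.tiv = np.asarray(self.tiv, dtype=float)
        n, r = self.values.shape
        if len(self.region_names) != r:
            raise CohortValidationError("region_names length must match values columns")
        for name, arr in (
            ("subject_ids", self.subject_ids),
            ("age", self.age),
            ("sex", self.sex),
            ("csf_abeta42", self.csf_abeta42),
            ("group", self.group),
        ):
            if arr.shape != (n,):
                raise CohortValidationError(f"{name} must have one entry per subject")
        if self.tiv is not None and self.tiv.shape != (n,):
            raise CohortValidationError("tiv must have one entry per subject")
        if self.modality not in MODALITIES:
            raise CohortValidationError(f"unknown modality {self.modality!r}")
        if not np.all(np.isfinite(self.values)):
            raise CohortValidationError("regional values contain missing data")
        if self.modality == AMYLOID and np.any(self.values <= 0):
            raise CohortValidationError("SUVR values must be strictly positive")
        if len(np.unique(self.subject_ids)) != n:
            dup = pd.Series(self.subject_ids).value_counts()
            dup = dup[dup > 1].index.tolist()
            raise CohortValidationError(f"duplicate subject id(s): {dup}")
        unknown = set(np.unique(self.group)) - set(GROUPS)
        if unknown:
            raise CohortValidationError(f"unknown group label(s): {sorted(unknown)}")
        if set(np.unique(self.sex)) - {0.0, 1.0}:
            raise CohortValidationError("sex must be coded {0, 1}")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]

    def subset(self, mask) -> "RegionalCohort":
        """Row-subset (e.g. one diagnostic group) preserving region order."""
        return replace(
            self,
            subject_ids=self.subject_ids[mask],
            values=self.values[mask],
            age=self.age[mask],
            sex=self.sex[mask],
            csf_abeta42=self.csf_abeta42[mask],
            group=self.group[mask],
            tiv=None if self.tiv is None else self.tiv[mask],
        )

    def by_group(self) -> dict[str, "RegionalCohort"]:
        return {
            g: self.subset(self.group == g)
            for g in GROUPS
            if np.any(self.group == g)
        }

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "subject_id": self.subject_ids,
                "age": self.age,
                "sex": self.sex.astype(int),
                "csf_abeta42": self.csf_abeta42,
                "group": self.group,
            }
        )
        if self.tiv is not None:
            df["tiv"] = self.tiv
        for j, name in enumerate(self.region_names):
            df[name] = self.values[:, j]
        return df


COVARIATE_COLUMNS = ("subject_id", "age", "sex", "csf_abeta42", "group")


def load_cohort(path, atlas: AtlasSpec | None = None, modality: str = GRAY_MATTER) -> RegionalCohort:
    """Read a delimited subject table and validate it against the atlas.

    The table needs one row per subject with columns ``subject_id``,
    ``age``, ``sex``, ``csf_abeta42``, ``group``, optionally ``tiv``, and
    one column per atlas region (any column order; regions are reordered
    to atlas order).  CSF values are clamped at the assay ceiling on load.
    """
    atlas = atlas or default_atlas()
    df = pd.read_csv(path, sep=None, engine="python")
    missing = [c for c in COVARIATE_COLUMNS if c not in df.columns]
    if missing:
        raise CohortValidationError(f"missing required column(s): {missing}")
    missing_regions = [r for r in atlas.region_names if r not in df.columns]
    if missing_regions:
        raise CohortValidationError(f"missing region column(s): {missing_regions}")
    if df[list(COVARIATE_COLUMNS) + list(atlas.region_names)].isna().any().any():
        raise CohortValidationError("table contains missing values; imputation is not supported")
    tiv = df["tiv"].to_numpy(float) if "tiv" in df.columns else None
    if modality == GRAY_MATTER and tiv is None:
        raise CohortValidationError("gray-matter tables must include a 'tiv' column")
    return RegionalCohort(
        subject_ids=df["subject_id"].to_numpy(str),
        values=df[list(atlas.region_names)].to_numpy(float),
        modality=modality,
        region_names=tuple(atlas.region_names),
        age=df["age"].to_numpy(float),
        sex=df["sex"].to_numpy(float),
        csf_abeta42=clamp_csf(df["csf_abeta42"].to_numpy(float)),
        group=df["group"].to_numpy(str),
        tiv=tiv,
    )


def adjust_cohort_tiv(cohort: RegionalCohort, atlas: AtlasSpec, beta_group: str | None = "CN_Aneg") -> RegionalCohort:
    """TIV-adjust the subcortical-volume regions of a gray-matter cohort.

    The slope is estimated per region over ``beta_group`` (default: the
    amyloid-negative controls; pass None to use all subjects); the TIV is
    centered on the mean over all analyzed subjects.
    """
    if cohort.tiv is None:
        raise CohortValidationError("cohort has no TIV; cannot adjust volumes")
    mask = atlas.volume_mask
    src = None if beta_group is None else (cohort.group == beta_group)
    if src is not None and src.sum() < 3:
        raise CohortValidationError(f"beta group {beta_group!r} has fewer than 3 subjects")
    values = cohort.values.copy()
    for j in np.flatnonzero(mask):
        values[:, j] = adjust_tiv(values[:, j], cohort.tiv, beta_source=src)
    return replace(cohort, values=values)
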