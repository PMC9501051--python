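"""Two-arm cohort data model and tab-separated I/O.

A :class:`Cohort` couples one clinical table with an RNA expression matrix
and (optionally) an RPPA matrix.  Expression values are on the z-score
scale throughout; the package never normalizes raw counts.  Whether such
z-scores were standardized within the cohort or against a larger reference
population is not recorded in the inputs; matrices are stored exactly as
given.

On disk everything is TSV with one header row.  Matrices may be stored
sample-major or feature-major; orientation is auto-detected by matching
identifiers against the clinical table.  ``NA``, ``NaN`` and the empty
string are accepted as missing values on read; ``NA`` is written.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

RNA = "RNA"
RPPA = "RPPA"

ARM_TR = "TR"
ARM_ET = "ET"

RESPONSE_CR = "CR"
RESPONSE_PD = "PD"
RESPONSE_UNKNOWN = "unknown"

REGIMEN_AI = "AI"
REGIMEN_SERM = "SERM"
REGIMEN_SERD = "SERD"

#: columns of the clinical table, in canonical order
CLINICAL_COLUMNS = [
    "sample_id",
    "cohort_arm",
    "response",
    "regimen",
    "age_years",
    "t_stage",
    "n_stage",
    "m_stage",
    "stage",
    "pfs_time",
    "pfs_event",
    "os_time",
    "os_event",
]

_CATEGORICAL_LEVELS = {
    "cohort_arm": {ARM_TR, ARM_ET},
    "response": {RESPONSE_CR, RESPONSE_PD, RESPONSE_UNKNOWN},
    "regimen": {REGIMEN_AI, REGIMEN_SERM, REGIMEN_SERD},
    "t_stage": {"T1_2", "T3_4"},
    "n_stage": {"N0", "N1_3"},
    "m_stage": {"M0", "M1"},
    "stage": {"I_II", "III_IV"},
}

MISSING_TOKENS = ("NA", "NaN", "")


class CohortValidationError(ValueError):
    """Raised when a cohort violates its structural invariants."""


@dataclass(frozen=True)
class ClinicalRecord:
    """One subject's clinical annotation.

    Times are durations in days (configurable unit, days by default, the
    TCGA convention); events are True when the endpoint (progression or
    death) was observed.  ``pfs_time <= os_time`` is *not* enforced:
    records are stored as given.
    """

    sample_id: str
    cohort_arm: str
    response: str
    regimen: str
    age_years: float
    t_stage: str
    n_stage: str
    m_stage: str
    stage: str
    pfs_time: float
    pfs_event: bool
    os_time: float
    os_event: bool


@dataclass(frozen=True)
class ExpressionMatrix:
    """Dense sample-by-feature expression grid on the z-score scale.

    ``values`` is float with NaN marking missing cells; rows follow
    ``sample_ids`` and columns follow ``feature_ids``.
    """

    platform: str
    sample_ids: tuple
    feature_ids: tuple
    values: np.ndarray = field(repr=False)

    def __post_init__(self):
        if self.platform not in (RNA, RPPA):
            raise CohortValidationError(f"unknown platform {self.platform!r}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise CohortValidationError(f"duplicate sample ids in {self.platform} matrix")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise CohortValidationError(f"duplicate feature ids in {self.platform} matrix")
        if self.values.shape != (len(self.sample_ids), len(self.feature_ids)):
            raise CohortValidationError(
                f"{self.platform} matrix shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.feature_ids)} features"
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.sample_ids), columns=list(self.feature_ids)
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, platform: str) -> "ExpressionMatrix":
        return cls(
            platform=platform,
            sample_ids=tuple(str(s) for s in frame.index),
            feature_ids=tuple(str(f) for f in frame.columns),
            values=frame.to_numpy(dtype=float),
        )

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        frame = self.to_frame().loc[list(sample_ids)]
        return ExpressionMatrix.from_frame(frame, self.platform)

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)


@dataclass(frozen=True)
class Cohort:
    """Clinical table plus linked expression matrices for one study arm.

    Invariants: every matrix sample resolves to a clinical row, the RPPA
    sample set is a subset of the RNA sample set, and the arm label is
    uniform across the clinical table.
    """

    clinical: pd.DataFrame = field(repr=False)
    rna: ExpressionMatrix
    rppa: ExpressionMatrix | None = None

    def __post_init__(self):
        validate_cohort(self)

    @property
    def arm(self) -> str:
        return str(self.clinical["cohort_arm"].iloc[0])

    @property
    def sample_ids(self) -> tuple:
        return tuple(self.clinical["sample_id"])

    def records(self):
        for row in self.clinical.itertuples(index=False):
            yield ClinicalRecord(**row._asdict())

    def response_of(self) -> pd.Series:
        return self.clinical.set_index("sample_id")["response"]

    def clinical_indexed(self) -> pd.DataFrame:
        return self.clinical.set_index("sample_id")

    def matrix(self, platform: str) -> ExpressionMatrix | None:
        return self.rna if platform == RNA else self.rppa


def validate_cohort(cohort: Cohort) -> None:
    clin = cohort.clinical
    missing_cols = [c for c in CLINICAL_COLUMNS if c not in clin.columns]
    if missing_cols:
        raise CohortValidationError(f"clinical table missing columns {missing_cols}")
    if clin["sample_id"].duplicated().any():
        raise CohortValidationError("duplicate sample ids in clinical table")
    if clin.empty:
        raise CohortValidationError("empty clinical table")
    for col, levels in _CATEGORICAL_LEVELS.items():
        bad = set(clin[col].astype(str)) - levels
        if bad:
            raise CohortValidationError(f"invalid {col} values {sorted(bad)}")
    arms = set(clin["cohort_arm"])
    if len(arms) != 1:
        raise CohortValidationError(f"mixed cohort arms {sorted(arms)}")
    arm = next(iter(arms))
    unknown = clin["response"] == RESPONSE_UNKNOWN
    if arm == ARM_ET and not unknown.all():
        raise CohortValidationError("ET-arm samples must have response=unknown")
    if arm == ARM_TR and unknown.any():
        raise CohortValidationError("TR-arm samples must have a CR/PD response")
    for col in ("pfs_time", "os_time"):
        if (clin[col].astype(float) < 0).any():
            raise CohortValidationError(f"negative {col}")
    clinical_ids = set(clin["sample_id"])
    for mat in (cohort.rna, cohort.rppa):
        if mat is None:
            continue
        extra = set(mat.sample_ids) - clinical_ids
        if extra:
            raise CohortValidationError(
                f"unknown sample(s) in {mat.platform} matrix: {sorted(extra)[:5]}"
            )
    if cohort.rppa is not None:
        if not set(cohort.rppa.sample_ids) <= set(cohort.rna.sample_ids):
            raise CohortValidationError("RPPA sample set is not a subset of RNA samples")


# ---------------------------------------------------------------------------
# TSV I/O


def _read_matrix(path: str, clinical_ids: set, platform: str) -> ExpressionMatrix:
    frame = pd.read_csv(
        path, sep="\t", index_col=0, na_values=list(MISSING_TOKENS), keep_default_na=False
    )
    frame.index = frame.index.astype(str)
    frame.columns = frame.columns.astype(str)
    rows_hit = len(set(frame.index) & clinical_ids)
    cols_hit = len(set(frame.columns) & clinical_ids)
    if rows_hit == 0 and cols_hit == 0:
        raise CohortValidationError(
            f"zero overlapping samples between clinical table and {path}"
        )
    if cols_hit > rows_hit:  # feature-major on disk
        frame = frame.T
    non_numeric = frame.apply(lambda col: pd.to_numeric(col, errors="coerce"))
    bad = non_numeric.isna() & frame.notna()
    if bad.any().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise CohortValidationError(
            f"non-numeric cell at sample {frame.index[r]!r}, feature {frame.columns[c]!r} in {path}"
        )
    return ExpressionMatrix.from_frame(non_numeric.astype(float), platform)


def read_cohort(clinical_path: str, rna_path: str, rppa_path: str | None = None) -> Cohort:
    """Read a cohort from its clinical and matrix TSV files.

    Matrix orientation (sample-major vs feature-major) is auto-detected by
    matching identifiers against the clinical table.  Samples present in a
    matrix but absent from the clinical table are an error; clinical
    samples absent from the RPPA matrix are allowed.
    """
    for path in (clinical_path, rna_path) + ((rppa_path,) if rppa_path else ()):
        if not os.path.exists(path):
            raise FileNotFoundError(path)
    clin = pd.read_csv(
        clinical_path, sep="\t", na_values=list(MISSING_TOKENS), keep_default_na=False,
        dtype={"sample_id": str},
    )
    for col in ("pfs_event", "os_event"):
        if col in clin.columns:
            clin[col] = clin[col].astype(int).astype(bool)
    clinical_ids = set(clin["sample_id"]) if "sample_id" in clin.columns else set()
    rna = _read_matrix(rna_path, clinical_ids, RNA)
    rppa = _read_matrix(rppa_path, clinical_ids, RPPA) if rppa_path else None
    return Cohort(clinical=clin.reset_index(drop=True), rna=rna, rppa=rppa)


def write_cohort(cohort: Cohort, directory: str, prefix: str = "cohort") -> dict:
    """Write a cohort as TSV files; returns ``{kind: path}``.

    Output is deterministic: clinical rows and matrix rows are ordered by
    sample id, matrix columns keep their feature order, and missing cells
    are written as ``NA``.
    """
    os.makedirs(directory, exist_ok=True)
    paths = {}
    clin = cohort.clinical.sort_values("sample_id").reset_index(drop=True)
    out = clin.copy()
    out["pfs_event"] = out["pfs_event"].astype(int)
    out["os_event"] = out["os_event"].astype(int)
    clinical_path = os.path.join(directory, f"{prefix}_clinical.tsv")
    out.to_csv(clinical_path, sep="\t", index=False, na_rep="NA")
    paths["clinical"] = clinical_path
    for mat in (cohort.rna, cohort.rppa):
        if mat is None:
            continue
        frame = mat.to_frame().sort_index()
        path = os.path.join(directory, f"{prefix}_{mat.platform.lower()}.tsv")
        frame.to_csv(path, sep="\t", index_label="sample_id", na_rep="NA")
        paths[mat.platform] = path
    return paths


def clinical_frame_from_records(records) -> pd.DataFrame:
    """Build a clinical DataFrame from an iterable of :class:`ClinicalRecord`."""
    rows = [vars(r) if not isinstance(r, dict) else r for r in records]
    return pd.DataFrame(rows, columns=CLINICAL_COLUMNS)
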