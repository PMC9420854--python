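"""Study-level data model, screening and endpoint classification.

This module holds the extraction-table schema of the evidence-synthesis
pipeline: one :class:`StudyRecord` per published study (metadata,
eligibility flags, Newcastle-Ottawa quality score) and one
:class:`EffectEstimate` per reported hazard or odds ratio.  Screening,
adjusted-estimate selection and the hierarchical endpoint classification
(SCD, CVD, study-specific MACE, inclusive MACE) operate on these records.

Screening works on extractor-assigned boolean flags, not on free text:
the literature search itself is upstream of this package.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .errors import SchemaError, UsageError


class Design(str, enum.Enum):
    PROSPECTIVE = "prospective"
    RETROSPECTIVE = "retrospective"


class Predictor(str, enum.Enum):
    TSH_CONTINUOUS = "TSH_CONTINUOUS"
    FT4_CONTINUOUS = "FT4_CONTINUOUS"
    SUBCLINICAL_HYPO = "SUBCLINICAL_HYPO"
    SUBCLINICAL_HYPER = "SUBCLINICAL_HYPER"


class EndpointClass(str, enum.Enum):
    SCD = "SCD"
    CVD = "CVD"
    STUDY_MACE = "STUDY_MACE"
    ALL_CAUSE_MORTALITY = "ALL_CAUSE_MORTALITY"
    ICD_THERAPY = "ICD_THERAPY"
    OTHER = "OTHER"


class AnalysisSet(str, enum.Enum):
    """The four pooled endpoint hierarchies.

    ``INCLUSIVE_MACE`` is the union of study-specific MACE and
    cardiovascular death; membership is always derived from the
    endpoint class of an estimate, never stored on input records.
    """

    SCD = "SCD"
    CVD = "CVD"
    STUDY_MACE = "STUDY_MACE"
    INCLUSIVE_MACE = "INCLUSIVE_MACE"


class Measure(str, enum.Enum):
    HR = "HR"
    OR = "OR"


class Scale(str, enum.Enum):
    PER_UNIT = "PER_UNIT"
    PER_LOG_UNIT = "PER_LOG_UNIT"
    PER_SD = "PER_SD"
    CATEGORICAL = "CATEGORICAL"


#: Boolean eligibility-flag columns, in schema order.
FLAG_COLUMNS = (
    "is_human",
    "is_longitudinal",
    "reports_quantitative_thyroid",
    "reports_hr_or_or",
    "is_case_report",
    "is_animal_or_cell",
    "is_therapeutic_trial",
    "is_nti_study",
    "is_amiodarone_study",
    "is_survey_or_review",
)

INCLUSION_FLAGS = FLAG_COLUMNS[:4]
EXCLUSION_FLAGS = FLAG_COLUMNS[4:]


@dataclass
class StudyRecord:
    """One published study: metadata, screening flags and quality score."""

    study_id: str
    first_author: str
    year: int
    design: Design
    n_subjects: int
    followup_years: float
    nos_score: int
    is_human: bool = True
    is_longitudinal: bool = True
    reports_quantitative_thyroid: bool = True
    reports_hr_or_or: bool = True
    is_case_report: bool = False
    is_animal_or_cell: bool = False
    is_therapeutic_trial: bool = False
    is_nti_study: bool = False
    is_amiodarone_study: bool = False
    is_survey_or_review: bool = False
    duplicate_of: Optional[str] = None

    def __post_init__(self) -> None:
        self.design = Design(self.design)
        if not (0 <= self.nos_score <= 9):
            raise SchemaError(
                f"study {self.study_id!r}: nos_score {self.nos_score} outside "
                "the Newcastle-Ottawa range [0, 9]"
            )
        if self.n_subjects < 1:
            raise SchemaError(f"study {self.study_id!r}: n_subjects must be >= 1")
        if not self.followup_years > 0:
            raise SchemaError(f"study {self.study_id!r}: followup_years must be > 0")
        if not (1900 <= self.year <= 2100):
            raise SchemaError(f"study {self.study_id!r}: implausible year {self.year}")
        if self.duplicate_of == self.study_id:
            raise SchemaError(
                f"study {self.study_id!r}: duplicate_of refers to itself"
            )


@dataclass
class EffectEstimate:
    """One reported HR/OR with confidence interval and scale annotation.

    ``scale`` records how the original study expressed the exposure
    contrast (per unit, per log unit, per SD, or categorical); the
    harmonization module uses it to choose the matching conversion
    equation.  ``conversion_factor`` is supplied by the extractor when
    the measurement unit differs from the target unit (pmol/L for FT4,
    linear mIU/L for TSH).
    """

    study_id: str
    predictor: Predictor
    endpoint_label: str
    endpoint_class: EndpointClass
    measure: Measure
    point: float
    ci_lower: float
    ci_upper: float
    ci_level: float = 0.95
    scale: Scale = Scale.PER_UNIT
    unit: str = ""
    sd_value: Optional[float] = None
    conversion_factor: Optional[float] = None
    adjusted: bool = False

    def __post_init__(self) -> None:
        self.predictor = Predictor(self.predictor)
        self.endpoint_class = EndpointClass(self.endpoint_class)
        self.measure = Measure(self.measure)
        self.scale = Scale(self.scale)
        if not (0 < self.ci_lower <= self.point <= self.ci_upper):
            raise SchemaError(
                f"study {self.study_id!r}: confidence interval "
                f"({self.ci_lower}, {self.ci_upper}) does not bracket the "
                f"point estimate {self.point} (all must be positive)"
            )
        if not (0 < self.ci_level < 1):
            raise SchemaError(f"study {self.study_id!r}: ci_level must be in (0, 1)")
        if self.scale is Scale.PER_SD and self.sd_value is None:
            raise SchemaError(
                f"study {self.study_id!r}: scale PER_SD requires sd_value"
            )
        if self.sd_value is not None and not self.sd_value > 0:
            raise SchemaError(f"study {self.study_id!r}: sd_value must be > 0")
        if self.conversion_factor is not None and not self.conversion_factor > 0:
            raise SchemaError(
                f"study {self.study_id!r}: conversion_factor must be > 0"
            )


# ---------------------------------------------------------------------------
# Screening


#: Exclusion reason codes, in fixed priority order.  A record failing
#: several criteria is reported under the first matching reason only, so
#: every exclusion is auditable against exactly one rule.
REASON_PRIORITY = (
    "duplicate",
    "non-human",
    "non-longitudinal",
    "case report",
    "animal/cell",
    "therapeutic trial",
    "NTI",
    "amiodarone",
    "survey/review",
    "missing quantitative/HR data",
)


def _exclusion_reason(record: StudyRecord) -> Optional[str]:
    if record.duplicate_of is not None:
        return "duplicate"
    if not record.is_human:
        return "non-human"
    if not record.is_longitudinal:
        return "non-longitudinal"
    if record.is_case_report:
        return "case report"
    if record.is_animal_or_cell:
        return "animal/cell"
    if record.is_therapeutic_trial:
        return "therapeutic trial"
    if record.is_nti_study:
        return "NTI"
    if record.is_amiodarone_study:
        return "amiodarone"
    if record.is_survey_or_review:
        return "survey/review"
    if not (record.reports_quantitative_thyroid and record.reports_hr_or_or):
        return "missing quantitative/HR data"
    return None


def screen_studies(
    records: Sequence[StudyRecord],
) -> tuple[list[StudyRecord], list[tuple[StudyRecord, str]]]:
    """Partition study records into included and excluded sets.

    A record is included iff all four inclusion flags are true (human,
    longitudinal, quantitative thyroid data, HR or OR reported), every
    exclusion flag is false and it is not marked as a duplicate.  Each
    excluded record carries exactly one reason code chosen by the fixed
    priority in :data:`REASON_PRIORITY`.

    Returns ``(included, excluded)`` where ``excluded`` is a list of
    ``(record, reason_code)`` pairs; the two lists partition the input.
    """
    seen: set[str] = set()
    for r in records:
        if r.study_id in seen:
            raise SchemaError(f"duplicate study_id {r.study_id!r} in input")
        seen.add(r.study_id)
    for r in records:
        if r.duplicate_of is not None and r.duplicate_of not in seen:
            raise SchemaError(
                f"study {r.study_id!r}: duplicate_of {r.duplicate_of!r} "
                "does not name a study in the input"
            )

    included: list[StudyRecord] = []
    excluded: list[tuple[StudyRecord, str]] = []
    for r in records:
        reason = _exclusion_reason(r)
        if reason is None:
            included.append(r)
        else:
            excluded.append((r, reason))
    return included, excluded


def select_estimate(candidates: Sequence[EffectEstimate]) -> EffectEstimate:
    """Pick the estimate to carry forward when a study reports several
    models for the same predictor and endpoint.

    The fully adjusted multivariable model is preferred over unadjusted
    ones.  If several adjusted candidates remain, extractor order is the
    tiebreak (the first one wins) and a warning is emitted so the choice
    can be audited.
    """
    if not candidates:
        raise UsageError("select_estimate called with no candidates")
    keys = {(c.study_id, c.predictor, c.endpoint_class) for c in candidates}
    if len(keys) > 1:
        raise UsageError(
            f"select_estimate candidates are not homogeneous: {sorted(map(str, keys))}"
        )
    adjusted = [c for c in candidates if c.adjusted]
    if not adjusted:
        if len(candidates) > 1:
            warnings.warn(
                f"study {candidates[0].study_id!r}: multiple unadjusted "
                "estimates; keeping the first in extractor order",
                stacklevel=2,
            )
        return candidates[0]
    if len(adjusted) > 1:
        warnings.warn(
            f"study {adjusted[0].study_id!r}: multiple adjusted estimates; "
            "keeping the first in extractor order",
            stacklevel=2,
        )
    return adjusted[0]


def classify_endpoint(
    estimate: EffectEstimate, scd_into_cvd: bool = False
) -> set[AnalysisSet]:
    """Map an estimate's endpoint class to the analysis sets it feeds.

    Cardiovascular death and study-specific MACE both feed inclusive
    MACE (their union set).  Sudden cardiac death is analysed separately
    by default; ``scd_into_cvd=True`` additionally routes SCD estimates
    into the CVD pool (and hence inclusive MACE) for sensitivity
    analysis.  All-cause mortality, ICD therapy and other endpoints are
    not pooled.
    """
    ec = estimate.endpoint_class
    if ec is EndpointClass.SCD:
        if scd_into_cvd:
            return {AnalysisSet.SCD, AnalysisSet.CVD, AnalysisSet.INCLUSIVE_MACE}
        return {AnalysisSet.SCD}
    if ec is EndpointClass.CVD:
        return {AnalysisSet.CVD, AnalysisSet.INCLUSIVE_MACE}
    if ec is EndpointClass.STUDY_MACE:
        return {AnalysisSet.STUDY_MACE, AnalysisSet.INCLUSIVE_MACE}
    return set()


def build_analysis_pools(
    estimates: Sequence[EffectEstimate], scd_into_cvd: bool = False
) -> dict[tuple[AnalysisSet, Predictor], list[EffectEstimate]]:
    """Group selected estimates into (analysis set, predictor) pools.

    Enforces one estimate per study per pool: when a study contributes
    both a CVD and a study-specific MACE estimate to inclusive MACE, the
    broader study-specific MACE composite is kept and the CVD estimate
    dropped from that pool only.
    """
    pools: dict[tuple[AnalysisSet, Predictor], list[EffectEstimate]] = {}
    for est in estimates:
        for aset in classify_endpoint(est, scd_into_cvd=scd_into_cvd):
            pools.setdefault((aset, est.predictor), []).append(est)

    for (aset, _pred), ests in pools.items():
        if aset is not AnalysisSet.INCLUSIVE_MACE:
            continue
        by_study: dict[str, list[EffectEstimate]] = {}
        for e in ests:
            by_study.setdefault(e.study_id, []).append(e)
        kept: list[EffectEstimate] = []
        for e in ests:
            group = by_study[e.study_id]
            if len(group) > 1:
                mace = [g for g in group if g.endpoint_class is EndpointClass.STUDY_MACE]
                if mace and e is not mace[0]:
                    continue
            kept.append(e)
        ests[:] = kept
    return pools


def mean_nos(included: Sequence[StudyRecord]) -> float:
    """Mean Newcastle-Ottawa score of the included studies, one decimal."""
    if not included:
        raise UsageError("mean_nos of an empty study set")
    return round(sum(r.nos_score for r in included) / len(included), 1)


# ---------------------------------------------------------------------------
# Delimited-text I/O

_STUDY_COLUMNS = [
    "study_id",
    "first_author",
    "year",
    "design",
    "n_subjects",
    "followup_years",
    "nos_score",
    *FLAG_COLUMNS,
    "duplicate_of",
]

_ESTIMATE_COLUMNS = [
    "study_id",
    "predictor",
    "endpoint_label",
    "endpoint_class",
    "measure",
    "point",
    "ci_lower",
    "ci_upper",
    "ci_level",
    "scale",
    "unit",
    "sd_value",
    "conversion_factor",
    "adjusted",
]


def _parse_bool(value, row: int, column: str) -> bool:
    if isinstance(value, bool):
        return value
    text = str(value).strip().lower()
    if text in {"true", "1"}:
        return True
    if text in {"false", "0"}:
        return False
    raise SchemaError(f"row {row}: column {column!r} is not a boolean: {value!r}")


def _opt(value):
    if value is None:
        return None
    if isinstance(value, float) and math.isnan(value):
        return None
    if isinstance(value, str) and not value.strip():
        return None
    return value


def read_studies(path: str | Path) -> list[StudyRecord]:
    """Read ``studies.csv`` into validated :class:`StudyRecord` objects."""
    df = pd.read_csv(
        path,
        dtype={"study_id": str, "duplicate_of": str},
        keep_default_na=False,
        float_precision="round_trip",
    )
    missing = [c for c in _STUDY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory columns {missing}")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        d = row._asdict()
        try:
            records.append(
                StudyRecord(
                    study_id=str(d["study_id"]),
                    first_author=str(d["first_author"]),
                    year=int(d["year"]),
                    design=Design(str(d["design"])),
                    n_subjects=int(d["n_subjects"]),
                    followup_years=float(d["followup_years"]),
                    nos_score=int(d["nos_score"]),
                    **{f: _parse_bool(d[f], i, f) for f in FLAG_COLUMNS},
                    duplicate_of=_opt(d["duplicate_of"]),
                )
            )
        except (ValueError, SchemaError) as exc:
            raise SchemaError(f"{path} row {i}: {exc}") from exc
    return records


def read_estimates(path: str | Path) -> list[EffectEstimate]:
    """Read ``estimates.csv`` into validated :class:`EffectEstimate` objects."""
    df = pd.read_csv(
        path,
        dtype={"study_id": str, "unit": str},
        keep_default_na=False,
        float_precision="round_trip",
    )
    missing = [c for c in _ESTIMATE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory columns {missing}")
    estimates = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        d = row._asdict()
        try:
            sd = _opt(d["sd_value"])
            cf = _opt(d["conversion_factor"])
            estimates.append(
                EffectEstimate(
                    study_id=str(d["study_id"]),
                    predictor=Predictor(str(d["predictor"])),
                    endpoint_label=str(d["endpoint_label"]),
                    endpoint_class=EndpointClass(str(d["endpoint_class"])),
                    measure=Measure(str(d["measure"])),
                    point=float(d["point"]),
                    ci_lower=float(d["ci_lower"]),
                    ci_upper=float(d["ci_upper"]),
                    ci_level=float(d["ci_level"]),
                    scale=Scale(str(d["scale"])),
                    unit="" if _opt(d["unit"]) is None else str(d["unit"]),
                    sd_value=None if sd is None else float(sd),
                    conversion_factor=None if cf is None else float(cf),
                    adjusted=_parse_bool(d["adjusted"], i, "adjusted"),
                )
            )
        except (ValueError, SchemaError) as exc:
            raise SchemaError(f"{path} row {i}: {exc}") from exc
    return estimates


def read_extraction_table(
    studies_path: str | Path, estimates_path: str | Path
) -> tuple[list[StudyRecord], list[EffectEstimate]]:
    """Read the two-file extraction table (studies.csv + estimates.csv)."""
    return read_studies(studies_path), read_estimates(estimates_path)


def studies_to_frame(records: Iterable[StudyRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        d = {f.name: getattr(r, f.name) for f in fields(r)}
        d["design"] = r.design.value
        rows.append(d)
    return pd.DataFrame(rows, columns=_STUDY_COLUMNS)


def estimates_to_frame(estimates: Iterable[EffectEstimate]) -> pd.DataFrame:
    rows = []
    for e in estimates:
        d = {f.name: getattr(e, f.name) for f in fields(e)}
        for enum_field in ("predictor", "endpoint_class", "measure", "scale"):
            d[enum_field] = d[enum_field].value
        rows.append(d)
    return pd.DataFrame(rows, columns=_ESTIMATE_COLUMNS)


def write_extraction_table(
    records: Sequence[StudyRecord],
    estimates: Sequence[EffectEstimate],
    studies_path: str | Path,
    estimates_path: str | Path,
) -> None:
    """Write the extraction table; inverse of :func:`read_extraction_table`.

    Reals are serialized at full precision (repr round-trip) and booleans
    as ``true``/``false`` so a write/read cycle is lossless.
    """
    sdf = studies_to_frame(records)
    edf = estimates_to_frame(estimates)
    for df in (sdf, edf):
        for col in df.columns:
            if df[col].dtype == bool:
                df[col] = df[col].map({True: "true", False: "false"})
    sdf.to_csv(studies_path, index=False, float_format=None)
    edf.to_csv(estimates_path, index=False)
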