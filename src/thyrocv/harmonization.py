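"""Hazard-ratio harmonization onto common measurement scales.

Published studies report hazard ratios per unit of FT4 in assorted units
(pmol/L, ng/dL), per log unit of TSH, or per standard deviation of either
hormone.  Before pooling, every estimate is rescaled to a common basis:
pmol/L for FT4 and linear mIU/L for TSH.  Three linear rescalings on the
HR scale are used:

* unit conversion:        ``HR_c = 1 + (HR - 1) * cf``
* log-scale presentation: ``HR_c = 1 + (HR - 1) / e``
* per-SD presentation:    ``HR_c = 1 + (HR - 1) / SD``

All three fix HR = 1 and preserve the direction of association; they are
first-order approximations that can produce a non-positive value for
strongly protective effects with large factors, in which case a
:class:`~thyrocv.errors.HarmonizationError` is raised rather than a
meaningless negative ratio being propagated.

The rescaling is applied to the point estimate and to both confidence
limits identically; the log-scale standard error is then extracted from
the rescaled interval.  An exact power rescaling ``HR ** cf`` (log-linear
in the exposure) is available as an opt-in alternative for sensitivity
analysis.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import HarmonizationError, SchemaError
from .records import EffectEstimate, Measure, Scale

#: Standard-normal 97.5% quantile, fixed to six decimals so that golden
#: values are bit-stable across SciPy versions.
Z_95 = 1.959964

_Z_CACHE = {0.95: Z_95}


def _z_quantile(level: float) -> float:
    if level in _Z_CACHE:
        return _Z_CACHE[level]
    from scipy.stats import norm

    return float(norm.ppf((1.0 + level) / 2.0))


class Transform(str, enum.Enum):
    NONE = "NONE"
    UNIT = "UNIT"
    LOG_SCALE = "LOG_SCALE"
    PER_SD = "PER_SD"


@dataclass
class HarmonizedEstimate:
    """A log hazard ratio with standard error on the common scale."""

    study_id: str
    predictor: object
    log_hr: float
    se_log_hr: float
    transform_applied: Transform = Transform.NONE
    source: Optional[EffectEstimate] = None

    def __post_init__(self) -> None:
        if not self.se_log_hr > 0:
            raise SchemaError(
                f"study {self.study_id!r}: se_log_hr must be > 0"
            )

    @property
    def hr(self) -> float:
        return math.exp(self.log_hr)


def _check_positive(value: float, what: str, study_id: str) -> float:
    if not value > 0:
        raise HarmonizationError(
            f"study {study_id!r}: rescaled {what} is {value:.6g} <= 0; the "
            "linear HR rescaling is inapplicable to this record"
        )
    return value


def convert_unit(hr: float, cf: float, study_id: str = "?") -> float:
    """Rescale an HR to a new measurement unit: ``1 + (HR - 1) * cf``."""
    if not (hr > 0 and cf > 0):
        raise HarmonizationError("convert_unit requires hr > 0 and cf > 0")
    return _check_positive(1.0 + (hr - 1.0) * cf, "HR", study_id)


def convert_log_scale(hr: float, study_id: str = "?") -> float:
    """Undo a logarithmic exposure presentation: ``1 + (HR - 1) / e``."""
    if not hr > 0:
        raise HarmonizationError("convert_log_scale requires hr > 0")
    return _check_positive(1.0 + (hr - 1.0) / math.e, "HR", study_id)


def convert_per_sd(hr: float, sd: float, study_id: str = "?") -> float:
    """Rescale a per-SD HR to per-unit: ``1 + (HR - 1) / SD``."""
    if not (hr > 0 and sd > 0):
        raise HarmonizationError("convert_per_sd requires hr > 0 and sd > 0")
    return _check_positive(1.0 + (hr - 1.0) / sd, "HR", study_id)


def se_from_ci(point: float, lo: float, hi: float, level: float = 0.95) -> float:
    """Log-scale standard error implied by a ratio confidence interval.

    ``(ln hi - ln lo) / (2 z)`` with ``z`` the standard-normal quantile
    at ``(1 + level) / 2``.
    """
    if not (0 < lo <= point <= hi):
        raise SchemaError(
            f"interval ({lo}, {hi}) does not bracket point {point}"
        )
    if not (0 < level < 1):
        raise SchemaError(f"ci_level {level} outside (0, 1)")
    if lo == hi:
        raise HarmonizationError(
            "degenerate confidence interval (lower == upper); cannot derive SE"
        )
    z = _z_quantile(level)
    return (math.log(hi) - math.log(lo)) / (2.0 * z)


def _rescale(value: float, est: EffectEstimate, mode: str, study_id: str) -> float:
    """Apply the transform matching ``est.scale`` to one HR-scale value."""
    if est.scale is Scale.CATEGORICAL:
        return value
    if mode == "exact":
        if est.scale is Scale.PER_UNIT:
            cf = est.conversion_factor
            return value if cf is None else value**cf
        if est.scale is Scale.PER_LOG_UNIT:
            return value ** (1.0 / math.e)
        if est.scale is Scale.PER_SD:
            return value ** (1.0 / est.sd_value)
    if est.scale is Scale.PER_UNIT:
        cf = est.conversion_factor
        return value if cf is None else convert_unit(value, cf, study_id)
    if est.scale is Scale.PER_LOG_UNIT:
        return convert_log_scale(value, study_id)
    if est.scale is Scale.PER_SD:
        return convert_per_sd(value, est.sd_value, study_id)
    raise SchemaError(f"study {study_id!r}: unknown scale {est.scale}")


_TRANSFORM_FOR_SCALE = {
    Scale.CATEGORICAL: Transform.NONE,
    Scale.PER_LOG_UNIT: Transform.LOG_SCALE,
    Scale.PER_SD: Transform.PER_SD,
}


def harmonize(estimate: EffectEstimate, rescale: str = "paper") -> HarmonizedEstimate:
    """Harmonize one reported estimate to the common log-HR scale.

    The matching transform is applied identically to the point estimate
    and both confidence limits on the ratio scale; the harmonized values
    are then log-transformed and the standard error extracted from the
    rescaled interval.  Categorical contrasts pass through untouched.

    ``rescale`` selects the rescaling family: ``"paper"`` (the linear
    form, default) or ``"exact"`` (power rescaling, for sensitivity
    analysis).

    Odds ratios are carried forward as rare-event hazard-ratio
    approximations; a warning records the caveat.
    """
    if rescale not in {"paper", "exact"}:
        raise SchemaError(f"unknown rescale mode {rescale!r}")
    sid = estimate.study_id
    if estimate.scale is Scale.PER_SD and estimate.sd_value is None:
        raise SchemaError(f"study {sid!r}: PER_SD estimate lacks sd_value")
    if estimate.measure is Measure.OR:
        warnings.warn(
            f"study {sid!r}: odds ratio pooled as a rare-event hazard-ratio "
            "approximation",
            stacklevel=2,
        )

    point = _rescale(estimate.point, estimate, rescale, sid)
    lo = _rescale(estimate.ci_lower, estimate, rescale, sid)
    hi = _rescale(estimate.ci_upper, estimate, rescale, sid)
    for v, what in ((point, "point"), (lo, "ci_lower"), (hi, "ci_upper")):
        _check_positive(v, what, sid)

    if estimate.scale is Scale.PER_UNIT:
        transform = (
            Transform.NONE if estimate.conversion_factor is None else Transform.UNIT
        )
    else:
        transform = _TRANSFORM_FOR_SCALE[estimate.scale]

    se = se_from_ci(point, lo, hi, estimate.ci_level)
    return HarmonizedEstimate(
        study_id=sid,
        predictor=estimate.predictor,
        log_hr=math.log(point),
        se_log_hr=se,
        transform_applied=transform,
        source=estimate,
    )


def harmonize_all(
    estimates: Sequence[EffectEstimate], rescale: str = "paper"
) -> list[HarmonizedEstimate]:
    return [harmonize(e, rescale=rescale) for e in estimates]


class HazardRatioHarmonizer(TransformerMixin, BaseEstimator):
    """Scikit-learn style transformer over an estimates DataFrame.

    Stateless: :meth:`fit` only validates parameters.  :meth:`transform`
    maps a DataFrame in the ``estimates.csv`` schema to a harmonized
    DataFrame with columns ``study_id, predictor, endpoint_class,
    log_hr, se_log_hr, transform_applied``.

    Parameters
    ----------
    rescale : {"paper", "exact"}
        Linear HR rescaling (default) or exact power rescaling.
    """

    def __init__(self, rescale: str = "paper"):
        self.rescale = rescale

    def fit(self, X: pd.DataFrame, y=None) -> "HazardRatioHarmonizer":
        if self.rescale not in {"paper", "exact"}:
            raise SchemaError(f"unknown rescale mode {self.rescale!r}")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        from .records import read_estimates  # noqa: F401  (schema shared)

        rows = []
        for _, row in X.iterrows():
            est = EffectEstimate(
                study_id=str(row["study_id"]),
                predictor=row["predictor"],
                endpoint_label=str(row.get("endpoint_label", "")),
                endpoint_class=row["endpoint_class"],
                measure=row.get("measure", "HR"),
                point=float(row["point"]),
                ci_lower=float(row["ci_lower"]),
                ci_upper=float(row["ci_upper"]),
                ci_level=float(row.get("ci_level", 0.95)),
                scale=row.get("scale", "PER_UNIT"),
                unit=str(row.get("unit", "") or ""),
                sd_value=None if pd.isna(row.get("sd_value")) else float(row["sd_value"]),
                conversion_factor=(
                    None
                    if pd.isna(row.get("conversion_factor"))
                    else float(row["conversion_factor"])
                ),
                adjusted=bool(row.get("adjusted", True)),
            )
            h = harmonize(est, rescale=self.rescale)
            rows.append(
                {
                    "study_id": h.study_id,
                    "predictor": est.predictor.value,
                    "endpoint_class": est.endpoint_class.value,
                    "log_hr": h.log_hr,
                    "se_log_hr": h.se_log_hr,
                    "transform_applied": h.transform_applied.value,
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "study_id",
                "predictor",
                "endpoint_class",
                "log_hr",
                "se_log_hr",
                "transform_applied",
            ],
        )
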