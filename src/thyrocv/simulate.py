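"""Synthetic data: study-level effects and dual-etiology cohorts.

Two generators make the whole pipeline runnable with no external data.

The first draws study-level log hazard ratios from the normal
random-effects model that the pooling engine assumes — within-study
standard errors uniform on a range, true effects
``y_i ~ N(mu, tau^2 + se_i^2)`` — and is used to test estimator
calibration (coverage, parameter recovery).

The second simulates subject-level cohorts under a dual-etiology model
of the thyroid-cardiovascular link.  A cohort mixes three latent
classes:

* **euthyroid** — FT4 around the population mean, TSH at the normal
  set point;
* **dyshomeostatic** — ensuing primary thyrotoxicosis: FT4 shifted up
  and TSH *suppressed* (negative log-TSH/FT4 coupling), representing
  the classical feedback response;
* **allostatic** — a raised central set point (type 2 allostatic load):
  TSH and FT4 both elevated (positive coupling).

Cardiovascular risk is driven by FT4 only; TSH is associated with
events solely through class mixing.  Because the high-risk (high-FT4)
subjects sit at *both* ends of the TSH distribution — suppressed TSH in
the dyshomeostatic class, raised TSH in the allostatic class — the
mixture yields a U-shaped TSH-risk association alongside a monotone
FT4-risk association.

The hazard link is either a loglinear function of the FT4 z-score or an
electrophysiological toy model through the excitation wavelength
``lambda = ERP * theta``: thyroid hormones shorten the effective
refractory period (ERP) and slow conduction velocity (theta), and when
the wavelength falls below the dimension of a latent re-entry circuit,
re-entrant tachyarrhythmia — and hence the event hazard — becomes
possible.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import DomainError, EstimationError, SchemaError
from .harmonization import Z_95, HarmonizedEstimate, Transform
from .records import EffectEstimate, EndpointClass, Measure, Predictor, Scale


# ---------------------------------------------------------------------------
# Study-level generator

@dataclass
class StudyLevelParams:
    """Parameters of the study-level random-effects generator."""

    k: int = 10
    mu: float = 0.3
    tau: float = 0.2
    se_range: tuple[float, float] = (0.1, 0.3)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 2:
            raise SchemaError("k must be >= 2")
        if self.tau < 0:
            raise SchemaError("tau must be >= 0")
        lo, hi = self.se_range
        if not (0 < lo <= hi):
            raise SchemaError("se_range must satisfy 0 < low <= high")


def simulate_study_level(params: StudyLevelParams) -> list[HarmonizedEstimate]:
    """Draw ``k`` study effects from the random-effects model.

    ``se_i ~ Uniform(se_range)``; ``y_i ~ Normal(mu, tau^2 + se_i^2)``.
    Deterministic given ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    se = rng.uniform(*params.se_range, size=params.k)
    y = rng.normal(params.mu, np.sqrt(params.tau**2 + se**2))
    return [
        HarmonizedEstimate(
            study_id=f"sim{i:03d}",
            predictor=Predictor.FT4_CONTINUOUS,
            log_hr=float(y[i]),
            se_log_hr=float(se[i]),
            transform_applied=Transform.NONE,
        )
        for i in range(params.k)
    ]


# ---------------------------------------------------------------------------
# Electrophysiology toy model

@dataclass
class ElectroParams:
    """Excitation-wavelength hazard link parameters.

    ``erp0`` (ms) and ``theta0`` (mm/ms) are baseline effective
    refractory period and conduction velocity; ``alpha_erp`` and
    ``alpha_theta`` are the per-SD-FT4 decrements in the same units.
    ``circuit_length`` (mm) is the dimension of a latent re-entry
    circuit and ``kappa`` the hazard gain per unit relative wavelength
    deficit.  Baseline magnitudes are plausible for ventricular tissue
    but deliberately schematic; only orderings are meaningful.
    """

    erp0: float = 250.0
    theta0: float = 0.5
    alpha_erp: float = 30.0
    alpha_theta: float = 0.05
    floor_frac: float = 0.3
    circuit_length: float = 100.0
    kappa: float = 2.0

    def __post_init__(self) -> None:
        if min(self.erp0, self.theta0, self.circuit_length) <= 0:
            raise SchemaError("erp0, theta0 and circuit_length must be > 0")
        if not (0 < self.floor_frac < 1):
            raise SchemaError("floor_frac must be in (0, 1)")
        if self.kappa < 0:
            raise SchemaError("kappa must be >= 0")


def excitation_wavelength(erp: float, theta: float) -> float:
    """Wavelength of excitation ``lambda = ERP * theta`` (mm)."""
    if erp < 0 or theta < 0:
        raise DomainError("ERP and theta must be non-negative")
    return erp * theta


def reentry_possible(lambda_mm: float, circuit_length_mm: float) -> bool:
    """Re-entry is possible iff the wavelength is strictly shorter than
    the re-entry circuit dimension."""
    if lambda_mm <= 0 or circuit_length_mm <= 0:
        raise DomainError("wavelength and circuit length must be > 0")
    return lambda_mm < circuit_length_mm


# ---------------------------------------------------------------------------
# Cohort simulator

class HazardLink(str, enum.Enum):
    DIRECT = "direct"
    WAVELENGTH = "wavelength"


@dataclass
class CohortParams:
    """Generative parameters of the dual-etiology cohort model.

    Defaults define the reference study conditions: a cohort of 50,000
    with 10% dyshomeostatic and 10% allostatic subjects, class FT4
    shifts of +1.5 SD, log-TSH/FT4 couplings of -1 (dyshomeostatic) and
    +1 (allostatic), a baseline event rate of 0.02 per person-year, a
    hazard ratio of 1.5 per SD of FT4 and five years of follow-up.
    """

    n: int = 50_000
    p_dys: float = 0.10
    p_allo: float = 0.10
    ft4_shift_dys: float = 1.5
    ft4_shift_allo: float = 1.5
    tsh_coupling_dys: float = -1.0
    tsh_coupling_allo: float = 1.0
    sigma_tsh: float = 0.45
    sigma_ft4: float = 1.0
    log_tsh_intercept: float = math.log(1.5)
    h0: float = 0.02
    beta_ft4: float = math.log(1.5)
    tsh_direct_beta: float = 0.0
    followup_years: float = 5.0
    link: HazardLink = HazardLink.DIRECT
    seed: int = 0

    def __post_init__(self) -> None:
        self.link = HazardLink(self.link)
        if self.n < 1:
            raise SchemaError("n must be >= 1")
        if min(self.p_dys, self.p_allo) < 0 or self.p_dys + self.p_allo > 1:
            raise SchemaError("class fractions must be >= 0 and sum to <= 1")
        if self.h0 <= 0:
            raise SchemaError("h0 must be > 0")
        if self.followup_years <= 0:
            raise SchemaError("followup_years must be > 0")
        if min(self.sigma_tsh, self.sigma_ft4) <= 0:
            raise SchemaError("all SDs must be > 0")
        if self.tsh_coupling_dys > 0:
            raise SchemaError("dyshomeostatic coupling must be <= 0")
        if self.tsh_coupling_allo < 0:
            raise SchemaError("allostatic coupling must be >= 0")


@dataclass
class Subject:
    """One simulated individual."""

    class_label: str
    tsh: float
    ft4_z: float
    event_time: float
    event: bool


def subject_hazard(
    ft4_z: float,
    cohort: CohortParams,
    electro: Optional[ElectroParams] = None,
) -> float:
    """Event hazard (events per person-year) for a given FT4 z-score.

    ``direct`` link: ``h0 * exp(beta_ft4 * ft4_z)``.  ``wavelength``
    link: FT4 shortens ERP and slows conduction (each clamped at
    ``floor_frac`` of baseline); the hazard rises linearly with the
    relative deficit of the excitation wavelength below the re-entry
    circuit dimension.  Both links are strictly positive and
    non-decreasing in ``ft4_z`` for non-negative slopes.
    """
    if cohort.link is HazardLink.DIRECT:
        return cohort.h0 * math.exp(cohort.beta_ft4 * ft4_z)
    ep = electro if electro is not None else ElectroParams()
    erp = max(ep.floor_frac * ep.erp0, ep.erp0 - ep.alpha_erp * ft4_z)
    theta = max(ep.floor_frac * ep.theta0, ep.theta0 - ep.alpha_theta * ft4_z)
    lam = excitation_wavelength(erp, theta)
    deficit = max(0.0, (ep.circuit_length - lam) / ep.circuit_length)
    return cohort.h0 * (1.0 + ep.kappa * deficit)


_CLASS_LABELS = ("euthyroid", "dyshomeostatic", "allostatic")


def simulate_cohort(
    cohort: CohortParams, electro: Optional[ElectroParams] = None
) -> list[Subject]:
    """Simulate one cohort under the dual-etiology model.

    Class membership is multinomial with probabilities
    ``(1 - p_dys - p_allo, p_dys, p_allo)``.  Within a class,
    ``ft4_z ~ N(shift, sigma_ft4^2)`` and
    ``ln TSH = intercept + coupling * ft4_z + N(0, sigma_tsh^2)``, with
    coupling 0 for euthyroid subjects, negative in the dyshomeostatic
    class and positive in the allostatic class.  Event times are
    exponential at the subject hazard, censored administratively at the
    end of follow-up.  Deterministic given ``cohort.seed``.
    """
    rng = np.random.default_rng(cohort.seed)
    n = cohort.n
    probs = np.array(
        [1.0 - cohort.p_dys - cohort.p_allo, cohort.p_dys, cohort.p_allo]
    )
    cls = rng.choice(3, size=n, p=probs)

    shift = np.array([0.0, cohort.ft4_shift_dys, cohort.ft4_shift_allo])
    coupling = np.array([0.0, cohort.tsh_coupling_dys, cohort.tsh_coupling_allo])
    ft4 = rng.normal(shift[cls], cohort.sigma_ft4)
    log_tsh = (
        cohort.log_tsh_intercept
        + coupling[cls] * ft4
        + rng.normal(0.0, cohort.sigma_tsh, size=n)
    )
    tsh = np.exp(log_tsh)

    if cohort.link is HazardLink.DIRECT and cohort.tsh_direct_beta == 0.0:
        hazard = cohort.h0 * np.exp(cohort.beta_ft4 * ft4)
    else:
        hazard = np.array(
            [subject_hazard(float(z), cohort, electro) for z in ft4]
        )
        if cohort.tsh_direct_beta != 0.0:
            hazard = hazard * np.exp(
                cohort.tsh_direct_beta * (log_tsh - cohort.log_tsh_intercept)
            )

    raw = rng.exponential(1.0 / hazard)
    event = raw < cohort.followup_years
    time = np.where(event, raw, cohort.followup_years)

    return [
        Subject(
            class_label=_CLASS_LABELS[cls[i]],
            tsh=float(tsh[i]),
            ft4_z=float(ft4[i]),
            event_time=float(time[i]),
            event=bool(event[i]),
        )
        for i in range(n)
    ]


def tertile_hr(
    subjects: Sequence[Subject],
    exposure: str = "TSH",
    contrast: tuple[int, int] = (3, 2),
) -> EffectEstimate:
    """Person-time rate ratio between exposure tertiles.

    Splits the cohort into tertiles of the chosen exposure (cut points
    computed within the cohort, mirroring studies' internal reference
    ranges) and estimates ``HR = (d_a / T_a) / (d_b / T_b)`` for the
    contrast tertiles ``(a, b)`` with ``d`` events and ``T`` person-
    years; ``se(log HR) = sqrt(1/d_a + 1/d_b)``, the standard error of
    a two-group Poisson rate ratio.  The middle tertile is the default
    reference.
    """
    exposure = exposure.upper()
    if exposure not in {"TSH", "FT4"}:
        raise SchemaError("exposure must be 'TSH' or 'FT4'")
    a, b = contrast
    if not ({a, b} <= {1, 2, 3}) or a == b:
        raise SchemaError("contrast must name two distinct tertiles in 1..3")

    values = np.array(
        [s.tsh if exposure == "TSH" else s.ft4_z for s in subjects]
    )
    events = np.array([s.event for s in subjects])
    time = np.array([s.event_time for s in subjects])
    q1, q2 = np.quantile(values, [1 / 3, 2 / 3])
    tert = np.where(values <= q1, 1, np.where(values <= q2, 2, 3))

    def rate(t: int) -> tuple[float, float]:
        mask = tert == t
        return float(events[mask].sum()), float(time[mask].sum())

    d_a, t_a = rate(a)
    d_b, t_b = rate(b)
    if d_a < 1 or d_b < 1:
        raise EstimationError(
            f"zero events in tertile {a if d_a < 1 else b}; increase the "
            "cohort size or the baseline event rate"
        )
    hr = (d_a / t_a) / (d_b / t_b)
    se = math.sqrt(1.0 / d_a + 1.0 / d_b)
    return EffectEstimate(
        study_id=f"cohort-{exposure}-T{a}vT{b}",
        predictor=(
            Predictor.TSH_CONTINUOUS if exposure == "TSH" else Predictor.FT4_CONTINUOUS
        ),
        endpoint_label=f"{exposure} tertile {a} vs {b} event rate ratio",
        endpoint_class=EndpointClass.STUDY_MACE,
        measure=Measure.HR,
        point=hr,
        ci_lower=hr * math.exp(-Z_95 * se),
        ci_upper=hr * math.exp(Z_95 * se),
        scale=Scale.CATEGORICAL,
        unit="tertile",
        adjusted=True,
    )


def subjects_to_frame(subjects: Sequence[Subject]):
    """Subjects as a pandas DataFrame (``subjects.csv`` schema)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "class_label": [s.class_label for s in subjects],
            "tsh": [s.tsh for s in subjects],
            "ft4_z": [s.ft4_z for s in subjects],
            "event_time": [s.event_time for s in subjects],
            "event": [s.event for s in subjects],
        }
    )
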