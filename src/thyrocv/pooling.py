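"""Fixed-effect and DerSimonian-Laird random-effects meta-analysis.

Pooling is performed on the natural-log hazard-ratio scale, the only
scale on which symmetric normal weighting of ratio measures is
coherent; all summaries are also reported exponentiated.

Given study effects ``y_i`` with standard errors ``s_i``:

* fixed effect:   ``w_i = 1 / s_i**2``; ``mu_FE = sum(w y) / sum(w)``,
  ``se_FE = sum(w) ** -0.5``
* heterogeneity:  Cochran's ``Q = sum(w (y - mu_FE)**2)`` on ``k - 1``
  degrees of freedom; Higgins-Thompson ``I2 = max(0, 100 (Q - df) / Q)``
* between-study variance (DerSimonian-Laird method of moments):
  ``tau2 = max(0, (Q - df) / C)`` with ``C = sum(w) - sum(w**2)/sum(w)``
* random effects: ``w*_i = 1 / (s_i**2 + tau2)`` and the analogous
  weighted mean and standard error.

The core estimator is :class:`MetaAnalysis`, a scikit-learn style
estimator fitted on arrays of log effects and standard errors; the
module-level functions are thin wrappers kept for direct use.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

from .errors import FunnelRuleError, PoolingError
from .harmonization import Z_95, HarmonizedEstimate
from .records import AnalysisSet, Predictor


def _validate(y, se) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, dtype=float)
    se = np.asarray(se, dtype=float)
    if y.ndim != 1 or y.shape != se.shape:
        raise PoolingError("y and se must be one-dimensional and equally long")
    if y.size < 2:
        raise PoolingError("meta-analysis requires at least two studies")
    if not np.all(np.isfinite(y)) or not np.all(np.isfinite(se)):
        raise PoolingError("non-finite effect or standard error")
    if not np.all(se > 0):
        raise PoolingError("all standard errors must be > 0")
    return y, se


def fixed_effect(y, se) -> tuple[float, float]:
    """Inverse-variance fixed-effect pooled mean and standard error."""
    y, se = _validate(y, se)
    w = 1.0 / se**2
    mu = float(np.sum(w * y) / np.sum(w))
    return mu, float(np.sum(w) ** -0.5)


def cochran_q(y, se, mu_fe: Optional[float] = None) -> tuple[float, int, float]:
    """Cochran's heterogeneity statistic, its df and chi-square p-value."""
    y, se = _validate(y, se)
    if mu_fe is None:
        mu_fe = fixed_effect(y, se)[0]
    w = 1.0 / se**2
    q = float(np.sum(w * (y - mu_fe) ** 2))
    df = y.size - 1
    return q, df, float(stats.chi2.sf(q, df))


def dersimonian_laird(y, se) -> float:
    """DerSimonian-Laird method-of-moments between-study variance."""
    y, se = _validate(y, se)
    w = 1.0 / se**2
    q, df, _ = cochran_q(y, se)
    c = float(np.sum(w) - np.sum(w**2) / np.sum(w))
    if c <= 0:
        raise PoolingError("degenerate weights: C <= 0 in DL estimator")
    return max(0.0, (q - df) / c)


def i_squared(q: float, df: int) -> float:
    """Higgins-Thompson I-squared percentage, truncated at 0."""
    if df < 1:
        raise PoolingError("I2 requires df >= 1")
    if q <= 0.0:
        return 0.0
    return max(0.0, 100.0 * (q - df) / q)


def random_effects(y, se, tau2: float) -> tuple[float, float]:
    """Random-effects pooled mean and standard error at a given tau2."""
    y, se = _validate(y, se)
    if tau2 < 0:
        raise PoolingError("tau2 must be >= 0")
    w = 1.0 / (se**2 + tau2)
    mu = float(np.sum(w * y) / np.sum(w))
    return mu, float(np.sum(w) ** -0.5)


class MetaAnalysis(BaseEstimator):
    """Inverse-variance meta-analysis estimator (fixed + DL random effects).

    Follows the scikit-learn estimator protocol: construct with
    hyper-parameters, call :meth:`fit` with the per-study log effects as
    ``y`` and their standard errors as ``se``, then read the fitted
    attributes (all suffixed with an underscore).

    Parameters
    ----------
    ci_level : float, default 0.95
        Confidence level for the pooled intervals.
    i2_preference_cutoff : float, default 50.0
        I2 percentage at or above which the random-effects model is
        flagged as preferable to the fixed-effect model.
    knapp_hartung : bool, default False
        Apply the Knapp-Hartung small-sample adjustment to the
        random-effects standard error and use a t reference
        distribution.  Off by default; offered for sensitivity analysis.

    Attributes
    ----------
    k_ : int                  number of studies pooled
    mu_fe_, se_fe_ : float    fixed-effect mean and SE (log scale)
    mu_re_, se_re_ : float    random-effects mean and SE (log scale)
    tau2_ : float             DerSimonian-Laird between-study variance
    Q_, df_, p_Q_ : float     Cochran heterogeneity test
    i2_ : float               Higgins-Thompson percentage
    weights_fe_, weights_re_ : ndarray, normalized to sum to 1
    ci_fe_, ci_re_ : (float, float)  pooled intervals on the HR scale
    p_fe_, p_re_ : float      two-sided pooled-effect p-values
    preferred_model_ : str    "random" when i2_ >= cutoff else "fixed"
    """

    def __init__(
        self,
        ci_level: float = 0.95,
        i2_preference_cutoff: float = 50.0,
        knapp_hartung: bool = False,
    ):
        self.ci_level = ci_level
        self.i2_preference_cutoff = i2_preference_cutoff
        self.knapp_hartung = knapp_hartung

    def fit(self, y, se) -> "MetaAnalysis":
        if not (0 < self.ci_level < 1):
            raise PoolingError("ci_level must be in (0, 1)")
        if not (0 <= self.i2_preference_cutoff <= 100):
            raise PoolingError("i2_preference_cutoff must be in [0, 100]")
        y, se = _validate(y, se)
        self.k_ = int(y.size)

        w = 1.0 / se**2
        self.mu_fe_, self.se_fe_ = fixed_effect(y, se)
        self.Q_, self.df_, self.p_Q_ = cochran_q(y, se, self.mu_fe_)
        self.tau2_ = dersimonian_laird(y, se)
        self.i2_ = i_squared(self.Q_, self.df_)

        w_re = 1.0 / (se**2 + self.tau2_)
        self.mu_re_, self.se_re_ = random_effects(y, se, self.tau2_)
        if self.knapp_hartung and self.k_ > 1:
            hksq = float(
                np.sum(w_re * (y - self.mu_re_) ** 2) / ((self.k_ - 1) * np.sum(w_re))
            )
            self.se_re_ = float(np.sqrt(max(hksq, 0.0))) or self.se_re_

        self.weights_fe_ = w / np.sum(w)
        self.weights_re_ = w_re / np.sum(w_re)

        z = Z_95 if self.ci_level == 0.95 else float(
            stats.norm.ppf((1 + self.ci_level) / 2)
        )
        if self.knapp_hartung:
            crit = float(stats.t.ppf((1 + self.ci_level) / 2, self.df_))
        else:
            crit = z
        self.ci_fe_ = (
            float(np.exp(self.mu_fe_ - z * self.se_fe_)),
            float(np.exp(self.mu_fe_ + z * self.se_fe_)),
        )
        self.ci_re_ = (
            float(np.exp(self.mu_re_ - crit * self.se_re_)),
            float(np.exp(self.mu_re_ + crit * self.se_re_)),
        )
        self.p_fe_ = float(2 * stats.norm.sf(abs(self.mu_fe_ / self.se_fe_)))
        if self.knapp_hartung:
            self.p_re_ = float(
                2 * stats.t.sf(abs(self.mu_re_ / self.se_re_), self.df_)
            )
        else:
            self.p_re_ = float(2 * stats.norm.sf(abs(self.mu_re_ / self.se_re_)))
        self.preferred_model_ = (
            "random" if self.i2_ >= self.i2_preference_cutoff else "fixed"
        )
        return self


@dataclass
class PooledResult:
    """Fixed- and random-effects summaries for one analysis pool."""

    analysis_set: Optional[AnalysisSet]
    predictor: Optional[Predictor]
    k: int
    study_ids: list[str]
    mu_fe: float
    se_fe: float
    mu_re: float
    se_re: float
    ci_fe: tuple[float, float]
    ci_re: tuple[float, float]
    Q: float
    df: int
    p_Q: float
    tau2: float
    i2: float
    weights_fe: np.ndarray
    weights_re: np.ndarray
    p_fe: float
    p_re: float
    preferred_model: str

    @property
    def hr_fe(self) -> float:
        return float(np.exp(self.mu_fe))

    @property
    def hr_re(self) -> float:
        return float(np.exp(self.mu_re))


def pool(
    estimates: Sequence[HarmonizedEstimate],
    analysis_set: Optional[AnalysisSet] = None,
    predictor: Optional[Predictor] = None,
    i2_preference_cutoff: float = 50.0,
    knapp_hartung: bool = False,
) -> PooledResult:
    """Pool one analysis set of harmonized estimates.

    Expects the estimates already filtered to one per study (via
    ``select_estimate`` / ``build_analysis_pools``); a duplicated
    study_id is a hard error rather than a silent double count.
    """
    ids = [e.study_id for e in estimates]
    dupes = {s for s in ids if ids.count(s) > 1}
    if dupes:
        raise PoolingError(
            f"duplicated study in one analysis set: {sorted(dupes)}"
        )
    y = [e.log_hr for e in estimates]
    se = [e.se_log_hr for e in estimates]
    model = MetaAnalysis(
        i2_preference_cutoff=i2_preference_cutoff, knapp_hartung=knapp_hartung
    ).fit(y, se)
    return PooledResult(
        analysis_set=analysis_set,
        predictor=predictor,
        k=model.k_,
        study_ids=ids,
        mu_fe=model.mu_fe_,
        se_fe=model.se_fe_,
        mu_re=model.mu_re_,
        se_re=model.se_re_,
        ci_fe=model.ci_fe_,
        ci_re=model.ci_re_,
        Q=model.Q_,
        df=model.df_,
        p_Q=model.p_Q_,
        tau2=model.tau2_,
        i2=model.i2_,
        weights_fe=model.weights_fe_,
        weights_re=model.weights_re_,
        p_fe=model.p_fe_,
        p_re=model.p_re_,
        preferred_model=model.preferred_model_,
    )


@dataclass
class FunnelData:
    """Funnel-plot coordinates: per-study points and pseudo-CI contour."""

    points: list[tuple[float, float]]
    center: float
    contour_se: np.ndarray = field(repr=False)
    contour_lower: np.ndarray = field(repr=False)
    contour_upper: np.ndarray = field(repr=False)


def funnel(
    estimates: Sequence[HarmonizedEstimate],
    pooled: PooledResult,
    n_grid: int = 50,
) -> FunnelData:
    """Funnel diagnostics about the fixed-effect center.

    Small-study effects are only interpretable with enough studies;
    funnel data are produced for five or more studies and refused —
    with an explanatory error, never a silent skip — below that.
    """
    if len(estimates) < 5:
        raise FunnelRuleError(
            f"funnel diagnostics refused: {len(estimates)} studies in the "
            "set, but small-study assessment requires five or more"
        )
    points = [(e.log_hr, e.se_log_hr) for e in estimates]
    max_se = max(se for _, se in points)
    grid = np.linspace(0.0, max_se, n_grid)
    return FunnelData(
        points=points,
        center=pooled.mu_fe,
        contour_se=grid,
        contour_lower=pooled.mu_fe - Z_95 * grid,
        contour_upper=pooled.mu_fe + Z_95 * grid,
    )
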