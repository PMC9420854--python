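# Methods

## Scope and data model

The package operates on an already-extracted study table, not on
literature retrieval: each record carries extractor-assigned boolean
eligibility flags, and screening is a deterministic partition over
those flags. When a record violates several criteria it receives the
single highest-priority reason code (duplicate > non-human >
non-longitudinal > case report > animal/cell > therapeutic trial >
non-thyroidal illness > amiodarone > survey/review > missing
quantitative/HR data). The fixed priority is a design choice: the
exclusion criteria themselves have no inherent order, but one reason
per record keeps the screening log auditable. Screening is idempotent —
re-screening the included set excludes nothing.

When a study reports several models for the same predictor and
endpoint, the fully adjusted multivariable estimate is preferred; among
several adjusted candidates the extractor's ordering decides, with a
warning, because no principled covariate-count comparison is available
from an extraction table.

Endpoints form a hierarchy: SCD, CVD and study-specific MACE are pooled
separately, and *inclusive MACE* is derived as the union of
study-specific MACE and CVD. A study contributing both a CVD and a
study-specific MACE estimate enters the inclusive pool once, through
the broader MACE composite, to avoid double counting. SCD does not feed
the CVD pool by default; `scd_into_cvd=True` (CLI `--scd-into-cvd`)
enables that alternative reading as a sensitivity analysis. Odds ratios
are carried as rare-event hazard-ratio approximations with a logged
caveat; no OR↔HR conversion is attempted beyond that.

## Harmonization

Three linear rescalings on the hazard-ratio scale bring reported
estimates onto a common basis (pmol/L for FT4, linear mIU/L for TSH):
`1 + (HR−1)·cf` for unit changes, `1 + (HR−1)/e` for log-scale exposure
presentations, `1 + (HR−1)/SD` for per-SD presentations. All three fix
HR = 1, preserve the direction of association, are strictly increasing,
and the unit form composes multiplicatively in its factor. They are
first-order approximations: for a strongly protective HR with a large
factor the result can be non-positive, which raises a harmonization
error naming the record instead of propagating a meaningless value.
An exact power rescaling `HR^cf` (log-linear in the exposure) is
available via `rescale="exact"` for sensitivity analysis; the linear
form is the default because it is the form the synthesized literature
uses.

The transform is applied identically to the point estimate and both
confidence limits before the log-scale standard error is extracted as
`(ln hi − ln lo)/(2z)`. Rescaling the limits alongside the point is a
deliberate, auditable choice: the standard error must reflect the
rescaled interval, not the original one. The 95% normal quantile is
fixed at 1.959964 so golden values are bit-stable; other confidence
levels use `scipy.stats.norm.ppf` at run time.

## Pooling

Meta-analysis is performed on the natural-log HR scale — the only scale
on which symmetric normal weighting of ratio measures is coherent — and
all summaries are also exponentiated. Fixed-effect weights are inverse
variances; heterogeneity is quantified by Cochran's Q (chi-square on
k−1 df), the DerSimonian–Laird method-of-moments τ² (truncated at 0),
and Higgins–Thompson I² = max(0, 100·(Q−df)/Q), reported as a point
value without an interval. Random-effects weights are
1/(se² + τ²). When every estimate is identical, Q = τ² = 0 and both
models return the common value exactly. Two-sided pooled-effect
p-values come from the standard normal; the Q p-value from the
chi-square upper tail.

The random-effects model is flagged as "preferable" when I² ≥ 50%
(configurable), mirroring standard practice for substantial
heterogeneity; both models are always reported with an explicit label.
The Knapp–Hartung small-sample adjustment is off by default and
available as a flag — it widens the random-effects interval and moves
the reference distribution to a t on k−1 df.

Funnel diagnostics (effect vs. standard error about the fixed-effect
center, with a ±1.959964·s pseudo-confidence contour) are produced only
for five or more studies; below that the function refuses with an
explanatory error rather than skipping silently, and the pipeline logs
the omission. No Egger/Begg test, meta-regression or trim-and-fill is
implemented.

Correctness of the pooling engine is established two ways: exact
agreement (1e-10) with an independent loop-based evaluation of the
formulas on random instances, and a cross-check against
`statsmodels.stats.meta_analysis.combine_effects(method_re="dl")`,
which is used only as an oracle, never as the implementation.

## Synthetic data

### Study-level generator

`simulate_study_level` draws within-study standard errors uniformly on
a range and effects from N(μ, τ² + se²) — exactly the model the
random-effects estimator assumes — so calibration statements are
meaningful: over 2,000 replicates at k = 30, μ = 0.3, τ = 0.2,
se ~ U(0.1, 0.3), the empirical 95% CI coverage of the DL
random-effects interval is ≈ 0.94 (normal-quantile DL is known to
undercover slightly at moderate k), and at k = 200 replicated pooling
recovers μ and τ² = 0.04 to within Monte-Carlo error.

### Dual-etiology cohort model

The cohort simulator realizes, in the simplest distributional forms,
a two-mechanism account of the thyroid–cardiovascular link:

* **euthyroid** background (80% by default): FT4 z-score ~ N(0, 1),
  ln TSH ~ N(ln 1.5, 0.45²) — median TSH 1.5 mIU/L with a log-scale SD
  typical of population surveys, and no residual TSH–FT4 coupling
  (set-point variation dominates within the reference range);
* **dyshomeostatic** class (10%): FT4 shifted +1.5 SD, ln TSH coupled
  to FT4 with slope −1 (classical negative feedback: ensuing primary
  thyrotoxicosis suppresses TSH);
* **allostatic** class (10%): FT4 shifted +1.5 SD, coupling slope +1
  (a raised central set point drives TSH and FT4 up together).

Event times are exponential with subject hazard
`h0·exp(β_FT4·ft4_z)` (h0 = 0.02 per person-year, β_FT4 = ln 1.5 per
SD), censored administratively at 5 years. Risk is driven by FT4 only;
a `tsh_direct_beta` parameter (default 0) allows probing a direct
myocardial TSH effect. Because high-FT4 subjects sit at both extremes
of the TSH distribution, the mixture produces tertile rate ratios
> 1 for both outer TSH tertiles against the middle (≈ 1.24
asymptotically under the defaults) alongside monotone-increasing FT4
tertile ratios; removing either class removes the corresponding branch.
Only these orderings — not the absolute magnitudes — are asserted,
since class prevalences and couplings are illustrative.

The alternative `wavelength` hazard link routes the FT4 effect through
cardiac electrophysiology: ERP(z) = max(0.3·ERP₀, ERP₀ − 30·z) ms and
θ(z) = max(0.3·θ₀, θ₀ − 0.05·z) mm/ms with ERP₀ = 250 ms,
θ₀ = 0.5 mm/ms, so the excitation wavelength λ = ERP·θ (125 mm at
baseline) can fall below a 100 mm re-entry circuit; the hazard is
h0·(1 + κ·max(0, (L−λ)/L)) with κ = 2. The magnitudes are plausible for
ventricular tissue but deliberately schematic; tests assert only
monotonicity, clamping and the strict-inequality re-entry condition.

Tertile rate ratios are person-time estimators
HR = (d_a/T_a)/(d_b/T_b) with se(log HR) = √(1/d_a + 1/d_b) — the MLE
of a two-group Poisson model, verified against a grid-search
maximization of the profile likelihood. Tertile cut points are computed
within each simulated cohort, mirroring the internal reference ranges
of real studies; the middle tertile is the reference.

What the simulator does **not** emulate: competing risks, covariate
adjustment (simulated "studies" are unadjusted rate ratios),
time-varying hormone levels, measurement error in TSH/FT4, assay
differences between cohorts, and treatment effects. Passing tests
therefore show that the pipeline is correct under its own assumptions
and that the dual-etiology mechanism suffices to generate the U-shape;
they do not validate the mechanism against real cohorts.

## Numerical choices and degenerate inputs

* Pooling requires k ≥ 2; a single study, a duplicated study within one
  pool, non-positive standard errors and non-finite inputs are hard
  errors.
* τ² and I² truncate at zero; Q = 0 yields I² = 0 directly.
* The DL denominator C ≤ 0 is guarded although unreachable for k ≥ 2
  with finite positive weights.
* Degenerate confidence intervals (lower = upper) cannot yield a
  standard error and are rejected.
* CSV I/O round-trips floats exactly (`float_precision="round_trip"`,
  shortest-repr serialization) and booleans as `true`/`false`.
* All randomness flows through `numpy.random.default_rng` seeded per
  call; no global state.

## Problem sizes

The test suite and the acceptance script use: 200 random instances for
the oracle-equivalence check, 2,000 replicates for coverage (k = 30)
and for the τ = 0.3 recovery check (k = 200), 400 replicates for the
μ/τ² recovery summary at k = 200, and single cohorts of n = 50,000 for
the dual-etiology reproduction — sizes at which Monte-Carlo error is
small relative to every asserted margin while the whole suite runs in
well under a minute.

## Known limitations

* The linear HR rescalings are first-order approximations and
  inapplicable to strongly protective estimates with large conversion
  factors (they error out rather than extrapolate).
* ORs are pooled as HRs under a rare-event assumption without
  correction.
* I² is reported without a confidence interval; no publication-bias
  tests beyond the funnel coordinates.
* The cohort model's class prevalences, shifts and couplings are
  illustrative, chosen to realize the stated directions of coupling and
  risk, not fitted to any cohort.
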