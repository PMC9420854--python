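"""Pipeline driver and plain-text reporting.

``run_pipeline`` chains screening, estimate selection, endpoint
classification, harmonization, pooling and funnel diagnostics over a
two-file extraction table, writing CSV outputs, a plain-text forest
table and a run manifest.  Outputs are deterministic given the inputs
and configuration; re-running reproduces identical files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from . import __version__
from .errors import ConfigError
from .harmonization import HarmonizedEstimate, harmonize
from .pooling import FunnelData, PooledResult, funnel, pool
from .records import (
    AnalysisSet,
    EffectEstimate,
    Predictor,
    StudyRecord,
    build_analysis_pools,
    mean_nos,
    read_extraction_table,
    screen_studies,
    select_estimate,
)

log = logging.getLogger("thyrocv")

_ALL_SETS = [s.value for s in AnalysisSet]
_ALL_PREDICTORS = [p.value for p in Predictor]


@dataclass
class PipelineConfig:
    """Configuration of one evidence-synthesis run."""

    studies: str
    estimates: str
    out_dir: str = "thyrocv-out"
    analysis_sets: list[str] = field(default_factory=lambda: list(_ALL_SETS))
    predictors: list[str] = field(default_factory=lambda: list(_ALL_PREDICTORS))
    i2_cutoff: float = 50.0
    scd_into_cvd: bool = False
    rescale: str = "paper"
    knapp_hartung: bool = False
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not (0 <= self.i2_cutoff <= 100):
            raise ConfigError("i2_cutoff must be in [0, 100]")
        if self.rescale not in {"paper", "exact"}:
            raise ConfigError(f"unknown rescale mode {self.rescale!r}")
        bad = [s for s in self.analysis_sets if s not in _ALL_SETS]
        if bad:
            raise ConfigError(f"unknown analysis set(s) {bad}; choose from {_ALL_SETS}")
        bad = [p for p in self.predictors if p not in _ALL_PREDICTORS]
        if bad:
            raise ConfigError(f"unknown predictor(s) {bad}; choose from {_ALL_PREDICTORS}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a key-value mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
        if "studies" not in raw or "estimates" not in raw:
            raise ConfigError(f"{path}: 'studies' and 'estimates' paths are required")
        return cls(**raw)


def render_forest(
    pooled: PooledResult, estimates: Sequence[HarmonizedEstimate]
) -> str:
    """Plain-text forest table for one analysis pool.

    One row per study (label, HR with CI, fixed- and random-effects
    weight percentages), summary rows for both models and a
    heterogeneity footer.
    """
    z = 1.959964
    lines = []
    title = f"{pooled.analysis_set.value if pooled.analysis_set else '?'}" \
            f" / {pooled.predictor.value if pooled.predictor else '?'}"
    lines.append(title)
    lines.append("-" * len(title))
    header = f"{'Study':<18}{'HR':>8}{'95% CI':>18}{'w_FE%':>8}{'w_RE%':>8}"
    lines.append(header)
    import math

    for e, wf, wr in zip(estimates, pooled.weights_fe, pooled.weights_re):
        hr = math.exp(e.log_hr)
        lo = math.exp(e.log_hr - z * e.se_log_hr)
        hi = math.exp(e.log_hr + z * e.se_log_hr)
        lines.append(
            f"{e.study_id:<18}{hr:>8.3f}{f'[{lo:.3f}, {hi:.3f}]':>18}"
            f"{100 * wf:>8.1f}{100 * wr:>8.1f}"
        )
    for model, hr, ci in (
        ("fixed effect", pooled.hr_fe, pooled.ci_fe),
        ("random effects", pooled.hr_re, pooled.ci_re),
    ):
        mark = " *" if model.startswith(pooled.preferred_model) else ""
        lines.append(
            f"{model + mark:<18}{hr:>8.3f}{f'[{ci[0]:.3f}, {ci[1]:.3f}]':>18}"
        )
    lines.append(
        f"Q = {pooled.Q:.3f} on df = {pooled.df} (p = {pooled.p_Q:.4f}); "
        f"tau2 = {pooled.tau2:.4f}; I2 = {pooled.i2:.1f}%"
    )
    lines.append("")
    return "\n".join(lines)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run screen -> harmonize -> pool -> funnel -> report.

    Writes ``screening_log.csv``, ``harmonized.csv``, ``pooled.csv``,
    ``forest.txt``, ``funnel.csv`` (analysis sets with five or more
    studies only) and ``manifest.json`` into the output directory.
    Returns a summary dict of the pooled results keyed by
    ``(analysis_set, predictor)``.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    records, estimates = read_extraction_table(config.studies, config.estimates)
    included, excluded = screen_studies(records)
    log.info("screening: %d included, %d excluded", len(included), len(excluded))

    screening_rows = [
        {"study_id": r.study_id, "included": "true", "reason": ""} for r in included
    ] + [
        {"study_id": r.study_id, "included": "false", "reason": reason}
        for r, reason in excluded
    ]
    pd.DataFrame(screening_rows, columns=["study_id", "included", "reason"]).to_csv(
        out / "screening_log.csv", index=False
    )

    included_ids = {r.study_id for r in included}
    usable = [e for e in estimates if e.study_id in included_ids]
    dropped = [e for e in estimates if e.study_id not in included_ids]
    for e in dropped:
        log.info("estimate from excluded study %s dropped", e.study_id)

    # one estimate per study x predictor x endpoint (adjusted preferred)
    groups: dict[tuple, list[EffectEstimate]] = {}
    for e in usable:
        groups.setdefault((e.study_id, e.predictor, e.endpoint_class), []).append(e)
    selected = [select_estimate(g) for g in groups.values()]

    pools = build_analysis_pools(selected, scd_into_cvd=config.scd_into_cvd)

    harmonized_rows = []
    pooled_rows = []
    funnel_rows = []
    forest_sections = []
    results: dict[tuple[str, str], PooledResult] = {}

    wanted_sets = {AnalysisSet(s) for s in config.analysis_sets}
    wanted_preds = {Predictor(p) for p in config.predictors}

    for (aset, pred), ests in sorted(
        pools.items(), key=lambda kv: (kv[0][0].value, kv[0][1].value)
    ):
        if aset not in wanted_sets or pred not in wanted_preds:
            continue
        hzd = [harmonize(e, rescale=config.rescale) for e in ests]
        for h in hzd:
            harmonized_rows.append(
                {
                    "analysis_set": aset.value,
                    "study_id": h.study_id,
                    "predictor": pred.value,
                    "endpoint_class": h.source.endpoint_class.value,
                    "log_hr": h.log_hr,
                    "se_log_hr": h.se_log_hr,
                    "transform_applied": h.transform_applied.value,
                }
            )
        if len(hzd) < 2:
            log.warning(
                "analysis set %s/%s has %d study; not pooled",
                aset.value, pred.value, len(hzd),
            )
            continue
        res = pool(
            hzd,
            analysis_set=aset,
            predictor=pred,
            i2_preference_cutoff=config.i2_cutoff,
            knapp_hartung=config.knapp_hartung,
        )
        results[(aset.value, pred.value)] = res
        for model in ("fixed", "random"):
            fe = model == "fixed"
            pooled_rows.append(
                {
                    "analysis_set": aset.value,
                    "predictor": pred.value,
                    "model": model,
                    "k": res.k,
                    "log_hr": res.mu_fe if fe else res.mu_re,
                    "se_log_hr": res.se_fe if fe else res.se_re,
                    "hr": res.hr_fe if fe else res.hr_re,
                    "ci_lower": (res.ci_fe if fe else res.ci_re)[0],
                    "ci_upper": (res.ci_fe if fe else res.ci_re)[1],
                    "p": res.p_fe if fe else res.p_re,
                    "Q": res.Q,
                    "df": res.df,
                    "p_Q": res.p_Q,
                    "tau2": res.tau2,
                    "i2": res.i2,
                    "preferred": model == res.preferred_model,
                }
            )
        forest_sections.append(render_forest(res, hzd))
        if res.k >= 5:
            fd = funnel(hzd, res)
            for lh, se in fd.points:
                funnel_rows.append(
                    {
                        "analysis_set": aset.value,
                        "predictor": pred.value,
                        "log_hr": lh,
                        "se_log_hr": se,
                        "center": fd.center,
                    }
                )
        else:
            log.warning(
                "analysis set %s/%s has %d studies; funnel plot omitted "
                "(five or more required)",
                aset.value, pred.value, res.k,
            )

    pd.DataFrame(
        harmonized_rows,
        columns=[
            "analysis_set", "study_id", "predictor", "endpoint_class",
            "log_hr", "se_log_hr", "transform_applied",
        ],
    ).to_csv(out / "harmonized.csv", index=False)
    pd.DataFrame(
        pooled_rows,
        columns=[
            "analysis_set", "predictor", "model", "k", "log_hr", "se_log_hr",
            "hr", "ci_lower", "ci_upper", "p", "Q", "df", "p_Q", "tau2",
            "i2", "preferred",
        ],
    ).to_csv(out / "pooled.csv", index=False)
    (out / "forest.txt").write_text("\n".join(forest_sections))
    if funnel_rows:
        pd.DataFrame(
            funnel_rows,
            columns=["analysis_set", "predictor", "log_hr", "se_log_hr", "center"],
        ).to_csv(out / "funnel.csv", index=False)

    manifest = {
        "package": "thyrocv",
        "version": __version__,
        "config": dataclasses.asdict(config),
        "inputs": {
            "studies": _sha256(config.studies),
            "estimates": _sha256(config.estimates),
        },
        "n_studies_included": len(included),
        "n_studies_excluded": len(excluded),
        "mean_nos_included": mean_nos(included) if included else None,
        "pools": sorted(f"{a}/{p}" for a, p in results),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return {
        "included": included,
        "excluded": excluded,
        "results": results,
        "manifest": manifest,
    }
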