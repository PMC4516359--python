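"""End-to-end two-scenario projection pipeline.

The flow: ingest or simulate two cohort waves and two population pyramids;
apply eligibility and the incident-MI case definition to the first wave; fit
the nine-term Poisson incidence model on it; summarise covariates per (sex,
band) in both waves; turn the model plus each wave's summaries into annual
incidences; project onto the base-year and horizon-year pyramids under the
constant-prevalence scenario (wave-1 covariates on both years) and the
trend-prevalence scenario (wave-2 covariates on the horizon year); attach
delta-method confidence intervals; and report the headline relative changes
alongside the directly standardized prevalence trends.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .cohort import (
    RiskFactorCoder,
    ValidationError,
    apply_eligibility,
    classify_incident_mi,
    compute_group_summaries,
)
from .glm import PoissonGLM
from .io import (
    RunConfig,
    read_cohort,
    read_pyramid,
    truemodel_from_dict,
    wavespec_from_dict,
    write_model,
    write_pyramid,
    write_summaries,
)
from .projection import (
    ProjectionResult,
    group_incidence,
    project_cases,
    projection_ci,
    scenario_compare,
)
from .standardization import change_table
from .synthetic import (
    PYRAMID_2006,
    PYRAMID_2017,
    default_trend_spec,
    default_true_model,
    default_wave_spec,
    generate_cohort,
    generate_pyramid,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineReport:
    """Everything one run produces, plus provenance."""

    model: PoissonGLM
    exclusions: dict  # wave -> tally
    summaries: dict  # wave -> GroupSummary frame
    incidence: dict  # scenario -> incidence table
    projections: dict  # (scenario, year) -> ProjectionResult
    changes: dict  # scenario -> per-sex percent change vs the base year
    standardized: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def headline(self) -> dict:
        """The four headline numbers: per-sex change under each scenario (%)."""
        return {
            f"{sex}_{scen}": self.changes[scen][sex]
            for scen in ("constant_prevalence", "trend_prevalence")
            for sex in ("male", "female")
        }


def _resolve_wave(config: RunConfig, key: str):
    entry = config.inputs[key]
    if "path" in entry:
        return read_cohort(entry["path"])
    spec = entry["synthetic"]
    if spec == "default" or spec is None or spec is True:
        wspec = default_wave_spec() if key == "wave1" else default_trend_spec()
    elif isinstance(spec, dict) and "cells" in spec:
        wspec = wavespec_from_dict(spec)
    elif isinstance(spec, dict):
        base = default_wave_spec() if key == "wave1" else default_trend_spec()
        n = int(spec.get("n", base.n))
        wspec = type(base)(
            label=spec.get("label", base.label), n=n,
            age_sex_weights=base.age_sex_weights, factor_params=base.factor_params,
            followup_years=float(spec.get("followup_years", base.followup_years)),
            death_fraction=float(spec.get("death_fraction", base.death_fraction)),
            lost_fraction=float(spec.get("lost_fraction", base.lost_fraction)),
        )
    else:
        raise ValidationError(f"config inputs.{key}.synthetic: unrecognised value {spec!r}")
    tm = config.true_model
    model = (
        default_true_model(config.coding_mode)
        if tm in ("default", None)
        else truemodel_from_dict(tm)
    )
    # waves are independent samples: derive distinct sub-seeds from the run seed
    offset = 1 if key == "wave1" else 2
    return generate_cohort(wspec, model, seed=int(config.seed) + offset)


def _resolve_pyramid(config: RunConfig, key: str) -> pd.DataFrame:
    entry = config.inputs[key]
    if "path" in entry:
        return read_pyramid(entry["path"])
    spec = entry["synthetic"]
    defaults = PYRAMID_2006 if key == "pyramid_base" else PYRAMID_2017
    year_default = 2006 if key == "pyramid_base" else 2017
    if spec in ("default", None, True):
        return generate_pyramid(year_default, defaults["total"], dict(defaults["shape"]))
    if isinstance(spec, dict):
        return generate_pyramid(
            int(spec.get("year", year_default)),
            int(spec.get("total", defaults["total"])),
            dict(spec.get("shape", defaults["shape"])),
        )
    raise ValidationError(f"config inputs.{key}.synthetic: unrecognised value {spec!r}")


def fit_wave(records: pd.DataFrame, config: RunConfig) -> tuple[PoissonGLM, dict, pd.DataFrame]:
    """Eligibility -> case definition -> coding -> Poisson fit on one wave.

    Returns the fitted model, the exclusion tally, and the eligible records.
    """
    eligible, tally = apply_eligibility(records, max_age=config.max_age)
    events = classify_incident_mi(eligible, icd_codes=config.icd_codes)
    coder = RiskFactorCoder(coding_mode=config.coding_mode, cutoffs=config.cutoffs)
    design = coder.fit(eligible).transform(eligible)
    model = PoissonGLM().fit(design, events, exposure=config.followup_years)
    logger.info(
        "fitted wave: n=%d, events=%d, loglik=%.3f, iterations=%d",
        model.n_, model.events_, model.loglik_, model.n_iter_,
    )
    return model, tally, eligible


def run_pipeline(config: RunConfig) -> PipelineReport:
    """Execute the full two-scenario projection from one configuration."""

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise type(exc)(f"[stage {name}] {exc}") from exc

    wave1 = stage("ingest-wave1", _resolve_wave, config, "wave1")
    wave2 = stage("ingest-wave2", _resolve_wave, config, "wave2")
    pyr_base = stage("ingest-pyramid-base", _resolve_pyramid, config, "pyramid_base")
    pyr_horizon = stage("ingest-pyramid-horizon", _resolve_pyramid, config, "pyramid_horizon")

    model, tally1, eligible1 = stage("fit", fit_wave, wave1, config)
    eligible2, tally2 = stage("eligibility-wave2", apply_eligibility, wave2, config.max_age)

    summaries1 = stage(
        "summaries-wave1", compute_group_summaries, eligible1, config.coding_mode, config.cutoffs
    )
    summaries2 = stage(
        "summaries-wave2", compute_group_summaries, eligible2, config.coding_mode, config.cutoffs
    )

    def make_incidence(summaries, eligible):
        if config.prediction_mode == "individual_average":
            coder = RiskFactorCoder(coding_mode=config.coding_mode, cutoffs=config.cutoffs)
            design = coder.fit(eligible).transform(eligible)
            from .cohort import _band_series

            groups = pd.DataFrame(
                {"sex": eligible["sex"], "age_band": _band_series(eligible["age"])}
            )
            return group_incidence(
                model, summaries, mode="individual_average",
                records_design=design, records_groups=groups,
            )
        return group_incidence(model, summaries, mode="plugin_mean")

    inc_const = stage("incidence-constant", make_incidence, summaries1, eligible1)
    inc_trend = stage("incidence-trend", make_incidence, summaries2, eligible2)

    year_base = pyr_base.attrs.get("year", 2006)
    year_horizon = pyr_horizon.attrs.get("year", 2017)
    projections: dict = {}
    for scen, inc, pyramid, year in (
        ("constant_prevalence", inc_const, pyr_base, year_base),
        ("constant_prevalence", inc_const, pyr_horizon, year_horizon),
        ("trend_prevalence", inc_trend, pyr_horizon, year_horizon),
    ):
        result = stage(f"project-{scen}-{year}", project_cases, inc, pyramid, scen, year)
        summaries = summaries1 if scen == "constant_prevalence" else summaries2
        result.ci = stage(
            f"ci-{scen}-{year}", projection_ci, model, summaries, pyramid,
            config.ci_level, config.ci_method, 1.0, 2000,
            (int(config.seed) + 7 if config.seed is not None else None),
        )
        projections[(scen, year)] = result

    ref = projections[("constant_prevalence", year_base)]
    changes = {
        "constant_prevalence": scenario_compare(ref, projections[("constant_prevalence", year_horizon)]),
        "trend_prevalence": scenario_compare(ref, projections[("trend_prevalence", year_horizon)]),
    }

    standardized = stage("standardize", change_table, summaries1, summaries2, pyr_base)

    provenance = {
        "package_version": __version__,
        "seed": config.seed,
        "coding_mode": config.coding_mode,
        "prediction_mode": config.prediction_mode,
        "ci_method": config.ci_method,
        "config": config.raw or "built in code",
        "years": {"base": int(year_base), "horizon": int(year_horizon)},
    }
    return PipelineReport(
        model=model,
        exclusions={"wave1": tally1, "wave2": tally2},
        summaries={"wave1": summaries1, "wave2": summaries2},
        incidence={"constant_prevalence": inc_const, "trend_prevalence": inc_trend},
        projections=projections,
        changes=changes,
        standardized=standardized,
        provenance=provenance,
    )


def render_summary(report: PipelineReport) -> str:
    """Human-readable summary block; display rounding (1 decimal) applied here only."""
    lines = ["Projected incident first-MI cases", "=" * 34]
    for (scen, year), res in sorted(report.projections.items()):
        for sex in ("male", "female"):
            lo, hi = res.ci.get(sex, (float("nan"), float("nan")))
            lines.append(
                f"{scen:20s} {year}  {sex:6s} {res.totals[sex]:9.1f}  "
                f"(95% CI {lo:.1f}-{hi:.1f})"
            )
    lines.append("")
    lines.append("Relative change vs base year (%)")
    for scen, per_sex in report.changes.items():
        for sex in ("male", "female"):
            lines.append(f"{scen:20s} {sex:6s} {per_sex[sex]:+.1f}%")
    lines.append("")
    lines.append(f"Model: n={report.model.n_}, events={report.model.events_}")
    return "\n".join(lines) + "\n"


def write_report(report: PipelineReport, out_dir: str | Path) -> None:
    """Write all report artifacts as delimited text (full precision) + summary."""
    import json

    import yaml

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_model(report.model, out / "model.json")
    report.model.wald_summary().to_csv(out / "model_summary.csv", index=False)
    for wave, summ in report.summaries.items():
        write_summaries(summ, out / f"summaries_{wave}.csv")
    for scen, inc in report.incidence.items():
        inc.to_csv(out / f"incidence_{scen}.csv", index=False)
    totals_rows = []
    for (scen, year), res in sorted(report.projections.items()):
        res.groups.to_csv(out / f"projection_{scen}_{year}.csv", index=False)
        for key, val in res.totals.items():
            lo, hi = res.ci.get(key, (float("nan"), float("nan")))
            totals_rows.append(
                {"scenario": scen, "year": year, "group": key,
                 "expected_cases": val, "ci_low": lo, "ci_high": hi}
            )
    pd.DataFrame(totals_rows).to_csv(out / "totals.csv", index=False)
    changes_rows = [
        {"scenario": scen, "group": key, "relative_change_pct": val}
        for scen, per in report.changes.items()
        for key, val in per.items()
    ]
    pd.DataFrame(changes_rows).to_csv(out / "changes.csv", index=False)
    report.standardized.to_csv(out / "standardized_changes.csv", index=False)
    with open(out / "exclusions.json", "w", encoding="utf-8") as fh:
        json.dump(report.exclusions, fh, indent=1, sort_keys=True)
        fh.write("\n")
    with open(out / "provenance.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(report.provenance, fh, sort_keys=True)
    with open(out / "summary.txt", "w", encoding="utf-8") as fh:
        fh.write(render_summary(report))
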