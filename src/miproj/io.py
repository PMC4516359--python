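"""Delimited-text and config I/O for cohorts, pyramids, summaries and models.

All tabular data travel as delimited text (comma default, tab accepted) with
a header row; missing values are an empty field or ``NA``.  Persisted
numerics always use the period decimal separator at full precision — any
comma-decimal styling is a display concern only.  Write/read round-trips are
the identity on all typed fields.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import (
    AGE_BANDS,
    COHORT_COLUMNS,
    MI_ICD10_CODES,
    SEXES,
    TERMS,
    RiskCutoffs,
    ValidationError,
)
from .glm import PoissonGLM
from .synthetic import (
    BINARY_FACTORS,
    CONTINUOUS_FACTORS,
    TrueModel,
    WaveSpec,
)

_NA_VALUES = ["", "NA"]
_NUMERIC_COHORT_COLS = ("age", "wc", "tg", "hdl", "ldl")


def _detect_sep(path: Path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read a cohort table; validates mandatory columns and numeric cells.

    Unknown columns are preserved but ignored by the analysis; missing
    values may be empty fields or ``NA``.
    """
    path = Path(path)
    df = pd.read_csv(
        path, sep=_detect_sep(path), na_values=_NA_VALUES, keep_default_na=False, dtype=str
    )
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"cohort file {path} lacks mandatory column(s): {missing}")
    for col in _NUMERIC_COHORT_COLS:
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = parsed.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0]) + 2  # 1-based, after header
            raise ValidationError(
                f"unparseable numeric value {df[col][bad].iloc[0]!r} in column "
                f"{col!r} at line {row} of {path}"
            )
        df[col] = parsed
    df["death_icd10"] = df["death_icd10"].astype("string")
    return df


def write_cohort(records: pd.DataFrame, path: str | Path) -> None:
    records.to_csv(path, index=False, na_rep="")


def read_pyramid(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep=_detect_sep(path))
    for col in ("sex", "age_band", "count"):
        if col not in df.columns:
            raise ValidationError(f"pyramid file {path} lacks mandatory column {col!r}")
    if (df["count"] < 0).any():
        raise ValidationError(f"negative population count in {path}")
    if "year" in df.columns:
        years = df["year"].unique()
        if len(years) != 1:
            raise ValidationError(f"pyramid file {path} mixes calendar years {sorted(years)}")
        df.attrs["year"] = int(years[0])
        df = df.drop(columns=["year"])
    return df


def write_pyramid(pyramid: pd.DataFrame, path: str | Path) -> None:
    out = pyramid.copy()
    if "year" not in out.columns and pyramid.attrs.get("year") is not None:
        out.insert(0, "year", int(pyramid.attrs["year"]))
    out.to_csv(path, index=False)


def read_summaries(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep=_detect_sep(path))
    for col in ("sex", "age_band", "n", "age") + tuple(t for t in TERMS if t != "sex" and t != "age"):
        if col not in df.columns:
            raise ValidationError(f"summaries file {path} lacks mandatory column {col!r}")
    if "coding_mode" in df.columns:
        modes = df["coding_mode"].unique()
        if len(modes) != 1:
            raise ValidationError(f"summaries file {path} mixes coding modes {sorted(modes)}")
        df.attrs["coding_mode"] = str(modes[0])
        df = df.drop(columns=["coding_mode"])
    return df


def write_summaries(summaries: pd.DataFrame, path: str | Path) -> None:
    out = summaries.copy()
    mode = summaries.attrs.get("coding_mode")
    if mode is not None:
        out["coding_mode"] = mode
    out.to_csv(path, index=False)


# ------------------------------------------------------------------ models

def model_to_dict(model: PoissonGLM) -> dict:
    return {
        "terms": list(model.feature_names_in_),
        "intercept": model.intercept_,
        "coef": model.coef_.tolist(),
        "cov": model.cov_.tolist(),
        "loglik": model.loglik_,
        "n": model.n_,
        "events": model.events_,
        "coding_mode": model.coding_mode_,
    }


def model_from_dict(d: dict) -> PoissonGLM:
    from .glm import Z975
    from scipy import stats

    m = PoissonGLM()
    m.feature_names_in_ = np.asarray(d["terms"], dtype=object)
    m.n_features_in_ = len(d["terms"])
    m.intercept_ = float(d["intercept"])
    m.coef_ = np.asarray(d["coef"], dtype=float)
    m.cov_ = np.asarray(d["cov"], dtype=float)
    m.se_ = np.sqrt(np.diag(m.cov_))
    theta = m.params_
    m.ci95_ = np.column_stack([theta - Z975 * m.se_, theta + Z975 * m.se_])
    with np.errstate(divide="ignore", invalid="ignore"):
        m.p_ = 2.0 * stats.norm.sf(np.abs(theta / m.se_))
    m.loglik_ = float(d["loglik"])
    m.n_ = int(d["n"])
    m.events_ = int(d["events"])
    m.coding_mode_ = d.get("coding_mode")
    m.n_iter_ = d.get("n_iter", 0)
    return m


def write_model(model: PoissonGLM, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(model_to_dict(model), fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_model(path: str | Path) -> PoissonGLM:
    with open(path, "r", encoding="utf-8") as fh:
        return model_from_dict(json.load(fh))


# --------------------------------------------------------- synthetic specs

def wavespec_to_dict(spec: WaveSpec) -> dict:
    cells = {}
    for (sex, band), params in spec.factor_params.items():
        entry = {f: float(params[f]) for f in BINARY_FACTORS}
        for f in CONTINUOUS_FACTORS:
            entry[f] = [float(params[f][0]), float(params[f][1])]
        entry["weight"] = float(spec.age_sex_weights.get((sex, band), 0.0))
        cells.setdefault(sex, {})[band] = entry
    return {
        "label": spec.label,
        "n": spec.n,
        "followup_years": spec.followup_years,
        "death_fraction": spec.death_fraction,
        "lost_fraction": spec.lost_fraction,
        "cells": cells,
    }


def wavespec_from_dict(d: dict) -> WaveSpec:
    weights, params = {}, {}
    for sex, bands in d["cells"].items():
        if sex not in SEXES:
            raise ValidationError(f"unknown sex {sex!r} in wave spec")
        for band, entry in bands.items():
            if band not in AGE_BANDS:
                raise ValidationError(f"unknown age band {band!r} in wave spec")
            weights[(sex, band)] = float(entry["weight"])
            cell = {f: float(entry[f]) for f in BINARY_FACTORS}
            for f in CONTINUOUS_FACTORS:
                mean, sd = entry[f]
                cell[f] = (float(mean), float(sd))
            params[(sex, band)] = cell
    return WaveSpec(
        label=str(d["label"]),
        n=int(d["n"]),
        age_sex_weights=weights,
        factor_params=params,
        followup_years=float(d.get("followup_years", 5.0)),
        death_fraction=float(d.get("death_fraction", 33.0 / 67.0)),
        lost_fraction=float(d.get("lost_fraction", 0.0)),
    )


def truemodel_to_dict(model: TrueModel) -> dict:
    return {
        "intercept": model.intercept,
        "beta": dict(zip(TERMS, model.beta)),
        "coding_mode": model.coding_mode,
    }


def truemodel_from_dict(d: dict) -> TrueModel:
    return TrueModel.from_dict(float(d["intercept"]), d["beta"], d.get("coding_mode", "continuous"))


# ------------------------------------------------------------------ config

_INPUT_KEYS = ("wave1", "wave2", "pyramid_base", "pyramid_horizon")


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run.

    Each input (two cohort waves, two pyramids) is either a file path or a
    synthetic generator spec, never both; a seed is mandatory whenever any
    input is synthetic.
    """

    inputs: dict
    seed: int | None = None
    coding_mode: str = "continuous"
    cutoffs: RiskCutoffs = field(default_factory=RiskCutoffs)
    icd_codes: frozenset = MI_ICD10_CODES
    max_age: float = 80.0
    followup_years: float = 5.0
    ci_level: float = 0.95
    ci_method: str = "delta"
    prediction_mode: str = "plugin_mean"
    true_model: dict | str | None = "default"
    out_dir: str = "miproj-output"
    raw: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if self.coding_mode not in ("continuous", "binary"):
            raise ValidationError(f"config field coding_mode: unknown value {self.coding_mode!r}")
        if self.ci_method not in ("delta", "bootstrap"):
            raise ValidationError(f"config field ci_method: unknown value {self.ci_method!r}")
        if self.prediction_mode not in ("plugin_mean", "individual_average"):
            raise ValidationError(
                f"config field prediction_mode: unknown value {self.prediction_mode!r}"
            )
        if not 0 < self.ci_level < 1:
            raise ValidationError("config field ci_level must be in (0, 1)")
        any_synthetic = False
        for key in _INPUT_KEYS:
            if key not in self.inputs:
                raise ValidationError(f"config inputs: missing entry {key!r}")
            entry = self.inputs[key]
            if not isinstance(entry, dict) or not ({"path", "synthetic"} & set(entry)):
                raise ValidationError(
                    f"config inputs.{key}: expected a mapping with 'path' or 'synthetic'"
                )
            if "path" in entry and "synthetic" in entry:
                raise ValidationError(
                    f"config inputs.{key}: both 'path' and 'synthetic' given; choose one"
                )
            any_synthetic = any_synthetic or "synthetic" in entry
        if any_synthetic and self.seed is None:
            raise ValidationError("config: seed is mandatory when any input is synthetic")


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValidationError(f"config file {path} is not a mapping")
    known = {
        "inputs", "seed", "coding_mode", "cutoffs", "icd_codes", "max_age",
        "followup_years", "ci_level", "ci_method", "prediction_mode",
        "true_model", "out_dir",
    }
    unknown = set(raw) - known
    if unknown:
        raise ValidationError(f"unknown config field(s): {sorted(unknown)}")
    if "inputs" not in raw:
        raise ValidationError("config: missing 'inputs' section")
    kwargs = {k: v for k, v in raw.items() if k in known and k not in ("cutoffs", "icd_codes")}
    cutoffs = RiskCutoffs.from_config(raw.get("cutoffs")) if "cutoffs" in raw else RiskCutoffs()
    icd = frozenset(raw["icd_codes"]) if "icd_codes" in raw else MI_ICD10_CODES
    return RunConfig(cutoffs=cutoffs, icd_codes=icd, raw=raw, **kwargs)
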