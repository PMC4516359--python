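"""Project fitted incidence onto population pyramids under two scenarios.

The chain: a fitted Poisson model plus per-(sex, band) covariate summaries
give an age/sex-specific annual first-MI incidence (plug-in at the group
mean, the default, or the exact average of individual predictions); applying
those incidences to a population pyramid gives expected incident cases per
group and in total; the delta method on the coefficient covariance gives
asymptotic confidence intervals on the totals; comparing scenario totals
gives the headline relative changes.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import AGE_BANDS, SEXES, ValidationError, design_from_summaries
from .glm import PoissonGLM


def _check_coding(model: PoissonGLM, summaries: pd.DataFrame) -> None:
    m = getattr(model, "coding_mode_", None)
    s = summaries.attrs.get("coding_mode")
    if m is not None and s is not None and m != s:
        raise ValidationError(f"coding-mode mismatch: model {m!r} vs summaries {s!r}")


def _complete_summaries(summaries: pd.DataFrame) -> pd.DataFrame:
    """All 24 (sex, band) rows; empty groups borrow the nearest band's covariates."""
    have = {(r.sex, r.age_band) for r in summaries.itertuples()}
    missing = [(s, b) for s in SEXES for b in AGE_BANDS if (s, b) not in have]
    if not missing:
        return summaries
    warnings.warn(
        f"{len(missing)} empty (sex, band) group(s) {missing}; borrowing covariates "
        "from the nearest non-empty band of the same sex",
        stacklevel=3,
    )
    rows = [summaries]
    for sex, band in missing:
        j = AGE_BANDS.index(band)
        sub = summaries[summaries["sex"] == sex]
        if sub.empty:
            raise ValidationError(f"no groups at all for sex {sex!r}")
        dist = sub["age_band"].map(lambda b: abs(AGE_BANDS.index(b) - j))
        donor = sub.loc[dist.idxmin()].copy()
        donor["age_band"] = band
        donor["age"] = (int(band.split("-")[0]) + int(band.split("-")[1]) + 1) / 2.0
        donor["mean_age"] = donor["age"]
        donor["n"] = 0
        rows.append(donor.to_frame().T)
    out = pd.concat(rows, ignore_index=True)
    order = {(s, b): i * len(AGE_BANDS) + j
             for i, s in enumerate(SEXES) for j, b in enumerate(AGE_BANDS)}
    key = [order[(s, b)] for s, b in zip(out["sex"], out["age_band"])]
    out = out.iloc[np.argsort(key, kind="stable")].reset_index(drop=True)
    for c in out.columns:
        if c not in ("sex", "age_band"):
            out[c] = out[c].astype(float)
    out.attrs["coding_mode"] = summaries.attrs.get("coding_mode")
    return out


def group_incidence(
    model: PoissonGLM,
    summaries: pd.DataFrame,
    mode: str = "plugin_mean",
    records_design: pd.DataFrame | None = None,
    records_groups: pd.DataFrame | None = None,
    exposure_unit_years: float = 1.0,
) -> pd.DataFrame:
    """Annual first-MI incidence per (sex, 5-year band).

    ``plugin_mean`` (default) evaluates the model at each group's mean
    covariate vector (age at the band midpoint) — the group-level plug-in
    used when only prevalences are available; it underestimates the exact
    group mean rate under the convex log link (Jensen gap).
    ``individual_average`` averages individual predicted rates and needs the
    individual design rows (``records_design``) plus their (sex, band)
    assignment (``records_groups`` with columns sex, age_band).

    ``exposure_unit_years`` converts the model's rate scale to annual
    incidence: 1.0 when the model was fitted with exposure in years (the
    pipeline default), 5.0 when it was fitted per 5-year interval so the
    5-year rate must be divided by 5.  The annual incidence is treated as
    constant across ages within a band.
    """
    _check_coding(model, summaries)
    summaries = _complete_summaries(summaries)
    design = design_from_summaries(summaries)
    if mode == "plugin_mean":
        rate = model.predict_rate(design)
    elif mode == "individual_average":
        if records_design is None or records_groups is None:
            raise ValidationError("individual_average mode needs records_design and records_groups")
        indiv = pd.DataFrame(
            {
                "sex": records_groups["sex"].to_numpy(),
                "age_band": records_groups["age_band"].to_numpy(),
                "rate": model.predict_rate(records_design),
            }
        )
        means = indiv.groupby(["sex", "age_band"], sort=False)["rate"].mean()
        key = pd.MultiIndex.from_frame(summaries[["sex", "age_band"]])
        rate = means.reindex(key).to_numpy()
        if np.any(np.isnan(rate)):
            raise ValidationError("individual_average: some (sex, band) groups have no records")
    else:
        raise ValidationError(f"unknown prediction mode {mode!r}")
    out = summaries[["sex", "age_band", "n"]].copy()
    out["annual_incidence"] = np.asarray(rate, dtype=float) / exposure_unit_years
    out.attrs["mode"] = mode
    out.attrs["coding_mode"] = summaries.attrs.get("coding_mode")
    return out


@dataclass
class ProjectionResult:
    """Expected incident cases for one scenario-year."""

    scenario: str
    year: int
    groups: pd.DataFrame  # sex, age_band, annual_incidence, population, cases
    totals: dict  # sex -> expected cases, plus "total"
    ci: dict = field(default_factory=dict)  # sex -> (low, high)
    inputs_digest: str = ""

    def __post_init__(self) -> None:
        for sex in SEXES:
            grp_sum = self.groups.loc[self.groups["sex"] == sex, "cases"].sum()
            if not np.isclose(grp_sum, self.totals[sex], rtol=1e-9, atol=1e-12):
                raise ValidationError(f"total for {sex} does not match its group sum")
        for sex, (lo, hi) in self.ci.items():
            if not lo <= self.totals[sex] <= hi:
                raise ValidationError(f"CI for {sex} does not bracket the point estimate")


def _align_pyramid(inc: pd.DataFrame, pyramid: pd.DataFrame) -> pd.DataFrame:
    outside = ~pyramid["age_band"].isin(AGE_BANDS)
    if outside.any():
        warnings.warn(
            f"{int(outside.sum())} pyramid cell(s) outside the 20-79 bands dropped "
            "(ages 80+ are outside the modelled range)",
            stacklevel=3,
        )
        pyramid = pyramid[~outside]
    merged = inc.merge(pyramid[["sex", "age_band", "count"]], on=["sex", "age_band"], how="left")
    if merged["count"].isna().any():
        missing = merged.loc[merged["count"].isna(), ["sex", "age_band"]].to_records(index=False)
        raise ValidationError(f"pyramid lacks cells for groups: {list(missing)}")
    return merged


def project_cases(inc: pd.DataFrame, pyramid: pd.DataFrame, scenario: str = "",
                  year: int | None = None) -> ProjectionResult:
    """Expected incident cases per group: annual incidence x population count."""
    merged = _align_pyramid(inc, pyramid)
    merged = merged.rename(columns={"count": "population"})
    merged["cases"] = merged["annual_incidence"] * merged["population"]
    totals = {sex: float(merged.loc[merged["sex"] == sex, "cases"].sum()) for sex in SEXES}
    totals["total"] = float(merged["cases"].sum())
    digest = hashlib.sha256(
        json.dumps(
            {
                "incidence": merged["annual_incidence"].round(15).tolist(),
                "population": merged["population"].tolist(),
            },
            sort_keys=True,
        ).encode()
    ).hexdigest()[:16]
    return ProjectionResult(
        scenario=scenario,
        year=int(year if year is not None else pyramid.attrs.get("year", 0)),
        groups=merged[["sex", "age_band", "annual_incidence", "population", "cases"]],
        totals=totals,
        inputs_digest=digest,
    )


def projection_ci(
    model: PoissonGLM,
    summaries: pd.DataFrame,
    pyramid: pd.DataFrame,
    level: float = 0.95,
    method: str = "delta",
    exposure_unit_years: float = 1.0,
    n_boot: int = 2000,
    seed: int | None = None,
) -> dict:
    """Asymptotic CI per sex total (and overall) for the projected cases.

    ``delta`` (default): the total ``T = sum_g N_g exp(theta . d_g)`` has
    gradient ``dT/dtheta = sum_g N_g exp(theta . d_g) d_g``; its variance is
    propagated through the coefficient covariance and the interval is built
    on the log scale, ``exp(log T +/- z se(T)/T)``, keeping bounds positive.
    Population counts and prevalences are treated as fixed.

    ``bootstrap``: parametric — coefficients resampled from their asymptotic
    normal, percentile interval of the recomputed totals (sensitivity check).
    """
    _check_coding(model, summaries)
    cov = np.asarray(model.cov_, dtype=float)
    if not np.all(np.isfinite(np.linalg.cholesky(cov + 1e-15 * np.eye(len(cov))))):
        raise ValidationError("coefficient covariance is not positive semi-definite")
    summaries = _complete_summaries(summaries)
    design = design_from_summaries(summaries)
    merged = _align_pyramid(
        summaries[["sex", "age_band"]].assign(annual_incidence=0.0), pyramid
    )
    N = merged["count"].to_numpy(dtype=float)
    D = np.column_stack([np.ones(len(design)), np.asarray(design, dtype=float)])
    theta = model.params_
    rate = np.exp(D @ theta) / exposure_unit_years
    z = stats.norm.ppf(0.5 + level / 2.0)
    out: dict = {}
    sex_col = merged["sex"].to_numpy()
    groups = {sex: sex_col == sex for sex in SEXES}
    groups["total"] = np.ones(len(sex_col), dtype=bool)
    if method == "delta":
        for name, mask in groups.items():
            T = float(np.sum(N[mask] * rate[mask]))
            grad = (N[mask] * rate[mask]) @ D[mask]
            var = float(grad @ cov @ grad)
            if T <= 0:
                raise ValidationError(f"non-positive projected total for {name}")
            se_log = np.sqrt(var) / T
            out[name] = (T * np.exp(-z * se_log), T * np.exp(z * se_log))
    elif method == "bootstrap":
        rng = np.random.default_rng(seed)
        draws = rng.multivariate_normal(theta, cov, size=n_boot, method="svd")
        rates = np.exp(draws @ D.T) / exposure_unit_years  # (n_boot, n_groups)
        for name, mask in groups.items():
            totals = rates[:, mask] @ N[mask]
            lo, hi = np.quantile(totals, [0.5 - level / 2.0, 0.5 + level / 2.0])
            out[name] = (float(lo), float(hi))
    else:
        raise ValidationError(f"unknown CI method {method!r}")
    return out


def scenario_compare(ref: ProjectionResult, alt: ProjectionResult) -> dict:
    """Per-sex (and overall) relative change in projected cases, percent.

    ``100 * (alt - ref) / ref``, returned at full precision; round to one
    decimal only at reporting time.
    """
    if set(ref.totals) != set(alt.totals):
        raise ValidationError("scenario results have different sex stratification")
    out = {}
    for key in ref.totals:
        if ref.totals[key] == 0:
            raise ValidationError(f"reference total for {key!r} is zero")
        out[key] = 100.0 * (alt.totals[key] - ref.totals[key]) / ref.totals[key]
    return out


def relative_change_pct(ref_total: float, alt_total: float) -> float:
    """Headline percent change between two projected totals."""
    if ref_total == 0:
        raise ValidationError("reference total is zero")
    return 100.0 * (alt_total - ref_total) / ref_total


def __getattr__(name):
    # the full pipeline lives in .pipeline; re-exported here lazily to avoid
    # a circular import
    if name == "run_pipeline":
        from .pipeline import run_pipeline

        return run_pipeline
    raise AttributeError(name)
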