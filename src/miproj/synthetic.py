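"""Synthetic two-wave cohort and population-pyramid generator.

Emulates the data structure the projection pipeline assumes: two independent
population-based cohort waves roughly a decade apart (ages 20-79, twelve
5-year bands per sex), each participant carrying diagnosed-hypertension /
diabetes / smoking status and measured waist circumference and lipids, with
first-MI events over a 5-year follow-up driven by a log-linear intensity.

Events are generated through the exponential-probability transform of the
log-linear rate, ``P(event) = 1 - exp(-e^eta * t/5)`` with ``eta`` the 5-year
log-rate, so the generator is exactly consistent with the Poisson rate model
being fitted whenever events are rare (the bridge assumption; a warning fires
if any stratum's event probability exceeds 0.5).

The module also carries the default study conditions: wave sizes and factor
prevalences anchored to the published cohort descriptives, the published
coefficient column as generating truth, between-wave prevalence multipliers,
and an ageing population pyramid.  Analytic helpers (truncated-normal moments
and moment-generating functions) provide exact expectations for calibration
and for independent verification of the stochastic pipeline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .cohort import AGE_BANDS, SEXES, TERMS, RiskFactorCoder, RiskCutoffs, ValidationError

#: Qualifying causes of death and their sampling weights for fatal events.
#: Weights reflect the observed certificate mix (acute MI codes dominate,
#: with a sizeable share of imprecise chronic-IHD coding).
DEATH_CODE_WEIGHTS = {
    "I21.9": 18.0,
    "I24.9": 1.0,
    "I25.0": 1.0,
    "I25.1": 1.0,
    "I25.9": 10.0,
    "I28.8": 2.0,
}

BINARY_FACTORS = ("hypertension", "diabetes", "smoking")
CONTINUOUS_FACTORS = ("wc", "tg", "hdl", "ldl")

_CELLS = tuple((s, b) for s in SEXES for b in AGE_BANDS)


@dataclass(frozen=True)
class WaveSpec:
    """Sampling design of one synthetic cohort wave.

    ``age_sex_weights`` maps (sex, band) to a sampling probability (sums to
    1); ``factor_params`` maps (sex, band) to a dict with a prevalence per
    binary factor and a ``(mean, sd)`` pair per measured factor (drawn from
    a normal truncated at zero).  ``death_fraction`` is the share of events
    recorded as deaths (with an ICD-10 cause sampled from the qualifying
    codes) rather than as between-wave self-reports.
    """

    label: str
    n: int
    age_sex_weights: dict = field(repr=False)
    factor_params: dict = field(repr=False)
    followup_years: float = 5.0
    death_fraction: float = 33.0 / 67.0
    lost_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValidationError("n must be positive")
        if not (0 <= self.death_fraction <= 1 and 0 <= self.lost_fraction < 1):
            raise ValidationError("death_fraction/lost_fraction out of range")
        w = np.array([self.age_sex_weights.get(c, 0.0) for c in _CELLS])
        if np.any(w < 0) or not np.isclose(w.sum(), 1.0, atol=1e-8):
            raise ValidationError("age_sex_weights must be non-negative and sum to 1")
        for cell in _CELLS:
            if self.age_sex_weights.get(cell, 0.0) == 0:
                continue
            params = self.factor_params[cell]
            for f in BINARY_FACTORS:
                p = params[f]
                if not 0 <= p <= 1:
                    raise ValidationError(f"prevalence of {f} in {cell} out of [0,1]: {p}")
            for f in CONTINUOUS_FACTORS:
                mean, sd = params[f]
                if sd <= 0:
                    raise ValidationError(f"sd of {f} in {cell} must be > 0")


@dataclass(frozen=True)
class TrueModel:
    """Generating truth: log baseline 5-year rate and one slope per term.

    ``beta`` is ordered as the canonical model terms (sex, age, hypertension,
    diabetes, smoking, wc, tg, hdl, ldl).  ``coding_mode`` states whether the
    measured factors enter the linear predictor as raw values or 0/1 flags.
    """

    intercept: float
    beta: tuple
    coding_mode: str = "continuous"

    def __post_init__(self) -> None:
        b = np.asarray(self.beta, dtype=float)
        if b.shape != (len(TERMS),) or not np.all(np.isfinite(b)):
            raise ValidationError(f"beta must be {len(TERMS)} finite values in term order")
        if not np.isfinite(self.intercept):
            raise ValidationError("intercept must be finite")
        if self.coding_mode not in ("continuous", "binary"):
            raise ValidationError(f"unknown coding_mode {self.coding_mode!r}")
        object.__setattr__(self, "beta", tuple(float(x) for x in b))

    @classmethod
    def from_dict(cls, intercept: float, beta: dict, coding_mode: str = "continuous") -> "TrueModel":
        return cls(intercept, tuple(float(beta[t]) for t in TERMS), coding_mode)

    @property
    def beta_dict(self) -> dict:
        return dict(zip(TERMS, self.beta))


# --------------------------------------------------------------------------
# truncated-normal helpers (truncation at zero from below)
# --------------------------------------------------------------------------

def truncnorm_mean(mu: float, sd: float) -> float:
    """Mean of N(mu, sd^2) truncated to (0, inf)."""
    a = -mu / sd
    return mu + sd * stats.norm.pdf(a) / stats.norm.sf(a)

def truncnorm_mgf(t: float, mu: float, sd: float) -> float:
    """E[exp(tX)] for X ~ N(mu, sd^2) truncated to (0, inf)."""
    a = -mu / sd
    return float(np.exp(t * mu + 0.5 * t * t * sd * sd)
                 * stats.norm.sf(a - t * sd) / stats.norm.sf(a))

def truncnorm_cdf(x: float, mu: float, sd: float) -> float:
    """P(X <= x) for X ~ N(mu, sd^2) truncated to (0, inf)."""
    a = -mu / sd
    z = (x - mu) / sd
    return float((stats.norm.cdf(z) - stats.norm.cdf(a)) / stats.norm.sf(a))


def _uniform_mgf(t: float, lo: float, hi: float) -> float:
    if t == 0:
        return 1.0
    return float((np.exp(t * hi) - np.exp(t * lo)) / (t * (hi - lo)))


def _band_bounds(band: str) -> tuple[float, float]:
    lo, hi = band.split("-")
    return float(lo), float(hi) + 1.0  # ages uniform on [lo, hi+1)


# --------------------------------------------------------------------------
# cohort generation
# --------------------------------------------------------------------------

def generate_cohort(spec: WaveSpec, model: TrueModel, seed: int) -> pd.DataFrame:
    """Draw one synthetic cohort wave; identical (spec, model, seed) -> identical table.

    Sampling order is fixed: stratum, age, diagnoses, smoking category,
    measurements, event indicator, death/self-report split, cause-of-death
    code, loss to follow-up.  All draws come from one seeded generator.
    """
    rng = np.random.default_rng(seed)
    n = spec.n
    weights = np.array([spec.age_sex_weights.get(c, 0.0) for c in _CELLS])
    cell_idx = rng.choice(len(_CELLS), size=n, p=weights / weights.sum())
    sexes = np.array([_CELLS[i][0] for i in cell_idx], dtype=object)
    bands = np.array([_CELLS[i][1] for i in cell_idx], dtype=object)
    lo = np.array([_band_bounds(b)[0] for b in bands])
    hi = np.array([_band_bounds(b)[1] for b in bands])
    ages = rng.uniform(lo, hi)

    def cell_param(getter):
        return np.array([getter(spec.factor_params[_CELLS[i]]) for i in cell_idx])

    cols: dict[str, np.ndarray] = {}
    for f in BINARY_FACTORS:
        p = cell_param(lambda d, f=f: d[f])
        cols[f] = rng.random(n) < p
    # current smokers come from the smoking prevalence; the remainder split
    # between former and never (the split does not enter the model)
    former = rng.random(n) < 0.5
    smoking_status = np.where(cols["smoking"], "current", np.where(former, "former", "never"))
    for f in CONTINUOUS_FACTORS:
        mu = cell_param(lambda d, f=f: d[f][0])
        sd = cell_param(lambda d, f=f: d[f][1])
        a = (0.0 - mu) / sd
        cols[f] = stats.truncnorm.rvs(a, np.inf, loc=mu, scale=sd, size=n, random_state=rng)

    records = pd.DataFrame(
        {
            "id": [f"{spec.label}-{i:06d}" for i in range(n)],
            "sex": sexes,
            "age": ages,
            "mi_history": "no",
            "followup_status": "completed",
            "death_icd10": pd.array([None] * n, dtype="string"),
            "hypertension": np.where(cols["hypertension"], "yes", "no"),
            "diabetes": np.where(cols["diabetes"], "yes", "no"),
            "smoking_status": smoking_status,
            "wc": cols["wc"],
            "tg": cols["tg"],
            "hdl": cols["hdl"],
            "ldl": cols["ldl"],
            "self_reported_incident_mi": "no",
        }
    )

    design = RiskFactorCoder(coding_mode=model.coding_mode).fit(records).transform(records)
    eta = model.intercept + np.asarray(design) @ np.asarray(model.beta)
    p_event = 1.0 - np.exp(-np.exp(eta) * spec.followup_years / 5.0)
    strata = pd.Series(p_event).groupby([sexes, bands]).mean()
    if (strata > 0.5).any():
        worst = strata.idxmax()
        warnings.warn(
            f"mean event probability {strata.max():.2f} in stratum {worst} exceeds 0.5; "
            "the rare-event Poisson approximation is degraded",
            stacklevel=2,
        )
    event = rng.random(n) < p_event

    is_death = event & (rng.random(n) < spec.death_fraction)
    codes = list(DEATH_CODE_WEIGHTS)
    code_p = np.array(list(DEATH_CODE_WEIGHTS.values()))
    code_draw = rng.choice(len(codes), size=n, p=code_p / code_p.sum())
    records.loc[is_death, "followup_status"] = "died"
    records.loc[is_death, "death_icd10"] = np.array(codes, dtype=object)[code_draw[is_death]]
    records.loc[event & ~is_death, "self_reported_incident_mi"] = "yes"

    lost = ~event & (rng.random(n) < spec.lost_fraction)
    records.loc[lost, "followup_status"] = "lost"
    return records


# --------------------------------------------------------------------------
# population pyramids
# --------------------------------------------------------------------------

def _apportion(total: float, weights: np.ndarray) -> np.ndarray:
    """Integer counts proportional to weights, exact total (largest remainder)."""
    q = total * weights / weights.sum()
    base = np.floor(q).astype(int)
    rem = int(round(total - base.sum()))
    order = np.argsort(-(q - base), kind="stable")
    base[order[:rem]] += 1
    return base


def generate_pyramid(year: int, total: int, shape_params: dict | None = None,
                     seed: int | None = None) -> pd.DataFrame:
    """Deterministic population pyramid: persons per sex x 5-year band.

    ``shape_params``: ``peak_band`` and ``spread`` give a Gaussian band-shape
    over band indices 0..11 (omit both for a uniform pyramid);
    ``male_share`` splits the total between sexes (default 0.5).  The
    ``seed`` argument is accepted for interface symmetry; the construction is
    fully deterministic in its arguments.
    """
    if total <= 0:
        raise ValidationError("total must be positive")
    shape_params = dict(shape_params or {})
    male_share = shape_params.pop("male_share", 0.5)
    peak = shape_params.pop("peak_band", None)
    spread = shape_params.pop("spread", None)
    if shape_params:
        raise ValidationError(f"unknown shape parameter(s): {sorted(shape_params)}")
    idx = np.arange(len(AGE_BANDS), dtype=float)
    if peak is None:
        band_w = np.ones_like(idx)
    else:
        band_w = np.exp(-((idx - peak) ** 2) / (2.0 * (spread or 3.0) ** 2))
    rows = []
    male_total = round(total * male_share)
    for sex, sex_total in (("male", male_total), ("female", total - male_total)):
        counts = _apportion(sex_total, band_w)
        for b, c in zip(AGE_BANDS, counts):
            rows.append({"sex": sex, "age_band": b, "count": int(c)})
    pyr = pd.DataFrame(rows)
    pyr.attrs["year"] = int(year)
    return pyr


def age_pyramid(pyramid: pd.DataFrame, shift: float = 0.3, year: int | None = None,
                total_scale: float = 1.0) -> pd.DataFrame:
    """Shift a fraction ``shift`` of each band's population one band older.

    Mass leaving band i enters band i+1; the top band keeps what it receives.
    ``total_scale`` rescales the overall size (demographic shrinkage or
    growth).  The mean band index strictly increases for shift > 0 whenever
    any population sits below the top band.
    """
    if not 0 <= shift < 1:
        raise ValidationError("shift must be in [0, 1)")
    out_rows = []
    for sex in SEXES:
        sub = pyramid[pyramid["sex"] == sex].set_index("age_band")["count"].reindex(AGE_BANDS).fillna(0.0)
        c = sub.to_numpy(dtype=float)
        moved = shift * c[:-1]
        new = c.copy()
        new[:-1] -= moved
        new[1:] += moved
        counts = _apportion(round(new.sum() * total_scale), new) if new.sum() > 0 else new.astype(int)
        for b, v in zip(AGE_BANDS, counts):
            out_rows.append({"sex": sex, "age_band": b, "count": int(v)})
    out = pd.DataFrame(out_rows)
    out.attrs["year"] = int(year) if year is not None else pyramid.attrs.get("year")
    return out


# --------------------------------------------------------------------------
# trend scenarios
# --------------------------------------------------------------------------

def make_trend_scenario(baseline: WaveSpec, relative_changes: dict,
                        label: str | None = None, n: int | None = None) -> WaveSpec:
    """Second-wave spec with prevalences/means scaled by per-factor multipliers.

    ``relative_changes`` maps a factor name to a positive multiplier, either
    a scalar or a per-sex dict ``{"male": m, "female": m}``.  Binary-factor
    prevalences are multiplied and clipped to [0, 1] (with a warning);
    continuous-factor means are multiplied, standard deviations kept.
    """
    known = set(BINARY_FACTORS) | set(CONTINUOUS_FACTORS)
    unknown = set(relative_changes) - known
    if unknown:
        raise ValidationError(f"unknown factor(s) in relative_changes: {sorted(unknown)}")

    def mult(factor: str, sex: str) -> float:
        m = relative_changes.get(factor, 1.0)
        if isinstance(m, dict):
            m = m[sex]
        if m <= 0:
            raise ValidationError(f"multiplier for {factor} must be > 0, got {m}")
        return float(m)

    clipped = 0
    new_params = {}
    for (sex, band), params in baseline.factor_params.items():
        p2 = dict(params)
        for f in BINARY_FACTORS:
            v = params[f] * mult(f, sex)
            if v > 1.0:
                clipped += 1
                v = 1.0
            p2[f] = v
        for f in CONTINUOUS_FACTORS:
            mean, sd = params[f]
            p2[f] = (mean * mult(f, sex), sd)
        new_params[(sex, band)] = p2
    if clipped:
        warnings.warn(f"{clipped} prevalence value(s) clipped to 1 in trend scenario", stacklevel=2)
    return replace(
        baseline,
        label=label or f"{baseline.label}-trend",
        n=n or baseline.n,
        factor_params=new_params,
    )


# --------------------------------------------------------------------------
# analytic expectations (for calibration and independent verification)
# --------------------------------------------------------------------------

def expected_rate_factor(spec: WaveSpec, model: TrueModel, cell: tuple[str, str]) -> float:
    """E[exp(beta . x)] for one (sex, band) cell, exactly, under independence."""
    sex, band = cell
    params = spec.factor_params[cell]
    beta = model.beta_dict
    lo, hi = _band_bounds(band)
    out = np.exp(beta["sex"] * (1.0 if sex == "female" else 0.0))
    out *= _uniform_mgf(beta["age"], lo, hi)
    for f in BINARY_FACTORS:
        p = params[f]
        out *= (1.0 - p) + p * np.exp(beta[f])
    cutoffs = RiskCutoffs()
    for f in CONTINUOUS_FACTORS:
        mu, sd = params[f]
        if model.coding_mode == "continuous":
            out *= truncnorm_mgf(beta[f], mu, sd)
        else:
            if f == "wc":
                cut, flag_if = (cutoffs.wc_female if sex == "female" else cutoffs.wc_male), "ge"
            elif f == "tg":
                cut, flag_if = cutoffs.tg, "gt"
            elif f == "hdl":
                cut, flag_if = (cutoffs.hdl_female if sex == "female" else cutoffs.hdl_male), "lt"
            else:
                cut, flag_if = cutoffs.ldl, "gt"
            below = truncnorm_cdf(cut, mu, sd)
            p = below if flag_if == "lt" else 1.0 - below
            out *= (1.0 - p) + p * np.exp(beta[f])
    return float(out)


def expected_overall_rate(spec: WaveSpec, model: TrueModel) -> float:
    """Population-average 5-year event rate E[exp(intercept + beta . x)]."""
    acc = 0.0
    for cell in _CELLS:
        w = spec.age_sex_weights.get(cell, 0.0)
        if w > 0:
            acc += w * expected_rate_factor(spec, model, cell)
    return float(np.exp(model.intercept) * acc)


def calibrate_intercept(spec: WaveSpec, beta: tuple, target_rate: float,
                        coding_mode: str = "continuous") -> float:
    """Intercept such that the population-average 5-year rate equals the target."""
    probe = TrueModel(0.0, tuple(beta), coding_mode)
    base = expected_overall_rate(spec, probe)
    return float(np.log(target_rate) - np.log(base))


def true_group_summaries(spec: WaveSpec, coding_mode: str = "continuous") -> pd.DataFrame:
    """Exact per-(sex, band) covariate expectations implied by a WaveSpec.

    Same shape as the empirical group summaries; the infinite-n limit of
    ``compute_group_summaries`` on a cohort drawn from ``spec``.
    """
    cutoffs = RiskCutoffs()
    rows = []
    for sex in SEXES:
        for band in AGE_BANDS:
            cell = (sex, band)
            if spec.age_sex_weights.get(cell, 0.0) == 0:
                continue
            params = spec.factor_params[cell]
            lo, hi = _band_bounds(band)
            row = {
                "sex": sex,
                "age_band": band,
                "n": np.nan,
                "age": (lo + hi) / 2.0,
                "mean_age": (lo + hi) / 2.0,
                "hypertension": params["hypertension"],
                "diabetes": params["diabetes"],
                "smoking": params["smoking"],
            }
            for f in CONTINUOUS_FACTORS:
                mu, sd = params[f]
                if coding_mode == "continuous":
                    row[f] = truncnorm_mean(mu, sd)
                else:
                    if f == "wc":
                        cut = cutoffs.wc_female if sex == "female" else cutoffs.wc_male
                        row[f] = 1.0 - truncnorm_cdf(cut, mu, sd)
                    elif f == "tg":
                        row[f] = 1.0 - truncnorm_cdf(cutoffs.tg, mu, sd)
                    elif f == "hdl":
                        cut = cutoffs.hdl_female if sex == "female" else cutoffs.hdl_male
                        row[f] = truncnorm_cdf(cut, mu, sd)
                    else:
                        row[f] = 1.0 - truncnorm_cdf(cutoffs.ldl, mu, sd)
            rows.append(row)
    out = pd.DataFrame(rows)
    out.attrs["coding_mode"] = coding_mode
    return out


# --------------------------------------------------------------------------
# default study conditions
# --------------------------------------------------------------------------

#: Published per-sex descriptives of the first wave used as age-averaged
#: anchors: prevalence for the diagnoses/smoking, (mean, sd) for measurements.
WAVE1_ANCHORS = {
    "male": {
        "hypertension": 0.6360, "diabetes": 0.1244, "smoking": 0.3205,
        "wc": (95.86, 11.5), "tg": (2.11, 1.42), "hdl": (1.30, 0.37), "ldl": (3.68, 1.16),
    },
    "female": {
        "hypertension": 0.4206, "diabetes": 0.0877, "smoking": 0.2493,
        "wc": (82.94, 12.86), "tg": (1.56, 1.18), "hdl": (1.60, 0.43), "ldl": (3.53, 1.18),
    },
}

#: Log-odds change per 5-year band step for the binary factors (diagnoses
#: rise steeply with age, current smoking declines) and additive change per
#: band step for the measured means.  Chosen once as a realistic age profile;
#: the anchors above are reproduced as the band-averaged values exactly.
AGE_GRADIENTS = {
    "hypertension": 0.45, "diabetes": 0.55, "smoking": -0.30,
    "wc": 1.2, "tg": 0.04, "hdl": 0.0, "ldl": 0.08,
}

#: Second-wave / first-wave ratios of the published per-sex descriptives
#: (prevalence ratios for diagnoses/smoking, mean ratios for measurements).
TREND_MULTIPLIERS = {
    "hypertension": {"male": 48.69 / 63.60, "female": 39.12 / 42.06},
    "diabetes": {"male": 10.49 / 12.44, "female": 8.37 / 8.77},
    "smoking": {"male": 29.49 / 32.05, "female": 24.86 / 24.93},
    "wc": {"male": 97.09 / 95.86, "female": 85.02 / 82.94},
    "tg": {"male": 1.90 / 2.11, "female": 1.44 / 1.56},
    "hdl": {"male": 1.28 / 1.30, "female": 1.59 / 1.60},
    "ldl": {"male": 3.36 / 3.68, "female": 3.38 / 3.53},
}

#: Published coefficient column used as generating truth (canonical term order).
TABLE_BETA = {
    "sex": -0.123, "age": 0.069, "hypertension": 1.232, "diabetes": 0.507,
    "smoking": 0.678, "wc": 0.007, "tg": -0.092, "hdl": -0.726, "ldl": 0.293,
}

#: Analysed first-wave size and events: 3,377 participants, 67 first MIs.
WAVE1_N = 3377
WAVE2_N = 4010
WAVE1_MALE_SHARE = 1632.0 / 3377.0
WAVE1_TARGET_RATE = 67.0 / 3377.0  # population-average 5-year event rate


def _logistic_anchor(anchor: float, slope: float) -> np.ndarray:
    """Per-band prevalences with a logistic age gradient averaging to the anchor."""
    idx = np.arange(len(AGE_BANDS), dtype=float) - 5.5

    def mean_prev(a: float) -> float:
        return float(np.mean(1.0 / (1.0 + np.exp(-(a + slope * idx)))))

    a = optimize.brentq(lambda a: mean_prev(a) - anchor, -30.0, 30.0)
    return 1.0 / (1.0 + np.exp(-(a + slope * idx)))


def default_wave_spec(label: str = "wave1", n: int = WAVE1_N,
                      male_share: float = WAVE1_MALE_SHARE,
                      anchors: dict | None = None) -> WaveSpec:
    """Default first-wave sampling design.

    Equal sampling weight per age band within sex (a stratified design),
    per-band factor levels built from the per-sex anchors with the standard
    age gradients.
    """
    anchors = anchors or WAVE1_ANCHORS
    weights = {}
    factor_params = {}
    idx = np.arange(len(AGE_BANDS), dtype=float) - 5.5
    for sex in SEXES:
        share = male_share if sex == "male" else 1.0 - male_share
        per_band = {f: _logistic_anchor(anchors[sex][f], AGE_GRADIENTS[f]) for f in BINARY_FACTORS}
        for j, band in enumerate(AGE_BANDS):
            weights[(sex, band)] = share / len(AGE_BANDS)
            params = {f: float(per_band[f][j]) for f in BINARY_FACTORS}
            for f in CONTINUOUS_FACTORS:
                mean, sd = anchors[sex][f]
                params[f] = (mean + AGE_GRADIENTS[f] * idx[j], sd)
            factor_params[(sex, band)] = params
    return WaveSpec(label=label, n=n, age_sex_weights=weights, factor_params=factor_params)


def default_true_model(coding_mode: str = "continuous",
                       spec: WaveSpec | None = None,
                       target_rate: float = WAVE1_TARGET_RATE) -> TrueModel:
    """Published coefficients as truth, intercept calibrated to the observed
    first-wave event rate (the coefficient table reports no intercept)."""
    spec = spec or default_wave_spec()
    beta = tuple(TABLE_BETA[t] for t in TERMS)
    intercept = calibrate_intercept(spec, beta, target_rate, coding_mode)
    return TrueModel(intercept, beta, coding_mode)


def default_trend_spec(baseline: WaveSpec | None = None, n: int = WAVE2_N) -> WaveSpec:
    """Default second-wave spec: baseline levels scaled by the observed
    between-wave per-sex multipliers."""
    baseline = baseline or default_wave_spec()
    return make_trend_scenario(baseline, TREND_MULTIPLIERS, label="wave2", n=n)


#: Default pyramid conditions: a bell-shaped adult age structure for the base
#: year and an older, slightly smaller population for the horizon year,
#: emulating the direction and rough size of the regional demographic change.
PYRAMID_2006 = {"total": 1_200_000, "shape": {"peak_band": 5.0, "spread": 3.4, "male_share": 0.49}}
PYRAMID_2017 = {"total": 1_140_000, "shape": {"peak_band": 5.6, "spread": 3.4, "male_share": 0.49}}


def default_pyramids() -> tuple[pd.DataFrame, pd.DataFrame]:
    """(base-year, horizon-year) pyramids under the default conditions."""
    p06 = generate_pyramid(2006, PYRAMID_2006["total"], dict(PYRAMID_2006["shape"]))
    p17 = generate_pyramid(2017, PYRAMID_2017["total"], dict(PYRAMID_2017["shape"]))
    return p06, p17
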