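"""Group incidence, case projection, delta-method CIs, scenario comparison."""

import numpy as np
import pandas as pd
import pytest

from miproj.cohort import AGE_BANDS, TERMS, ValidationError
from miproj.projection import (
    ProjectionResult,
    group_incidence,
    project_cases,
    projection_ci,
    relative_change_pct,
    scenario_compare,
)
from tests.conftest import full_summaries, synthetic_model, uniform_pyramid


def result_from_totals(male, female, scenario="s", year=2006):
    groups = pd.DataFrame(
        {
            "sex": ["male", "female"],
            "age_band": ["50-54", "50-54"],
            "annual_incidence": [0.0, 0.0],
            "population": [0, 0],
            "cases": [male, female],
        }
    )
    return ProjectionResult(
        scenario=scenario, year=year, groups=groups,
        totals={"male": male, "female": female, "total": male + female},
    )


class TestGroupIncidence:
    def test_null_slopes_constant_incidence(self):
        # intercept ln(0.05) on the 5-year scale -> annual incidence 0.01
        m = synthetic_model(intercept=np.log(0.05))
        inc = group_incidence(m, full_summaries(), exposure_unit_years=5.0)
        assert len(inc) == 24
        np.testing.assert_allclose(inc["annual_incidence"], 0.01, rtol=1e-12)

    def test_prevalence_contrast_gives_rate_ratio(self):
        beta = 0.9
        m = synthetic_model({"hypertension": beta})
        summ = full_summaries()
        summ.loc[(summ.sex == "male") & (summ.age_band == "50-54"), "hypertension"] = 1.0
        inc = group_incidence(m, summ).set_index(["sex", "age_band"])
        ratio = (
            inc.loc[("male", "50-54"), "annual_incidence"]
            / inc.loc[("male", "45-49"), "annual_incidence"]
        )
        assert ratio == pytest.approx(np.exp(beta), rel=1e-12)

    def test_plugin_underestimates_individual_average(self):
        # Jensen's inequality on the convex exponential: exp(mean) < mean(exp)
        m = synthetic_model({"ldl": 1.0})
        rng = np.random.default_rng(8)
        n = 500
        design = pd.DataFrame(0.0, index=range(n), columns=list(TERMS))
        design["age"] = 52.5
        design["ldl"] = rng.normal(3.5, 1.5, n)  # high-variance covariate
        groups = pd.DataFrame({"sex": ["male"] * n, "age_band": ["50-54"] * n})
        summ = full_summaries()
        mask = (summ.sex == "male") & (summ.age_band == "50-54")
        summ.loc[mask, "ldl"] = design["ldl"].mean()
        plug = group_incidence(m, summ, mode="plugin_mean")
        indiv_rate = m.predict_rate(design).mean()
        plug_rate = plug.set_index(["sex", "age_band"]).loc[("male", "50-54"), "annual_incidence"]
        assert plug_rate < indiv_rate

    def test_empty_groups_borrow_nearest_band_with_warning(self):
        summ = full_summaries()
        summ = summ[~((summ.sex == "female") & (summ.age_band == "75-79"))]
        with pytest.warns(UserWarning, match="borrowing"):
            inc = group_incidence(synthetic_model(intercept=np.log(0.05)), summ)
        assert len(inc) == 24

    def test_coding_mode_mismatch_rejected(self):
        m = synthetic_model(coding_mode="binary")
        with pytest.raises(ValidationError, match="coding-mode"):
            group_incidence(m, full_summaries(coding_mode="continuous"))


class TestProjectCases:
    def test_zero_incidence_zero_cases(self):
        inc = group_incidence(synthetic_model(intercept=-np.inf), full_summaries())
        res = project_cases(inc, uniform_pyramid(1000))
        assert res.totals["total"] == 0.0

    def test_hand_arithmetic(self):
        inc = group_incidence(synthetic_model(intercept=np.log(0.001)), full_summaries())
        inc.loc[(inc.sex == "male") & (inc.age_band == "50-54"), "annual_incidence"] = 0.002
        pyr = uniform_pyramid(0)
        pyr.loc[(pyr.sex == "male") & (pyr.age_band == "45-49"), "count"] = 10_000
        pyr.loc[(pyr.sex == "male") & (pyr.age_band == "50-54"), "count"] = 20_000
        res = project_cases(inc, pyr)
        assert res.totals["male"] == pytest.approx(10 + 40, rel=1e-12)
        assert res.totals["female"] == 0.0

    def test_linearity_in_population(self):
        inc = group_incidence(synthetic_model({"age": 0.05}, intercept=-8.0), full_summaries())
        r1 = project_cases(inc, uniform_pyramid(1000))
        pyr2 = uniform_pyramid(1000)
        pyr2["count"] *= 2
        r2 = project_cases(inc, pyr2)
        for key in r1.totals:
            assert r2.totals[key] == pytest.approx(2 * r1.totals[key], rel=1e-12)

    def test_conservation_and_group_sum(self):
        inc = group_incidence(synthetic_model({"age": 0.06}, intercept=-9.0), full_summaries())
        res = project_cases(inc, uniform_pyramid(12345))
        for sex in ("male", "female"):
            sub = res.groups[res.groups.sex == sex]
            assert res.totals[sex] == pytest.approx(sub["cases"].sum(), rel=1e-9)
        assert res.totals["total"] == pytest.approx(
            res.totals["male"] + res.totals["female"], rel=1e-12
        )

    def test_cells_over_79_dropped_with_warning(self):
        inc = group_incidence(synthetic_model(intercept=np.log(0.05)), full_summaries())
        pyr = uniform_pyramid(1000)
        extra = pd.DataFrame([{"sex": "male", "age_band": "80-84", "count": 500}])
        pyr = pd.concat([pyr, extra], ignore_index=True)
        with pytest.warns(UserWarning, match="80"):
            res = project_cases(inc, pyr)
        assert res.groups["population"].sum() == 24_000

    def test_missing_band_rejected(self):
        inc = group_incidence(synthetic_model(intercept=np.log(0.05)), full_summaries())
        pyr = uniform_pyramid(1000)
        pyr = pyr[pyr.age_band != "75-79"]
        with pytest.raises(ValidationError, match="75-79"):
            project_cases(inc, pyr)

    def test_monotone_in_prevalence_for_positive_coefficient(self):
        m = synthetic_model({"hypertension": 1.2}, intercept=-7.0)
        pyr = uniform_pyramid(1000)
        base = project_cases(group_incidence(m, full_summaries({"hypertension": 0.3})), pyr)
        higher = project_cases(group_incidence(m, full_summaries({"hypertension": 0.5})), pyr)
        assert (higher.groups["cases"].to_numpy() >= base.groups["cases"].to_numpy()).all()
        assert higher.totals["total"] > base.totals["total"]


class TestProjectionCI:
    def test_zero_covariance_collapses_to_point(self):
        m = synthetic_model(intercept=np.log(0.01))
        ci = projection_ci(m, full_summaries(), uniform_pyramid(1000))
        res = project_cases(group_incidence(m, full_summaries()), uniform_pyramid(1000))
        for key in ("male", "female", "total"):
            assert ci[key][0] == pytest.approx(res.totals[key], rel=1e-12)
            assert ci[key][1] == pytest.approx(res.totals[key], rel=1e-12)

    def test_intercept_only_matches_lognormal_closed_form(self):
        # T = N exp(theta0), theta0 ~ N(mu, v)  =>  CI = T exp(+/- z sqrt(v))
        v = 0.04
        cov = np.zeros((10, 10))
        cov[0, 0] = v
        m = synthetic_model(intercept=np.log(0.01), cov=cov)
        ci = projection_ci(m, full_summaries(), uniform_pyramid(1000))
        T = 24_000 * 0.01
        z = 1.959963984540054
        assert ci["total"][0] == pytest.approx(T * np.exp(-z * np.sqrt(v)), rel=1e-6)
        assert ci["total"][1] == pytest.approx(T * np.exp(z * np.sqrt(v)), rel=1e-6)

    def test_covariance_scaling_scales_log_halfwidth(self):
        cov = np.zeros((10, 10))
        cov[0, 0] = 0.01
        m1 = synthetic_model(intercept=np.log(0.01), cov=cov)
        m4 = synthetic_model(intercept=np.log(0.01), cov=4 * cov)
        ci1 = projection_ci(m1, full_summaries(), uniform_pyramid(1000))
        ci4 = projection_ci(m4, full_summaries(), uniform_pyramid(1000))
        hw1 = np.log(ci1["total"][1]) - np.log(ci1["total"][0])
        hw4 = np.log(ci4["total"][1]) - np.log(ci4["total"][0])
        assert hw4 == pytest.approx(2 * hw1, rel=1e-9)

    def test_bootstrap_brackets_point_and_tracks_delta(self):
        # moderate uncertainty on intercept and one prevalence-linked slope
        cov = np.zeros((10, 10))
        cov[0, 0] = 0.01
        cov[3, 3] = 0.04  # hypertension slope
        m = synthetic_model({"age": 0.05, "hypertension": 0.5}, intercept=-8.0, cov=cov)
        summ = full_summaries({"hypertension": 0.4})
        pyr = uniform_pyramid(1000)
        point = project_cases(group_incidence(m, summ), pyr).totals["total"]
        delta = projection_ci(m, summ, pyr, method="delta")
        boot = projection_ci(m, summ, pyr, method="bootstrap", seed=0, n_boot=4000)
        assert boot["total"][0] < point < boot["total"][1]
        assert boot["total"][0] == pytest.approx(delta["total"][0], rel=0.15)
        assert boot["total"][1] == pytest.approx(delta["total"][1], rel=0.15)


class TestScenarioCompare:
    @pytest.mark.parametrize(
        "ref,alt,expected",
        [
            (2745.0, 3061.0, 11.5),
            (1990.0, 2149.0, 8.0),
            (2745.0, 2094.0, -23.7),
            (1990.0, 1649.0, -17.1),
        ],
    )
    def test_headline_percent_changes(self, ref, alt, expected):
        assert round(relative_change_pct(ref, alt), 1) == expected

    def test_per_sex_comparison(self):
        ref = result_from_totals(2745.0, 1990.0)
        alt = result_from_totals(3061.0, 2149.0, year=2017)
        change = scenario_compare(ref, alt)
        assert round(change["male"], 1) == 11.5
        assert round(change["female"], 1) == 8.0

    def test_identity(self):
        r = result_from_totals(100.0, 50.0)
        assert scenario_compare(r, r) == {"male": 0.0, "female": 0.0, "total": 0.0}

    def test_zero_reference_rejected(self):
        with pytest.raises(ValidationError, match="zero"):
            relative_change_pct(0.0, 10.0)


class TestProjectionResultInvariants:
    def test_total_must_match_group_sum(self):
        groups = pd.DataFrame(
            {"sex": ["male"], "age_band": ["50-54"], "annual_incidence": [0.01],
             "population": [100], "cases": [1.0]}
        )
        with pytest.raises(ValidationError, match="group sum"):
            ProjectionResult("s", 2006, groups, {"male": 2.0, "female": 0.0, "total": 2.0})

    def test_ci_must_bracket_point(self):
        groups = pd.DataFrame(
            {"sex": ["male"], "age_band": ["50-54"], "annual_incidence": [0.01],
             "population": [100], "cases": [1.0]}
        )
        with pytest.raises(ValidationError, match="bracket"):
            ProjectionResult(
                "s", 2006, groups, {"male": 1.0, "female": 0.0, "total": 1.0},
                ci={"male": (2.0, 3.0)},
            )
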