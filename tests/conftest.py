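import numpy as np
import pandas as pd
import pytest

from miproj.io import model_from_dict


def make_records(rows: list[dict]) -> pd.DataFrame:
    """Cohort frame from partial row dicts; unspecified fields get benign defaults."""
    defaults = {
        "id": None,
        "sex": "male",
        "age": 50.0,
        "mi_history": "no",
        "followup_status": "completed",
        "death_icd10": None,
        "hypertension": "no",
        "diabetes": "no",
        "smoking_status": "never",
        "wc": 90.0,
        "tg": 1.5,
        "hdl": 1.4,
        "ldl": 2.8,
        "self_reported_incident_mi": "no",
    }
    full = []
    for i, row in enumerate(rows):
        r = dict(defaults, **row)
        if r["id"] is None:
            r["id"] = f"p{i:03d}"
        full.append(r)
    df = pd.DataFrame(full, columns=list(defaults))
    df["death_icd10"] = df["death_icd10"].astype("string")
    return df


def synthetic_model(beta: dict | None = None, intercept: float = 0.0,
                    cov: np.ndarray | None = None, coding_mode: str = "continuous"):
    """Hand-built fitted-model object with chosen coefficients (synthetic
    stand-in for a fit; used to test prediction/projection arithmetic)."""
    from miproj.cohort import TERMS

    beta = beta or {}
    coef = [float(beta.get(t, 0.0)) for t in TERMS]
    k = len(TERMS) + 1
    cov = np.zeros((k, k)) if cov is None else np.asarray(cov, dtype=float)
    return model_from_dict(
        {
            "terms": list(TERMS),
            "intercept": intercept,
            "coef": coef,
            "cov": cov.tolist(),
            "loglik": 0.0,
            "n": 0,
            "events": 0,
            "coding_mode": coding_mode,
        }
    )


def full_summaries(values: dict | None = None, coding_mode: str = "continuous") -> pd.DataFrame:
    """All-24-group summaries frame with constant covariates (overridable)."""
    from miproj.cohort import AGE_BANDS, SEXES, band_midpoint

    base = {"hypertension": 0.0, "diabetes": 0.0, "smoking": 0.0,
            "wc": 0.0, "tg": 0.0, "hdl": 0.0, "ldl": 0.0}
    base.update(values or {})
    rows = []
    for sex in SEXES:
        for band in AGE_BANDS:
            rows.append({"sex": sex, "age_band": band, "n": 10,
                         "age": band_midpoint(band), "mean_age": band_midpoint(band), **base})
    df = pd.DataFrame(rows)
    df.attrs["coding_mode"] = coding_mode
    return df


def uniform_pyramid(count_per_cell: int = 1000, year: int = 2006) -> pd.DataFrame:
    from miproj.cohort import AGE_BANDS, SEXES

    rows = [{"sex": s, "age_band": b, "count": count_per_cell} for s in SEXES for b in AGE_BANDS]
    pyr = pd.DataFrame(rows)
    pyr.attrs["year"] = year
    return pyr


@pytest.fixture(scope="session")
def default_synthetic_config():
    from miproj.io import RunConfig

    return RunConfig(
        inputs={k: {"synthetic": "default"} for k in
                ("wave1", "wave2", "pyramid_base", "pyramid_horizon")},
        seed=3,
    )


@pytest.fixture(scope="session")
def default_report(default_synthetic_config):
    import warnings

    from miproj.pipeline import run_pipeline

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_pipeline(default_synthetic_config)
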