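"""Direct age-sex standardization of risk-factor prevalences.

Makes two cohort waves comparable by weighting each wave's per-(sex, band)
prevalence (or mean, for continuous factors — the direct method applies
unchanged) with a fixed reference population's band weights, then expressing
the between-wave difference as a percent change per factor and sex.
Weights are normalised within sex, matching the per-sex reporting shape.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import SEXES, ValidationError

STANDARDIZABLE_FACTORS = ("hypertension", "diabetes", "smoking", "wc", "tg", "hdl", "ldl")


@dataclass(frozen=True)
class StandardizedPrevalence:
    """One factor's age-standardized level for one sex."""

    factor: str
    sex: str
    value: float
    reference: str  # identifier of the reference pyramid (e.g. its year)


def direct_standardize(
    summaries: pd.DataFrame, reference: pd.DataFrame, factor: str, sex: str
) -> StandardizedPrevalence:
    """Directly standardized level: sum_g w_g p_g with reference band weights.

    ``w_g`` is the reference population count of band g divided by the
    reference total for that sex; the result is an exact weighted average of
    the group levels, hence lies between their minimum and maximum.
    """
    if factor not in summaries.columns:
        raise ValidationError(f"unknown factor {factor!r}")
    if sex not in SEXES:
        raise ValidationError(f"unknown sex {sex!r}")
    ref = reference[reference["sex"] == sex].set_index("age_band")["count"]
    if ref.sum() <= 0:
        raise ValidationError(f"reference population for {sex!r} is empty")
    sub = summaries[summaries["sex"] == sex].set_index("age_band")[factor]
    used = ref[ref > 0]
    missing = [b for b in used.index if b not in sub.index]
    if missing:
        raise ValidationError(
            f"bands present in reference but absent in summaries for {sex!r}: {missing}"
        )
    w = used / used.sum()
    value = float((w * sub.reindex(used.index)).sum())
    return StandardizedPrevalence(
        factor=factor,
        sex=sex,
        value=value,
        reference=str(reference.attrs.get("year", "reference")),
    )


def relative_change(new: StandardizedPrevalence, old: StandardizedPrevalence) -> float:
    """Percent change of the standardized level, 100 * (new - old) / old."""
    if (new.factor, new.sex, new.reference) != (old.factor, old.sex, old.reference):
        raise ValidationError(
            "relative_change requires matching factor, sex and reference: "
            f"{(new.factor, new.sex, new.reference)} vs {(old.factor, old.sex, old.reference)}"
        )
    if old.value == 0:
        raise ValidationError(f"standardized {old.factor} for {old.sex} is zero in the old wave")
    return 100.0 * (new.value - old.value) / old.value


def change_table(
    summaries_old: pd.DataFrame,
    summaries_new: pd.DataFrame,
    reference: pd.DataFrame,
    factors: tuple = STANDARDIZABLE_FACTORS,
) -> pd.DataFrame:
    """Factor x sex table of standardized levels and their percent change."""
    rows = []
    for factor in factors:
        for sex in SEXES:
            old = direct_standardize(summaries_old, reference, factor, sex)
            new = direct_standardize(summaries_new, reference, factor, sex)
            rows.append(
                {
                    "factor": factor,
                    "sex": sex,
                    "standardized_old": old.value,
                    "standardized_new": new.value,
                    "relative_change_pct": relative_change(new, old),
                }
            )
    out = pd.DataFrame(rows)
    out.attrs["reference"] = str(reference.attrs.get("year", "reference"))
    return out
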