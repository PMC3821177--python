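"""Animal demographics: age conversion and age-group assignment.

Macaque ages are converted to human-equivalent years with the standard
1:3 scaling (1 monkey year = 3 human years, i.e. human years =
months / 4).  The cohort is split at 21.66 monkey-years — 65 human
years — into middle-aged and aged groups; an animal exactly at the
cutoff is aged (inclusive upper group).

Displayed human ages round to the nearest integer (half away from
zero), except that an exact half-integer is kept as-is; this is the one
rule consistent with how such converted ages are conventionally printed
(e.g. 306 months -> 76.5, 276 months -> 69).
"""

from __future__ import annotations

import math
import warnings

import pandas as pd

__all__ = [
    "HUMAN_YEARS_PER_MONKEY_YEAR",
    "CUTOFF_HUMAN_YEARS",
    "CUTOFF_MONKEY_YEARS",
    "convert_age_exact",
    "convert_age",
    "assign_group",
    "prepare_demographics",
    "read_demographics",
    "table1_demographics",
]

HUMAN_YEARS_PER_MONKEY_YEAR = 3.0
CUTOFF_HUMAN_YEARS = 65.0
CUTOFF_MONKEY_YEARS = 21.66  # = 65 human years / 3, to the printed precision

MIDDLE_AGED = "middle-aged"
AGED = "aged"


def convert_age_exact(age_months: float) -> float:
    """Exact human-equivalent age: months / 12 * 3 = months / 4."""
    if age_months <= 0:
        raise ValueError(f"age must be positive, got {age_months}")
    return age_months / 12.0 * HUMAN_YEARS_PER_MONKEY_YEAR


def convert_age(age_months: float) -> float:
    """Human-equivalent age as displayed: nearest integer, half away
    from zero, but exact half-integers are preserved."""
    exact = convert_age_exact(age_months)
    if (exact * 2) == round(exact * 2) and exact != round(exact):
        return exact  # exact half-integer, e.g. 76.5
    return float(math.floor(exact + 0.5))


def assign_group(human_age_years: float,
                 cutoff: float = CUTOFF_HUMAN_YEARS) -> str:
    """'aged' iff human-equivalent age >= cutoff, else 'middle-aged'."""
    if human_age_years <= 0:
        raise ValueError(f"age must be positive, got {human_age_years}")
    return AGED if human_age_years >= cutoff else MIDDLE_AGED


def prepare_demographics(df: pd.DataFrame,
                         cutoff: float = CUTOFF_HUMAN_YEARS) -> pd.DataFrame:
    """Derive human ages, monkey-year ages and groups for a demographics
    table with at least animal_id and age_months columns.

    If the table already carries a ``human_age_years`` column it is kept
    as authoritative (it may encode a species-specific conversion) and a
    warning is emitted wherever it disagrees with the months / 4 rule by
    more than one display unit.
    """
    df = df.copy()
    df["animal_id"] = df["animal_id"].astype(str)
    if (df["age_months"] <= 0).any():
        bad = df.loc[df["age_months"] <= 0, "animal_id"].tolist()
        raise ValueError(f"non-positive age_months for animals {bad}")
    derived = df["age_months"].map(convert_age)
    if "human_age_years" in df.columns and df["human_age_years"].notna().all():
        mismatch = (df["human_age_years"] - derived).abs() > 1.0
        if mismatch.any():
            rows = df.loc[mismatch, ["animal_id", "age_months",
                                     "human_age_years"]]
            warnings.warn(
                "printed human age disagrees with the months/4 conversion "
                f"for: {rows.to_dict('records')}; keeping the printed value",
                stacklevel=2,
            )
    else:
        df["human_age_years"] = derived
    df["age_monkey_years"] = df["age_months"] / 12.0
    df["group"] = df["human_age_years"].map(lambda a: assign_group(a, cutoff))
    return df


def read_demographics(path, cutoff: float = CUTOFF_HUMAN_YEARS) -> pd.DataFrame:
    """Read a demographics CSV (animal_id, age_months, sex, thickness_um,
    optionally human_age_years and group) and derive groups."""
    df = pd.read_csv(path)
    required = {"animal_id", "age_months"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return prepare_demographics(df, cutoff)


def table1_demographics() -> pd.DataFrame:
    """The published demographics of the seven-macaque cohort.

    The printed human age is carried verbatim; note the first animal's
    printed 37 years is inconsistent with its 417-month chronological
    age under the months/4 rule (a known internal inconsistency of the
    published table), which `prepare_demographics` will flag.
    """
    return pd.DataFrame(
        {
            "animal_id": ["M1", "M2", "M3", "M4", "M5", "M6", "M7"],
            "age_months": [417, 243, 245, 267, 276, 306, 427],
            "human_age_years": [37.0, 61.0, 61.0, 67.0, 69.0, 76.5, 107.0],
            "sex": ["M", "F", "F", "F", "F", "M", "F"],
            "thickness_um": [25, 50, 40, 50, 50, 50, 25],
        }
    )
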