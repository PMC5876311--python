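"""The 40-category pediatric age grid shared by the whole pipeline.

Ages are categorical at the source: integer months for children under two
years (24 monthly categories) and integer years from 2 to 17 (16 yearly
categories).  Every category is represented by its midpoint in years for
modeling, e.g. the 0-1 month category becomes 0.5 months = 0.042 years.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "AgeCategory",
    "AGE_CATEGORIES",
    "N_CATEGORIES",
    "MONTHS",
    "YEARS",
    "age_midpoint",
    "category_for_age",
    "category_for_midpoint",
]

MONTHS = "months"
YEARS = "years"


@dataclass(frozen=True)
class AgeCategory:
    index: int
    age_value: int
    age_unit: str
    midpoint_years: float
    midpoint_label: str
    description: str


def _month_description(m: int) -> str:
    if m == 0:
        return "<1 month"
    if m == 23:
        return "23 months to <2 years"
    return f"{m} to <{m + 1} months"


def _build_grid() -> tuple[AgeCategory, ...]:
    cats = []
    for m in range(24):
        cats.append(AgeCategory(
            index=len(cats),
            age_value=m,
            age_unit=MONTHS,
            midpoint_years=(m + 0.5) / 12.0,
            midpoint_label=f"{m + 0.5} months",
            description=_month_description(m),
        ))
    for y in range(2, 18):
        cats.append(AgeCategory(
            index=len(cats),
            age_value=y,
            age_unit=YEARS,
            midpoint_years=y + 0.5,
            midpoint_label=f"{y + 0.5} years",
            description=f"{y} to <{y + 1} years",
        ))
    return tuple(cats)


AGE_CATEGORIES: tuple[AgeCategory, ...] = _build_grid()
N_CATEGORIES = len(AGE_CATEGORIES)

_BY_KEY = {(c.age_value, c.age_unit): c for c in AGE_CATEGORIES}


def age_midpoint(age_value: int, age_unit: str) -> float:
    """Midpoint in years of a categorical age.

    Months ``m`` map to ``(m + 0.5)/12`` years (valid for 0-23 months only);
    years ``y`` map to ``y + 0.5`` (valid for 2-17).
    """
    return category_for_age(age_value, age_unit).midpoint_years


def category_for_age(age_value: int, age_unit: str) -> AgeCategory:
    if age_unit not in (MONTHS, YEARS):
        raise ValueError(f"age_unit must be '{MONTHS}' or '{YEARS}', got {age_unit!r}")
    age_value = int(age_value)
    if age_value < 0:
        raise ValueError(f"negative age {age_value}")
    if age_unit == MONTHS and age_value >= 24:
        raise ValueError("ages of 2 years and over must be recorded in years")
    if age_unit == YEARS and age_value < 2:
        raise ValueError("ages under 2 years must be recorded in months")
    if age_unit == YEARS and age_value >= 18:
        raise ValueError(f"age {age_value} years is outside the 0 to <18 range")
    return _BY_KEY[(age_value, age_unit)]


def category_for_midpoint(age_years: float, *, atol: float = 1e-6) -> AgeCategory:
    """Resolve an age in years to the category containing it.

    Accepts any age in [0, 18): exact midpoints resolve directly; other ages
    resolve to the enclosing monthly/yearly bin.
    """
    if not 0.0 <= age_years < 18.0 + atol:
        raise ValueError(f"age {age_years} years is outside the 0 to <18 range")
    if age_years < 2.0:
        m = min(int(age_years * 12.0), 23)
        return AGE_CATEGORIES[m]
    y = min(int(age_years), 17)
    return _BY_KEY[(y, YEARS)]
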