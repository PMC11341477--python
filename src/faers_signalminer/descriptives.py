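"""Demographic breakdown and annual report counts for a drug cohort.

Reproduces the usual "clinical characteristics" table of a
pharmacovigilance study: gender, weight bins (kg), age bins (years),
reporter country and report year, each with counts and half-up-rounded
percentages that sum to the cohort size.  Ages and weights arrive in
mixed units (the FAERS AGE_COD / WT_COD codes) and are converted before
binning.
"""

from __future__ import annotations

from collections import Counter
from typing import Optional, Sequence

import pandas as pd

from .faers_io import CaseReport, DatePrecision
from .util import percent

MISSING = "Missing"
COUNTRY_NOT_SPECIFIED = "Country not specified"

_AGE_FACTORS = {
    "YR": 1.0,
    "DEC": 10.0,
    "MON": 1.0 / 12.0,
    "WK": 1.0 / 52.143,
    "DY": 1.0 / 365.25,
    "HR": 1.0 / (365.25 * 24.0),
}

_WT_FACTORS = {"KG": 1.0, "LBS": 0.45359237}

#: Age bin labels with ownership of the 65 and 85 edges by "65~85".
AGE_BINS = ("<18", "18~64.9", "65~85", ">85")
#: Weight bin labels; 50 and 100 kg both belong to "50~100".
WEIGHT_BINS = ("<50", "50~100", ">100")


def age_in_years(age: Optional[float], age_cod: Optional[str]) -> Optional[float]:
    """Convert a FAERS age to years; an absent unit code means years."""
    if age is None:
        return None
    factor = _AGE_FACTORS.get((age_cod or "YR").upper())
    if factor is None:
        return None
    return age * factor


def weight_kg(wt: Optional[float], wt_cod: Optional[str]) -> Optional[float]:
    """Convert a FAERS weight to kilograms; an absent unit code means kg."""
    if wt is None:
        return None
    factor = _WT_FACTORS.get((wt_cod or "KG").upper())
    if factor is None:
        return None
    return wt * factor


def age_bin(years: Optional[float]) -> str:
    if years is None:
        return MISSING
    if years < 18:
        return "<18"
    if years < 65:
        return "18~64.9"
    if years <= 85:
        return "65~85"
    return ">85"


def weight_bin(kg: Optional[float]) -> str:
    if kg is None:
        return MISSING
    if kg < 50:
        return "<50"
    if kg <= 100:
        return "50~100"
    return ">100"


def _sex_label(sex: Optional[str]) -> str:
    return {"F": "Female", "M": "Male"}.get((sex or "").upper(), "Unknown")


def demographics(reports: Sequence[CaseReport]) -> pd.DataFrame:
    """Characteristic / category / count / percent table for a cohort.

    Within each characteristic the counts (Missing included) sum to the
    cohort size and the percents to 100 up to rounding.
    """
    total = len(reports)
    sections: list[tuple[str, Counter]] = [
        ("Gender", Counter(_sex_label(r.demo.sex) for r in reports)),
        ("Weight (kg)", Counter(weight_bin(weight_kg(r.demo.wt, r.demo.wt_cod)) for r in reports)),
        ("Age (years)", Counter(age_bin(age_in_years(r.demo.age, r.demo.age_cod)) for r in reports)),
        (
            "Reporter country",
            Counter((r.demo.reporter_country or COUNTRY_NOT_SPECIFIED) for r in reports),
        ),
        (
            "Report year",
            Counter(
                str(r.demo.fda_dt.year) if not r.demo.fda_dt.is_absent else MISSING
                for r in reports
            ),
        ),
    ]
    rows = []
    for characteristic, counts in sections:
        for category in sorted(counts, key=str):
            rows.append(
                {
                    "characteristic": characteristic,
                    "category": category,
                    "count": counts[category],
                    "percent": percent(counts[category], total),
                }
            )
    return pd.DataFrame(rows, columns=["characteristic", "category", "count", "percent"])


def annual_counts(reports: Sequence[CaseReport]) -> tuple[dict[int, int], int]:
    """Report counts by FDA receipt year; returns (year counts, missing count).

    The receipt date (FDA_DT) defines the report's year, not the event
    onset date; any date precision down to year suffices.
    """
    years: Counter = Counter()
    missing = 0
    for report in reports:
        fda = report.demo.fda_dt
        if fda.is_absent or fda.year is None:
            missing += 1
        else:
            years[fda.year] += 1
    return dict(sorted(years.items())), missing
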