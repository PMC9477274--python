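"""Reading and writing cohort, truth and per-case metrics tables (CSV).

Cohort CSV schema (header required, UTF-8, '.' decimal separator), one row
per screening case:

``case_id, cancer(0/1), consistency(solid|part_solid), interval_days,
vol_base_mm3, vol_fu_mm3, diam_base_mm, diam_fu_mm, solid_vol_base_mm3,
solid_vol_fu_mm3, solid_diam_base_mm, solid_diam_fu_mm,
nonsolid_diam_base_mm, nonsolid_diam_fu_mm, radiologist_growth(0/1/empty),
radiologist_referral(0/1/empty)``

Empty cells are missing values.  An optional adapter converts a spreadsheet
(first sheet, same column names) to this schema.
"""

from __future__ import annotations

import math
from pathlib import Path

import pandas as pd

from .errors import CohortValidationError, NoduleGrowthError
from .types import Consistency, NoduleObservation, ScreeningCase

COHORT_COLUMNS = [
    "case_id",
    "cancer",
    "consistency",
    "interval_days",
    "vol_base_mm3",
    "vol_fu_mm3",
    "diam_base_mm",
    "diam_fu_mm",
    "solid_vol_base_mm3",
    "solid_vol_fu_mm3",
    "solid_diam_base_mm",
    "solid_diam_fu_mm",
    "nonsolid_diam_base_mm",
    "nonsolid_diam_fu_mm",
    "radiologist_growth",
    "radiologist_referral",
]


def _opt_float(value) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        return None
    return float(value)


def _opt_bool(value) -> bool | None:
    v = _opt_float(value)
    return None if v is None else bool(int(v))


def _case_from_row(row: pd.Series) -> ScreeningCase:
    case_id = str(row["case_id"])
    consistency = Consistency(str(row["consistency"]))
    base = NoduleObservation(
        nodule_id=case_id,
        consistency=consistency,
        whole_volume=float(row["vol_base_mm3"]),
        whole_avg_diameter=float(row["diam_base_mm"]),
        solid_volume=_opt_float(row.get("solid_vol_base_mm3")),
        solid_avg_diameter=_opt_float(row.get("solid_diam_base_mm")),
        nonsolid_avg_diameter=_opt_float(row.get("nonsolid_diam_base_mm")),
    )
    follow = NoduleObservation(
        nodule_id=case_id,
        consistency=consistency,
        whole_volume=float(row["vol_fu_mm3"]),
        whole_avg_diameter=float(row["diam_fu_mm"]),
        solid_volume=_opt_float(row.get("solid_vol_fu_mm3")),
        solid_avg_diameter=_opt_float(row.get("solid_diam_fu_mm")),
        nonsolid_avg_diameter=_opt_float(row.get("nonsolid_diam_fu_mm")),
    )
    return ScreeningCase(
        case_id=case_id,
        baseline=base,
        followup=follow,
        interval_days=int(row["interval_days"]),
        cancer=bool(int(row["cancer"])),
        radiologist_growth=_opt_bool(row.get("radiologist_growth")),
        radiologist_referral=_opt_bool(row.get("radiologist_referral")),
    )


def cases_from_frame(df: pd.DataFrame) -> list[ScreeningCase]:
    """Build validated screening cases from a cohort data frame."""
    required = [c for c in COHORT_COLUMNS[:8] if c not in df.columns]
    if required:
        raise CohortValidationError([f"missing required columns: {', '.join(required)}"])
    cases: list[ScreeningCase] = []
    errors: list[str] = []
    for idx, row in df.iterrows():
        try:
            cases.append(_case_from_row(row))
        except (NoduleGrowthError, ValueError, KeyError) as err:
            errors.append(f"row {idx}: {err}")
    if errors:
        raise CohortValidationError(errors)
    return cases


def read_cohort_csv(path: str | Path) -> list[ScreeningCase]:
    """Read and validate a cohort CSV; raises with per-row messages on failure."""
    df = pd.read_csv(path, float_precision="round_trip")
    return cases_from_frame(df)


def read_cohort_spreadsheet(path: str | Path) -> list[ScreeningCase]:
    """Adapter for a spreadsheet carrying the same columns (first sheet)."""
    df = pd.read_excel(path)
    unmapped = [c for c in df.columns if c not in COHORT_COLUMNS]
    if unmapped:
        raise CohortValidationError(
            [f"unmappable spreadsheet columns: {', '.join(map(str, unmapped))}"]
        )
    return cases_from_frame(df)


def cases_to_frame(cases: list[ScreeningCase]) -> pd.DataFrame:
    rows = []
    for c in cases:
        b, f = c.baseline, c.followup
        rows.append(
            {
                "case_id": c.case_id,
                "cancer": int(c.cancer),
                "consistency": c.consistency.value,
                "interval_days": c.interval_days,
                "vol_base_mm3": b.whole_volume,
                "vol_fu_mm3": f.whole_volume,
                "diam_base_mm": b.whole_avg_diameter,
                "diam_fu_mm": f.whole_avg_diameter,
                "solid_vol_base_mm3": b.solid_volume,
                "solid_vol_fu_mm3": f.solid_volume,
                "solid_diam_base_mm": b.solid_avg_diameter,
                "solid_diam_fu_mm": f.solid_avg_diameter,
                "nonsolid_diam_base_mm": b.nonsolid_avg_diameter,
                "nonsolid_diam_fu_mm": f.nonsolid_avg_diameter,
                "radiologist_growth": None
                if c.radiologist_growth is None
                else int(c.radiologist_growth),
                "radiologist_referral": None
                if c.radiologist_referral is None
                else int(c.radiologist_referral),
            }
        )
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)


def write_cohort_csv(cases: list[ScreeningCase], path: str | Path) -> None:
    cases_to_frame(cases).to_csv(path, index=False)
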