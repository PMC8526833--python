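"""Deterministic categorization of questionnaire covariates into analysis strata.

Raw per-subject covariates (age, sex, height/weight, smoking, alcohol and
coffee intake in g/day, recreational and household MET-hours per week,
occupational activity class, menopausal status) are mapped onto the strata the
association analysis compares:

* BMI classes per WHO (underweight < 18.5, normal 18.5-24.9, overweight
  25.0-29.9, obese >= 30.0 kg/m^2);
* age tertiles from the empirical age distribution;
* smoking never/former and current split at 16 cigarettes/day (heavy
  inclusive);
* alcohol non/low/high with sex-specific high thresholds (> 24 g/day male,
  > 12 g/day female);
* coffee non/low/high at a configurable cutoff (default 8 g/day);
* a physical activity index (PAI): total MET-hours/week quartiled within sex
  and cross-classified with occupational activity into inactive / moderately
  inactive / moderately active / active.

Every categorizer is total over valid inputs and idempotent.
"""

from __future__ import annotations

import logging
import math
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

logger = logging.getLogger("faecomir")

MISSING = "missing"

SMOKING_HEAVY_CIGS = 16.0
ALCOHOL_HIGH_G_DAY = {"male": 24.0, "female": 12.0}
COFFEE_CUTOFF_G_DAY = 8.0

#: Cross-classification of sex-specific MET-hour quartile (columns q1..q4)
#: by occupational activity class, following the EPIC/Cambridge-index
#: convention: a more demanding occupation shifts the category upward, and
#: heavy manual work is "active" regardless of recreational activity.
DEFAULT_PAI_TABLE: Dict[str, List[str]] = {
    "sedentary": ["inactive", "inactive", "moderately_inactive", "moderately_active"],
    "unemployed": ["inactive", "inactive", "moderately_inactive", "moderately_active"],
    "standing": ["moderately_inactive", "moderately_inactive",
                 "moderately_active", "moderately_active"],
    "manual": ["moderately_active", "moderately_active", "active", "active"],
    "heavy_manual": ["active", "active", "active", "active"],
}

PAI_LEVELS = ["inactive", "moderately_inactive", "moderately_active", "active"]


# ---------------------------------------------------------------------------
# Published 335-subject cohort characteristics that the synthetic defaults
# emulate, and the sequencing summary of the corresponding stool miRNome.
# Category counts exclude subjects with missing values for that variable.
# ---------------------------------------------------------------------------

STUDY_COHORT_COUNTS = {
    "n_subjects": 335,
    "sex": {"female": 213, "male": 122},
    "mean_age_by_sex": {"female": 43.9, "male": 46.1},
    "sd_age": 14.7,
    "age_range": (18.0, 81.0),
    "age_tertile": {"t1": 122, "t2": 111, "t3": 102},
    "bmi_class": {"underweight": 25, "normal": 215, "overweight": 66, "obese": 18},
    "smoking": {"never": 181, "former": 94, "light_current": 41, "heavy_current": 16},
    "alcohol_class": {"non_drinker": 29, "low": 230, "high": 75},
    "coffee_class": {"non_drinker": 135, "low": 149, "high": 50},
    "pai": {"active": 21, "moderately_active": 108,
            "moderately_inactive": 114, "inactive": 90},
    "menopausal": {"pre": 132, "post": 77},
    "n_repeat_subjects": 6,
}

STUDY_MIRNOME_COUNTS = {
    "reference_mature": 3524,
    "reference_precursors": 1917,
    "detected_any_sample": 3277,
    "detected_half_samples": 449,
    "detected_all_samples": 9,
    "median_detected_per_sample": 594,
    "analysed_detected": 3041,
    "de_any_variable": 151,
    "de_two_or_more": 52,
    "mean_library_reads": 10.3e6,
    "mirna_read_fraction": 0.0092,
}


# ---------------------------------------------------------------------------
# Summary arithmetic helpers (used by reports and the acceptance script)
# ---------------------------------------------------------------------------

def percentage(part: float, whole: float) -> float:
    """``100 * part / whole``."""
    if whole == 0:
        raise ValueError("whole must be non-zero")
    return 100.0 * part / whole


def pooled_mean(means: Sequence[float], ns: Sequence[int]) -> float:
    """Sample-size-weighted mean of per-group means."""
    if len(means) != len(ns) or not means:
        raise ValueError("means and ns must be equal-length, non-empty")
    total = sum(ns)
    if total <= 0:
        raise ValueError("total n must be positive")
    return float(sum(m * n for m, n in zip(means, ns)) / total)


# ---------------------------------------------------------------------------
# Categorizers
# ---------------------------------------------------------------------------

def bmi_class(bmi: Optional[float]) -> str:
    if bmi is None or (isinstance(bmi, float) and math.isnan(bmi)):
        return MISSING
    if not math.isfinite(bmi) or bmi <= 0:
        raise ValueError(f"BMI must be finite and positive, got {bmi}")
    if bmi < 18.5:
        return "underweight"
    if bmi < 25.0:
        return "normal"
    if bmi < 30.0:
        return "overweight"
    return "obese"


def tertile_breakpoints(values: Iterable[float]) -> Tuple[float, float]:
    """Empirical 1/3 and 2/3 quantiles with linear interpolation."""
    arr = np.asarray([v for v in values if not pd.isna(v)], dtype=float)
    if arr.size < 3:
        raise ValueError("need at least 3 observations for tertiles")
    b1, b2 = np.quantile(arr, [1 / 3, 2 / 3])
    return float(b1), float(b2)


def age_tertiles(ages: Sequence[float],
                 breakpoints: Optional[Tuple[float, float]] = None
                 ) -> Tuple[Tuple[float, float], pd.Series]:
    """Assign each subject an age tertile (t1/t2/t3); ties go to the lower class."""
    s = pd.Series(ages, dtype=float)
    if breakpoints is None:
        if s.dropna().nunique() == 1:
            logger.warning("all ages identical; single tertile class")
            b = float(s.dropna().iloc[0])
            breakpoints = (b, b)
        else:
            breakpoints = tertile_breakpoints(s)
    b1, b2 = breakpoints
    labels = pd.Series(MISSING, index=s.index, dtype=object)
    labels[s <= b1] = "t1"
    labels[(s > b1) & (s <= b2)] = "t2"
    labels[s > b2] = "t3"
    labels[s.isna()] = MISSING
    return (b1, b2), labels


def smoking_category(status: Optional[str],
                     cigs_per_day: Optional[float],
                     heavy_threshold: float = SMOKING_HEAVY_CIGS) -> str:
    if status is None or pd.isna(status):
        return MISSING
    if status in ("never", "former"):
        return status
    if status != "current":
        raise ValueError(f"smoking status must be never/former/current, got {status!r}")
    if cigs_per_day is None or pd.isna(cigs_per_day):
        return MISSING
    return "heavy_current" if cigs_per_day >= heavy_threshold else "light_current"


def alcohol_category(g_day: Optional[float], sex: str) -> str:
    if g_day is None or pd.isna(g_day):
        return MISSING
    if g_day < 0:
        raise ValueError("alcohol intake cannot be negative")
    if sex not in ALCOHOL_HIGH_G_DAY:
        raise ValueError(f"sex must be male/female, got {sex!r}")
    if g_day == 0:
        return "non_drinker"
    return "high" if g_day > ALCOHOL_HIGH_G_DAY[sex] else "low"


def coffee_category(g_day: Optional[float],
                    cutoff: float = COFFEE_CUTOFF_G_DAY) -> str:
    if cutoff <= 0:
        raise ValueError("coffee cutoff must be positive")
    if g_day is None or pd.isna(g_day):
        return MISSING
    if g_day < 0:
        raise ValueError("coffee intake cannot be negative")
    if g_day == 0:
        return "non_drinker"
    return "high" if g_day > cutoff else "low"


def sex_specific_quartiles(totals: pd.Series, sexes: pd.Series) -> pd.Series:
    """Quartile (1..4) of MET-hour totals computed within each sex.

    Linear-interpolation quantiles; values at a breakpoint go to the lower
    quartile.
    """
    quart = pd.Series(np.nan, index=totals.index, dtype=float)
    for sex in sexes.dropna().unique():
        mask = (sexes == sex) & totals.notna()
        vals = totals[mask]
        if vals.empty:
            continue
        b1, b2, b3 = np.quantile(vals.to_numpy(dtype=float), [0.25, 0.5, 0.75])
        q = np.full(len(vals), 4)
        v = vals.to_numpy(dtype=float)
        q[v <= b3] = 3
        q[v <= b2] = 2
        q[v <= b1] = 1
        quart[vals.index] = q
    return quart


def physical_activity_index(recreational_met_h: pd.Series,
                            household_met_h: pd.Series,
                            occupational: pd.Series,
                            sex: pd.Series,
                            pai_table: Optional[Dict[str, List[str]]] = None
                            ) -> pd.Series:
    """EPIC-style physical activity index for every subject of a cohort.

    Total MET-hours/week (recreational + household) are quartiled within sex
    and cross-classified with the occupational activity class.
    """
    table = pai_table if pai_table is not None else DEFAULT_PAI_TABLE
    totals = recreational_met_h.fillna(0) + household_met_h.fillna(0)
    if (totals < 0).any():
        raise ValueError("MET-hour components must be non-negative")
    quartiles = sex_specific_quartiles(totals, sex)
    out = pd.Series(MISSING, index=totals.index, dtype=object)
    for idx in totals.index:
        occ = occupational.get(idx)
        q = quartiles.get(idx)
        if occ is None or pd.isna(occ) or pd.isna(q):
            continue
        if occ not in table:
            raise ValueError(f"unknown occupational class {occ!r}")
        out[idx] = table[occ][int(q) - 1]
    return out


# ---------------------------------------------------------------------------
# Whole-table categorization
# ---------------------------------------------------------------------------

RAW_COLUMNS = [
    "subject_id", "age", "sex", "height_cm", "weight_kg", "smoking_status",
    "cigs_per_day", "alcohol_g_day", "coffee_g_day", "recreational_met_h",
    "household_met_h", "occupational", "menopausal",
]


def categorize_cohort(raw: pd.DataFrame,
                      coffee_cutoff: float = COFFEE_CUTOFF_G_DAY,
                      heavy_smoking_threshold: float = SMOKING_HEAVY_CIGS,
                      pai_table: Optional[Dict[str, List[str]]] = None
                      ) -> pd.DataFrame:
    """Derive every analysis stratum from a raw questionnaire table.

    Recomputing on an already-categorized table is a no-op: derived columns
    depend only on the raw covariates.
    """
    df = raw.copy()
    if "bmi" not in df.columns or df["bmi"].isna().all():
        if {"height_cm", "weight_kg"} <= set(df.columns):
            h_m = df["height_cm"] / 100.0
            df["bmi"] = df["weight_kg"] / (h_m * h_m)
        else:
            df["bmi"] = np.nan
    df["bmi"] = df["bmi"].astype(float)
    df["bmi_class"] = df["bmi"].map(bmi_class)

    (b1, b2), tert = age_tertiles(df["age"])
    df["age_tertile"] = tert
    df.attrs["age_tertile_breakpoints"] = (b1, b2)

    df["smoking"] = [
        smoking_category(s, c, heavy_smoking_threshold)
        for s, c in zip(df.get("smoking_status"), df.get("cigs_per_day"))
    ]
    df["alcohol_class"] = [
        alcohol_category(g, s) for g, s in zip(df["alcohol_g_day"], df["sex"])
    ]
    df["coffee_class"] = [
        coffee_category(g, coffee_cutoff) for g in df["coffee_g_day"]
    ]
    df["pai"] = physical_activity_index(
        df["recreational_met_h"], df["household_met_h"],
        df["occupational"], df["sex"], pai_table,
    )
    # menopausal status is defined for females only
    if "menopausal" in df.columns:
        df.loc[df["sex"] != "female", "menopausal"] = np.nan
    return df
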