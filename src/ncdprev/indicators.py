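"""Derivation of the six analysis indicators from raw survey variables.

Each derivation is a pure function with missing-aware (Kleene
three-valued) logic: an OR-of-criteria indicator is 1 as soon as any
criterion is met, 0 only when every criterion is observed to fail, and
missing otherwise.  Unit non-respondents therefore come out missing on
every indicator, ready for the imputation engine, and derived
missingness is minimal -- the output is missing only when no truth value
is forced by the observed fields.

Indicator definitions:

* current smoking - has ever smoked regularly and last smoked within a
  configurable recency window (default 30 days);
* leisure-time sedentary lifestyle - the most inactive of four
  leisure-activity response options;
* hypertension - systolic blood pressure >= 140 mmHg and/or diastolic
  >= 90 mmHg and/or blood-pressure medication in the last seven days;
* elevated total cholesterol - total cholesterol >= 5 mmol/l and/or
  cholesterol-lowering medication;
* BMI category - normal (< 25 kg/m^2, underweight merged in),
  overweight (>= 25, < 30), obese (>= 30), from measured height and
  weight;
* diabetes (any type) - diabetes medication and/or HbA1c >= 48 mmol/mol;
  in waves where HbA1c was not measured (1997, 2007) the HbA1c criterion
  is undecidable, so medication alone can only confirm, never rule out.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

STRUCTURAL_HBA1C_MISSING_YEARS = (1997, 2007)

#: leisure-activity response option coding; option 1 is the most
#: inactive ("reading, watching TV, light household tasks")
MOST_INACTIVE_LEVEL = 1


@dataclass(frozen=True)
class IndicatorThresholds:
    """Clinical cut-offs defining the indicators (all inclusive)."""

    sbp_cut: float = 140.0  # mmHg
    dbp_cut: float = 90.0  # mmHg
    tc_cut: float = 5.0  # mmol/l
    hba1c_cut: float = 48.0  # mmol/mol
    bmi_overweight: float = 25.0  # kg/m^2
    bmi_obese: float = 30.0  # kg/m^2
    smoking_recency_days: float = 30.0

    def __post_init__(self) -> None:
        if not (0 < self.bmi_overweight < self.bmi_obese):
            raise ValueError("require 0 < bmi_overweight < bmi_obese")
        for name in ("sbp_cut", "dbp_cut", "tc_cut", "hba1c_cut"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def _as_float(x) -> np.ndarray:
    return np.asarray(x, dtype=float)


def kleene_or(*criteria) -> np.ndarray:
    """Three-valued OR over arrays coded 1 / 0 / NaN.

    1 if any criterion is 1; 0 if all are 0; NaN otherwise.
    """
    stacked = np.vstack([np.atleast_1d(_as_float(c)) for c in criteria])
    any_true = np.nansum(stacked == 1.0, axis=0) > 0
    all_false = np.all(stacked == 0.0, axis=0)
    out = np.full(stacked.shape[1], np.nan)
    out[any_true] = 1.0
    out[all_false & ~any_true] = 0.0
    return out


def _ge(x, cut) -> np.ndarray:
    """x >= cut with NaN propagation."""
    x = np.atleast_1d(_as_float(x))
    out = np.where(np.isnan(x), np.nan, (x >= cut).astype(float))
    return out


def derive_smoking(ever_regular, last_smoked_days,
                   t: IndicatorThresholds = IndicatorThresholds()) -> np.ndarray:
    """Current smoking: ever smoked regularly AND last smoked within the
    recency window.  Never-regular smokers are 0 regardless of the
    recency answer."""
    ever = np.atleast_1d(_as_float(ever_regular))
    days = np.atleast_1d(_as_float(last_smoked_days))
    recent = np.where(np.isnan(days), np.nan, (days <= t.smoking_recency_days).astype(float))
    out = np.full(ever.shape, np.nan)
    out[ever == 0.0] = 0.0
    out[(ever == 1.0) & (recent == 1.0)] = 1.0
    out[(ever == 1.0) & (recent == 0.0)] = 0.0
    return out


def derive_sedentary(leisure_activity) -> np.ndarray:
    """Sedentary lifestyle: the most inactive of the four leisure-time
    activity options."""
    act = np.atleast_1d(_as_float(leisure_activity))
    return np.where(np.isnan(act), np.nan, (act == MOST_INACTIVE_LEVEL).astype(float))


def derive_hypertension(sbp, dbp, bp_medication,
                        t: IndicatorThresholds = IndicatorThresholds()) -> np.ndarray:
    """Hypertension: SBP >= 140 and/or DBP >= 90 and/or blood-pressure
    medication within seven days."""
    return kleene_or(_ge(sbp, t.sbp_cut), _ge(dbp, t.dbp_cut), bp_medication)


def derive_elevated_cholesterol(total_cholesterol, lipid_medication,
                                t: IndicatorThresholds = IndicatorThresholds()) -> np.ndarray:
    """Elevated total cholesterol: >= 5 mmol/l and/or lipid-lowering
    medication."""
    return kleene_or(_ge(total_cholesterol, t.tc_cut), lipid_medication)


def derive_bmi_category(height_cm, weight_kg,
                        t: IndicatorThresholds = IndicatorThresholds()) -> np.ndarray:
    """BMI category from measured height and weight: 0 normal (including
    underweight), 1 overweight, 2 obese; half-open intervals with
    inclusive lower bounds."""
    h = np.atleast_1d(_as_float(height_cm))
    w = np.atleast_1d(_as_float(weight_kg))
    observed = ~np.isnan(h) & ~np.isnan(w)
    if np.any((h[observed] <= 0) | (w[observed] <= 0)):
        raise ValueError("height and weight must be positive")
    bmi = w / (h / 100.0) ** 2
    out = np.full(h.shape, np.nan)
    out[observed & (bmi < t.bmi_overweight)] = 0.0
    out[observed & (bmi >= t.bmi_overweight) & (bmi < t.bmi_obese)] = 1.0
    out[observed & (bmi >= t.bmi_obese)] = 2.0
    return out


def derive_diabetes(diabetes_medication, hba1c, wave_year=None,
                    t: IndicatorThresholds = IndicatorThresholds(),
                    hba1c_missing_years=STRUCTURAL_HBA1C_MISSING_YEARS) -> np.ndarray:
    """Diabetes (any type): medication and/or HbA1c >= 48 mmol/mol.

    In waves listed in *hba1c_missing_years* the HbA1c criterion is
    treated as undecidable even if a value is present, so the result is 1
    for medicated persons and missing otherwise (coding 0 would bias the
    trend; these cells are left for the imputation engine).
    """
    med = np.atleast_1d(_as_float(diabetes_medication))
    lab = np.atleast_1d(_as_float(hba1c)).copy()
    if wave_year is not None:
        wy = np.atleast_1d(np.asarray(wave_year))
        if wy.size == 1:
            wy = np.full(med.shape, wy.item())
        structural = np.isin(wy, list(hba1c_missing_years))
        lab = np.where(structural, np.nan, lab)
    return kleene_or(med, _ge(lab, t.hba1c_cut))


def plausibility_flags(frame: pd.DataFrame,
                       bounds: dict[str, tuple[float, float]] | None = None) -> pd.DataFrame:
    """Flag physically implausible raw values (never silently dropped).

    Returns a boolean DataFrame, True where a present value falls outside
    its plausibility interval.
    """
    bounds = bounds or {
        "sbp": (60.0, 280.0),
        "dbp": (30.0, 160.0),
        "total_cholesterol": (1.5, 15.0),
        "hba1c": (15.0, 180.0),
        "height_cm": (120.0, 220.0),
        "weight_kg": (30.0, 250.0),
    }
    flags = {}
    for col, (lo, hi) in bounds.items():
        if col in frame.columns:
            v = frame[col].to_numpy(dtype=float)
            flags[col] = ~np.isnan(v) & ((v < lo) | (v > hi))
    return pd.DataFrame(flags, index=frame.index)


def derive_indicators(frame: pd.DataFrame,
                      t: IndicatorThresholds = IndicatorThresholds()) -> pd.DataFrame:
    """Derive the analysis columns for a whole survey frame.

    Accepts either raw variables (sbp/dbp/medication flags, cholesterol,
    height/weight, smoking questionnaire items, leisure activity) or
    pre-derived indicator columns, which pass through unchanged; the
    synthetic generator emits pre-derived indicators except for diabetes,
    which is always recombined from its medication flag and HbA1c so the
    structural missingness of HbA1c propagates correctly.
    """
    out = frame.copy()
    if "sbp" in out.columns:
        out["hypertension"] = derive_hypertension(out["sbp"], out["dbp"],
                                                  out.get("bp_medication"), t)
    if "total_cholesterol" in out.columns:
        out["elevated_tc"] = derive_elevated_cholesterol(
            out["total_cholesterol"], out.get("lipid_medication"), t)
    if "height_cm" in out.columns:
        out["bmi_cat"] = derive_bmi_category(out["height_cm"], out["weight_kg"], t)
    if "ever_regular" in out.columns:
        out["smoking"] = derive_smoking(out["ever_regular"], out["last_smoked_days"], t)
    if "leisure_activity" in out.columns:
        out["sedentary"] = derive_sedentary(out["leisure_activity"])
    if "diabetes_med" in out.columns:
        out["diabetes"] = derive_diabetes(out["diabetes_med"], out["hba1c"],
                                          out["year"], t)
    return out
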