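"""Conversion of raw biomarker measurements to reference intakes.

Recovery biomarkers scale a measured 24-h excretion up by a known excretion
fraction (urinary nitrogen 81%, potassium 80%, sodium 86%); urinary nitrogen
is further multiplied by a nitrogen→protein conversion ratio (default 6.25).
The predictive sugar biomarker maps total urinary sucrose + fructose through
a log-linear calibration with age and sex terms.  Resting energy expenditure
comes from the Weir equation on the mean of the last 10 minutes of the
VO2/VCO2 series; total energy expenditure adds activity energy expenditure
and removes the assumed 10% thermic effect of food.

Completeness of the 24-h urine collection is classified from PABA recovery:
85–110% complete, 50–<85% adjustable (analytes rescaled to the 93% reference
recovery), otherwise excluded.  :func:`apply_exclusions` implements the main
analysis rules (≥2 missed voids, >5% weight change) and the sensitivity
regimes (PABA adjustment, armband wear time, recall proximity to biomarker).

All derivations are pure functions of their inputs and the constants.
"""
from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd

from .config import BIOMARKER, DerivationConstants, TOOLS
from .errors import ConfigError, ContractError, InputError

PABA_COMPLETE = (85.0, 110.0)
PABA_ADJUSTABLE_MIN = 50.0

#: Nutrient columns derived from the 24-h urine collection.
URINARY_NUTRIENTS = ("protein", "potassium", "sodium", "total_sugars")

EXCLUSION_MODES = ("main", "paba_sensitivity", "wear_sensitivity", "proximity_sensitivity")


def classify_paba(recovery) -> np.ndarray | str:
    """Classify PABA recovery (%) as ``complete``/``adjustable``/``excluded``.

    Boundaries are inclusive at 50, 85 and 110: recovery of exactly 85 counts
    as complete, exactly 50 as adjustable.
    """
    arr = np.asarray(recovery, dtype=float)
    if np.any(arr < 0):
        raise InputError("PABA recovery must be non-negative")
    out = np.where(
        (arr >= PABA_COMPLETE[0]) & (arr <= PABA_COMPLETE[1]),
        "complete",
        np.where(arr >= PABA_ADJUSTABLE_MIN, "adjustable", "excluded"),
    )
    out = np.where(arr > PABA_COMPLETE[1], "excluded", out)
    if np.isscalar(recovery) or np.ndim(recovery) == 0:
        return str(out[()])
    return out


def paba_adjust(analyte_amount: float, recovery: float, constants: DerivationConstants | None = None) -> float:
    """Rescale a urinary analyte to the reference 93% PABA recovery.

    Only valid for adjustable collections (recovery 50–<85%); amounts from
    complete collections must pass through unchanged in the calling pipeline.
    """
    constants = constants or DerivationConstants()
    if classify_paba(recovery) != "adjustable":
        raise ContractError(
            f"paba_adjust called with non-adjustable recovery {recovery!r}"
        )
    return analyte_amount * 100.0 * constants.paba_excretion_fraction / recovery


def protein_from_nitrogen(urinary_nitrogen, constants: DerivationConstants | None = None,
                          ratio=None):
    """Protein intake (g/d) from 24-h urinary nitrogen (g).

    ``ratio`` overrides the nitrogen→protein conversion ratio per value, for
    food-source-specific ratios.
    """
    constants = constants or DerivationConstants()
    n = np.asarray(urinary_nitrogen, dtype=float)
    if np.any(n < 0):
        raise InputError("urinary nitrogen must be non-negative")
    r = constants.nitrogen_to_protein_ratio if ratio is None else np.asarray(ratio, float)
    out = n / constants.nitrogen_excretion_fraction * r
    return float(out) if np.ndim(urinary_nitrogen) == 0 else out


def mineral_from_urine(amount, excretion_fraction: float):
    """Mineral intake (g/d) from 24-h urinary excretion and its recovery fraction."""
    if not 0.0 < excretion_fraction <= 1.0:
        raise InputError("excretion fraction must lie in (0, 1]")
    a = np.asarray(amount, dtype=float)
    if np.any(a < 0):
        raise InputError("urinary amount must be non-negative")
    out = a / excretion_fraction
    return float(out) if np.ndim(amount) == 0 else out


def predict_total_sugars(sucrose, fructose, age, sex,
                         constants: DerivationConstants | None = None):
    """Predicted total sugar intake (g/d) from urinary sucrose + fructose (mg/24 h).

    ``exp(a + b*ln(sucrose+fructose) + c*age + d*I[female])`` with coefficients
    from :class:`DerivationConstants`.  A zero total excretion leaves the
    prediction undefined and raises rather than fabricating a value.
    """
    constants = constants or DerivationConstants()
    total = np.asarray(sucrose, dtype=float) + np.asarray(fructose, dtype=float)
    if np.any(total <= 0):
        raise InputError("sucrose + fructose must be > 0 for the sugar calibration")
    female = np.isin(np.asarray(sex, dtype=object), ["F", "f", "female"]).astype(float)
    out = np.exp(
        constants.sugar_intercept
        + constants.sugar_slope * np.log(total)
        + constants.sugar_age_coef * np.asarray(age, dtype=float)
        + constants.sugar_female_coef * female
    )
    return float(out) if np.ndim(out) == 0 else out


def _parse_series(series) -> np.ndarray:
    if isinstance(series, str):
        return np.array([float(v) for v in series.split(";")])
    return np.asarray(series, dtype=float)


def weir_ree(vo2_series, vco2_series, constants: DerivationConstants | None = None) -> float:
    """Resting energy expenditure (MJ/d) by the Weir equation.

    Uses the mean of the last 10 minutes of each gas series (earlier minutes
    are treated as equilibration and discarded), the standard Weir linear
    combination in kcal/min, scaled to 24 h and converted to MJ.
    """
    constants = constants or DerivationConstants()
    vo2 = _parse_series(vo2_series)
    vco2 = _parse_series(vco2_series)
    if len(vo2) < 10 or len(vco2) < 10:
        raise InputError("calorimetry series must contain at least 10 minutes")
    kcal_per_min = (
        constants.weir_vo2_kcal_per_l * vo2[-10:].mean()
        + constants.weir_vco2_kcal_per_l * vco2[-10:].mean()
    )
    return kcal_per_min * 1440.0 * constants.kcal_to_mj


def total_energy_expenditure(ree: float, aee: float,
                             constants: DerivationConstants | None = None) -> float:
    """TEE (MJ/d) from resting and activity expenditure, inflating for the
    thermic effect of food: ``(REE + AEE) / (1 - tef_fraction)``."""
    constants = constants or DerivationConstants()
    if constants.tef_fraction >= 1.0:
        raise ConfigError("tef_fraction must be < 1")
    if ree < 0 or aee < 0:
        raise InputError("REE and AEE must be non-negative")
    return (ree + aee) / (1.0 - constants.tef_fraction)


def derive_reference_intakes(
    dataset: pd.DataFrame,
    constants: DerivationConstants | None = None,
    nutrients: Iterable[str] = URINARY_NUTRIENTS + ("energy",),
) -> pd.DataFrame:
    """Recompute reference nutrient columns on biomarker rows from raw panels.

    Rows lacking the relevant raw measurements keep their existing values.
    Plasma concentrations are never converted to intakes; they pass through
    untouched for the ranking (ICC) analyses.
    """
    constants = constants or DerivationConstants()
    constants.validate()
    out = dataset.copy()
    bio = out["instrument"] == BIOMARKER
    idx = out.index[bio]
    nutrients = tuple(nutrients)

    def _set(col, values, mask):
        out.loc[idx[mask], col] = values[mask]

    if "protein" in nutrients and "urinary_nitrogen" in out.columns:
        nitrogen = out.loc[idx, "urinary_nitrogen"].to_numpy(float)
        ok = np.isfinite(nitrogen)
        ratio = None
        if "nitrogen_to_protein_ratio" in out.columns:
            ratio = out.loc[idx, "nitrogen_to_protein_ratio"].to_numpy(float)
            ratio = np.where(np.isfinite(ratio), ratio, constants.nitrogen_to_protein_ratio)
        vals = protein_from_nitrogen(np.where(ok, nitrogen, 0.0), constants, ratio=ratio)
        _set("protein", np.asarray(vals, float), ok)
    if "potassium" in nutrients and "urinary_potassium" in out.columns:
        k = out.loc[idx, "urinary_potassium"].to_numpy(float)
        ok = np.isfinite(k)
        vals = mineral_from_urine(np.where(ok, k, 0.0), constants.potassium_excretion_fraction)
        _set("potassium", np.asarray(vals, float), ok)
    if "sodium" in nutrients and "urinary_sodium" in out.columns:
        na = out.loc[idx, "urinary_sodium"].to_numpy(float)
        ok = np.isfinite(na)
        vals = mineral_from_urine(np.where(ok, na, 0.0), constants.sodium_excretion_fraction)
        _set("sodium", np.asarray(vals, float), ok)
    if "total_sugars" in nutrients and "urinary_sucrose" in out.columns:
        su = out.loc[idx, "urinary_sucrose"].to_numpy(float)
        fr = out.loc[idx, "urinary_fructose"].to_numpy(float)
        total = su + fr
        ok = np.isfinite(total) & (total > 0)
        if ok.any():
            vals = np.full(len(idx), np.nan)
            vals[ok] = predict_total_sugars(
                su[ok], fr[ok],
                out.loc[idx, "age"].to_numpy(float)[ok],
                out.loc[idx, "sex"].to_numpy()[ok],
                constants,
            )
            _set("total_sugars", vals, ok)
    if "energy" in nutrients and "vo2_series" in out.columns:
        vals = np.full(len(idx), np.nan)
        vo2 = out.loc[idx, "vo2_series"]
        aee = out.loc[idx, "aee"].to_numpy(float)
        for i, (row_vo2, row_vco2, row_aee) in enumerate(
            zip(vo2, out.loc[idx, "vco2_series"], aee)
        ):
            if isinstance(row_vo2, str) and np.isfinite(row_aee):
                ree = weir_ree(row_vo2, row_vco2, constants)
                vals[i] = total_energy_expenditure(ree, row_aee, constants)
        ok = np.isfinite(vals)
        _set("energy", vals, ok)
    return out


def apply_exclusions(
    dataset: pd.DataFrame,
    mode: str = "main",
    constants: DerivationConstants | None = None,
) -> pd.DataFrame:
    """Flag (and for PABA, adjust) records per the study's exclusion rules.

    Adds boolean columns ``excl_urinary``/``excl_tee``/``excl_recall`` with
    companion ``*_reason`` strings.  Main-mode rules always apply:

    * urinary-derived values excluded when ≥2 urine voids were missed;
    * TEE excluded at visits whose weight deviates >5% (strict) from the
      first appointment.

    ``paba_sensitivity`` additionally excludes collections with PABA recovery
    outside 50–110% and rescales urinary nitrogen, potassium and sodium (and
    their derived intakes) to 93% recovery where recovery is 50–<85%.
    ``wear_sensitivity`` excludes TEE when armband wear time is <23 h or
    >25 h (strict).  ``proximity_sensitivity`` excludes recall records dated
    within 24 h (calendar-day difference ≤1) of that participant-occasion's
    biomarker collection.
    """
    if mode not in EXCLUSION_MODES:
        raise InputError(f"unknown exclusion mode {mode!r}; expected one of {EXCLUSION_MODES}")
    constants = constants or DerivationConstants()
    out = dataset.copy()
    bio = out["instrument"] == BIOMARKER
    out["excl_urinary"] = False
    out["excl_urinary_reason"] = ""
    out["excl_tee"] = False
    out["excl_tee_reason"] = ""
    out["excl_recall"] = False
    out["excl_recall_reason"] = ""

    if "missed_voids" in out.columns:
        missed = bio & (out["missed_voids"].fillna(0) >= 2)
        out.loc[missed, "excl_urinary"] = True
        out.loc[missed, "excl_urinary_reason"] = "missed_voids>=2"

    # weight stability: compare each visit's weight with the first appointment
    first_weight = (
        out.loc[out["occasion"] == out.groupby("participant_id")["occasion"].transform("min")]
        .groupby("participant_id")["weight"]
        .first()
    )
    base = out["participant_id"].map(first_weight)
    unstable = bio & ((out["weight"] - base).abs() / base > 0.05)
    out.loc[unstable, "excl_tee"] = True
    out.loc[unstable, "excl_tee_reason"] = "weight_change>5%"

    if mode == "paba_sensitivity" and "paba_recovery" in out.columns:
        rec = out["paba_recovery"]
        status = pd.Series("", index=out.index, dtype=object)
        status[bio & rec.notna()] = classify_paba(rec[bio & rec.notna()].to_numpy())
        out["paba_status"] = status
        excl = bio & (status == "excluded")
        out.loc[excl, "excl_urinary"] = True
        out.loc[excl, "excl_urinary_reason"] = "paba_outside_50_110"
        adj = (bio & (status == "adjustable")).to_numpy()
        if adj.any():
            factor = (
                100.0 * constants.paba_excretion_fraction / out.loc[adj, "paba_recovery"]
            ).to_numpy(float)
            for col in ("urinary_nitrogen", "urinary_potassium", "urinary_sodium"):
                if col in out.columns:
                    out.loc[adj, col] = out.loc[adj, col].to_numpy(float) * factor
            # propagate to the linearly derived intakes
            for col in ("protein", "potassium", "sodium"):
                if col in out.columns:
                    out.loc[adj, col] = out.loc[adj, col].to_numpy(float) * factor

    if mode == "wear_sensitivity" and "wear_time" in out.columns:
        bad = bio & out["wear_time"].notna() & (
            (out["wear_time"] < 23.0) | (out["wear_time"] > 25.0)
        )
        out.loc[bad, "excl_tee"] = True
        out.loc[bad, "excl_tee_reason"] = "wear_time_outside_23_25"

    if mode == "proximity_sensitivity":
        bio_dates = out.loc[bio].set_index(["participant_id", "occasion"])["date"]
        bio_dates = bio_dates[~bio_dates.index.duplicated()]
        recall = out["instrument"].isin(TOOLS)
        key = pd.MultiIndex.from_frame(out.loc[recall, ["participant_id", "occasion"]])
        ref_date = pd.Series(bio_dates.reindex(key).to_numpy(), index=out.index[recall])
        delta = (out.loc[recall, "date"] - ref_date).dt.days.abs()
        near = delta <= 1
        near_idx = near[near.fillna(False)].index
        out.loc[near_idx, "excl_recall"] = True
        out.loc[near_idx, "excl_recall_reason"] = "within_24h_of_biomarker"

    return out


def mask_excluded(dataset: pd.DataFrame) -> pd.DataFrame:
    """Blank out nutrient values carried by excluded records.

    Urinary exclusions blank the urine-derived nutrients on biomarker rows,
    TEE exclusions blank reference energy, recall exclusions blank all
    nutrient values on the affected recall rows.
    """
    out = dataset.copy()
    if "excl_urinary" in out.columns:
        m = out["excl_urinary"].fillna(False).astype(bool)
        for col in URINARY_NUTRIENTS:
            if col in out.columns:
                out.loc[m, col] = np.nan
    if "excl_tee" in out.columns:
        m = out["excl_tee"].fillna(False).astype(bool)
        if "energy" in out.columns:
            out.loc[m, "energy"] = np.nan
    if "excl_recall" in out.columns:
        m = out["excl_recall"].fillna(False).astype(bool) & out["instrument"].isin(TOOLS)
        value_cols = [
            c for c in out.columns
            if c not in ("participant_id", "occasion", "date", "instrument",
                         "age", "sex", "weight", "bmi")
            and not c.startswith(("excl_", "paba_", "urinary_", "urine_", "vo2", "vco2",
                                  "plasma_", "aee", "wear_", "missed_"))
        ]
        out.loc[m, value_cols] = np.nan
    return out
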