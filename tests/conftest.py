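"""Shared fixtures: small study configurations and planted-violation datasets."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from dietval.config import (
    BIOMARKER,
    TOOL_INTERVIEWER,
    TOOL_ONLINE,
    default_config,
)

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


def protein_only_config(n_participants, seed, missingness=0.0):
    """Default protein truth (attenuation 0.30/0.38) with everything else dropped."""
    cfg = default_config(n_participants=n_participants, seed=seed)
    cfg.nutrients = {"protein": cfg.nutrients["protein"]}
    cfg.missingness = {k: missingness for k in cfg.missingness}
    return cfg


def noiseless_config(n_participants=40, seed=0):
    """Zero-noise, zero-bias study: both tools report exp(T) exactly."""
    cfg = default_config(n_participants=n_participants, seed=seed)
    for spec in cfg.nutrients.values():
        spec.truth.sigma2_within_ref = 0.0
        spec.rho_person_bias = 0.0
        for tb in spec.tools.values():
            tb.beta0 = 0.0
            tb.beta1 = 1.0
            tb.sigma2_person = 0.0
            tb.sigma2_within = 0.0
        if spec.plasma is not None:
            spec.plasma.intercept = spec.truth.mu
            spec.plasma.slope = 1.0
            spec.plasma.sigma2_within = 0.0
    # keep antioxidant tool values identical to their (noiseless) plasma values
    cfg.nutrients = {
        k: v for k, v in cfg.nutrients.items() if v.kind != "concentration"
    }
    cfg.missingness = {k: 0.0 for k in cfg.missingness}
    cfg.raw_signals.missed_void_probs = (0.0, 0.0)
    cfg.raw_signals.paba_sd = 0.0
    cfg.demographics.weight_visit_sd = 0.0
    return cfg


@pytest.fixture
def planted_violations():
    """Hand-built dataset with one violation of each exclusion rule.

    participant 1: 2 missed voids at occasion 1 (urinary exclusion, main mode)
    participant 2: +6.25% weight at occasion 3 (TEE exclusion, main mode)
    participant 3: 22-h armband wear at occasion 2 (wear-sensitivity exclusion)
    participant 4: online recall dated on the biomarker day (proximity exclusion)
    participant 5: clean
    """
    rows = []
    base = pd.Timestamp("2020-01-06")
    for pid in range(1, 6):
        weight = {1: 80.0, 2: 80.0, 3: 80.0}
        if pid == 2:
            weight[3] = 85.0  # +6.25%
        for occ in (1, 2, 3):
            bio_date = base + pd.Timedelta(days=14 * (occ - 1))
            rows.append(
                {
                    "participant_id": pid,
                    "occasion": occ,
                    "date": bio_date,
                    "instrument": BIOMARKER,
                    "age": 40.0,
                    "sex": "F",
                    "weight": weight[occ],
                    "bmi": 24.0,
                    "protein": 70.0,
                    "potassium": 2.5,
                    "sodium": 2.0,
                    "total_sugars": 90.0,
                    "energy": 10.0,
                    "missed_voids": 2.0 if (pid == 1 and occ == 1) else 0.0,
                    "wear_time": 22.0 if (pid == 3 and occ == 2) else 24.0,
                    "paba_recovery": 95.0,
                }
            )
            for inst, offset in ((TOOL_ONLINE, 2), (TOOL_INTERVIEWER, 5)):
                recall_offset = offset
                if pid == 4 and occ == 1 and inst == TOOL_ONLINE:
                    recall_offset = 0  # same day as the biomarker collection
                rows.append(
                    {
                        "participant_id": pid,
                        "occasion": occ,
                        "date": bio_date + pd.Timedelta(days=recall_offset),
                        "instrument": inst,
                        "age": 40.0,
                        "sex": "F",
                        "weight": weight[occ],
                        "bmi": 24.0,
                        "protein": 72.0,
                        "potassium": 2.6,
                        "sodium": 2.1,
                        "total_sugars": 85.0,
                        "energy": 9.0,
                        "missed_voids": np.nan,
                        "wear_time": np.nan,
                        "paba_recovery": np.nan,
                    }
                )
    return pd.DataFrame(rows)


def paired_dataset(tool_values, ref_values, nutrient="protein", tool=TOOL_ONLINE):
    """One-occasion paired tool/reference records for difference statistics."""
    rows = []
    for i, (a, b) in enumerate(zip(tool_values, ref_values), start=1):
        rows.append(
            {"participant_id": i, "occasion": 1, "instrument": tool, nutrient: a}
        )
        rows.append(
            {"participant_id": i, "occasion": 1, "instrument": BIOMARKER, nutrient: b}
        )
    return pd.DataFrame(rows)
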