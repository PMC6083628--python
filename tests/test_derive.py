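"""Biomarker derivation: converters vs hand oracles, PABA rules, exclusions."""
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import dietval as dv
from dietval.config import DerivationConstants
from dietval.derive import apply_exclusions, classify_paba, paba_adjust
from dietval.errors import ConfigError, ContractError, InputError


@pytest.mark.parametrize(
    "recovery,expected",
    [
        (95.0, "complete"),
        (85.0, "complete"),   # boundary inclusive
        (110.0, "complete"),
        (84.9, "adjustable"),
        (70.0, "adjustable"),
        (50.0, "adjustable"),  # boundary inclusive
        (49.9, "excluded"),
        (40.0, "excluded"),
        (110.1, "excluded"),
        (0.0, "excluded"),
    ],
)
def test_paba_classification(recovery, expected):
    assert classify_paba(recovery) == expected


def test_paba_classification_rejects_negative_and_vectorizes():
    with pytest.raises(InputError):
        classify_paba(-1.0)
    out = classify_paba(np.array([95.0, 70.0, 40.0]))
    assert list(out) == ["complete", "adjustable", "excluded"]


def test_paba_adjustment_is_93_over_recovery():
    assert paba_adjust(1.0, 70.0) == pytest.approx(93.0 / 70.0, rel=1e-12)
    assert paba_adjust(2.0, 50.0) == pytest.approx(3.72, rel=1e-12)
    # the rescale targets 93% recovery, so the factor tends to 1 there
    assert paba_adjust(1.0, 84.9) * 84.9 / 93.0 == pytest.approx(1.0, rel=1e-12)
    for bad in (95.0, 40.0):  # complete and excluded collections are out of contract
        with pytest.raises(ContractError):
            paba_adjust(1.0, bad)


@pytest.mark.parametrize(
    "fn,args,expected",
    [
        (dv.protein_from_nitrogen, (0.0,), 0.0),
        (dv.protein_from_nitrogen, (8.86,), 8.86 / 0.81 * 6.25),
        (dv.protein_from_nitrogen, (10.0,), 10.0 / 0.81 * 6.25),
        (dv.mineral_from_urine, (0.0, 0.80), 0.0),
        (dv.mineral_from_urine, (1.68, 0.80), 1.68 / 0.80),
        (dv.mineral_from_urine, (1.72, 0.86), 1.72 / 0.86),
    ],
)
def test_recovery_converters_match_oracles(fn, args, expected):
    assert fn(*args) == pytest.approx(expected, rel=1e-12, abs=1e-15)


def test_mineral_rejects_bad_fraction():
    with pytest.raises(InputError):
        dv.mineral_from_urine(1.0, 0.0)


def test_sugar_calibration_identity_and_hand_oracle():
    ident = DerivationConstants(
        sugar_intercept=0.0, sugar_slope=1.0, sugar_age_coef=0.0, sugar_female_coef=0.0
    )
    assert dv.predict_total_sugars(60.0, 40.0, age=30, sex="F", constants=ident) == pytest.approx(100.0)
    c = DerivationConstants(
        sugar_intercept=2.0, sugar_slope=0.5, sugar_age_coef=0.0, sugar_female_coef=0.0
    )
    assert dv.predict_total_sugars(250.0, 150.0, age=50, sex="M", constants=c) == pytest.approx(
        math.exp(2.0 + 0.5 * math.log(400.0)), rel=1e-12
    )
    with pytest.raises(InputError):
        dv.predict_total_sugars(0.0, 0.0, age=30, sex="F")


def test_weir_ree_uses_last_ten_minutes():
    const = [0.25] * 15, [0.20] * 15
    expected = (3.941 * 0.25 + 1.106 * 0.20) * 1440 * 0.004184
    assert dv.weir_ree(*const) == pytest.approx(expected, rel=1e-12)
    # a noisy settling phase in the first 5 minutes must not matter
    noisy = [0.50] * 5 + [0.25] * 10
    assert dv.weir_ree(noisy, [0.20] * 15) == pytest.approx(expected, rel=1e-12)
    assert dv.weir_ree([0.0] * 15, [0.0] * 15) == 0.0
    with pytest.raises(InputError):
        dv.weir_ree([0.25] * 9, [0.20] * 9)


def test_total_energy_expenditure_oracles():
    assert dv.total_energy_expenditure(0.0, 0.0) == 0.0
    assert dv.total_energy_expenditure(7.0, 2.9) == pytest.approx(11.0, rel=1e-12)
    assert dv.total_energy_expenditure(6.3, 2.7) == pytest.approx(10.0, rel=1e-12)
    with pytest.raises(ConfigError):
        dv.total_energy_expenditure(7.0, 2.9, DerivationConstants(tef_fraction=1.0))


@given(
    a=st.floats(min_value=0.0, max_value=50.0),
    b=st.floats(min_value=0.0, max_value=50.0),
)
def test_converters_are_monotone_in_the_analyte(a, b):
    lo, hi = sorted((a, b))
    assert dv.protein_from_nitrogen(lo) <= dv.protein_from_nitrogen(hi)
    assert dv.mineral_from_urine(lo, 0.8) <= dv.mineral_from_urine(hi, 0.8)
    if lo > 0:
        assert dv.predict_total_sugars(lo, 0.0, 40, "F") <= dv.predict_total_sugars(hi, 0.0, 40, "F")


class TestExclusions:
    def test_unknown_mode_rejected(self, planted_violations):
        with pytest.raises(InputError):
            apply_exclusions(planted_violations, mode="bogus")

    def test_main_mode_flags_missed_voids_and_weight_change(self, planted_violations):
        out = apply_exclusions(planted_violations, mode="main")
        urinary = out[out["excl_urinary"]]
        assert set(zip(urinary["participant_id"], urinary["occasion"])) == {(1, 1)}
        tee = out[out["excl_tee"]]
        assert set(zip(tee["participant_id"], tee["occasion"])) == {(2, 3)}
        assert not out["excl_recall"].any()

    def test_single_missed_void_is_retained(self, planted_violations):
        df = planted_violations.copy()
        df.loc[(df.participant_id == 1) & (df.occasion == 1), "missed_voids"] = 1.0
        out = apply_exclusions(df, mode="main")
        assert not out["excl_urinary"].any()

    def test_wear_sensitivity_excludes_short_wear_only(self, planted_violations):
        out = apply_exclusions(planted_violations, mode="wear_sensitivity")
        tee = out[out["excl_tee_reason"] == "wear_time_outside_23_25"]
        assert set(zip(tee["participant_id"], tee["occasion"])) == {(3, 2)}

    def test_proximity_sensitivity_excludes_same_day_recall(self, planted_violations):
        out = apply_exclusions(planted_violations, mode="proximity_sensitivity")
        rec = out[out["excl_recall"]]
        assert set(
            zip(rec["participant_id"], rec["occasion"], rec["instrument"])
        ) == {(4, 1, dv.TOOL_ONLINE)}

    def test_paba_sensitivity_adjusts_and_excludes(self, planted_violations):
        df = planted_violations.copy()
        bio = df["instrument"] == "biomarker"
        df.loc[bio & (df.participant_id == 3) & (df.occasion == 1), "paba_recovery"] = 70.0
        df.loc[bio & (df.participant_id == 5) & (df.occasion == 1), "paba_recovery"] = 40.0
        out = apply_exclusions(df, mode="paba_sensitivity")
        adjusted = out[(out.participant_id == 3) & (out.occasion == 1) & bio]
        assert adjusted["protein"].iloc[0] == pytest.approx(70.0 * 93.0 / 70.0)
        excluded = out[(out.participant_id == 5) & (out.occasion == 1) & bio]
        assert excluded["excl_urinary"].all()
        untouched = out[(out.participant_id == 2) & (out.occasion == 1) & bio]
        assert untouched["protein"].iloc[0] == 70.0


def test_derivation_is_pure(planted_violations):
    cfg = dv.default_config(n_participants=10, seed=4)
    ds = dv.generate_validation_study(cfg)
    a = dv.derive_reference_intakes(ds)
    b = dv.derive_reference_intakes(ds)
    pd.testing.assert_frame_equal(a, b)
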