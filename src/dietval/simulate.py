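"""Synthetic validation-study generator.

Generates complete studies — participant covariates, self-reported intakes
from two 24-h recall tools, and raw biomarker panels (24-h urine, indirect
calorimetry, accelerometry, plasma antioxidants) — with the statistical
structure the downstream measurement-error analysis assumes:

* latent usual log intake ``T_i ~ N(mu, sigma2_between)`` per nutrient;
* reference (biomarker) log value ``T_i + u_ij`` with independent
  within-person error;
* tool ``m`` log value ``beta0_m + beta1_m*T_i + r_im + eps_ijm`` where the
  person-specific biases ``(r_iA, r_iB)`` are bivariate normal and correlated
  between tools;
* raw signals constructed by inverting the derivation equations, so that
  derivation with default constants reproduces the intended reference intakes
  exactly for occasions with complete PABA recovery;
* missing-at-random record deletion, independent of all latent quantities.

Everything is driven by a single seed through ``numpy.random.SeedSequence``,
so identical configurations give byte-identical datasets.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .config import (
    BIOMARKER,
    PLASMA_COLUMNS,
    SimulationConfig,
    DerivationConstants,
    TOOLS,
)
from .errors import ConfigError, InputError

#: Calendar anchor for simulated study dates.
STUDY_ANCHOR = np.datetime64("2020-01-06")

RAW_COLUMNS = [
    "urine_volume",
    "urinary_nitrogen",
    "urinary_potassium",
    "urinary_sodium",
    "urinary_sucrose",
    "urinary_fructose",
    "paba_recovery",
    "missed_voids",
    "vo2_series",
    "vco2_series",
    "aee",
    "wear_time",
] + list(PLASMA_COLUMNS.values())

ID_COLUMNS = ["participant_id", "occasion", "date", "instrument"]
COVARIATE_COLUMNS = ["age", "sex", "weight", "bmi"]


def _generate_participants(config: SimulationConfig, rng: np.random.Generator) -> dict:
    n, k = config.n_participants, config.n_occasions
    demo = config.demographics
    age = rng.uniform(*demo.age_range, size=n)
    sex = np.where(rng.random(n) < demo.female_fraction, "F", "M")
    weight0 = np.empty(n)
    bmi = np.empty(n)
    for s in ("M", "F"):
        m = sex == s
        weight0[m] = rng.normal(demo.weight_mean[s], demo.weight_sd[s], m.sum())
        bmi[m] = rng.normal(demo.bmi_mean[s], demo.bmi_sd[s], m.sum())
    weight0 = np.clip(weight0, 40.0, None)
    bmi = np.clip(bmi, 16.0, 45.0)
    # weight at each visit: the first-appointment weight, then relative drift
    weight = np.tile(weight0[:, None], (1, k))
    if k > 1:
        drift = rng.normal(0.0, demo.weight_visit_sd, size=(n, k - 1))
        weight[:, 1:] = weight0[:, None] * (1.0 + drift)

    lo, hi = config.occasion_spacing_days
    spacing = rng.integers(lo, hi + 1, size=(n, k))
    spacing[:, 0] = rng.integers(0, 61, size=n)  # staggered recruitment
    bio_day = np.cumsum(spacing, axis=1)
    first_offset = rng.integers(1, 4, size=(n, k))      # reference then 1-3 d later
    second_offset = first_offset + rng.integers(2, 5, size=(n, k))
    online_first = rng.random(n) < 0.5                  # randomised tool order

    return {
        "age": age,
        "sex": sex,
        "weight": weight,
        "bmi": bmi,
        "bio_day": bio_day,
        "first_offset": first_offset,
        "second_offset": second_offset,
        "online_first": online_first,
    }


def generate_validation_study(
    config: SimulationConfig,
    include_raw: bool = True,
    return_latents: bool = False,
):
    """Generate a complete synthetic validation study.

    Returns a long-format :class:`pandas.DataFrame` with one row per
    participant × occasion × instrument.  Biomarker rows carry the intended
    reference intakes in the nutrient columns plus, when ``include_raw``, a
    raw biomarker panel consistent with those intakes.  Missingness per
    ``config.missingness`` is applied last.

    With ``return_latents`` the per-participant latent usual log intakes are
    returned alongside (useful for simulation-truth checks).
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rng_part, rng_val, rng_raw, rng_miss = (np.random.default_rng(s) for s in ss.spawn(4))

    n, k = config.n_participants, config.n_occasions
    part = _generate_participants(config, rng_part)

    latents: dict[str, np.ndarray] = {}
    values = {inst: {} for inst in (*TOOLS, BIOMARKER)}
    plasma = {}
    for name, spec in config.nutrients.items():
        t = spec.truth
        T = t.mu + np.sqrt(t.sigma2_between) * rng_val.standard_normal(n)
        latents[name] = T
        # person-specific biases, correlated across the two tools
        tools = list(spec.tools)
        cov = np.array(
            [
                [spec.tools[tools[0]].sigma2_person, spec.sigma_person_cross],
                [spec.sigma_person_cross, spec.tools[tools[-1]].sigma2_person],
            ]
        )
        # exact PSD square root (handles zero variances and |rho| = 1 exactly)
        eigval, eigvec = np.linalg.eigh(cov)
        if np.min(eigval) < -1e-12 * max(np.trace(cov), 1.0):
            raise ConfigError(
                f"person-bias covariance for nutrient {name!r} (tools {tools}) "
                "is not positive semi-definite"
            )
        root = eigvec * np.sqrt(np.clip(eigval, 0.0, None))
        r = rng_val.standard_normal((n, 2)) @ root.T
        for j, tool in enumerate(tools):
            tb = spec.tools[tool]
            eps = np.sqrt(tb.sigma2_within) * rng_val.standard_normal((n, k))
            values[tool][name] = np.exp(tb.beta0 + tb.beta1 * T[:, None] + r[:, [j]] + eps)
        if spec.kind == "concentration":
            pc = spec.plasma
            if pc is None:
                raise ConfigError(f"concentration nutrient {name!r} needs plasma coupling")
            w = np.sqrt(pc.sigma2_within) * rng_val.standard_normal((n, k))
            plasma[name] = np.exp(pc.intercept + pc.slope * (T[:, None] - t.mu) + w)
            values[BIOMARKER][name] = np.full((n, k), np.nan)
        else:
            u = np.sqrt(t.sigma2_within_ref) * rng_val.standard_normal((n, k))
            values[BIOMARKER][name] = np.exp(T[:, None] + u)

    frames = []
    pid = np.repeat(np.arange(1, n + 1), k)
    occ = np.tile(np.arange(1, k + 1), n)
    for inst in (BIOMARKER, *TOOLS):
        if inst == BIOMARKER:
            day = part["bio_day"]
        else:
            first = (inst == TOOLS[0]) == part["online_first"][:, None]
            day = part["bio_day"] + np.where(
                first, part["first_offset"], part["second_offset"]
            )
        df = pd.DataFrame(
            {
                "participant_id": pid,
                "occasion": occ,
                "date": STUDY_ANCHOR + day.ravel().astype("timedelta64[D]"),
                "instrument": inst,
                "age": np.repeat(part["age"], k),
                "sex": np.repeat(part["sex"], k),
                "weight": part["weight"].ravel(),
                "bmi": np.repeat(part["bmi"], k),
            }
        )
        for name in config.nutrients:
            df[name] = values[inst][name].ravel()
        if inst == BIOMARKER:
            for name, conc in plasma.items():
                df[PLASMA_COLUMNS[name]] = conc.ravel()
        frames.append(df)
    dataset = pd.concat(frames, ignore_index=True)
    dataset = dataset.sort_values(["participant_id", "occasion", "instrument"]).reset_index(
        drop=True
    )

    if include_raw:
        dataset = generate_raw_panels(dataset, config, rng=rng_raw)
    dataset = apply_mar_missingness(dataset, config.missingness, rng=rng_miss)
    if return_latents:
        return dataset, latents
    return dataset


def generate_raw_panels(
    dataset: pd.DataFrame,
    config: SimulationConfig,
    constants: DerivationConstants | None = None,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Attach raw biomarker panels to the biomarker rows of ``dataset``.

    The raw signals invert the derivation equations: urinary nitrogen is the
    target protein divided by the nitrogen→protein ratio times the 81%
    excretion fraction, and so on.  Collections with PABA recovery below the
    complete range (85%) have their urinary analytes scaled by
    ``recovery / 93`` to emulate under-collection; complete collections are
    left exact so derivation reproduces the intended intakes.
    """
    constants = constants or DerivationConstants()
    constants.validate()
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([0 if seed is None else seed, 1]))
    raw = config.raw_signals
    out = dataset.copy()
    for col in RAW_COLUMNS:
        if col not in out.columns:
            if col in ("vo2_series", "vco2_series"):
                out[col] = pd.Series(np.nan, index=out.index, dtype=object)
            else:
                out[col] = np.nan
    bio = out["instrument"] == BIOMARKER
    nb = int(bio.sum())
    if nb == 0:
        raise InputError("dataset has no biomarker rows to attach raw panels to")

    out.loc[bio, "urine_volume"] = np.exp(
        rng.normal(raw.urine_volume_log_mean, raw.urine_volume_log_sd, nb)
    )
    recovery = np.clip(rng.normal(raw.paba_mean, raw.paba_sd, nb), 5.0, 120.0)
    out.loc[bio, "paba_recovery"] = recovery
    p1, p2 = raw.missed_void_probs
    out.loc[bio, "missed_voids"] = rng.choice(
        [0, 1, 2], size=nb, p=[1.0 - p1 - p2, p1, p2]
    ).astype(float)
    # under-collected urine loses analytes proportionally to the PABA shortfall;
    # collections in the complete range are left exact
    undercollect = np.where(recovery < 85.0, recovery / 93.0, 1.0)

    kinds = {name: spec.kind for name, spec in config.nutrients.items()}
    for name, kind in kinds.items():
        if kind == "recovery":
            target = out.loc[bio, name].to_numpy(float)
            if name == "protein":
                amount = target / constants.nitrogen_to_protein_ratio
                amount *= constants.nitrogen_excretion_fraction
                out.loc[bio, "urinary_nitrogen"] = amount * undercollect
            elif name == "potassium":
                out.loc[bio, "urinary_potassium"] = (
                    target * constants.potassium_excretion_fraction * undercollect
                )
            elif name == "sodium":
                out.loc[bio, "urinary_sodium"] = (
                    target * constants.sodium_excretion_fraction * undercollect
                )
        elif kind == "predictive":
            target = out.loc[bio, name].to_numpy(float)
            age = out.loc[bio, "age"].to_numpy(float)
            female = (out.loc[bio, "sex"] == "F").to_numpy()
            log_excretion = (
                np.log(target)
                - constants.sugar_intercept
                - constants.sugar_age_coef * age
                - constants.sugar_female_coef * female
            ) / constants.sugar_slope
            excretion = np.exp(log_excretion)  # mg/24 h of sucrose + fructose
            frac = rng.uniform(*raw.sucrose_fraction_range, nb)
            out.loc[bio, "urinary_sucrose"] = frac * excretion * undercollect
            out.loc[bio, "urinary_fructose"] = (1.0 - frac) * excretion * undercollect
        elif kind == "energy":
            tee = out.loc[bio, name].to_numpy(float)
            aee = np.clip(rng.normal(raw.aee_mean, raw.aee_sd, nb), 0.5, None)
            ree = (1.0 - constants.tef_fraction) * tee - aee
            low = ree < 1.0  # keep resting expenditure physiological
            aee[low] = (1.0 - constants.tef_fraction) * tee[low] - 1.0
            ree[low] = 1.0
            rq = np.clip(rng.normal(raw.rq_mean, raw.rq_sd, nb), 0.7, 1.0)
            kcal_per_min = ree / constants.kcal_to_mj / 1440.0
            vo2 = kcal_per_min / (
                constants.weir_vo2_kcal_per_l + constants.weir_vco2_kcal_per_l * rq
            )
            vco2 = rq * vo2
            m = raw.calorimetry_minutes
            settle = m - 10
            series_vo2 = np.tile(vo2[:, None], (1, m))
            series_vco2 = np.tile(vco2[:, None], (1, m))
            if settle > 0:
                # settling noise in the discarded first minutes only, so the
                # last-10-minute mean recovers REE exactly
                noise = 1.0 + np.abs(rng.normal(0.0, raw.calorimetry_settle_sd, (nb, settle)))
                series_vo2[:, :settle] *= noise
                series_vco2[:, :settle] *= noise
            out.loc[bio, "vo2_series"] = [
                ";".join(repr(float(v)) for v in row) for row in series_vo2
            ]
            out.loc[bio, "vco2_series"] = [
                ";".join(repr(float(v)) for v in row) for row in series_vco2
            ]
            out.loc[bio, "aee"] = aee
            out.loc[bio, "wear_time"] = rng.normal(raw.wear_time_mean, raw.wear_time_sd, nb)
    return out


def apply_mar_missingness(
    dataset: pd.DataFrame,
    probs: dict[str, float],
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Delete records independently at random, per instrument.

    Deletion depends on nothing but the instrument label and the random
    stream, so the mechanism is missing completely at random — a special case
    of the missing-at-random assumption the model fit relies on.
    """
    for inst, p in probs.items():
        if not 0.0 <= p <= 1.0:
            raise ConfigError(f"missingness probability for {inst!r} outside [0, 1]")
    if rng is None:
        rng = np.random.default_rng(seed)
    keep = np.ones(len(dataset), dtype=bool)
    for inst, p in probs.items():
        mask = (dataset["instrument"] == inst).to_numpy()
        keep[mask] = rng.random(int(mask.sum())) >= p
    return dataset.loc[keep].reset_index(drop=True)
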