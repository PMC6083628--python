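"""Study configuration: simulation truth, derivation constants, instrument labels.

The simulation truth is parameterized on the natural-log scale.  For each
nutrient a participant has a latent usual intake ``T ~ N(mu, sigma2_between)``;
the reference (recovery biomarker or energy-expenditure surrogate) observes
``T + u`` with within-person variance ``sigma2_within_ref``, while a
self-report tool observes ``beta0 + beta1*T + r + eps`` with a person-specific
bias ``r`` (variance ``sigma2_person``, correlated between the two tools) and
independent within-person error ``eps`` (variance ``sigma2_within``).

Default parameter values emulate a validation study of an online 24-h recall
against an interviewer-administered multiple-pass recall and recovery
biomarkers (~200 adults, 3 occasions two weeks apart).  They are chosen so
that, e.g., the online tool's single-administration attenuation factor for
protein is 0.30 with correlation 0.43 against usual intake.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

from .errors import ConfigError

#: Instrument labels used in the long-format dataset.
TOOL_ONLINE = "online_recall"
TOOL_INTERVIEWER = "interviewer_recall"
BIOMARKER = "biomarker"
TOOLS = (TOOL_ONLINE, TOOL_INTERVIEWER)
INSTRUMENTS = (TOOL_ONLINE, TOOL_INTERVIEWER, BIOMARKER)

#: Nutrients with an absolute reference measure (units: g/d except energy MJ/d).
MAIN_NUTRIENTS = ("protein", "potassium", "sodium", "total_sugars", "energy")
#: Nutrients validated through plasma concentration biomarkers (ranking only).
ANTIOXIDANTS = ("beta_carotene", "vitamin_c", "vitamin_e")

#: Column holding the plasma concentration for a concentration biomarker.
PLASMA_COLUMNS = {n: f"plasma_{n}" for n in ANTIOXIDANTS}


@dataclass
class TruthParams:
    """Latent usual-intake distribution and reference error, log scale."""

    mu: float
    sigma2_between: float
    sigma2_within_ref: float

    def validate(self, name: str) -> None:
        if self.sigma2_between < 0 or self.sigma2_within_ref < 0:
            raise ConfigError(f"negative variance in truth parameters for {name!r}")


@dataclass
class ToolBias:
    """Self-report bias structure for one tool and nutrient, log scale."""

    beta0: float
    beta1: float
    sigma2_person: float
    sigma2_within: float

    def validate(self, name: str, tool: str) -> None:
        if self.sigma2_person < 0 or self.sigma2_within < 0:
            raise ConfigError(f"negative variance for tool {tool!r}, nutrient {name!r}")


@dataclass
class PlasmaCoupling:
    """Concentration biomarker: log plasma = intercept + slope*(T - mu) + noise."""

    intercept: float
    slope: float = 0.8
    sigma2_within: float = 0.08


@dataclass
class NutrientSpec:
    """Truth, per-tool bias and (optionally) a plasma coupling for one nutrient.

    ``kind`` drives raw-signal generation and derivation:
    ``recovery`` (urinary N/K/Na), ``predictive`` (urinary sugars),
    ``energy`` (TEE from calorimetry + accelerometry), ``concentration``
    (plasma biomarker; ranking analyses only).
    """

    truth: TruthParams
    tools: dict[str, ToolBias]
    kind: str = "recovery"
    rho_person_bias: float = 0.5
    plasma: PlasmaCoupling | None = None

    def validate(self, name: str) -> None:
        self.truth.validate(name)
        for tool, tb in self.tools.items():
            tb.validate(name, tool)
        if not -1.0 <= self.rho_person_bias <= 1.0:
            raise ConfigError(
                f"person-bias correlation for {name!r} outside [-1, 1]; the implied "
                "cross-tool covariance is not positive semi-definite"
            )
        if self.kind not in ("recovery", "predictive", "energy", "concentration"):
            raise ConfigError(f"unknown nutrient kind {self.kind!r} for {name!r}")

    @property
    def sigma_person_cross(self) -> float:
        """Covariance of the two tools' person-specific biases."""
        tools = list(self.tools.values())
        if len(tools) < 2:
            return 0.0
        return self.rho_person_bias * math.sqrt(
            tools[0].sigma2_person * tools[1].sigma2_person
        )


@dataclass
class DemographicsModel:
    """Participant covariate distributions (age, sex, weight, BMI)."""

    age_range: tuple[float, float] = (18.0, 65.0)
    female_fraction: float = 0.60
    weight_mean: dict[str, float] = field(default_factory=lambda: {"M": 81.0, "F": 67.0})
    weight_sd: dict[str, float] = field(default_factory=lambda: {"M": 13.0, "F": 13.0})
    bmi_mean: dict[str, float] = field(default_factory=lambda: {"M": 26.0, "F": 25.0})
    bmi_sd: dict[str, float] = field(default_factory=lambda: {"M": 4.0, "F": 5.0})
    # relative SD of per-visit weight around the first-appointment weight;
    # 0.02 plants a realistic few percent of >5% weight changes
    weight_visit_sd: float = 0.02

    def validate(self) -> None:
        if not 0.0 <= self.female_fraction <= 1.0:
            raise ConfigError("female_fraction must lie in [0, 1]")
        if self.weight_visit_sd < 0:
            raise ConfigError("weight_visit_sd must be >= 0")


@dataclass
class RawSignalModel:
    """Distributions of raw biomarker signals (before derivation).

    Noise here is attached multiplicatively on the measurement scale so that
    all generated signals stay positive.
    """

    urine_volume_log_mean: float = math.log(1.6)   # L/24 h
    urine_volume_log_sd: float = 0.25
    paba_mean: float = 95.0                        # % recovery
    paba_sd: float = 7.0
    # P(missed_voids = 1), P(missed_voids = 2)
    missed_void_probs: tuple[float, float] = (0.02, 0.01)
    sucrose_fraction_range: tuple[float, float] = (0.35, 0.65)
    rq_mean: float = 0.85                          # VCO2/VO2 during calorimetry
    rq_sd: float = 0.03
    calorimetry_settle_sd: float = 0.10            # relative noise, first 5 min
    calorimetry_minutes: int = 15
    aee_mean: float = 2.9                          # MJ/24 h
    aee_sd: float = 0.6
    wear_time_mean: float = 24.0                   # h
    wear_time_sd: float = 0.4

    def validate(self) -> None:
        p1, p2 = self.missed_void_probs
        if min(p1, p2) < 0 or p1 + p2 > 1:
            raise ConfigError("missed_void_probs must be non-negative with sum <= 1")
        if self.calorimetry_minutes < 10:
            raise ConfigError("calorimetry series must be at least 10 minutes")


@dataclass
class SimulationConfig:
    """Full generative description of a synthetic validation study."""

    n_participants: int = 212
    n_occasions: int = 3
    nutrients: dict[str, NutrientSpec] = field(default_factory=dict)
    missingness: dict[str, float] = field(
        default_factory=lambda: {TOOL_ONLINE: 0.02, TOOL_INTERVIEWER: 0.07, BIOMARKER: 0.09}
    )
    demographics: DemographicsModel = field(default_factory=DemographicsModel)
    raw_signals: RawSignalModel = field(default_factory=RawSignalModel)
    occasion_spacing_days: tuple[int, int] = (12, 16)  # inclusive; ~2 weeks apart
    seed: int | None = None

    def validate(self) -> None:
        if self.n_participants < 1:
            raise ConfigError("n_participants must be >= 1")
        if self.n_occasions < 1:
            raise ConfigError("n_occasions must be >= 1")
        if not self.nutrients:
            raise ConfigError("at least one nutrient must be configured")
        for name, spec in self.nutrients.items():
            spec.validate(name)
        for instrument, p in self.missingness.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(
                    f"missingness probability for {instrument!r} outside [0, 1]"
                )
        self.demographics.validate()
        self.raw_signals.validate()

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class DerivationConstants:
    """Constants converting raw biomarker signals to reference intakes.

    Excretion fractions: 93% of a PABA dose, 81% of dietary nitrogen, 80% of
    potassium and 86% of sodium appear in a complete 24-h urine collection.
    The nitrogen→protein ratio defaults to the generic 6.25 and can be
    overridden per record for food-source-specific ratios.  Weir coefficients
    are the standard published kcal/L values with the protein correction
    omitted.  The sugar calibration coefficients are synthetic placeholders
    (the published calibration is not reproduced here); they are configurable.
    """

    paba_excretion_fraction: float = 0.93
    nitrogen_excretion_fraction: float = 0.81
    potassium_excretion_fraction: float = 0.80
    sodium_excretion_fraction: float = 0.86
    nitrogen_to_protein_ratio: float = 6.25
    tef_fraction: float = 0.10
    weir_vo2_kcal_per_l: float = 3.941
    weir_vco2_kcal_per_l: float = 1.106
    kcal_to_mj: float = 4.184e-3
    sugar_intercept: float = 2.26
    sugar_slope: float = 0.5
    sugar_age_coef: float = 0.005
    sugar_female_coef: float = -0.05

    def validate(self) -> None:
        for name in (
            "paba_excretion_fraction",
            "nitrogen_excretion_fraction",
            "potassium_excretion_fraction",
            "sodium_excretion_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ConfigError(f"{name} must lie in (0, 1]")
        if self.nitrogen_to_protein_ratio <= 0:
            raise ConfigError("nitrogen_to_protein_ratio must be > 0")
        if self.tef_fraction >= 1.0:
            raise ConfigError("tef_fraction must be < 1")


def _spec(mu, s2T, s2u, a, b, kind="recovery", rho=0.5, plasma=None):
    (b0a, b1a, ra, ea), (b0b, b1b, rb, eb) = a, b
    return NutrientSpec(
        truth=TruthParams(mu=mu, sigma2_between=s2T, sigma2_within_ref=s2u),
        tools={
            TOOL_ONLINE: ToolBias(b0a, b1a, ra, ea),
            TOOL_INTERVIEWER: ToolBias(b0b, b1b, rb, eb),
        },
        kind=kind,
        rho_person_bias=rho,
        plasma=plasma,
    )


def default_config(n_participants: int = 212, seed: int | None = None) -> SimulationConfig:
    """Default simulation truth for the standard study conditions.

    Per nutrient the tool parameters are solved from a target attenuation
    factor λ and correlation ρ via ``beta1 = ρ²/λ`` and total single-day
    variance ``V = beta1·σ²_T/λ``; intercepts are set so the tools' geometric
    means match realistic first-visit intakes (e.g. reference protein 68.4 g,
    online tool 70.5 g, interviewer tool 81.7 g).
    """
    nutrients = {
        # protein: λ 0.30/0.38, ρ 0.43/0.48 — the primary recovery-biomarker nutrient
        "protein": _spec(
            math.log(68.4), 0.09, 0.04,
            (1.65157, 0.61633, 0.020715, 0.13),
            (1.84125, 0.60632, 0.015519, 0.095),
        ),
        # potassium: λ 0.31/0.35, ρ 0.40/0.38
        "potassium": _spec(
            math.log(2.1), 0.09, 0.04,
            (0.61030, 0.51613, 0.015868, 0.11),
            (0.82529, 0.41257, 0.012770, 0.078),
        ),
        # sodium: λ 0.21/0.22, ρ 0.30/0.28
        "sodium": _spec(
            math.log(1.8), 0.09, 0.04,
            (0.58100, 0.42857, 0.017143, 0.15),
            (0.66600, 0.35636, 0.014355, 0.12),
        ),
        # total sugars: λ 0.15/0.25, ρ 0.24/0.31; predictive biomarker is noisier
        "total_sugars": _spec(
            math.log(128.3), 0.09, 0.06,
            (2.42364, 0.38400, 0.027129, 0.19),
            (2.64484, 0.38440, 0.020085, 0.105),
            kind="predictive",
        ),
        # energy: reference is TEE (MJ/d); λ 0.19/0.32, ρ 0.29/0.37
        "energy": _spec(
            math.log(11.0), 0.04, 0.01,
            (0.95348, 0.44263, 0.010348, 0.075),
            (1.11422, 0.42781, 0.010155, 0.036),
            kind="energy",
        ),
    }
    # concentration biomarkers: episodically consumed, highly variable day to day
    for name, (mu, b0a, b0b, plasma_gm) in {
        "beta_carotene": (0.0, math.log(0.65), math.log(1.53), 0.59),
        "vitamin_c": (math.log(70.0), math.log(59.0) - math.log(70.0),
                      math.log(75.0) - math.log(70.0), 60.0),
        "vitamin_e": (math.log(2.0), math.log(1.6) - math.log(2.0),
                      math.log(2.3) - math.log(2.0), 37.0),
    }.items():
        nutrients[name] = NutrientSpec(
            truth=TruthParams(mu=mu, sigma2_between=0.35, sigma2_within_ref=0.0),
            tools={
                TOOL_ONLINE: ToolBias(b0a, 1.0, 0.05, 0.50),
                TOOL_INTERVIEWER: ToolBias(b0b, 1.0, 0.05, 0.50),
            },
            kind="concentration",
            rho_person_bias=0.5,
            plasma=PlasmaCoupling(intercept=math.log(plasma_gm)),
        )
    return SimulationConfig(n_participants=n_participants, nutrients=nutrients, seed=seed)
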