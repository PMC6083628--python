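"""End-to-end analysis pipeline: exclusions → derivation → model → agreement.

The main analysis reproduces the shape of a full validation report:

* first-visit geometric means with 95% CIs per instrument × nutrient;
* attenuation factors, correlations with true intake and mean % differences
  (with CIs) per tool × nutrient, for intakes and nutrient densities;
* repeat-administration projections (k = 1, 2, 4, 7);
* between-tool agreement (log Bland–Altman + ICC) and plasma-vs-intake ICCs
  for the concentration biomarkers.

Stratified analyses are independent re-fits on subsets; sensitivity analyses
re-run the main analysis under the corresponding exclusion regimes.  All
randomness (bootstraps) flows from the configured seed.
"""
from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import __version__
from .config import (
    ANTIOXIDANTS,
    BIOMARKER,
    MAIN_NUTRIENTS,
    PLASMA_COLUMNS,
    DerivationConstants,
    SimulationConfig,
    TOOLS,
    default_config,
)
from .derive import apply_exclusions, derive_reference_intakes, mask_excluded
from .errors import ConfigError, ConvergenceError, InputError, UndefinedResultError
from .agreement import bland_altman_log, fit_two_way_mixed, icc_absolute
from .mem import (
    attenuation_factor,
    correlation_with_truth,
    derived_ci,
    fit_mem,
    mean_pct_difference,
)
from .io import read_dataset, write_dataset
from .simulate import generate_validation_study

log = logging.getLogger("dietval")

DENSITY_NUTRIENTS = ("protein", "potassium", "sodium", "total_sugars")
REPEAT_KS = (1, 2, 4, 7)


@dataclass
class AnalysisConfig:
    """Configuration of a full pipeline run."""

    input_csv: str | None = None
    sim: SimulationConfig | None = None
    nutrients: tuple[str, ...] = MAIN_NUTRIENTS
    densities: tuple[str, ...] = DENSITY_NUTRIENTS
    antioxidants: tuple[str, ...] = ANTIOXIDANTS
    sensitivity_modes: tuple[str, ...] = (
        "paba_sensitivity",
        "wear_sensitivity",
        "proximity_sensitivity",
    )
    constants: DerivationConstants = field(default_factory=DerivationConstants)
    ci_method: str = "delta"
    n_boot: int = 100
    min_stratum: int = 30
    seed: int = 0
    out_dir: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known - {"n_participants"}
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        n_part = raw.pop("n_participants", None)
        cfg = cls(**{k: v for k, v in raw.items() if k in known})
        if n_part is not None:
            cfg.sim = default_config(n_participants=int(n_part), seed=cfg.seed)
        for name in ("nutrients", "densities", "antioxidants", "sensitivity_modes"):
            setattr(cfg, name, tuple(getattr(cfg, name)))
        return cfg


def _load_dataset(config: AnalysisConfig) -> pd.DataFrame:
    if config.input_csv is not None:
        dataset = read_dataset(config.input_csv)
        required = {"participant_id", "occasion", "instrument"}
        missing = required - set(dataset.columns)
        if missing:
            raise ConfigError(f"input data lacks required columns: {sorted(missing)}")
        return dataset
    sim = config.sim or default_config(seed=config.seed)
    if sim.seed is None:
        sim.seed = config.seed
    return generate_validation_study(sim)


def add_density_columns(dataset: pd.DataFrame, nutrients=DENSITY_NUTRIENTS) -> pd.DataFrame:
    """Nutrient densities in g/MJ: nutrient value over the same record's energy.

    Tool rows use self-reported energy; biomarker rows use TEE, so the
    reference density is biomarker nutrient per MJ of energy expenditure.
    """
    out = dataset.copy()
    for nut in nutrients:
        if nut in out.columns and "energy" in out.columns:
            out[f"{nut}_density"] = out[nut] / out["energy"]
    return out


def geometric_mean_table(dataset: pd.DataFrame, nutrients, occasion: int = 1,
                         level: float = 0.95) -> pd.DataFrame:
    """First-visit geometric means with CIs (exp of the t-interval on log values)."""
    rows = []
    first = dataset[dataset["occasion"] == occasion]
    for inst in (*TOOLS, BIOMARKER):
        sub = first[first["instrument"] == inst]
        for nut in nutrients:
            col = nut
            if inst == BIOMARKER and nut in PLASMA_COLUMNS:
                col = PLASMA_COLUMNS[nut]
            if col not in sub.columns:
                continue
            vals = sub[col].dropna()
            vals = vals[vals > 0]
            n = len(vals)
            if n == 0:
                continue
            logs = np.log(vals.to_numpy(float))
            m = logs.mean()
            half = (
                stats.t.ppf(0.5 + level / 2, n - 1) * logs.std(ddof=1) / math.sqrt(n)
                if n > 1
                else math.nan
            )
            rows.append(
                {
                    "instrument": inst,
                    "nutrient": nut,
                    "n": n,
                    "geometric_mean": math.exp(m),
                    "ci_low": math.exp(m - half),
                    "ci_high": math.exp(m + half),
                }
            )
    return pd.DataFrame(rows)


def _ci_or_nan(params, functional, tool, dataset, nutrient, config, k=1):
    try:
        return derived_ci(
            params,
            functional,
            tool,
            k=k,
            method=config.ci_method,
            dataset=dataset,
            nutrient=nutrient,
            n_boot=config.n_boot,
            seed=config.seed,
        )
    except (ConvergenceError, UndefinedResultError):
        return (math.nan, math.nan)


def validation_table(dataset: pd.DataFrame, nutrients, config: AnalysisConfig) -> pd.DataFrame:
    """Attenuation/correlation/% difference per tool × nutrient."""
    rows = []
    for nut in nutrients:
        try:
            params = fit_mem(dataset, nut)
        except (InputError, ConvergenceError) as exc:
            log.warning("skipping %s: %s", nut, exc)
            continue
        for tool in TOOLS:
            try:
                lam = attenuation_factor(params, tool)
                rho = correlation_with_truth(params, tool)
            except UndefinedResultError as exc:
                log.warning("skipping %s/%s: %s", nut, tool, exc)
                continue
            pct = mean_pct_difference(dataset, tool, nut)
            lam_ci = _ci_or_nan(params, "attenuation", tool, dataset, nut, config)
            rho_ci = _ci_or_nan(params, "correlation", tool, dataset, nut, config)
            rows.append(
                {
                    "nutrient": nut,
                    "tool": tool,
                    "n": params.n,
                    "attenuation": lam,
                    "attenuation_ci_low": lam_ci[0],
                    "attenuation_ci_high": lam_ci[1],
                    "correlation": rho,
                    "correlation_ci_low": rho_ci[0],
                    "correlation_ci_high": rho_ci[1],
                    "pct_difference": pct.value,
                    "pct_difference_ci_low": pct.ci_low,
                    "pct_difference_ci_high": pct.ci_high,
                    "converged": params.converged,
                }
            )
    return pd.DataFrame(rows)


def repeat_administration_table(dataset: pd.DataFrame, nutrients, config: AnalysisConfig,
                                ks=REPEAT_KS) -> pd.DataFrame:
    """Attenuation and correlation for the mean of k repeat administrations."""
    rows = []
    for nut in nutrients:
        try:
            params = fit_mem(dataset, nut, compute_cov=False)
        except (InputError, ConvergenceError):
            continue
        for tool in TOOLS:
            for k in ks:
                rows.append(
                    {
                        "nutrient": nut,
                        "tool": tool,
                        "k": k,
                        "attenuation": attenuation_factor(params, tool, k),
                        "correlation": correlation_with_truth(params, tool, k),
                    }
                )
    return pd.DataFrame(rows)


def _occasion_pairs(dataset, nutrient, inst_a, inst_b, col_a=None, col_b=None):
    col_a, col_b = col_a or nutrient, col_b or nutrient
    a = dataset.loc[dataset["instrument"] == inst_a, ["participant_id", "occasion", col_a]]
    b = dataset.loc[dataset["instrument"] == inst_b, ["participant_id", "occasion", col_b]]
    merged = a.merge(b, on=["participant_id", "occasion"], suffixes=("_a", "_b"))
    ca = col_a + "_a" if col_a == col_b else col_a
    cb = col_b + "_b" if col_a == col_b else col_b
    merged = merged.dropna(subset=[ca, cb])
    return merged, ca, cb


def _tidy_for_icc(dataset, nutrient, inst_a, inst_b, col_a=None, col_b=None,
                  standardize=False):
    frames = []
    for inst, col in ((inst_a, col_a or nutrient), (inst_b, col_b or nutrient)):
        sub = dataset.loc[dataset["instrument"] == inst, ["participant_id", "occasion", col]]
        sub = sub.dropna(subset=[col])
        sub = sub[sub[col] > 0]
        vals = np.log(sub[col].to_numpy(float))
        if standardize:
            # different units (e.g. plasma µM vs intake mg): compare ranking
            # on the z-scale, where absolute agreement is defined
            vals = (vals - vals.mean()) / vals.std(ddof=1)
        frames.append(
            pd.DataFrame(
                {
                    "subject": sub["participant_id"].to_numpy(),
                    "method": inst,
                    "occasion": sub["occasion"].to_numpy(),
                    "value": vals,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def agreement_between_tools(dataset: pd.DataFrame, nutrients, config: AnalysisConfig) -> pd.DataFrame:
    """Log Bland–Altman and ICC between the two recall tools, occasion level."""
    rows = []
    for nut in nutrients:
        merged, ca, cb = _occasion_pairs(dataset, nut, TOOLS[0], TOOLS[1])
        if len(merged) < 2:
            continue
        ba = bland_altman_log(merged[ca], merged[cb])
        # % difference in means over all recalls (participant-mean based)
        pct = mean_pct_difference(dataset, TOOLS[0], nut, reference=TOOLS[1])
        tidy = _tidy_for_icc(dataset, nut, TOOLS[0], TOOLS[1])
        comp = fit_two_way_mixed(tidy, methods=TOOLS)
        icc = icc_absolute(
            comp, data=tidy, methods=TOOLS, n_boot=config.n_boot, seed=config.seed
        )
        rows.append(
            {
                "nutrient": nut,
                "method_a": TOOLS[0],
                "method_b": TOOLS[1],
                "n_pairs": ba.n,
                "pct_difference": pct.value,
                "pct_difference_ci_low": pct.ci_low,
                "pct_difference_ci_high": pct.ci_high,
                "loa_lower": ba.loa_lower,
                "loa_upper": ba.loa_upper,
                "icc": icc.value,
                "icc_ci_low": icc.ci_low,
                "icc_ci_high": icc.ci_high,
            }
        )
    return pd.DataFrame(rows)


def agreement_with_plasma(dataset: pd.DataFrame, antioxidants, config: AnalysisConfig) -> pd.DataFrame:
    """ICC between plasma concentration biomarkers and each tool's intakes.

    Units differ (µM vs mg), so log values are z-standardized within method
    before the two-way fit; the ICC then measures agreement in ranking.
    """
    rows = []
    for nut in antioxidants:
        plasma_col = PLASMA_COLUMNS.get(nut)
        if (
            plasma_col is None
            or plasma_col not in dataset.columns
            or nut not in dataset.columns
            or dataset[plasma_col].notna().sum() == 0
        ):
            continue
        for tool in TOOLS:
            tidy = _tidy_for_icc(
                dataset, nut, tool, BIOMARKER, col_a=nut, col_b=plasma_col,
                standardize=True,
            )
            if tidy["subject"].nunique() < 2:
                continue
            comp = fit_two_way_mixed(tidy, methods=(tool, BIOMARKER))
            icc = icc_absolute(
                comp, data=tidy, methods=(tool, BIOMARKER),
                n_boot=config.n_boot, seed=config.seed,
            )
            rows.append(
                {
                    "nutrient": nut,
                    "tool": tool,
                    "n": icc.n,
                    "icc": icc.value,
                    "icc_ci_low": icc.ci_low,
                    "icc_ci_high": icc.ci_high,
                }
            )
    return pd.DataFrame(rows)


def _prepare(config: AnalysisConfig, mode: str = "main"):
    dataset = _load_dataset(config)
    dataset = derive_reference_intakes(dataset, config.constants)
    flagged = apply_exclusions(dataset, mode=mode, constants=config.constants)
    masked = mask_excluded(flagged)
    masked = add_density_columns(masked, config.densities)
    return flagged, masked


def exclusion_log(flagged: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for col, reason_col in (
        ("excl_urinary", "excl_urinary_reason"),
        ("excl_tee", "excl_tee_reason"),
        ("excl_recall", "excl_recall_reason"),
    ):
        if col not in flagged.columns:
            continue
        sub = flagged[flagged[col].astype(bool)]
        for reason, grp in sub.groupby(reason_col):
            rows.append(
                {
                    "rule": col,
                    "reason": reason,
                    "n_records": len(grp),
                    "n_participants": grp["participant_id"].nunique(),
                }
            )
    return pd.DataFrame(rows, columns=["rule", "reason", "n_records", "n_participants"])


def run_main_analysis(config: AnalysisConfig) -> dict:
    """Run the full main analysis and (optionally) write the result bundle."""
    flagged, masked = _prepare(config, mode="main")
    density_cols = tuple(f"{n}_density" for n in config.densities)
    gm_nutrients = tuple(config.nutrients) + density_cols + tuple(config.antioxidants)
    results = {
        "dataset": masked,
        "geometric_means": geometric_mean_table(masked, gm_nutrients),
        "validation": validation_table(
            masked, tuple(config.nutrients) + density_cols, config
        ),
        "repeat_administrations": repeat_administration_table(
            masked, config.nutrients, config
        ),
        "agreement_tools": agreement_between_tools(masked, config.nutrients, config),
        "agreement_plasma": agreement_with_plasma(masked, config.antioxidants, config),
        "exclusions": exclusion_log(flagged),
        "provenance": {
            "package": "dietval",
            "version": __version__,
            "seed": config.seed,
            "mode": "main",
            "n_participants": int(masked["participant_id"].nunique()),
            "simulated": config.input_csv is None,
        },
    }
    if config.out_dir:
        _write_bundle(results, config.out_dir)
    return results


def run_stratified(config: AnalysisConfig, variable: str) -> dict[str, pd.DataFrame]:
    """Independent validation re-fits per stratum of sex, age group or BMI group."""
    if variable not in ("sex", "age_group", "bmi_group"):
        raise InputError(f"unknown stratification variable {variable!r}")
    _, masked = _prepare(config, mode="main")
    per_part = masked.groupby("participant_id").first()
    if variable == "sex":
        strata = {s: per_part.index[per_part["sex"] == s] for s in ("F", "M")}
    elif variable == "bmi_group":
        strata = {
            "bmi<25": per_part.index[per_part["bmi"] < 25.0],
            "bmi>=25": per_part.index[per_part["bmi"] >= 25.0],
        }
    else:
        tertiles = per_part["age"].quantile([1 / 3, 2 / 3]).to_numpy()
        strata = {
            "age_low": per_part.index[per_part["age"] < tertiles[0]],
            "age_mid": per_part.index[
                (per_part["age"] >= tertiles[0]) & (per_part["age"] < tertiles[1])
            ],
            "age_high": per_part.index[per_part["age"] >= tertiles[1]],
        }
    out = {}
    for name, ids in strata.items():
        if len(ids) < config.min_stratum:
            log.warning(
                "stratum %s has %d participants (< %d); skipped",
                name, len(ids), config.min_stratum,
            )
            continue
        sub = masked[masked["participant_id"].isin(ids)]
        table = validation_table(sub, config.nutrients, config)
        table.insert(0, "stratum", name)
        out[name] = table
    if config.out_dir and out:
        path = Path(config.out_dir)
        path.mkdir(parents=True, exist_ok=True)
        pd.concat(out.values(), ignore_index=True).to_csv(
            path / f"stratified_{variable}.csv", index=False
        )
    return out


def run_sensitivity(config: AnalysisConfig, mode: str) -> dict:
    """Re-run the main validation analysis under a sensitivity regime."""
    if mode not in ("paba_sensitivity", "wear_sensitivity", "proximity_sensitivity"):
        raise InputError(f"unknown sensitivity mode {mode!r}")
    flagged, masked = _prepare(config, mode=mode)
    density_cols = tuple(f"{n}_density" for n in config.densities)
    results = {
        "mode": mode,
        "geometric_means": geometric_mean_table(
            masked, tuple(config.nutrients) + density_cols
        ),
        "validation": validation_table(masked, config.nutrients, config),
        "exclusions": exclusion_log(flagged),
    }
    if config.out_dir:
        path = Path(config.out_dir)
        path.mkdir(parents=True, exist_ok=True)
        results["validation"].to_csv(path / f"sensitivity_{mode}.csv", index=False)
    return results


def _write_bundle(results: dict, out_dir) -> None:
    path = Path(out_dir)
    path.mkdir(parents=True, exist_ok=True)
    for key in (
        "geometric_means",
        "validation",
        "repeat_administrations",
        "agreement_tools",
        "agreement_plasma",
        "exclusions",
    ):
        results[key].to_csv(path / f"{key}.csv", index=False)
    write_dataset(results["dataset"], path / "dataset.csv")
    with open(path / "provenance.yaml", "w") as fh:
        yaml.safe_dump(results["provenance"], fh, sort_keys=False)
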