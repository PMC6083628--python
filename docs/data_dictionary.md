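# Data dictionary: long-format study dataset

One row per participant × occasion × instrument.  Written/read by
`dietval.io.write_dataset` / `read_dataset`.

## Identifiers

| column | type | description |
|---|---|---|
| `participant_id` | int | participant identifier (1..n) |
| `occasion` | int | clinic occasion index (1..K, default K = 3) |
| `date` | date | measurement date (ISO `YYYY-MM-DD` in CSV) |
| `instrument` | str | `online_recall`, `interviewer_recall` or `biomarker` |

## Covariates (repeated on every row of a participant)

| column | type | description |
|---|---|---|
| `age` | float | years at entry |
| `sex` | str | `F` / `M` |
| `weight` | float | kg at that visit (first visit = baseline weight) |
| `bmi` | float | kg/m² at entry |

## Nutrient values

Self-report rows carry reported intakes; biomarker rows carry reference
intakes (after derivation).

| column | unit | reference measure |
|---|---|---|
| `protein` | g/d | urinary nitrogen × 6.25 / 0.81 |
| `potassium` | g/d | urinary potassium / 0.80 |
| `sodium` | g/d | urinary sodium / 0.86 |
| `total_sugars` | g/d | calibrated urinary sucrose + fructose |
| `energy` | MJ/d | TEE = (REE + AEE)/0.9 |
| `beta_carotene`, `vitamin_c`, `vitamin_e` | mg/d | self-report only (plasma is the reference, see below) |
| `<nutrient>_density` | g/MJ | added by the pipeline: nutrient / energy of the same row |

## Raw biomarker panel (biomarker rows only; NaN elsewhere)

| column | unit | description |
|---|---|---|
| `urine_volume` | L/24 h | total collected volume |
| `urinary_nitrogen` | g/24 h | Kjeldahl total nitrogen |
| `urinary_potassium`, `urinary_sodium` | g/24 h | electrolyte excretion |
| `urinary_sucrose`, `urinary_fructose` | mg/24 h | sugar excretion |
| `paba_recovery` | % | PABA completeness check (85–110 = complete) |
| `missed_voids` | count | self-reported missed urine collections |
| `vo2_series`, `vco2_series` | L/min | 15 one-minute calorimetry values, `;`-joined |
| `aee` | MJ/24 h | accelerometer activity energy expenditure |
| `wear_time` | h | armband wear time |
| `plasma_beta_carotene` | µM | plasma concentration |
| `plasma_vitamin_c`, `plasma_vitamin_e` | µM | plasma concentrations |

## Exclusion flags (added by `apply_exclusions`)

| column | description |
|---|---|
| `excl_urinary` / `excl_urinary_reason` | urine-derived values excluded (`missed_voids>=2`, `paba_outside_50_110`) |
| `excl_tee` / `excl_tee_reason` | TEE excluded (`weight_change>5%`, `wear_time_outside_23_25`) |
| `excl_recall` / `excl_recall_reason` | recall record excluded (`within_24h_of_biomarker`) |
| `paba_status` | `complete` / `adjustable` / `excluded` (PABA sensitivity mode) |

Optional input column `nitrogen_to_protein_ratio` overrides the default 6.25
per record for food-source-specific conversion.
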