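# Data dictionary

All files are plain CSV (comma-separated, header row) or YAML. Times
inside a night are minutes from lights off unless a column says
otherwise.

## Subject table (`subjects.csv`)

One row per subject, written by `somnocal.io.write_subjects`.

| column | type | units | description |
|---|---|---|---|
| subject_id | str | — | opaque label, e.g. `MR01` |
| sex_code | int | — | 1 = male, 2 = female (estimation-equation convention) |
| group | str | — | `male_runner`, `amenorrheic_runner`, `menstruating_runner`, `female_control`, `male_control` |
| menstrual_status | str | — | `amenorrhea`, `menstruating`, `not_applicable` |
| phase | str | — | `follicular`, `luteal`, `none` |
| body_mass_kg | float | kg | FFM + FM |
| height_cm | float | cm | |
| ffm_kg | float | kg | fat-free mass |
| fm_kg | float | kg | fat mass |
| urinary_nitrogen_g_day | float | g/day | assumed constant over the run |
| energy_intake_kcal_day | float | kcal/day | |
| exercise_ee_kcal_day | float | kcal/day | exercise-specific EE (for energy availability) |
| active_ee_kcal_day | float | kcal/day | total activity EE (for PAL) |
| habitual_bedtime | str | clock | `HH:MM` |
| tissue_brain_kg … tissue_residual_kg | float | kg | organ/tissue masses feeding the RMR estimate |
| true_smr_kj_day, true_rmr_kj_day | float | kJ/day | generator ground truth; never inputs to the measurement chain |

## Hypnogram (`hyp.csv`)

One row per 30-s epoch.

| column | type | description |
|---|---|---|
| epoch_index | int | 0-based, 960 epochs for an 8-h night |
| clock_time | str | `HH:MM:SS` of epoch start, from lights off |
| stage | str | `W`, `N1`, `N2`, `N3`, `R` |

## Gas trace (`trace.csv`)

Outlet fractions sampled each minute; `n + 1` rows for `n` minute
sources. Chamber geometry travels in the YAML run config, not the CSV.

| column | type | units |
|---|---|---|
| time_min | float | minutes from chamber entry |
| o2_frac | float | outlet O₂ fraction (0–1) |
| co2_frac | float | outlet CO₂ fraction (0–1) |

## Gas exchange (`gas.csv`)

| column | type | units |
|---|---|---|
| minute | int | 0-based minute |
| vo2_l_min | float | L/min |
| vco2_l_min | float | L/min |
| urinary_nitrogen_g_day | float | g/day, repeated (constant per run) |

## EE series (`ee.csv`)

| column | type | units / values |
|---|---|---|
| minute | int | 0-based minute |
| ee_kj_min | float | kJ/min |
| rer | float | VCO₂/VO₂; empty where undefined |
| segment | str | `sleep`, `supine_rmr`, `sitting`, or empty |

## Run config (`run.yaml`)

```yaml
chamber:
  volume_l: 14490
  ventilation_l_min: 80        # or 110
  inlet_o2_fraction: 0.2093
  inlet_co2_fraction: 0.0004
  sensor_noise_sd: 0.00002     # fraction units (0.002 percentage points)
urinary_nitrogen_g_day: 11.0
```

## Night summary (`summary.json`)

Written by `somnocal sleep`: `msmr_kj_day`, `momr_kj_day`,
`smr_window_start_min` (0–300), `stage_ee_kj_min` and
`qualifying_minutes` keyed by stage (absent stages omitted), plus
`spt_min`, `tst_min`, `waso_min`, `sleep_efficiency_pct`,
`sws_rem_ratio_pct`.
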