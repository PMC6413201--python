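# Default end-to-end configuration.
#
# Published inputs: stratum case counts, the cohort person-year total, the
# workforce size and processed share, the published mortality grid the
# risks block references, and both scenario grids.
#
# ASSUMED inputs (never published; labeled so): the per-stratum person-year
# allocation, and the target population's size and stratum fractions (the
# population block here is a synthetic stand-in roughly the size of the ten
# cohort countries in 2010).
strata:
  total_person_years: 2279075
  allocation_note: "per-stratum person-years assumed, not published"
  table:
    - {label: "<10",     lower: 0,  upper: 10,   person_years: 569769, cases: 232}
    - {label: "10 to 20", lower: 10, upper: 20,   person_years: 501396, cases: 256}
    - {label: "20 to 40", lower: 20, upper: 40,   person_years: 638141, cases: 402}
    - {label: "40 to 80", lower: 40, upper: 80,   person_years: 387443, cases: 318}
    - {label: ">=80",    lower: 80, upper: null, person_years: 182326, cases: 121}

population:
  note: "synthetic stand-in; the 2010 stratum distribution was never published"
  total_persons: 363000000
  stratum_fractions:
    "<10": 0.25
    "10 to 20": 0.22
    "20 to 40": 0.28
    "40 to 80": 0.17
    ">=80": 0.08

workforce:
  sector_total: 1000000
  processed_share: 0.542
  baseline_4yr_mortality: 0.03   # assumed counterfactual probability

risks:
  # Per-worker 4-year excess-death probabilities, calibrated at read time
  # from the published grid cell for the reference scenario below
  # (expected deaths and 95% CI divided by the displaced-worker count).
  - {cause: "all-cause",          ref_deaths_mean: 272.30, ref_ci_low: 165.53, ref_ci_high: 378.02, ref_loss_fraction: 0.01}
  - {cause: "malignant neoplasm", ref_deaths_mean: 95.53,  ref_ci_low: -11.24, ref_ci_high: 201.25, ref_loss_fraction: 0.01}
  - {cause: "circulatory",        ref_deaths_mean: 87.60,  ref_ci_low: -19.18, ref_ci_high: 193.32, ref_loss_fraction: 0.01}
  - {cause: "suicide",            ref_deaths_mean: 21.35,  ref_ci_low: -91.86, ref_ci_high: 120.63, ref_loss_fraction: 0.01}
  - {cause: "alcohol-related",    ref_deaths_mean: 14.91,  ref_ci_low: -85.42, ref_ci_high: 127.07, ref_loss_fraction: 0.01}

rr:
  rr_per_unit: 1.18
  reference_intake_g: 50
  ci_low: 1.10
  ci_high: 1.28

scenarios:
  consumption_reductions: [0.01, 0.05, 0.10, 0.15]
  source_strata: ["40 to 80", ">=80"]
  destination_stratum: "20 to 40"
  employment_losses: [0.001, 0.003, 0.006, 0.01]

mc:
  n_sims: 10000
  seed: 0
  ci_level: 0.95
  paired_draws: false
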