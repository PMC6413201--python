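# EPIC cohort follow-up by processed-meat consumption stratum.
# Case counts and the person-year total are published cohort statistics;
# the per-stratum person-year allocation is ASSUMED, NOT FROM THE COHORT
# PUBLICATION (per-stratum exposure was never printed). Analyses that
# depend on the allocation must use synthetic tables instead.
strata:
  total_person_years: 2279075
  allocation_note: "per-stratum person-years assumed, not published"
  table:
    - {label: "<10",     lower: 0,  upper: 10,   person_years: 569769, cases: 232}
    - {label: "10 to 20", lower: 10, upper: 20,   person_years: 501396, cases: 256}
    - {label: "20 to 40", lower: 20, upper: 40,   person_years: 638141, cases: 402}
    - {label: "40 to 80", lower: 40, upper: 80,   person_years: 387443, cases: 318}
    - {label: ">=80",    lower: 80, upper: null, person_years: 182326, cases: 121}
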