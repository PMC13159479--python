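"""Score ambient pesticide exposure from application records and addresses.

Each participant-year, applications within a 500 m buffer of any active
address contribute pounds-per-acre; annual exposures are averaged over
1974..blood-draw, dichotomized at control medians, and summed into
per-group chemical counts.
"""

from pestewas import SimulationConfig, generate_applications, generate_cohort
from pestewas.exposure import (
    annual_buffer_exposure,
    average_window,
    dichotomize_and_count,
)

config = SimulationConfig(n_cases=150, n_controls=80, n_probes=100, seed=2)
applications = generate_applications(config)
addresses, covariates = generate_cohort(config)

annual = annual_buffer_exposure(
    applications, addresses, radius_m=500.0, participants=covariates.index
)
print(f"{len(annual)} nonzero participant-chemical-year exposure records")

profiles = average_window(
    annual, covariates["blood_draw_year"],
    chemicals=list(config.copper_codes) + list(config.op_codes),
)
controls = covariates.index[covariates["pd_status"] == 0]
scores = dichotomize_and_count(
    profiles, controls, config.copper_codes, config.op_codes
)

counts = scores.counts
print("copper count distribution (participants per count value):")
print(counts["copper_count"].value_counts().sort_index().to_string())
print(f"mean copper count: cases "
      f"{counts.loc[covariates['pd_status'] == 1, 'copper_count'].mean():.2f}, "
      f"controls {counts.loc[controls, 'copper_count'].mean():.2f}")

# A participant's copper count is the number of copper chemicals whose
# window-averaged buffer exposure exceeds the median among healthy controls;
# it is the exposure variable the EWAS regresses methylation on.
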