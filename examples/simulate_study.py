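"""Generate a complete synthetic study and inspect what was planted.

The generator emits every input the pipeline needs: pesticide application
records, participant address histories, covariates, a beta-value matrix with
probe annotation, and ground truth describing the planted effects.
"""

import numpy as np

from pestewas import DmrSpec, SimulationConfig, simulate_study

config = SimulationConfig(
    n_cases=150,
    n_controls=80,
    n_probes=5000,
    effect_probes=40,          # CpGs truly associated with copper exposure
    effect_size_r=0.3,         # target partial correlation after adjustment
    dmr_specs=(DmrSpec("1", 0, 8),),   # one 8-probe region on chromosome 1
    seed=1,
)
study = simulate_study(config)

print(f"applications: {len(study.applications)} events, "
      f"{study.applications['year'].min()}-{study.applications['year'].max()}")
print(f"cohort: {len(study.covariates)} participants "
      f"({int(study.covariates['pd_status'].sum())} cases)")
print(f"beta matrix: {study.beta.shape[0]} probes x {study.beta.shape[1]} samples, "
      f"values in ({study.beta.values.min():.4f}, {study.beta.values.max():.4f})")

flagged = (study.annotation["flags"] != "").mean()
print(f"QC-flagged probes: {flagged:.1%} (filtered before analysis)")

counts = study.counts
r = np.corrcoef(counts["copper_count"], counts["op_count"])[0, 1]
print(f"copper count: mean {counts['copper_count'].mean():.1f} of "
      f"{len(config.copper_codes)} chemicals; copper-OP correlation {r:.2f}")

truth = study.truth
region = truth.planted_regions[0]
print(f"planted: {len(truth.planted_probe_ids)} single CpGs and a region on "
      f"chr{region['chromosome']}:{region['start']}-{region['end']} "
      f"({len(region['probe_ids'])} probes)")

# The copper-OP correlation is the built-in confounding the OP adjustment
# exists for; the ground truth is what downstream recovery tests score against.
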