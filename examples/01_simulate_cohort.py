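"""Simulate a sleep-restriction × rotenone plasma cohort and check its structure.

Generates 11 rats per group for the six SHAM/ROT × CT/SR/REB groups and
verifies that the engineered group-mean ratios and metabolite correlations
come out as configured.
"""

import numpy as np

import sleepmet as sm
from sleepmet.simulate import SimConfig, simulate_cohort

manifest = sm.default_manifest()
cfg = SimConfig(manifest=manifest, n_per_group=11, seed=0)
table, design, covariates = simulate_cohort(cfg)

print(f"cohort: {len(table.study_samples())} study samples, "
      f"{len(table.metabolite_ids)} metabolites, groups: {sorted(set(design.table['group']))}")

ratios = sm.ratios_to_control(table, design)
print("\ngroup-mean ratios vs SHAM-CT (generator targets in brackets):")
for mid, targets in (("Ile", (1.22, 1.12, 1.35)), ("Kynurenine", (0.79, 1.15, 0.72))):
    got = ratios.loc[mid, ["SHAM-SR", "ROT-CT", "ROT-SR"]].round(2).tolist()
    print(f"  {mid:12s} SHAM-SR/ROT-CT/ROT-SR = {got}  targets {list(targets)}")

log_ile = np.log(table.study_concentrations()["Ile"])
log_leu = np.log(table.study_concentrations()["Leu"])
print(f"\nr(log LEU, log ILE) = {np.corrcoef(log_leu, log_ile)[0, 1]:.2f}  (target 0.90)")
r = np.corrcoef(covariates.table["total_activity"], covariates.table["sleep_condition"])[0, 1]
print(f"r(total_activity, sleep_condition) = {r:.2f}  (target -0.57)")
print("\nAt n=11/group sample correlations scatter around the targets; "
      "they converge within ±0.03 at n=1000/group.")
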