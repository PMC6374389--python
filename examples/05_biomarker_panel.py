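"""Grow a logistic biomarker panel for sleep restriction by stepwise LOOCV.

Candidates must pass three screens (FDR < 0.05, permutation-validated AUC,
>5% concentration difference); the panel then grows greedily by the
metabolite with the largest leave-one-out cross-validated AUC gain until no
strict improvement remains.
"""

import pandas as pd

import sleepmet as sm
from sleepmet.simulate import SimConfig, simulate_cohort

manifest = sm.default_manifest()
table, design, _ = simulate_cohort(SimConfig(manifest=manifest, n_per_group=11, seed=3))
cfg = sm.PipelineConfig(seed=3, n_perm_auc=999)

res = sm.compute_group_stats(table, design, cfg)
conc = table.study_concentrations()
sr = [s for s in conc.index if design.table.at[s, "procedure"] == "SR"]
ct = [s for s in conc.index if design.table.at[s, "procedure"] == "CT"]
ids = ct + sr
labels = pd.Series([1 if s in sr else 0 for s in ids], index=ids)

cand = sm.select_candidates(res.tests["q_sr"], conc.loc[ids], labels, cfg)
print(f"candidates passing all three screens: {len(cand.members)}")

model = sm.stepwise_select(cand, conc.loc[ids], labels, cfg)
print(f"selected panel: {model.selected}")
print("LOOCV AUC trajectory:", [round(a, 3) for a in model.trajectory])
m = model.metrics
print(f"at the 50% threshold: accuracy {m['accuracy']:.0%}, "
      f"sensitivity {m['sensitivity']:.0%}, specificity {m['specificity']:.0%}")
print("\nKynurenine (decreased under SR) anchors the panel; each step must "
      "strictly raise the held-out AUC, so the trajectory is increasing.")
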