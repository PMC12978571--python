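"""First-order Markov-chain analysis of profile sequences.

Generates per-subject state sequences from the three arm-specific
chains, estimates transition matrices, stationary distributions,
attractor states and trigram block entropy, and contrasts occupancy
and entropy between arms.
"""

import numpy as np

from loomdyn import SimConfig, synth
from loomdyn import dynamics as dy
from loomdyn.config import PROFILE_LABELS

cfg = SimConfig(seed=11)  # 37 subjects per arm, as in the study design
seq = synth.generate_state_sequences(cfg, n_trials=140)

models, groups = {}, {}
for arm, g in seq.groupby("arm"):
    groups[arm] = dy.sequences_from_frame(g)
    models[arm] = dy.estimate_transitions(groups[arm])

print("stationary distribution by arm (8 profiles):")
for arm in ("PLC", "AVP", "LT"):
    pi = np.round(models[arm].pi, 3)
    print(f"  {arm}: {dict(zip(PROFILE_LABELS, pi))}")
print("PLC concentrates on E1; AVP shifts mass to E3/L3; LT is flat")

out = dy.within_group_significant_transitions(models["PLC"])
sig = [(e["from"], e["to"], round(e["P"], 2)) for e in out["edges"]
       if e["significant"] and e["P"] > 0.10]
print(f"\nPLC attractors (self-transition > 0.45): {out['attractors']}")
print(f"PLC significant visible pathways: {sig[:6]} ...")

# occupancy contrast: does state occupancy depend on treatment?
table = np.stack([np.bincount([s for q in groups[a] for s in q],
                              minlength=8) for a in ("PLC", "AVP", "LT")])
oc = dy.occupancy_contrast(table)
print(f"\noccupancy chi2({oc['df']}) = {oc['chi2']:.1f}, p = {oc['p']:.2g}")
print("cells with |adjusted residual| > 1.96 drive the treatment effect:")
flag = oc["flagged"]
for i, arm in enumerate(("PLC", "AVP", "LT")):
    hits = [PROFILE_LABELS[j] for j in range(8) if flag[i, j]]
    print(f"  {arm}: {hits}")

ent = dy.entropy_contrast(groups, n_boot=300, seed=2)
print("\ntrigram block entropy (bits) with subject-bootstrap 95% CIs:")
for _, row in ent[ent["kind"] == "group"].iterrows():
    print(f"  {row['a']}: {row['value']:.2f} "
          f"[{row['ci_low']:.2f}, {row['ci_high']:.2f}]")
print("higher entropy = less predictable trial-to-trial dynamics; "
      "the generator's LT > AVP > PLC ordering mirrors the flexibility "
      "gradient the analysis is designed to detect")
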