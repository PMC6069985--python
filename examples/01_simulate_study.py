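"""Simulate the three-experiment reaction-norm study and look at its truth table.

The study crosses two C. elegans strains (laboratory N2, wild-isolate AB1)
with an agar -> liquid -> agar generation sequence: P0 on OP50-seeded agar,
F1 in a liquid medium (axenic CeHR or bacterial S-Medium), F2 back on agar.
The generator plants environment responders (with a known transmission
probability tau), constitutive strain offsets, single-cell interaction
genes and condition-triggered dormant genes.
"""
from wormnorm import SimulationConfig, simulate_study

config = SimulationConfig(n_genes=5000, rng_seed=7)
bundle = simulate_study(config)

print("experiments:", ", ".join(bundle.experiments))
print("planted classes:")
for label, count in bundle.truth["class_label"].value_counts().items():
    print(f"  {label:28s} {count}")

responders = bundle.truth[bundle.truth["class_label"] == "ENV_RESPONDER"]
print(f"transmitted responders: {int(responders['transmitted'].sum())} of "
      f"{len(responders)} (planted tau = {config.transmission_tau})")

matrix = bundle.experiments["N2_CeHR"].matrix
print(f"N2/CeHR matrix: {matrix.values.shape[0]} genes x {matrix.values.shape[1]} samples")
# Each experiment carries 3 generations x 3 replicates of FPKM values; the
# truth table is the oracle every recovery analysis is scored against.
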