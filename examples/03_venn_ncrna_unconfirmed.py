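"""Three-generation Venn categorization, ncRNA profiles, unconfirmed-gene evidence.

Each experiment's expressed genes fall into seven disjoint categories by
the generations they appear in (P0-only ... P0F1F2).  ncRNA percentages
are taken after discarding miRNA/piRNA/rRNA (too short for poly(A)
RNA-seq), and computationally predicted genes without prior transcript
evidence count as "evidenced" once they are expressed anywhere.
"""
from wormnorm import (
    SimulationConfig,
    call_expression,
    compare_category_counts,
    conserved_ncrna,
    ncrna_profile,
    simulate_study,
    unconfirmed_evidence,
    venn_partition,
)

bundle = simulate_study(SimulationConfig(n_genes=5000, rng_seed=7))

partitions = []
for exp_id, exp in bundle.experiments.items():
    calls = call_expression(exp.matrix, 1.0)
    part = venn_partition(calls, experiment_id=exp_id)
    partitions.append(part)
    sizes = part.sizes()
    print(f"{exp_id}: " + ", ".join(f"{k}={v}" for k, v in sizes.items() if v))

profile = ncrna_profile(partitions[0], bundle.annotation)
print("\nncRNA percentages (N2/CeHR):")
print(profile["pct_ncrna"].round(1).to_string())

conserved = conserved_ncrna(partitions, bundle.annotation)
print(f"\nall-generation ncRNAs shared by the three experiments: {len(conserved['shared'])}")
for exp_id, frac in conserved["fractions"].items():
    print(f"  {exp_id}: {100 * frac:.0f}% of its all-generation ncRNAs are shared")

evidence = unconfirmed_evidence([call_expression(bundle.combined_matrix(), 1.0)],
                                bundle.annotation)
print(f"\ntranscript evidence for {evidence['pct_evidenced']:.0f}% of the "
      f"{evidence['n_unconfirmed']} unconfirmed genes")

# are condition-specific (single-generation) genes equally frequent in two
# experiments?  Yates chi-squared on the category counts:
unique_a = sum(partitions[0].sizes()[c] for c in ("P0_only", "F1_only", "F2_only"))
unique_b = sum(partitions[2].sizes()[c] for c in ("P0_only", "F1_only", "F2_only"))
stat, p = compare_category_counts(unique_a, len(partitions[0].universe),
                                  unique_b, len(partitions[2].universe))
print(f"\nuniquely expressed genes, N2/CeHR vs AB1/CeHR: chi2 = {stat:.2f}, p = {p:.3g}")
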