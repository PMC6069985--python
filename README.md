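# wormnorm

Transgenerational reaction-norm transcriptome analysis for *C. elegans*
strain × environment × generation RNA-seq designs.

## The problem

Moving *C. elegans* from bacteria-seeded agar plates into liquid culture
(axenic CeHR or bacterial S-Medium) is a drastic environmental change that
reshapes the transcriptome, and part of that response persists in the next
generation after the worms return to agar.  How much of the response is
driven by the environment, how much by the genotype (laboratory N2 vs the
wild isolate AB1), how much by their interaction — and what fraction of the
environment-induced change is transmitted from F1 to F2?

`wormnorm` implements that analysis as a tested, reusable pipeline that
starts from gene × sample FPKM matrices (no read alignment):

- **Expression calling** — a gene is expressed in a condition when its
  replicate-mean FPKM exceeds a threshold: `FPKM > 1` (lenient) or
  `FPKM > 21` (stringent, anchored at the stable housekeeping gene
  *pmp-3*).
- **Venn categorization** — each expressed gene of an experiment falls into
  one of seven disjoint generation-membership classes (P0-only … P0F1F2),
  with ncRNA percentages per class (after discarding miRNA/piRNA/rRNA) and
  cross-experiment conservation of all-generation ncRNAs.
- **Unconfirmed-gene evidence** — computationally predicted genes without
  prior EST/cDNA support count as evidenced once they are expressed in any
  condition.
- **G/E/G×E classification** — a gene's stringent expression pattern over
  the strain × environment grid reduces to ENVIRONMENT_SPECIFIC (one
  environment, both strains), GENOTYPE_SPECIFIC (one strain only),
  INTERACTION (a single strain × environment cell), or UNCLASSIFIED; the
  most specific label wins.
- **Differential expression** — DEGs jointly satisfy `FPKM > 1` in at least
  one condition, |log2FC| ≥ 1 (two-fold; a four-fold preset exists), and
  Benjamini–Hochberg `q ≤ 0.05`, with an in-house BH step-up and a
  replicate-aware t-test on `log2(FPKM + 1)`.
- **Transmission** — per direction, F1-vs-P0 DEGs partition into F1-only /
  F2-only / F1F2 (same direction in both generations); the transmission
  fraction is `|F1F2| / (|F1-only| + |F1F2|)`, with an upper-tail
  hypergeometric overlap test computed in log space.
- **Sample similarity** — Jensen–Shannon distance (base-2, square root;
  a metric on [0, 1]) between per-condition profiles, clustered with
  average linkage and serialized as Newick.
- **Synthetic studies** — `simulate_study` generates the full
  three-experiment design (N2/CeHR, N2/S-Medium, AB1/CeHR; P0 agar → F1
  liquid → F2 agar, three replicates each) with planted gene classes,
  effect sizes and a known transmission probability τ, so every stage is
  testable against an exact truth table without sequencing data.

## Worked example

```sh
python examples/05_deg_transmission.py
```

```
N2_CeHR: F1 DEGs 672 up / 564 down; F1F2 = 380, transmission fraction = 0.307 (hypergeometric p = 1.6e-278)
N2_SMedium: F1 DEGs 671 up / 566 down; F1F2 = 379, transmission fraction = 0.306 (hypergeometric p = 2.6e-277)
AB1_CeHR: F1 DEGs 671 up / 567 down; F1F2 = 381, transmission fraction = 0.308 (hypergeometric p = 1.5e-280)
```

Each line is one experiment: the number of genes up- and down-regulated in
F1 (liquid) relative to P0 (agar), the count of responses that persist with
the same direction in F2 (F1F2), and the resulting transmission fraction —
here ≈ 0.31 against a planted τ = 0.3.  The hypergeometric p-value shows
the F1/F2 overlap is vastly larger than chance for sets of these sizes.

The other scripts in `examples/` walk through simulation and the truth
table (01), expression calling and the strain-separating Jensen–Shannon
dendrogram (02), Venn/ncRNA/unconfirmed profiling with a Yates-corrected
chi-squared comparison (03), and G/E/G×E classification scored against the
planted classes (04).

A thin CLI mirrors the library:

```sh
wormnorm simulate --seed 7 --out bundle/
wormnorm run-all --bundle bundle/ --out results/
wormnorm deg --matrix bundle/N2_CeHR/matrix.tsv --samples bundle/N2_CeHR/samples.tsv \
    --a N2:OP50_NGM:P0 --b N2:CeHR:F1 --out deg.tsv
```

All artifacts are tab-separated UTF-8; the run directory echoes the
resolved configuration and logs every threshold applied.

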