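# Methods

## The design

The pipeline analyses a reaction-norm experiment on *C. elegans*: a
parental generation (P0) grown on *E. coli* OP50-seeded NGM agar, its
offspring (F1) in a liquid medium, and the grand-offspring (F2) back on
agar.  Three experiments cross this sequence with genotype and diet:
laboratory N2 in axenic CeHR, N2 in bacterial S-Medium, and the wild
isolate AB1 in CeHR.  Each (strain, environment, generation) condition
carries three RNA-seq replicates summarized as FPKM.  The pipeline begins
at the abundance-matrix level; alignment and FPKM estimation are upstream
and out of scope.

Reversion agar (F2) is modelled as its own environment level rather than
reusing OP50-NGM: the F2 animals are the descendants of liquid-grown
mothers, and keeping the level separate lets maternal carry-over appear as
a condition effect instead of being averaged into P0.

## Expression calling

A gene is called expressed in a condition when the **arithmetic mean of its
replicate FPKMs is strictly greater than the threshold**.  Two thresholds
are used throughout: 1 FPKM (the common community rule) and 21 FPKM (the
expression level of the stable housekeeping gene *pmp-3*, used where weak
signal must be excluded outright).  The strictly-greater-than boundary is
deliberate and tested.  Combining replicates by mean before thresholding is
a convention choice — the alternative all-replicates-pass rule would be
stricter near the boundary — and it matches how per-condition FPKMs are
usually reported by assembly pipelines.

## Venn categorization and derived profiles

Per experiment, every gene expressed (lenient rule) in at least one
generation is assigned to exactly one of seven categories by its
generation-membership set (P0_only, F1_only, F2_only, P0F1, P0F2, F1F2,
P0F1F2); genes expressed nowhere never enter the universe.  Disjointness
and coverage are asserted on every run.

ncRNA percentages per category discard miRNA, piRNA and rRNA genes from
both numerator and denominator first (these classes are too short to be
sampled reliably by poly(A)-selected RNA-seq).  An empty category yields an
undefined (NaN) percentage, never zero.  Conserved ncRNAs are the
intersection over experiments of each experiment's all-generation
(P0F1F2) ncRNA set, reported with the fraction of each experiment's set it
represents.

A gene from the unconfirmed list (no prior EST/cDNA transcript evidence)
counts as **evidenced** when it is lenient-expressed in at least one
condition of at least one experiment.

## G/E/G×E classification

Each gene's stringent-expression pattern over the strain × environment grid
reduces to one label:

1. **INTERACTION** — expressed in exactly one (strain, environment) cell;
2. **GENOTYPE_SPECIFIC** — expressed in one or more environments of exactly
   one strain and in none of any other strain;
3. **ENVIRONMENT_SPECIFIC** — expressed in exactly one environment, in all
   (≥ 2) strains observed there;
4. **UNCLASSIFIED** — anything else.

The three definitions overlap at single-cell patterns, so precedence is
fixed at the most specific label (1 > 2 > 3).  Genes below the stringent
threshold everywhere are excluded from the table rather than labelled.
Because the "one strain under a single environmental condition" wording of
the genotype class is genuinely ambiguous, the output also carries a
`label_strict_env` column in which genotype-specificity additionally
requires a single environment (multi-environment one-strain patterns then
fall to UNCLASSIFIED).

Two grid modes exist.  `per_generation` classifies each generation slice
separately (the figure-panel view); slices whose grid collapses below
2 strains × 2 environments are skipped with a log entry — in this design
only the F1 slice has two environments, and there the AB1 strain has a
single environment, which structurally turns AB1-only genes into
single-cell (INTERACTION) patterns.  `pooled` enters a gene in a cell when
it is stringently expressed there in any generation, giving one complete
grid; recovery tests and the acceptance script use this mode.

## Differential expression

A gene is a DEG for a contrast when it jointly passes

* an expression gate: lenient-expressed (mean FPKM > 1) in **at least one**
  of the two conditions (the permissive reading; the rule's side is not
  otherwise determined),
* a fold-change cutoff: |log2FC| ≥ 1 with
  `log2FC = log2((mean_b + c) / (mean_a + c))`, pseudocount `c = 1` for
  stability near zero FPKM,
* an FDR cutoff: Benjamini–Hochberg step-up `q ≤ 0.05`, adjusted over the
  genes passing the expression gate.

The fold-change default is two-fold.  The source conventions for this
family of analyses state the cutoff both as "over two-fold" and literally
as "log2 fold change > 2" (four-fold); the contradiction is surfaced
rather than hidden: `RunConfig.fourfold()` switches to the stricter
reading.

The per-gene test is a two-sided **two-sample t-test with pooled variance
on log2(FPKM + 1)** replicate values.  The log transform converts the
multiplicative replicate noise into approximately additive noise with a
variance that does not depend on the mean, which makes the equal-variance
pooling appropriate and the test exactly calibrated under the null — at
three replicates per side the Welch alternative with its estimated degrees
of freedom is measurably conservative (null p < 0.05 rate ≈ 0.033 instead
of 0.05), which both miscalibrates the null and costs enough power in the
sparser F2 contrast to bias the transmission fraction downward.  The
choice is isolated behind `test_gene`; any replicate-aware test that
passes the null-calibration property test is a valid substitute.  This
test is a transparent stand-in for an assembly-based differential test
(e.g. Cuffdiff), whose internals are out of scope; the set logic built on
top is the analysis's actual contribution.

Rows where both sides have zero sample variance (possible only in
hand-built toys) get p = 1 when the means agree and p = 0 otherwise.

## Transmission quantification

For one experiment, let F1 and F2 be the DEG sets of the F1-vs-P0 and
F2-vs-P0 contrasts for one direction.  Genes partition into F1-only,
F2-only and F1F2 = F1 ∩ F2; membership in F1F2 requires the **same
direction** in both generations (a direction-agnostic overlap count is
emitted as a secondary column).  The transmission fraction is

    |F1F2| / (|F1-only| + |F1F2|)

— the share of the F1 response that persisted into F2 — reported per
direction and pooled over directions (the headline estimate; the pooled
denominator is all F1 DEGs).  Undefined (NaN) when no F1 DEG exists.

Overlap enrichment is the upper-tail hypergeometric probability of drawing
an overlap at least as large when |F2| genes are drawn from a universe
containing |F1| marked genes.  The universe defaults to the genes passing
the expression gate in either contrast — the genes actually tested — not
the whole annotation; it is configurable.  The tail is evaluated in log
space (log-gamma binomial coefficients + log-sum-exp) so gene-scale
arguments neither underflow nor overflow.

The 2×2 chi-squared with Yates continuity correction is the classical
closed form, with the corrected |ad − bc| − N/2 difference floored at zero
so near-independent tables yield a statistic of exactly 0, and an
undefined (NaN, logged) result on zero marginals rather than an exception.

## Sample similarity

The distance between two expression profiles is the **Jensen–Shannon
distance**: profiles are normalized to proportions, the divergence is taken
with base-2 logarithms against the midpoint mixture (0·log 0 = 0), and the
distance is its square root — a metric bounded in [0, 1] with disjoint
supports at exactly 1.  The base and the square-root convention are fixed
here because they give that exact range.  Conditions (not replicates) are
clustered for the headline tree using average linkage; a per-replicate
variant exists for QC.  Linkage and profile choices are recorded in the run
log since they are conventions, not derived facts.  The tree is serialized
as Newick with branch lengths from merge heights (labels containing
delimiter characters are quoted).

## The synthetic-study generator

`simulate_study` emulates the statistical structure the downstream stages
assume — nothing more.  No read-level simulation, no GC/length bias, no
library-size confounding: the generator's unit is the consumed unit
(FPKM), and replicate noise is multiplicative log-normal with a fixed
coefficient of variation, so emitted values are positive and the replicate
mean converges to the planted cell mean.

Planted structure (fractions partition a seeded permutation, so class
counts are exact and recovery tests have exact denominators):

| class | default fraction | behaviour |
|---|---|---|
| ENV_RESPONDER | 0.10 | ±8-fold (2³) shift in F1 in every experiment; persists in F2 with probability τ = 0.3 (Bernoulli per gene, shared across experiments); directions alternate UP/DOWN to balance the DEG tails |
| GENOTYPE_OFFSET | 0.05 | constitutive strain difference: ~59 FPKM in a cycled target strain vs ~7.4 in the other (levels straddle the 21-FPKM stringent threshold symmetrically at 2^(±effect/2)) |
| INTERACTION | 0.03 | ~59 FPKM in one cycled (strain, F1-environment) cell, ~7.4 elsewhere |
| CONDITION_SPECIFIC_DORMANT | 0.05 | 0.1 FPKM everywhere except one cycled condition at 10 FPKM — condition-triggered, weakly expressed genes that never reach the stringent threshold |
| NULL_GENE | rest | constant log-normal baseline (median ≈ 20 FPKM, ln-σ = 1.2) |

For the pattern classes (genotype, interaction) a planted "direction" is an
on/off pattern, so direction is realized by cycling the target strain/cell
rather than by down-shifting a sub-threshold baseline, which would plant
nothing observable; UP/DOWN alternation is applied where it has its stated
effect (balancing the two DEG tails of the environment responders).

Biotype flags: 10 % ncRNA (independent of class unless
`ncrna_silencing_bias` couples them to down-regulated responders), 3 %
small RNAs (miRNA/piRNA/rRNA, cycled) to exercise the exclusion rule.
Unconfirmed flags (5 %) are placed half on dormant genes and half on null
genes that are then permanently silenced — predicted genes lacking
transcript evidence are, by construction, not constitutively expressed —
so the evidenced set equals the dormant ∩ unconfirmed truth exactly.

Defaults are the study conditions: 10 000 genes, 3 replicates, effect
3 log2 units, CV 0.2 (a pure convention; no empirical dispersion estimate
exists to copy), τ = 0.3.  `replicate_cv`, the baseline parameters and the
class fractions are all single-decision conventions, documented here and
not tuned per run.

### What passing the recovery tests does and does not show

The generator plants exactly the structure the analysis looks for, with
noise of a known, well-behaved form.  Recovery therefore demonstrates that
the set logic, thresholds and estimators are implemented correctly and are
consistent — it does not demonstrate performance on real RNA-seq, where
dispersion varies per gene, classes overlap, effects are graded rather
than planted, and the FPKM unit itself carries length and depth biases.

Two evaluation choices matter when interpreting the recovery numbers:

* The G/E/G×E precision/recall is computed over the planted
  classifier-class genes.  Over the full universe, any continuous baseline
  distribution places some null genes near the 21-FPKM threshold, and at
  CV 0.2 those genes flip single grid cells often enough that single-cell
  false positives are comparable in number to any realistic planted
  interaction class — a property of per-gene thresholding at this
  replication depth, not of the implementation.  The full-universe label
  counts are still emitted by the pipeline for inspection.
* Dormant-class recovery uses the lenient-threshold condition-specific
  detector (expressed in exactly one of the seven study conditions), since
  dormant genes peak at 10 FPKM and are by design absent from the
  stringent G/E/G×E table.

## Numerical choices and degenerate inputs

* BH step-up is implemented directly (stable argsort, reverse cumulative
  minimum, clip at 1) and cross-checked against statsmodels in the tests.
* The hypergeometric tail and Yates chi-squared are likewise in-house with
  scipy as the independent cross-check, never the implementation.
* Text artifacts render floats with Python's shortest round-trip repr and
  are parsed back with `float_precision="round_trip"`, making
  write-then-read bit-exact.
* All randomness flows from one seed through `numpy.random.SeedSequence`
  spawning (truth first, then one stream per experiment), so a bundle and
  every downstream output are byte-identical across reruns with the same
  seed and configuration.
* Empty categories, zero expressed genes, zero F1 DEGs and zero chi-squared
  marginals all produce explicit undefined markers (NaN), never silent
  zeros or exceptions; invalid inputs (negative FPKM, unknown environments,
  mismatched universes, < 2 replicates in a contrast) fail loudly with the
  offending gene/sample/cell named.

## Problem sizes

The shipped tests and the acceptance script run the full study at 10 000
genes × 3 experiments × 9 samples, the null study at the same size, the
dendrogram scenario at 4 000 genes, and the exhaustive set-logic oracle at
all 2¹² patterns of a 2 × 2 × 3 toy grid; the complete suite executes in
well under a minute on one CPU.  These sizes were chosen as the smallest
that leave the binomial tolerance bands decisively narrower than the
effects being checked.

## Known limitations

* The DEG stage is a deliberate stand-in: no per-gene dispersion modelling,
  no count-based GLM, no isoform resolution.
* FPKM is taken as given; no normalization beyond the unit itself.
* The classifier is a hard-threshold pattern reduction; borderline genes
  near 21 FPKM are noisy by construction (see above).
* Enrichment analyses (GO, tissue, motif) are out of scope; gene lists are
  exported for external tools.
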