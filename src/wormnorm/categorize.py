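"""Gene-set categorization: three-generation Venn partition, ncRNA profiling,
unconfirmed-gene evidence, and the genotype/environment/interaction classifier.

The Venn partition assigns each gene expressed in at least one generation of
an experiment to exactly one of seven generation-membership categories
(P0_only ... P0F1F2).  The G/E/GxE classifier reduces a gene's stringent
expression pattern over the strain x environment grid to one of four labels:

* INTERACTION — expressed in exactly one (strain, environment) cell;
* GENOTYPE_SPECIFIC — expressed in one or more environments of exactly one
  strain and in no environment of any other strain;
* ENVIRONMENT_SPECIFIC — expressed in exactly one environment, in every
  strain observed in that environment (at least two strains);
* UNCLASSIFIED — any other pattern.

The three definitions overlap at single-cell patterns; the most specific
label wins (INTERACTION > GENOTYPE_SPECIFIC > ENVIRONMENT_SPECIFIC).  Genes
with no stringent expression anywhere are excluded from the table rather
than labelled, mirroring the exclusion of sub-threshold genes from the
analysis.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    EXCLUDED_BIOTYPES,
    GeneAnnotation,
    Generation,
    ValidationError,
)
from .expression import ExpressionCalls

VENN_CATEGORIES = ("P0_only", "F1_only", "F2_only", "P0F1", "P0F2", "F1F2", "P0F1F2")

_MEMBERSHIP_TO_CATEGORY = {
    (True, False, False): "P0_only",
    (False, True, False): "F1_only",
    (False, False, True): "F2_only",
    (True, True, False): "P0F1",
    (True, False, True): "P0F2",
    (False, True, True): "F1F2",
    (True, True, True): "P0F1F2",
}


@dataclass
class VennPartition:
    """The 7 disjoint generation-membership classes of one experiment."""

    experiment_id: str
    categories: dict[str, set[str]]

    def __post_init__(self) -> None:
        unknown = set(self.categories) - set(VENN_CATEGORIES)
        if unknown:
            raise ValidationError(f"unknown venn categories: {sorted(unknown)}")
        for cat in VENN_CATEGORIES:
            self.categories.setdefault(cat, set())
        sets = [self.categories[c] for c in VENN_CATEGORIES]
        total = sum(len(s) for s in sets)
        union = set().union(*sets)
        if total != len(union):
            raise ValidationError("venn categories are not pairwise disjoint")

    @property
    def universe(self) -> set[str]:
        return set().union(*self.categories.values())

    def sizes(self) -> dict[str, int]:
        return {c: len(self.categories[c]) for c in VENN_CATEGORIES}

    def category_of(self, gene_id: str) -> str | None:
        for cat, genes in self.categories.items():
            if gene_id in genes:
                return cat
        return None

    def to_frame(self) -> pd.DataFrame:
        rows = [(g, c) for c in VENN_CATEGORIES for g in sorted(self.categories[c])]
        return pd.DataFrame(rows, columns=["gene_id", "category"]).set_index("gene_id")


def venn_partition(calls: ExpressionCalls, experiment_id: str = "") -> VennPartition:
    """Partition genes by the set of generations in which they are expressed.

    ``calls`` must cover exactly the three generations of one experiment; a
    generation with several conditions (not the standard design) counts a
    gene as expressed if any of its conditions does.  Genes expressed in no
    generation never enter the universe.
    """
    gens_present = set(calls.conditions["generation"])
    expected = {g.value for g in Generation}
    if gens_present != expected:
        raise ValidationError(
            f"venn partition needs all three generations; found {sorted(gens_present)}"
        )
    member = {}
    for gen in Generation:
        cols = calls.conditions.index[calls.conditions["generation"] == gen.value]
        member[gen.value] = calls.expressed[list(cols)].any(axis=1)
    categories: dict[str, set[str]] = {c: set() for c in VENN_CATEGORIES}
    keys = pd.DataFrame(member)
    for gene_id, row in zip(keys.index, keys.to_numpy()):
        key = tuple(bool(v) for v in row)
        cat = _MEMBERSHIP_TO_CATEGORY.get(key)
        if cat is not None:
            categories[cat].add(gene_id)
    return VennPartition(experiment_id, categories)


def ncrna_profile(partition: VennPartition, annotation: GeneAnnotation) -> pd.DataFrame:
    """Per-category ncRNA counts and percentages after small-RNA exclusion.

    miRNA, piRNA and rRNA genes are removed from both the numerator and the
    denominator before the percentage is taken; an empty category yields a
    NaN percentage (undefined, not zero).
    """
    missing = annotation.check_covers(partition.universe)
    if missing:
        raise ValidationError(f"annotation does not cover the venn universe; e.g. {missing[:5]}")
    excluded = annotation.excluded_small_rna_ids
    ncrna = annotation.ncrna_ids
    rows = []
    for cat in VENN_CATEGORIES:
        genes = partition.categories[cat] - excluded
        n_nc = len(genes & ncrna)
        size = len(genes)
        rows.append({
            "category": cat,
            "size_after_exclusion": size,
            "n_ncrna": n_nc,
            "pct_ncrna": (100.0 * n_nc / size) if size else float("nan"),
        })
    return pd.DataFrame(rows).set_index("category")


def conserved_ncrna(partitions: Sequence[VennPartition], annotation: GeneAnnotation) -> dict:
    """ncRNAs expressed in all three generations of every experiment.

    Returns the shared gene set plus, per experiment, the fraction of that
    experiment's all-generation ncRNAs the shared set represents.
    """
    if len(partitions) < 2:
        raise ValidationError("need at least two partitions to intersect")
    ncrna = annotation.ncrna_ids - annotation.excluded_small_rna_ids
    per_exp = {p.experiment_id: p.categories["P0F1F2"] & ncrna for p in partitions}
    shared = set.intersection(*per_exp.values())
    fractions = {
        exp: (len(shared) / len(s)) if s else float("nan") for exp, s in per_exp.items()
    }
    return {"shared": shared, "per_experiment_sets": per_exp, "fractions": fractions}


def unconfirmed_evidence(calls_list: Sequence[ExpressionCalls], annotation: GeneAnnotation) -> dict:
    """Unconfirmed genes with lenient expression anywhere in the study.

    A gene counts as evidenced if expressed in at least one condition of at
    least one experiment.  Returns per-condition sets, the overall evidenced
    set, and the percentage of the unconfirmed list covered (NaN if the
    annotation contains no unconfirmed gene).
    """
    unconfirmed = annotation.unconfirmed_ids
    per_condition: dict[str, set[str]] = {}
    evidenced: set[str] = set()
    for calls in calls_list:
        for cond in calls.condition_labels:
            hits = calls.expressed_set(cond) & unconfirmed
            per_condition.setdefault(cond, set()).update(hits)
            evidenced |= hits
    pct = (100.0 * len(evidenced) / len(unconfirmed)) if unconfirmed else float("nan")
    return {
        "evidenced": evidenced,
        "per_condition": per_condition,
        "n_unconfirmed": len(unconfirmed),
        "pct_evidenced": pct,
    }


GXE_LABELS = ("INTERACTION", "GENOTYPE_SPECIFIC", "ENVIRONMENT_SPECIFIC", "UNCLASSIFIED")


def classify_gxe(cell_expressed: pd.DataFrame) -> pd.DataFrame:
    """Classify stringent expression patterns over a strain x environment grid.

    ``cell_expressed`` is a boolean genes x cells frame whose columns are
    ``(strain, environment)`` string tuples.  Genes expressed in no cell are
    dropped.  Returns a frame with ``label``, ``detail`` (the defining
    strain/environment/cell) and ``label_strict_env`` — the alternative
    reading in which GENOTYPE_SPECIFIC additionally requires a single
    environment (under which multi-environment one-strain patterns fall to
    UNCLASSIFIED).

    Labels are invariant under permuting the column order.
    """
    cols = list(cell_expressed.columns)
    if not cols or not all(isinstance(c, tuple) and len(c) == 2 for c in cols):
        raise ValidationError("columns must be (strain, environment) tuples")
    strains = {s for s, _ in cols}
    envs = {e for _, e in cols}
    if len(strains) < 2 or len(envs) < 2:
        raise ValidationError(
            f"classification needs >= 2 strains and >= 2 environments; got {sorted(strains)} x {sorted(envs)}"
        )
    values = cell_expressed.to_numpy(dtype=bool)
    records = []
    for gene_id, row in zip(cell_expressed.index, values):
        on = [cols[i] for i in np.flatnonzero(row)]
        if not on:
            continue
        on_strains = {s for s, _ in on}
        on_envs = {e for _, e in on}
        if len(on) == 1:
            s, e = on[0]
            label, detail = "INTERACTION", f"{s}:{e}"
        elif len(on_strains) == 1:
            label, detail = "GENOTYPE_SPECIFIC", next(iter(on_strains))
        elif len(on_envs) == 1:
            label, detail = "ENVIRONMENT_SPECIFIC", next(iter(on_envs))
        else:
            label, detail = "UNCLASSIFIED", ""
        strict = label
        if label == "GENOTYPE_SPECIFIC" and len(on_envs) > 1:
            strict = "UNCLASSIFIED"
        records.append((gene_id, label, detail, strict))
    return pd.DataFrame(
        records, columns=["gene_id", "label", "detail", "label_strict_env"]
    ).set_index("gene_id")


def _cells_from_calls(calls: ExpressionCalls, generation: str | None) -> pd.DataFrame:
    cond = calls.conditions
    keep = cond.index if generation is None else cond.index[cond["generation"] == generation]
    cells: dict[tuple[str, str], pd.Series] = {}
    for label in keep:
        cell = (cond.at[label, "strain"], cond.at[label, "environment"])
        col = calls.expressed[label]
        cells[cell] = cells.get(cell, False) | col
    return pd.DataFrame(cells, index=calls.expressed.index)


def gxe_classification(calls: ExpressionCalls, mode: str = "per_generation"):
    """Run the classifier over study-wide stringent calls.

    ``mode='per_generation'`` matches generations across experiments (one
    table per generation slice, skipping slices whose grid is degenerate);
    ``mode='pooled'`` enters a gene in a (strain, environment) cell if it is
    stringently expressed there in any generation, giving a single table
    over the full grid.
    """
    if mode == "pooled":
        return classify_gxe(_cells_from_calls(calls, None))
    if mode != "per_generation":
        raise ValidationError(f"unknown gxe mode {mode!r}")
    out: dict[str, pd.DataFrame] = {}
    for gen in Generation:
        cells = _cells_from_calls(calls, gen.value)
        strains = {s for s, _ in cells.columns}
        envs = {e for _, e in cells.columns}
        if len(strains) < 2 or len(envs) < 2:
            continue  # degenerate slice (single environment or strain)
        out[gen.value] = classify_gxe(cells)
    return out


def condition_specific_genes(calls: ExpressionCalls) -> pd.DataFrame:
    """Genes expressed in exactly one condition of the study.

    The lenient-threshold version of this list is the detector for
    condition-triggered dormant genes.
    """
    expressed = calls.expressed
    counts = expressed.sum(axis=1)
    mask = counts == 1
    cond = expressed.columns[np.argmax(expressed.loc[mask].to_numpy(), axis=1)] if mask.any() else []
    return pd.DataFrame({"condition": list(cond)}, index=expressed.index[mask])
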