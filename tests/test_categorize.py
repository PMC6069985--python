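"""Set logic: Venn partition, ncRNA profiling, unconfirmed evidence, G/E/GxE."""
from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

from wormnorm import (
    Biotype,
    GeneAnnotation,
    GeneClass,
    VENN_CATEGORIES,
    ValidationError,
    VennPartition,
    call_expression,
    classify_gxe,
    condition_specific_genes,
    conserved_ncrna,
    gxe_classification,
    ncrna_profile,
    unconfirmed_evidence,
    venn_partition,
)
from tests.conftest import make_matrix


def _experiment_calls(membership: dict[str, tuple[bool, bool, bool]]):
    """Build one-replicate-pair calls where each gene is on/off per generation."""
    samples = [
        ("p0_r1", "N2", "OP50_NGM", "P0", 1), ("p0_r2", "N2", "OP50_NGM", "P0", 2),
        ("f1_r1", "N2", "CeHR", "F1", 1), ("f1_r2", "N2", "CeHR", "F1", 2),
        ("f2_r1", "N2", "REVERSION_AGAR", "F2", 1), ("f2_r2", "N2", "REVERSION_AGAR", "F2", 2),
    ]
    genes = list(membership)
    cols = {}
    for si, s in enumerate(samples):
        gen_index = si // 2
        cols[s[0]] = [30.0 if membership[g][gen_index] else 0.0 for g in genes]
    df = pd.DataFrame(cols, index=genes)
    from wormnorm import ExpressionMatrix, SampleDescriptor, Strain, Environment, Generation
    descriptors = [
        SampleDescriptor(sid, Strain(st), Environment(env), Generation(gen), rep)
        for sid, st, env, gen, rep in samples
    ]
    return call_expression(ExpressionMatrix(df, descriptors), 1.0)


def _brute_force_category(p0: bool, f1: bool, f2: bool) -> str | None:
    """Independent 8-way truth table for the Venn category of one gene."""
    if not (p0 or f1 or f2):
        return None
    names = {
        (1, 0, 0): "P0_only", (0, 1, 0): "F1_only", (0, 0, 1): "F2_only",
        (1, 1, 0): "P0F1", (1, 0, 1): "P0F2", (0, 1, 1): "F1F2", (1, 1, 1): "P0F1F2",
    }
    return names[(int(p0), int(f1), int(f2))]


class TestVennPartition:
    @pytest.mark.parametrize("pattern, expected", [
        ((True, True, True), "P0F1F2"),
        ((False, True, True), "F1F2"),
        ((True, False, False), "P0_only"),
    ])
    def test_definition_examples(self, pattern, expected):
        calls = _experiment_calls({"g": pattern})
        part = venn_partition(calls, "exp")
        assert part.category_of("g") == expected

    def test_never_expressed_gene_is_outside_the_universe(self):
        part = venn_partition(_experiment_calls({"g": (False, False, False)}), "exp")
        assert part.universe == set()

    def test_exhaustive_truth_table_on_random_toy(self):
        """50 random genes: category sizes match the 8-way enumeration oracle."""
        rng = np.random.default_rng(5)
        membership = {f"g{i}": tuple(rng.random(3) < 0.5) for i in range(50)}
        part = venn_partition(_experiment_calls(membership), "exp")
        for gene, (p0, f1, f2) in membership.items():
            assert part.category_of(gene) == _brute_force_category(p0, f1, f2)

    def test_partition_is_disjoint_and_covers_universe(self, small_bundle):
        exp = small_bundle.experiments["N2_CeHR"]
        part = venn_partition(call_expression(exp.matrix, 1.0), "N2_CeHR")
        sizes = part.sizes()
        assert sum(sizes.values()) == len(part.universe)  # disjoint + cover

    def test_missing_generation_is_fatal(self, small_bundle):
        exp = small_bundle.experiments["N2_CeHR"]
        sub = exp.matrix.subset_samples(
            [s.sample_id for s in exp.matrix.samples if s.generation.value != "F2"]
        )
        with pytest.raises(ValidationError, match="three generations"):
            venn_partition(call_expression(sub, 1.0), "exp")


def _annotation(biotypes: dict[str, str], unconfirmed: set[str] = frozenset()):
    table = pd.DataFrame(
        {
            "biotype": [Biotype(b) for b in biotypes.values()],
            "confirmed": [g not in unconfirmed for g in biotypes],
        },
        index=pd.Index(biotypes.keys(), name="gene_id"),
    )
    return GeneAnnotation(table)


class TestNcrnaProfile:
    def test_hand_fraction(self):
        part = VennPartition("e", {"P0F1F2": {"g1", "g2"}})
        ann = _annotation({"g1": "ncRNA", "g2": "protein_coding"})
        prof = ncrna_profile(part, ann)
        assert prof.at["P0F1F2", "pct_ncrna"] == pytest.approx(50.0)

    def test_small_rna_exclusion_can_empty_a_category(self):
        part = VennPartition("e", {"F1_only": {"g1"}})
        ann = _annotation({"g1": "miRNA"})
        prof = ncrna_profile(part, ann)
        assert prof.at["F1_only", "size_after_exclusion"] == 0
        assert np.isnan(prof.at["F1_only", "pct_ncrna"])

    def test_uncoupled_ncrna_percentages_near_global_fraction(self, study_bundle):
        """No class-biotype coupling: each big category sits near 10 percent."""
        exp = study_bundle.experiments["N2_CeHR"]
        part = venn_partition(call_expression(exp.matrix, 1.0), "N2_CeHR")
        prof = ncrna_profile(part, study_bundle.annotation)
        for cat in VENN_CATEGORIES:
            n = prof.at[cat, "size_after_exclusion"]
            if n < 30:
                continue
            p = prof.at[cat, "pct_ncrna"] / 100.0
            sd = np.sqrt(0.1 * 0.9 / n)
            assert abs(p - 0.1) <= 3 * sd + 1e-9, f"{cat}: {p:.3f} at n={n}"


class TestConservedNcrna:
    def test_identical_sets_give_fraction_one(self):
        ann = _annotation({f"g{i}": "ncRNA" for i in range(3)})
        parts = [VennPartition(e, {"P0F1F2": {"g0", "g1", "g2"}}) for e in "abc"]
        out = conserved_ncrna(parts, ann)
        assert out["shared"] == {"g0", "g1", "g2"}
        assert all(f == 1.0 for f in out["fractions"].values())

    def test_disjoint_sets_give_empty_intersection(self):
        ann = _annotation({f"g{i}": "ncRNA" for i in range(3)})
        parts = [VennPartition(e, {"P0F1F2": {f"g{i}"}}) for i, e in enumerate("abc")]
        out = conserved_ncrna(parts, ann)
        assert out["shared"] == set()
        assert all(f == 0.0 for f in out["fractions"].values())

    def test_hand_enumerated_fractions(self):
        ann = _annotation({g: "ncRNA" for g in "abcdxyz"})
        parts = [
            VennPartition("e1", {"P0F1F2": {"a", "b", "c"}}),
            VennPartition("e2", {"P0F1F2": {"a", "b", "d"}}),
            VennPartition("e3", {"P0F1F2": {"a", "b", "x", "y"}}),
        ]
        out = conserved_ncrna(parts, ann)
        assert out["shared"] == {"a", "b"}
        assert out["fractions"] == {"e1": 2 / 3, "e2": 2 / 3, "e3": 2 / 4}


class TestUnconfirmedEvidence:
    def test_hand_fraction(self):
        calls = _experiment_calls({
            "g1": (True, False, False), "g2": (False, False, False),
            "g3": (False, False, False), "g4": (False, False, False),
        })
        ann = _annotation({f"g{i}": "protein_coding" for i in range(1, 5)},
                          unconfirmed={"g1", "g2", "g3", "g4"})
        out = unconfirmed_evidence([calls], ann)
        assert out["evidenced"] == {"g1"}
        assert out["pct_evidenced"] == pytest.approx(25.0)

    def test_no_expression_anywhere_gives_zero_percent(self):
        calls = _experiment_calls({"g1": (False,) * 3, "g2": (False,) * 3})
        ann = _annotation({"g1": "protein_coding", "g2": "protein_coding"},
                          unconfirmed={"g1", "g2"})
        assert unconfirmed_evidence([calls], ann)["pct_evidenced"] == 0.0

    def test_no_unconfirmed_genes_gives_undefined_marker(self):
        calls = _experiment_calls({"g1": (True, True, True)})
        ann = _annotation({"g1": "protein_coding"})
        assert np.isnan(unconfirmed_evidence([calls], ann)["pct_evidenced"])


def _brute_force_gxe(cells_on: set[tuple[str, str]]) -> tuple[str, str]:
    """Independent case analysis for a 2-strain x 2-environment grid."""
    strains = {s for s, _ in cells_on}
    envs = {e for _, e in cells_on}
    if len(cells_on) == 1:
        s, e = next(iter(cells_on))
        return "INTERACTION", f"{s}:{e}"
    if len(strains) == 1:
        return "GENOTYPE_SPECIFIC", next(iter(strains))
    if len(envs) == 1:
        return "ENVIRONMENT_SPECIFIC", next(iter(envs))
    return "UNCLASSIFIED", ""


class TestClassifyGxe:
    GRID = [("N2", "CeHR"), ("N2", "S_MEDIUM"), ("AB1", "CeHR"), ("AB1", "S_MEDIUM")]

    def _frame(self, patterns: dict[str, tuple[bool, ...]]) -> pd.DataFrame:
        return pd.DataFrame.from_dict(patterns, orient="index", columns=self.GRID)

    def test_environment_specific_example(self):
        out = classify_gxe(self._frame({"g": (True, False, True, False)}))
        assert out.at["g", "label"] == "ENVIRONMENT_SPECIFIC"
        assert out.at["g", "detail"] == "CeHR"

    def test_single_cell_is_interaction(self):
        out = classify_gxe(self._frame({"g": (True, False, False, False)}))
        assert out.at["g", "label"] == "INTERACTION"
        assert out.at["g", "detail"] == "N2:CeHR"

    def test_silent_gene_is_excluded_not_labelled(self):
        out = classify_gxe(self._frame({"g": (False,) * 4, "h": (True,) * 4}))
        assert list(out.index) == ["h"]

    def test_all_16_patterns_match_hand_case_table(self):
        """Exhaustive 2x2 grid enumeration against an independent case analysis."""
        patterns = {
            f"g{i}": tuple(bool(i >> k & 1) for k in range(4)) for i in range(16)
        }
        out = classify_gxe(self._frame(patterns))
        for gene, pat in patterns.items():
            on = {self.GRID[k] for k in range(4) if pat[k]}
            if not on:
                assert gene not in out.index
                continue
            label, detail = _brute_force_gxe(on)
            assert out.at[gene, "label"] == label
            assert out.at[gene, "detail"] == detail

    def test_strict_env_reading_downgrades_multi_env_genotype(self):
        out = classify_gxe(self._frame({"g": (True, True, False, False)}))
        assert out.at["g", "label"] == "GENOTYPE_SPECIFIC"
        assert out.at["g", "label_strict_env"] == "UNCLASSIFIED"

    def test_labels_invariant_under_column_permutation(self):
        rng = np.random.default_rng(7)
        patterns = {f"g{i}": tuple(rng.random(4) < 0.5) for i in range(40)}
        frame = self._frame(patterns)
        base = classify_gxe(frame)
        shuffled = classify_gxe(frame[[self.GRID[i] for i in (2, 0, 3, 1)]])
        pd.testing.assert_frame_equal(base.sort_index(), shuffled.sort_index())

    def test_degenerate_grid_is_fatal(self):
        frame = pd.DataFrame({("N2", "CeHR"): [True], ("AB1", "CeHR"): [True]},
                             index=["g"])
        with pytest.raises(ValidationError, match="2 strains"):
            classify_gxe(frame)

    def test_full_generation_grid_enumeration(self):
        """All 2^12 on/off patterns over 2 strains x 2 envs x 3 generations:
        pooled-mode labels match the brute-force case analysis of the pooled
        cell pattern."""
        strains = ["N2", "AB1"]
        envs = ["CeHR", "S_MEDIUM"]
        gens = ["P0", "F1", "F2"]
        cells = [(s, e, g) for s in strains for e in envs for g in gens]
        n = 2 ** 12
        patterns = np.array([[bool(i >> k & 1) for k in range(12)] for i in range(n)])
        genes = [f"g{i:04d}" for i in range(n)]

        samples = []
        values = {}
        for k, (s, e, g) in enumerate(cells):
            for rep in (1, 2):
                sid = f"c{k}_r{rep}"
                samples.append((sid, s, e, g, rep))
                values[sid] = list(np.where(patterns[:, k], 30.0, 0.0))
        m = make_matrix(values, samples)
        # make_matrix generates its own gene names g1..; rename to match
        m.values.index = genes
        calls = call_expression(m, 1.0)
        out = gxe_classification(calls, mode="pooled")
        for i, gene in enumerate(genes):
            on = {(cells[k][0], cells[k][1]) for k in range(12) if patterns[i, k]}
            if not on:
                assert gene not in out.index
                continue
            label, detail = _brute_force_gxe(on)
            assert out.at[gene, "label"] == label


class TestConditionSpecific:
    def test_exactly_one_condition(self):
        calls = _experiment_calls({"g1": (False, True, False), "g2": (True, True, False)})
        cs = condition_specific_genes(calls)
        assert list(cs.index) == ["g1"]
        assert cs.at["g1", "condition"] == "N2:CeHR:F1"
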