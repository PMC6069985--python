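"""Expression calling, summaries, Jensen-Shannon distance and clustering."""
from __future__ import annotations

import io as _io
import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wormnorm import (
    SimulationConfig,
    ValidationError,
    call_expression,
    cluster_conditions,
    jensen_shannon_distance,
    simulate_study,
    summarize_expression,
)
from tests.conftest import make_matrix


def _single_condition_matrix(replicate_sets: dict[str, list[float]]):
    """One condition per key; three replicates each, gene rows from values."""
    samples = []
    values = {}
    envs = ["OP50_NGM", "CeHR", "S_MEDIUM", "REVERSION_AGAR"]
    for i, (name, _) in enumerate(replicate_sets.items()):
        for r in range(1, 4):
            samples.append((f"{name}_r{r}", "N2", envs[i % 4], "P0", r))
    for name, reps in replicate_sets.items():
        for r, rep_values in enumerate(reps, start=1):
            values[f"{name}_r{r}"] = rep_values if isinstance(rep_values, list) else [rep_values]
    return make_matrix(values, samples)


class TestCallExpression:
    def test_mean_above_threshold_is_expressed(self):
        m = _single_condition_matrix({"a": [1.2, 1.4, 1.6]})
        calls = call_expression(m, 1.0)
        assert calls.means.iloc[0, 0] == pytest.approx(1.4)
        assert bool(calls.expressed.iloc[0, 0])

    def test_boundary_is_strictly_greater_than(self):
        m = _single_condition_matrix({"a": [1.0, 1.0, 1.0]})
        assert not call_expression(m, 1.0).expressed.iloc[0, 0]

    @pytest.mark.parametrize(
        "reps, lenient, stringent",
        [([30.0, 30.0, 30.0], True, True), ([15.0, 15.0, 15.0], True, False)],
    )
    def test_lenient_and_stringent_thresholds(self, reps, lenient, stringent):
        m = _single_condition_matrix({"a": reps})
        assert bool(call_expression(m, 1.0).expressed.iloc[0, 0]) is lenient
        assert bool(call_expression(m, 21.0).expressed.iloc[0, 0]) is stringent

    def test_monotone_in_threshold(self, one_experiment_matrix):
        """Raising the threshold never adds expressed genes."""
        lo = call_expression(one_experiment_matrix, 0.5).expressed
        hi = call_expression(one_experiment_matrix, 5.0).expressed
        assert (hi <= lo).all().all()

    def test_brute_force_oracle_small_matrix(self):
        """Expressed sets match an independent double loop on a 5x4 grid."""
        rng = np.random.default_rng(17)
        raw = rng.lognormal(0.5, 1.0, size=(5, 4))
        samples = [
            ("c1_r1", "N2", "OP50_NGM", "P0", 1), ("c1_r2", "N2", "OP50_NGM", "P0", 2),
            ("c2_r1", "N2", "CeHR", "F1", 1), ("c2_r2", "N2", "CeHR", "F1", 2),
        ]
        values = {s[0]: list(raw[:, i]) for i, s in enumerate(samples)}
        m = make_matrix(values, samples)
        calls = call_expression(m, 1.0)
        for gi in range(5):
            for cond, cols in (("N2:OP50_NGM:P0", [0, 1]), ("N2:CeHR:F1", [2, 3])):
                mean = sum(raw[gi, c] for c in cols) / len(cols)
                assert bool(calls.expressed.iloc[gi][cond]) == (mean > 1.0)

    def test_nonpositive_threshold_rejected(self, one_experiment_matrix):
        with pytest.raises(ValidationError):
            call_expression(one_experiment_matrix, 0.0)


class TestSummarize:
    def test_hand_sum(self):
        m = _single_condition_matrix({"a": [[10.0, 0.0], [10.0, 0.0], [10.0, 0.0]]})
        s = summarize_expression(m)
        assert s["total_fpkm"].iloc[0] == pytest.approx(10.0)
        assert s["n_expressed"].iloc[0] == 1
        assert s["mean_fpkm_expressed"].iloc[0] == pytest.approx(10.0)

    def test_all_zero_matrix_has_undefined_average(self):
        m = _single_condition_matrix({"a": [[0.0, 0.0], [0.0, 0.0], [0.0, 0.0]]})
        s = summarize_expression(m)
        assert s["total_fpkm"].iloc[0] == 0.0
        assert np.isnan(s["mean_fpkm_expressed"].iloc[0])

    def test_doubling_fpkm_doubles_total_and_average(self, small_bundle):
        m = small_bundle.experiments["N2_CeHR"].matrix
        from wormnorm import ExpressionMatrix
        m2 = ExpressionMatrix(m.values * 2.0, m.samples)
        s1 = summarize_expression(m)
        s2 = summarize_expression(m2)
        assert np.allclose(s2["total_fpkm"], 2 * s1["total_fpkm"])
        # expressed sets can differ near the threshold; restrict to conditions
        # where they do not
        same = (s1["n_expressed"] == s2["n_expressed"]).to_numpy()
        assert np.allclose(
            s2["mean_fpkm_expressed"].to_numpy()[same],
            2 * s1["mean_fpkm_expressed"].to_numpy()[same],
        )


class TestJensenShannon:
    def test_identity(self):
        assert jensen_shannon_distance([0.2, 0.3, 0.5], [0.2, 0.3, 0.5]) == 0.0

    def test_disjoint_supports_give_exactly_one(self):
        assert jensen_shannon_distance([1.0, 0.0], [0.0, 1.0]) == 1.0

    def test_matches_term_by_term_base2_formula(self):
        """Independent closed-form evaluation of sqrt(JSD) for a fixed pair."""
        p = np.array([0.5, 0.5])
        q = np.array([0.9, 0.1])
        m = (p + q) / 2
        kl = lambda x, y: sum(xi * np.log2(xi / yi) for xi, yi in zip(x, y) if xi > 0)
        expected = np.sqrt((kl(p, m) + kl(q, m)) / 2)
        assert jensen_shannon_distance(p, q) == pytest.approx(expected, abs=1e-12)

    def test_unnormalized_inputs_are_treated_as_proportions(self):
        a = jensen_shannon_distance([5.0, 5.0], [9.0, 1.0])
        b = jensen_shannon_distance([0.5, 0.5], [0.9, 0.1])
        assert a == pytest.approx(b, abs=1e-12)

    def test_metric_properties_on_random_triples(self):
        """Identity, symmetry, triangle inequality, [0, 1] bound; 1000 triples."""
        rng = np.random.default_rng(23)
        for _ in range(1000):
            p, q, r = rng.lognormal(0, 1, size=(3, 5))
            dpq = jensen_shannon_distance(p, q)
            dqp = jensen_shannon_distance(q, p)
            dpr = jensen_shannon_distance(p, r)
            dqr = jensen_shannon_distance(q, r)
            assert dpq == pytest.approx(dqp, abs=1e-12)
            assert -1e-12 <= dpq <= 1 + 1e-12
            assert dpr <= dpq + dqr + 1e-12
        assert jensen_shannon_distance(p, p) == 0.0

    @pytest.mark.parametrize("bad_p, bad_q, msg", [
        ([1.0, -0.1], [0.5, 0.5], "negative"),
        ([0.0, 0.0], [0.5, 0.5], "zero sum"),
        ([1.0], [0.5, 0.5], "length"),
    ])
    def test_invalid_profiles_are_fatal(self, bad_p, bad_q, msg):
        with pytest.raises(ValidationError, match=msg):
            jensen_shannon_distance(bad_p, bad_q)


class TestClustering:
    def test_identical_conditions_merge_first(self):
        samples = [
            (f"{c}_r{r}", "N2", env, "P0", r)
            for c, env in (("a", "OP50_NGM"), ("b", "CeHR"), ("c", "S_MEDIUM"))
            for r in (1, 2)
        ]
        profile_ab = [10.0, 1.0, 5.0]
        profile_c = [1.0, 10.0, 0.5]
        values = {
            "a_r1": profile_ab, "a_r2": profile_ab,
            "b_r1": profile_ab, "b_r2": profile_ab,
            "c_r1": profile_c, "c_r2": profile_c,
        }
        m = make_matrix(values, samples)
        clustering = cluster_conditions(m)
        # A = B so the first merge joins them at height 0
        assert clustering.linkage[0, 2] == pytest.approx(0.0, abs=1e-12)
        left, right = clustering.root_bipartition()
        assert {frozenset(left), frozenset(right)} == {
            frozenset({"N2:OP50_NGM:P0", "N2:CeHR:P0"}),
            frozenset({"N2:S_MEDIUM:P0"}),
        }

    def test_distance_matrix_invariants(self, small_bundle):
        clustering = cluster_conditions(small_bundle.combined_matrix())
        d = clustering.distance.distances
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0)
        assert ((d >= 0) & (d <= 1)).all()

    def test_newick_parses_and_covers_all_conditions(self, small_bundle):
        Phylo = pytest.importorskip("Bio.Phylo")
        clustering = cluster_conditions(small_bundle.combined_matrix())
        tree = Phylo.read(_io.StringIO(clustering.newick), "newick")
        names = {leaf.name for leaf in tree.get_terminals()}
        assert names == set(clustering.distance.labels)

    def test_strong_genotype_offsets_split_tree_by_strain(self):
        """Planted strain differences 4x the environment effect dominate the root."""
        cfg = SimulationConfig(n_genes=3000, env_log2_effect=1.0,
                               genotype_log2_offset=4.0, rng_seed=31)
        bundle = simulate_study(cfg)
        clustering = cluster_conditions(bundle.combined_matrix())
        left, right = clustering.root_bipartition()
        strains = lambda labels: {l.split(":")[0] for l in labels}
        assert {frozenset(strains(left)), frozenset(strains(right))} == {
            frozenset({"N2"}), frozenset({"AB1"})
        }
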