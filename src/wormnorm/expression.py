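"""Expression calling, per-condition summaries, and Jensen-Shannon sample clustering.

A gene is called expressed in a condition when the arithmetic mean of its
replicate FPKMs is strictly greater than the threshold (lenient rule:
FPKM > 1; stringent rule: FPKM > 21, the expression level of the
housekeeping anchor pmp-3).  Sample similarity is the Jensen-Shannon
distance between per-condition expression profiles treated as proportions,
with average-linkage agglomerative clustering on top.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import jensenshannon, squareform

from .datatypes import ExpressionMatrix, ValidationError, parse_condition_label


@dataclass
class ExpressionCalls:
    """Per-(gene, condition) mean FPKM and expressed flags at one threshold."""

    means: pd.DataFrame      # genes x condition labels, arithmetic replicate means
    expressed: pd.DataFrame  # same shape, boolean: mean > threshold
    threshold: float
    conditions: pd.DataFrame  # condition label -> strain/environment/generation

    @property
    def condition_labels(self) -> list[str]:
        return list(self.means.columns)

    def expressed_set(self, condition: str) -> set[str]:
        return set(self.expressed.index[self.expressed[condition]])


def _condition_table(labels) -> pd.DataFrame:
    rows = []
    for label in labels:
        strain, env, gen = parse_condition_label(label)
        rows.append({"condition": label, "strain": strain.value,
                     "environment": env.value, "generation": gen.value})
    return pd.DataFrame(rows).set_index("condition")


def call_expression(matrix: ExpressionMatrix, threshold: float) -> ExpressionCalls:
    """Call expression per condition: replicate mean strictly above ``threshold``.

    Boundary behaviour is deliberate: a condition mean exactly equal to the
    threshold is *not* expressed ("greater than", not "at least").
    """
    if threshold <= 0:
        raise ValidationError(f"threshold must be > 0, got {threshold}")
    cols = matrix.condition_columns()
    empty = [c for c, ids in cols.items() if len(ids) == 0]
    if empty or not cols:
        raise ValidationError(f"conditions without replicates: {empty or 'none present'}")
    means = matrix.condition_means()
    return ExpressionCalls(means, means > threshold, float(threshold), _condition_table(means.columns))


def summarize_expression(matrix: ExpressionMatrix, expressed_threshold: float = 1.0) -> pd.DataFrame:
    """Per-condition total FPKM and average FPKM over expressed genes.

    ``total_fpkm`` sums the condition means over all genes;
    ``mean_fpkm_expressed`` divides by the number of genes passing the
    lenient call in that condition and is NaN (undefined, not zero) when no
    gene is expressed.
    """
    calls = call_expression(matrix, expressed_threshold)
    total = calls.means.sum(axis=0)
    n_expr = calls.expressed.sum(axis=0)
    avg = total / n_expr.where(n_expr > 0)
    return pd.DataFrame({
        "total_fpkm": total,
        "n_expressed": n_expr.astype(int),
        "mean_fpkm_expressed": avg,
    })


def jensen_shannon_distance(p_profile, q_profile) -> float:
    """Jensen-Shannon distance between two abundance profiles.

    Profiles are normalized to proportions; the divergence uses base-2
    logarithms against the midpoint mixture and the distance is its square
    root, a metric bounded in [0, 1] (disjoint supports give exactly 1).
    """
    p = np.asarray(p_profile, dtype=float)
    q = np.asarray(q_profile, dtype=float)
    if p.shape != q.shape:
        raise ValidationError(f"profile lengths differ: {p.shape} vs {q.shape}")
    for name, v in (("p", p), ("q", q)):
        if (v < 0).any():
            raise ValidationError(f"profile {name} has negative entries")
        if v.sum() <= 0:
            raise ValidationError(f"profile {name} has zero sum")
    return float(jensenshannon(p, q, base=2))


@dataclass
class SampleDistanceMatrix:
    """Symmetric pairwise Jensen-Shannon distances with labels."""

    labels: list[str]
    distances: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.distances, dtype=float)
        n = len(self.labels)
        if d.shape != (n, n):
            raise ValidationError(f"distance grid shape {d.shape} does not match {n} labels")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValidationError("distance matrix is not symmetric")
        if not np.allclose(np.diag(d), 0.0, atol=1e-12):
            raise ValidationError("distance matrix diagonal is not zero")
        if (d < -1e-12).any() or (d > 1 + 1e-12).any():
            raise ValidationError("distances must lie in [0, 1]")
        self.distances = d

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.distances, index=self.labels, columns=self.labels)


def distance_matrix(profiles: pd.DataFrame) -> SampleDistanceMatrix:
    """Pairwise JS distances between the columns of a genes x profiles frame."""
    labels = list(profiles.columns)
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = jensen_shannon_distance(
                profiles.iloc[:, i].to_numpy(), profiles.iloc[:, j].to_numpy()
            )
    return SampleDistanceMatrix(labels, d)


def _quote_newick_label(label: str) -> str:
    # condition labels contain ':', a Newick delimiter; quote when needed
    if any(ch in label for ch in ":;,()[]' \t"):
        return "'" + label.replace("'", "''") + "'"
    return label


def linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    """Serialize a scipy linkage as Newick with branch lengths from merge heights."""
    tree = hierarchy.to_tree(Z)

    def walk(node, parent_height: float) -> str:
        if node.is_leaf():
            return f"{_quote_newick_label(labels[node.id])}:{parent_height:.10g}"
        length = parent_height - node.dist
        left = walk(node.get_left(), node.dist)
        right = walk(node.get_right(), node.dist)
        return f"({left},{right}):{length:.10g}"

    inner = walk(tree, tree.dist)
    # the root carries no branch; strip its length
    return inner.rsplit(":", 1)[0] + ";"


@dataclass
class ConditionClustering:
    distance: SampleDistanceMatrix
    linkage: np.ndarray
    newick: str

    def root_bipartition(self) -> tuple[frozenset, frozenset]:
        """Labels on either side of the final (root) merge."""
        assignment = hierarchy.fcluster(self.linkage, t=2, criterion="maxclust")
        left = frozenset(l for l, a in zip(self.distance.labels, assignment) if a == 1)
        right = frozenset(l for l, a in zip(self.distance.labels, assignment) if a == 2)
        return left, right


def cluster_conditions(matrix: ExpressionMatrix, method: str = "average",
                       per_replicate: bool = False) -> ConditionClustering:
    """JS-distance clustering of per-condition mean profiles.

    The headline tree clusters conditions; ``per_replicate=True`` gives the
    per-sample QC variant.  Linkage defaults to average (UPGMA); the choice
    is recorded in the pipeline's threshold log.
    """
    profiles = matrix.values if per_replicate else matrix.condition_means()
    if profiles.shape[1] < 2:
        raise ValidationError("need at least two conditions to cluster")
    dm = distance_matrix(profiles)
    Z = hierarchy.linkage(squareform(dm.distances, checks=False), method=method)
    return ConditionClustering(dm, Z, linkage_to_newick(Z, dm.labels))
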