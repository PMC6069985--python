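"""Differential expression between two conditions from replicate FPKMs.

A gene is differentially expressed when it jointly passes three criteria:
an expression gate (lenient-expressed, FPKM > 1, in at least one of the two
conditions), a fold-change cutoff (|log2FC| >= 1, i.e. two-fold, by
default; a four-fold preset exists because the stricter reading of the
selection rule is log2FC > 2), and a Benjamini-Hochberg adjusted p-value
<= 0.05.  The per-gene test is a two-sided two-sample t-test on
log2(FPKM + pseudocount) replicate values with pooled variance — the log
transform stabilizes the multiplicative replicate noise, making the
equal-variance pooling appropriate and the test exactly calibrated under
the null at three replicates per side (an unequal-variance Welch test with
its estimated degrees of freedom is markedly conservative at such depths).
It is a transparent, replicate-aware stand-in for an assembly-based
differential test, isolated behind ``test_gene`` so the surrounding set
logic does not depend on the choice.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ExpressionMatrix, RunConfig, ValidationError


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in the input order.

    q_(i) = min_{j >= i} ( m * p_(j) / j ), clipped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValidationError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _log_t_test(a: np.ndarray, b: np.ndarray, pseudocount: float) -> np.ndarray:
    """Vectorized two-sided pooled-variance t on log2(x + pseudocount); rows are genes."""
    la = np.log2(a + pseudocount)
    lb = np.log2(b + pseudocount)
    with warnings.catch_warnings():
        # zero-variance rows trigger a precision warning; they are repaired below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(la, lb, axis=1, equal_var=True)
    p = np.asarray(res.pvalue, dtype=float)
    # degenerate rows: both sides have zero variance
    var_a = la.var(axis=1)
    var_b = lb.var(axis=1)
    degenerate = (var_a == 0) & (var_b == 0)
    if degenerate.any():
        equal = np.isclose(la.mean(axis=1), lb.mean(axis=1))
        p[degenerate & equal] = 1.0
        p[degenerate & ~equal] = 0.0
    return np.clip(p, 0.0, 1.0)


def test_gene(replicates_a, replicates_b, pseudocount: float = 1.0) -> tuple[float, float]:
    """Per-gene (log2 fold change, raw p) for one contrast.

    log2FC = log2((mean_b + pseudocount) / (mean_a + pseudocount)); the
    pseudocount stabilizes fold changes at near-zero FPKM.  Positive values
    mean higher in ``b``.
    """
    a = np.asarray(replicates_a, dtype=float)
    b = np.asarray(replicates_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError(f"need >= 2 replicates per side, got {a.size} and {b.size}")
    if pseudocount <= 0:
        raise ValidationError("pseudocount must be > 0")
    log2fc = float(np.log2((b.mean() + pseudocount) / (a.mean() + pseudocount)))
    p = float(_log_t_test(a[None, :], b[None, :], pseudocount)[0])
    return log2fc, p


test_gene.__test__ = False  # a library function, not a pytest case


def call_degs(
    matrix: ExpressionMatrix,
    condition_a: str,
    condition_b: str,
    config: RunConfig | None = None,
) -> pd.DataFrame:
    """DEG table for condition_b relative to condition_a.

    Columns: mean_a, mean_b, log2fc, p_raw, q_bh, direction (UP/DOWN/NONE,
    by the sign of log2fc; UP = higher in b), passes_expression, is_deg.
    BH adjustment runs over the genes passing the expression gate; gated-out
    genes carry q_bh = NaN and is_deg = False.
    """
    if config is None:
        config = RunConfig()
    if condition_a == condition_b:
        raise ValidationError(f"conditions are identical: {condition_a!r}")
    cols = matrix.condition_columns()
    for cond in (condition_a, condition_b):
        if cond not in cols:
            raise ValidationError(f"condition {cond!r} not present in the matrix")
        if len(cols[cond]) < 2:
            raise ValidationError(
                f"condition {cond!r} has {len(cols[cond])} replicate(s); contrasts need >= 2"
            )
    a = matrix.values[cols[condition_a]].to_numpy(dtype=float)
    b = matrix.values[cols[condition_b]].to_numpy(dtype=float)
    mean_a = a.mean(axis=1)
    mean_b = b.mean(axis=1)
    pc = config.pseudocount
    log2fc = np.log2((mean_b + pc) / (mean_a + pc))
    p_raw = _log_t_test(a, b, pc)

    gate = (mean_a > config.expressed_threshold) | (mean_b > config.expressed_threshold)
    q = np.full(len(p_raw), np.nan)
    if gate.any():
        q[gate] = bh_adjust(p_raw[gate])

    is_deg = gate & (np.abs(log2fc) >= config.log2fc_threshold) & (q <= config.fdr_alpha)
    direction = np.where(log2fc > 0, "UP", np.where(log2fc < 0, "DOWN", "NONE"))

    table = pd.DataFrame(
        {
            "mean_a": mean_a,
            "mean_b": mean_b,
            "log2fc": log2fc,
            "p_raw": p_raw,
            "q_bh": q,
            "direction": direction,
            "passes_expression": gate,
            "is_deg": is_deg,
        },
        index=matrix.gene_ids,
    )
    table.attrs["condition_a"] = condition_a
    table.attrs["condition_b"] = condition_b
    table.attrs["config"] = config.to_dict()
    return table


def deg_sets(table: pd.DataFrame) -> dict[str, set[str]]:
    """Up/down DEG gene sets of a table (UP = higher in condition_b)."""
    up = set(table.index[table["is_deg"] & (table["direction"] == "UP")])
    down = set(table.index[table["is_deg"] & (table["direction"] == "DOWN")])
    return {"UP": up, "DOWN": down}
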