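"""In-house statistical tests: hypergeometric overlap and Yates-corrected chi-squared.

Both are small enough to state exactly.  The hypergeometric upper tail is
evaluated in log-space (log-gamma binomials + log-sum-exp) so overlaps of
thousands of genes out of a 20k universe do not underflow; the chi-squared
statistic uses the classical continuity-corrected closed form for a 2x2
table with the corrected difference floored at zero.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, logsumexp
from scipy.stats import chi2

from .datatypes import ValidationError


def _log_comb(n, k) -> np.ndarray:
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def hypergeom_upper_tail(universe_n: int, marked_k: int, drawn_n: int, overlap_k: int) -> float:
    """P(X >= overlap_k) when drawing ``drawn_n`` genes without replacement
    from a universe of ``universe_n`` containing ``marked_k`` marked genes.

    Returns a probability in (0, 1]; ``overlap_k = 0`` gives exactly 1.
    """
    N, K, n, k = universe_n, marked_k, drawn_n, overlap_k
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValidationError(f"inconsistent arguments: universe={N}, marked={K}, drawn={n}")
    if not (0 <= k <= min(K, n)):
        raise ValidationError(f"overlap {k} outside [0, min(marked={K}, drawn={n})]")
    if k == 0:
        return 1.0
    support = np.arange(max(k, n - (N - K)), min(K, n) + 1)
    log_pmf = _log_comb(K, support) + _log_comb(N - K, n - support) - _log_comb(N, n)
    return float(min(1.0, np.exp(logsumexp(log_pmf))))


@dataclass(frozen=True)
class ContingencyTable2x2:
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        cells = (self.a, self.b, self.c, self.d)
        if any(int(x) != x or x < 0 for x in cells):
            raise ValidationError(f"cells must be non-negative integers, got {cells}")
        if sum(cells) == 0:
            raise ValidationError("at least one cell must be positive")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


def chisq_yates(table: ContingencyTable2x2) -> tuple[float, float]:
    """Yates continuity-corrected chi-squared statistic and p (1 df).

    statistic = N * (max(|ad - bc| - N/2, 0))^2 / (r1 * r2 * c1 * c2).
    A zero marginal makes the statistic undefined: (nan, nan) is returned
    rather than raising, so callers can log and continue.
    """
    a, b, c, d = float(table.a), float(table.b), float(table.c), float(table.d)
    n = a + b + c + d
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        return float("nan"), float("nan")
    corrected = max(abs(a * d - b * c) - n / 2.0, 0.0)
    stat = n * corrected**2 / (r1 * r2 * c1 * c2)
    return float(stat), float(chi2.sf(stat, df=1))


def compare_category_counts(count_a: int, total_a: int, count_b: int, total_b: int) -> tuple[float, float]:
    """Yates chi-squared comparing two category proportions.

    Builds the 2x2 table (count, total - count) per group and delegates to
    :func:`chisq_yates` — e.g. comparing the number of uniquely expressed
    genes between two experiments.
    """
    for count, total, name in ((count_a, total_a, "a"), (count_b, total_b, "b")):
        if count < 0 or total < 0:
            raise ValidationError(f"group {name}: counts must be non-negative")
        if count > total:
            raise ValidationError(f"group {name}: count {count} exceeds total {total}")
    table = ContingencyTable2x2(count_a, total_a - count_a, count_b, total_b - count_b)
    return chisq_yates(table)
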