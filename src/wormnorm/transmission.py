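"""Transgenerational transmission of environment-induced differential expression.

Given DEG tables for F1-vs-P0 and F2-vs-P0 of one experiment, genes are
partitioned per direction into F1-only, F2-only and F1F2 (differential in
both generations with a consistent direction — the transmitted response).
The transmission fraction is |F1F2| / (|F1-only| + |F1F2|): the share of
the F1 response that persisted in F2 after the return to the original
environment.  Overlap enrichment is an upper-tail hypergeometric test
against the tested gene universe.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .datatypes import ValidationError
from .degs import deg_sets
from .stats import hypergeom_upper_tail


@dataclass
class TransmissionResult:
    experiment_id: str
    direction: str  # "UP", "DOWN" or "pooled"
    f1_only: frozenset
    f2_only: frozenset
    f1f2: frozenset
    transmission_fraction: float  # NaN when no F1 DEGs exist
    universe_size: int
    hypergeom_p: float
    n_overlap_any_direction: int = 0  # secondary, direction-agnostic overlap

    def __post_init__(self) -> None:
        if self.f1_only & self.f1f2 or self.f2_only & self.f1f2 or self.f1_only & self.f2_only:
            raise ValidationError("transmission categories must be pairwise disjoint")

    @property
    def n_f1(self) -> int:
        return len(self.f1_only) + len(self.f1f2)

    @property
    def n_f2(self) -> int:
        return len(self.f2_only) + len(self.f1f2)


def _one_direction(f1: set, f2: set, universe_size: int, any_overlap: int,
                   experiment_id: str, direction: str) -> TransmissionResult:
    f1f2 = f1 & f2
    f1_only = f1 - f2
    f2_only = f2 - f1
    denom = len(f1_only) + len(f1f2)
    fraction = len(f1f2) / denom if denom else float("nan")
    p = hypergeom_upper_tail(universe_size, len(f1), len(f2), min(len(f1f2), len(f1), len(f2)))
    return TransmissionResult(
        experiment_id, direction, frozenset(f1_only), frozenset(f2_only), frozenset(f1f2),
        fraction, universe_size, p, any_overlap,
    )


def transmission(
    deg_f1: pd.DataFrame,
    deg_f2: pd.DataFrame,
    universe: set | None = None,
    experiment_id: str = "",
) -> dict[str, TransmissionResult]:
    """Per-direction and pooled transmission of F1 DEGs into F2.

    Both tables must be computed against the same P0 baseline over the same
    gene universe.  ``universe`` defaults to the genes passing the
    expression gate in both contrasts (the tested genes, not the whole
    annotation); pass an explicit set to override.

    F1F2 membership requires the same direction in both generations; the
    direction-agnostic overlap is reported as a secondary count.  The
    ``pooled`` entry combines both directions (direction consistency still
    required gene-wise).
    """
    if set(deg_f1.index) != set(deg_f2.index):
        raise ValidationError("DEG tables cover different gene universes")
    if universe is None:
        universe = set(deg_f1.index[deg_f1["passes_expression"] | deg_f2["passes_expression"]])
    else:
        universe = set(universe)
        stray = (set(deg_f1.index[deg_f1["is_deg"]]) | set(deg_f2.index[deg_f2["is_deg"]])) - universe
        if stray:
            raise ValidationError(f"DEGs outside the supplied universe, e.g. {sorted(stray)[:5]}")

    sets_f1 = deg_sets(deg_f1)
    sets_f2 = deg_sets(deg_f2)
    all_f1 = sets_f1["UP"] | sets_f1["DOWN"]
    all_f2 = sets_f2["UP"] | sets_f2["DOWN"]
    any_overlap = len(all_f1 & all_f2)

    out: dict[str, TransmissionResult] = {}
    for direction in ("UP", "DOWN"):
        out[direction] = _one_direction(
            sets_f1[direction], sets_f2[direction], len(universe), any_overlap,
            experiment_id, direction,
        )
    # pooled: union of directions with gene-wise direction consistency
    consistent_f2 = (sets_f1["UP"] & sets_f2["UP"]) | (sets_f1["DOWN"] & sets_f2["DOWN"])
    pooled_f1 = all_f1
    pooled_f2_for_sets = (all_f2 - all_f1) | consistent_f2
    out["pooled"] = _one_direction(
        pooled_f1, pooled_f2_for_sets, len(universe), any_overlap, experiment_id, "pooled"
    )
    return out


def transmission_table(results: dict[str, TransmissionResult]) -> pd.DataFrame:
    rows = []
    for direction, r in results.items():
        rows.append({
            "experiment_id": r.experiment_id,
            "direction": direction,
            "n_f1_only": len(r.f1_only),
            "n_f2_only": len(r.f2_only),
            "n_f1f2": len(r.f1f2),
            "transmission_fraction": r.transmission_fraction,
            "universe_size": r.universe_size,
            "hypergeom_p": r.hypergeom_p,
            "n_overlap_any_direction": r.n_overlap_any_direction,
        })
    return pd.DataFrame(rows).set_index(["experiment_id", "direction"])
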