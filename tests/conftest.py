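"""Shared fixtures: tiny hand-built matrices and seeded simulated studies."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from wormnorm import (
    Environment,
    ExpressionMatrix,
    Generation,
    RunConfig,
    SampleDescriptor,
    SimulationConfig,
    Strain,
    simulate_study,
)


def make_matrix(values: dict[str, list[float]], samples: list[tuple]) -> ExpressionMatrix:
    """Build an ExpressionMatrix from per-sample columns and descriptor tuples.

    ``samples`` entries are (sample_id, strain, environment, generation,
    replicate) with enum members or their string values.
    """
    descriptors = [
        SampleDescriptor(
            sid,
            Strain(strain),
            Environment(env),
            Generation(gen),
            rep,
        )
        for sid, strain, env, gen, rep in samples
    ]
    genes = [f"g{i}" for i in range(1, len(next(iter(values.values()))) + 1)]
    df = pd.DataFrame(values, index=genes)
    return ExpressionMatrix(df, descriptors)


@pytest.fixture
def one_experiment_matrix() -> ExpressionMatrix:
    """3 genes x 3 generations x 2 replicates of an N2 agar-liquid-agar run."""
    samples = [
        ("p0_r1", "N2", "OP50_NGM", "P0", 1),
        ("p0_r2", "N2", "OP50_NGM", "P0", 2),
        ("f1_r1", "N2", "CeHR", "F1", 1),
        ("f1_r2", "N2", "CeHR", "F1", 2),
        ("f2_r1", "N2", "REVERSION_AGAR", "F2", 1),
        ("f2_r2", "N2", "REVERSION_AGAR", "F2", 2),
    ]
    values = {
        "p0_r1": [10.0, 0.2, 5.0],
        "p0_r2": [12.0, 0.4, 5.0],
        "f1_r1": [10.0, 8.0, 0.1],
        "f1_r2": [11.0, 9.0, 0.2],
        "f2_r1": [9.0, 0.3, 5.5],
        "f2_r2": [10.0, 0.5, 4.5],
    }
    return make_matrix(values, samples)


@pytest.fixture(scope="session")
def run_config() -> RunConfig:
    return RunConfig()


@pytest.fixture(scope="session")
def small_bundle():
    """A fast 600-gene study bundle for structural checks."""
    return simulate_study(SimulationConfig(n_genes=600, rng_seed=11))


@pytest.fixture(scope="session")
def study_bundle():
    """The full-size study: 10k genes, planted classes at their defaults.

    Session-scoped because simulation plus the six DEG contrasts back most
    of the recovery tests.
    """
    return simulate_study(SimulationConfig(rng_seed=20260926 % (2**31)))
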