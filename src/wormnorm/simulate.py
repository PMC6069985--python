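"""Synthetic multi-generation FPKM study generator with planted ground truth.

The generator emulates a three-experiment reaction-norm design: in each
experiment one strain is grown on standard agar (P0), shifted to a liquid
medium (F1), and returned to agar (F2), with replicated RNA-seq per
generation.  Gene classes are planted with known effect sizes so every
downstream stage — expression calling, Venn partitioning, the
genotype/environment/interaction classifier, differential expression, and
transmission quantification — can be tested for recovery against an exact
truth table.

Planted classes
---------------
ENV_RESPONDER
    Shifts by +/- ``env_log2_effect`` in the F1 (liquid) generation of every
    experiment; a Bernoulli(``transmission_tau``) draw per gene decides
    whether the shift persists in F2 after the return to agar.
GENOTYPE_OFFSET
    Expressed at a high level in one target strain and a low level in the
    other, in all environments and generations (a constitutive strain
    difference).  Levels straddle the stringent call threshold so the
    pattern is "expressed in one strain only".
INTERACTION
    Expressed above the stringent threshold only in one target
    (strain, environment) cell — the single-cell reaction-norm pattern.
CONDITION_SPECIFIC_DORMANT
    Expected FPKM far below the lenient call threshold everywhere except
    one designated (strain, environment, generation) condition, where it is
    comfortably above it (but below the stringent threshold: these are
    weakly expressed, condition-triggered genes).
NULL_GENE
    Constant expectation everywhere.

Replicate values are drawn log-normally around the planted cell mean with a
fixed coefficient of variation, so emitted FPKMs are positive and the
empirical replicate mean converges to the planted mean.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, fields, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .datatypes import (
    Biotype,
    Condition,
    Environment,
    ExpressionMatrix,
    GeneAnnotation,
    Generation,
    SampleDescriptor,
    Strain,
    ValidationError,
    condition_label,
)

GENERATIONS = (Generation.P0, Generation.F1, Generation.F2)


class GeneClass(str, enum.Enum):
    NULL_GENE = "NULL_GENE"
    ENV_RESPONDER = "ENV_RESPONDER"
    GENOTYPE_OFFSET = "GENOTYPE_OFFSET"
    INTERACTION = "INTERACTION"
    CONDITION_SPECIFIC_DORMANT = "CONDITION_SPECIFIC_DORMANT"


@dataclass
class SimulationConfig:
    """Knobs of the generator; defaults are the study conditions.

    Fractions partition the gene universe deterministically (exact class
    sizes from a seeded permutation, not independent coin flips), so
    recovery tests have exact denominators.  ``replicate_cv`` is a pure
    convention (no empirical dispersion estimate exists to copy); 0.2 is a
    typical within-condition CV for bulk RNA-seq abundances.
    """

    n_genes: int = 10_000
    fraction_env_responders: float = 0.10
    fraction_genotype_offset: float = 0.05
    fraction_interaction: float = 0.03
    fraction_dormant: float = 0.05
    fraction_ncrna: float = 0.10
    fraction_small_rna: float = 0.03
    fraction_unconfirmed: float = 0.05
    transmission_tau: float = 0.30
    env_log2_effect: float = 3.0
    genotype_log2_offset: float | None = None
    baseline_log_mean: float = 3.0
    baseline_log_sd: float = 1.2
    replicate_cv: float = 0.2
    n_replicates: int = 3
    expressed_threshold: float = 1.0
    stringent_anchor_fpkm: float = 21.0
    ncrna_silencing_bias: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        frac_fields = [
            "fraction_env_responders",
            "fraction_genotype_offset",
            "fraction_interaction",
            "fraction_dormant",
            "fraction_ncrna",
            "fraction_small_rna",
            "fraction_unconfirmed",
            "transmission_tau",
            "ncrna_silencing_bias",
        ]
        for name in frac_fields:
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} must lie in [0, 1], got {v}")
        class_sum = (
            self.fraction_env_responders
            + self.fraction_genotype_offset
            + self.fraction_interaction
            + self.fraction_dormant
        )
        if class_sum > 1.0 + 1e-12:
            raise ValidationError(f"planted class fractions sum to {class_sum:.3f} > 1")
        if self.n_genes < 1:
            raise ValidationError("n_genes must be positive")
        if self.n_replicates < 2:
            raise ValidationError("n_replicates must be >= 2")
        if self.replicate_cv <= 0:
            raise ValidationError("replicate_cv must be > 0")

    @property
    def genotype_effect(self) -> float:
        return self.env_log2_effect if self.genotype_log2_offset is None else self.genotype_log2_offset

    @property
    def dormant_off_fpkm(self) -> float:
        # a tenth of the call threshold: replicate noise essentially never
        # crosses the threshold spuriously
        return self.expressed_threshold / 10.0

    @property
    def dormant_on_fpkm(self) -> float:
        return 10.0 * self.expressed_threshold

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, data: Mapping) -> "SimulationConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown SimulationConfig keys: {sorted(unknown)}")
        return cls(**dict(data))


#: the three experiments of the default study design
STUDY_DESIGN: tuple[tuple[str, Strain, dict[Generation, Environment]], ...] = (
    (
        "N2_CeHR",
        Strain.N2,
        {Generation.P0: Environment.OP50_NGM, Generation.F1: Environment.CEHR, Generation.F2: Environment.REVERSION_AGAR},
    ),
    (
        "N2_SMedium",
        Strain.N2,
        {Generation.P0: Environment.OP50_NGM, Generation.F1: Environment.S_MEDIUM, Generation.F2: Environment.REVERSION_AGAR},
    ),
    (
        "AB1_CeHR",
        Strain.AB1,
        {Generation.P0: Environment.OP50_NGM, Generation.F1: Environment.CEHR, Generation.F2: Environment.REVERSION_AGAR},
    ),
)


def study_conditions(design=STUDY_DESIGN) -> list[Condition]:
    """Distinct (strain, environment, generation) cells of a design, in order."""
    seen: list[Condition] = []
    for _, strain, env_by_gen in design:
        for gen in GENERATIONS:
            cond = (strain, env_by_gen[gen], gen)
            if cond not in seen:
                seen.append(cond)
    return seen


#: F1 liquid cells available for interaction-gene targets
def _interaction_cells(design=STUDY_DESIGN) -> list[tuple[Strain, Environment]]:
    cells: list[tuple[Strain, Environment]] = []
    for _, strain, env_by_gen in design:
        cell = (strain, env_by_gen[Generation.F1])
        if cell not in cells:
            cells.append(cell)
    return cells


def plan_truth(config: SimulationConfig, rng: np.random.Generator | None = None,
               design=STUDY_DESIGN) -> pd.DataFrame:
    """Draw the study-level ground truth shared by all experiments.

    Returns a table indexed by gene_id with the planted class, direction,
    effect size, transmission flag, per-class targets, biotype flags and
    the baseline expected FPKM.
    """
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    n = config.n_genes
    width = max(6, len(str(n)))
    gene_ids = np.array([f"g{i:0{width}d}" for i in range(1, n + 1)])

    n_env = round(config.fraction_env_responders * n)
    n_geno = round(config.fraction_genotype_offset * n)
    n_int = round(config.fraction_interaction * n)
    n_dorm = round(config.fraction_dormant * n)
    if n_env + n_geno + n_int + n_dorm > n:
        raise ValidationError("planted class counts exceed the gene universe")

    perm = rng.permutation(n)
    classes = np.full(n, GeneClass.NULL_GENE.value, dtype=object)
    cursor = 0
    idx_env = perm[cursor:cursor + n_env]; cursor += n_env
    idx_geno = perm[cursor:cursor + n_geno]; cursor += n_geno
    idx_int = perm[cursor:cursor + n_int]; cursor += n_int
    idx_dorm = perm[cursor:cursor + n_dorm]; cursor += n_dorm
    classes[idx_env] = GeneClass.ENV_RESPONDER.value
    classes[idx_geno] = GeneClass.GENOTYPE_OFFSET.value
    classes[idx_int] = GeneClass.INTERACTION.value
    classes[idx_dorm] = GeneClass.CONDITION_SPECIFIC_DORMANT.value
    idx_null = perm[cursor:]

    baseline = rng.lognormal(config.baseline_log_mean, config.baseline_log_sd, size=n)

    direction = np.full(n, "", dtype=object)
    planted_log2fc = np.zeros(n)
    transmitted = np.zeros(n, dtype=bool)
    target_strain = np.full(n, "", dtype=object)
    target_environment = np.full(n, "", dtype=object)
    on_condition = np.full(n, "", dtype=object)

    # environment responders: direction alternates to balance the DEG tails
    e = config.env_log2_effect
    for rank, gi in enumerate(idx_env):
        up = rank % 2 == 0
        direction[gi] = "UP" if up else "DOWN"
        planted_log2fc[gi] = e if up else -e
    transmitted[idx_env] = rng.random(n_env) < config.transmission_tau

    # genotype-offset genes: on-level in the target strain (cycled), off-level
    # in the other, in every environment and generation
    g = config.genotype_effect
    anchor = config.stringent_anchor_fpkm
    geno_off = anchor * 2.0 ** (-g / 2.0)
    strains = [s for s in (Strain.N2, Strain.AB1)]
    for rank, gi in enumerate(idx_geno):
        target_strain[gi] = strains[rank % len(strains)].value
        direction[gi] = "UP"
        planted_log2fc[gi] = g
        baseline[gi] = geno_off

    # interaction genes: on-level only in one (strain, F1-environment) cell
    int_cells = _interaction_cells(design)
    int_off = anchor * 2.0 ** (-e / 2.0)
    for rank, gi in enumerate(idx_int):
        s, env = int_cells[rank % len(int_cells)]
        target_strain[gi] = s.value
        target_environment[gi] = env.value
        direction[gi] = "UP"
        planted_log2fc[gi] = e
        baseline[gi] = int_off

    # dormant genes: off everywhere except one designated condition
    conds = study_conditions(design)
    for rank, gi in enumerate(idx_dorm):
        s, env, gen = conds[rank % len(conds)]
        on_condition[gi] = condition_label(s, env, gen)
        direction[gi] = "UP"
        planted_log2fc[gi] = np.log2(config.dormant_on_fpkm / config.dormant_off_fpkm)
        baseline[gi] = config.dormant_off_fpkm

    # biotypes: ncRNA flags drawn independently of class unless a silencing
    # bias couples them to down-regulated environment responders
    is_ncrna = np.zeros(n, dtype=bool)
    n_nc = round(config.fraction_ncrna * n)
    n_biased = round(config.ncrna_silencing_bias * n_nc)
    down_responders = [gi for gi in idx_env if direction[gi] == "DOWN"]
    biased_pick = rng.permutation(down_responders)[:n_biased] if n_biased else np.array([], dtype=int)
    is_ncrna[biased_pick.astype(int)] = True
    remaining = np.setdiff1d(np.arange(n), biased_pick.astype(int), assume_unique=False)
    rest_pick = rng.permutation(remaining)[: n_nc - is_ncrna.sum()]
    is_ncrna[rest_pick] = True

    biotype = np.full(n, Biotype.PROTEIN_CODING.value, dtype=object)
    biotype[is_ncrna] = Biotype.NCRNA.value
    n_small = round(config.fraction_small_rna * n)
    small_pool = rng.permutation(np.flatnonzero(~is_ncrna))[:n_small]
    small_types = (Biotype.MIRNA.value, Biotype.PIRNA.value, Biotype.RRNA.value)
    for rank, gi in enumerate(small_pool):
        biotype[gi] = small_types[rank % 3]

    # unconfirmed genes: half planted on dormant genes, the rest on null
    # genes that are then permanently silenced (predicted genes lacking
    # transcript evidence are, by construction, not constitutively expressed)
    is_unconfirmed = np.zeros(n, dtype=bool)
    n_unconf = round(config.fraction_unconfirmed * n)
    from_dormant = min(n_dorm, n_unconf // 2)
    pick_dorm = rng.permutation(idx_dorm)[:from_dormant]
    is_unconfirmed[pick_dorm] = True
    n_rest = n_unconf - from_dormant
    pick_null = rng.permutation(idx_null)[:n_rest]
    is_unconfirmed[pick_null] = True
    baseline[pick_null] = config.dormant_off_fpkm  # silenced everywhere

    truth = pd.DataFrame(
        {
            "class_label": classes,
            "direction": direction,
            "planted_log2fc": planted_log2fc,
            "transmitted": transmitted,
            "target_strain": target_strain,
            "target_environment": target_environment,
            "on_condition": on_condition,
            "baseline_fpkm": baseline,
            "biotype": biotype,
            "is_ncrna": is_ncrna,
            "is_unconfirmed": is_unconfirmed,
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    return truth


def annotation_from_truth(truth: pd.DataFrame) -> GeneAnnotation:
    table = pd.DataFrame(
        {
            "biotype": [Biotype(b) for b in truth["biotype"]],
            "confirmed": ~truth["is_unconfirmed"].to_numpy(dtype=bool),
        },
        index=truth.index,
    )
    return GeneAnnotation(table)


def expected_cell_mean(truth: pd.DataFrame, strain: Strain, environment: Environment,
                       generation: Generation, config: SimulationConfig) -> np.ndarray:
    """Planted expected FPKM of every gene in one condition cell."""
    base = truth["baseline_fpkm"].to_numpy(dtype=float).copy()
    cls = truth["class_label"].to_numpy()
    sign = np.where(truth["direction"].to_numpy() == "DOWN", -1.0, 1.0)

    env_mask = cls == GeneClass.ENV_RESPONDER.value
    shift_now = np.zeros(len(truth), dtype=bool)
    if generation == Generation.F1:
        shift_now = env_mask
    elif generation == Generation.F2:
        shift_now = env_mask & truth["transmitted"].to_numpy(dtype=bool)
    base[shift_now] *= 2.0 ** (sign[shift_now] * config.env_log2_effect)

    geno_mask = (cls == GeneClass.GENOTYPE_OFFSET.value) & (truth["target_strain"].to_numpy() == strain.value)
    base[geno_mask] *= 2.0 ** config.genotype_effect

    int_mask = (
        (cls == GeneClass.INTERACTION.value)
        & (truth["target_strain"].to_numpy() == strain.value)
        & (truth["target_environment"].to_numpy() == environment.value)
    )
    base[int_mask] *= 2.0 ** config.env_log2_effect

    dorm_mask = (cls == GeneClass.CONDITION_SPECIFIC_DORMANT.value) & (
        truth["on_condition"].to_numpy() == condition_label(strain, environment, generation)
    )
    base[dorm_mask] = config.dormant_on_fpkm
    return base


@dataclass
class Experiment:
    """One simulated strain x environment-sequence experiment."""

    experiment_id: str
    strain: Strain
    environments: dict[Generation, Environment]
    matrix: ExpressionMatrix
    expected_means: pd.DataFrame  # genes x condition labels, planted cell means

    def condition_label_of(self, generation: Generation) -> str:
        return condition_label(self.strain, self.environments[generation], generation)


def simulate_experiment(
    config: SimulationConfig,
    strain: Strain,
    environments: Mapping[Generation, Environment],
    experiment_id: str = "experiment",
    truth: pd.DataFrame | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[Experiment, GeneAnnotation, pd.DataFrame]:
    """Simulate one P0/F1/F2 experiment; returns (experiment, annotation, truth).

    If ``truth`` is omitted, a fresh study-level truth is planned from the
    config (stand-alone use); pass a shared truth to keep a common gene
    universe across experiments.
    """
    missing = [g.value for g in GENERATIONS if g not in environments]
    if missing:
        raise ValidationError(f"environment sequence must cover P0, F1, F2; missing {missing}")
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    if truth is None:
        truth = plan_truth(config, rng)

    sigma = float(np.sqrt(np.log1p(config.replicate_cv**2)))
    columns: dict[str, np.ndarray] = {}
    samples: list[SampleDescriptor] = []
    expected: dict[str, np.ndarray] = {}
    for gen in GENERATIONS:
        env = environments[gen]
        mean = expected_cell_mean(truth, strain, env, gen, config)
        expected[condition_label(strain, env, gen)] = mean
        for rep in range(1, config.n_replicates + 1):
            noise = rng.lognormal(-0.5 * sigma**2, sigma, size=len(truth))
            sid = f"{experiment_id}_{gen.value}_r{rep}"
            columns[sid] = mean * noise
            samples.append(
                SampleDescriptor(sid, strain, env, gen, rep, experiment_id=experiment_id)
            )
    values = pd.DataFrame(columns, index=truth.index)
    matrix = ExpressionMatrix(values, samples)
    experiment = Experiment(experiment_id, strain, dict(environments), matrix,
                            pd.DataFrame(expected, index=truth.index))
    return experiment, annotation_from_truth(truth), truth


@dataclass
class StudyBundle:
    """Three experiments sharing one gene universe, annotation and truth."""

    experiments: dict[str, Experiment]
    annotation: GeneAnnotation
    truth: pd.DataFrame
    config: SimulationConfig

    def combined_matrix(self) -> ExpressionMatrix:
        """All samples of the study in one matrix (27 columns by default)."""
        frames = []
        samples: list[SampleDescriptor] = []
        for exp in self.experiments.values():
            frames.append(exp.matrix.values)
            samples.extend(exp.matrix.samples)
        return ExpressionMatrix(pd.concat(frames, axis=1), samples)


def simulate_study(config: SimulationConfig, design=STUDY_DESIGN) -> StudyBundle:
    """Simulate the full three-experiment bundle from one seed."""
    ss = np.random.SeedSequence(config.rng_seed)
    truth_seed, *exp_seeds = ss.spawn(1 + len(design))
    truth = plan_truth(config, np.random.default_rng(truth_seed), design)
    annotation = annotation_from_truth(truth)
    experiments: dict[str, Experiment] = {}
    for (exp_id, strain, env_by_gen), seed in zip(design, exp_seeds):
        exp, _, _ = simulate_experiment(
            config, strain, env_by_gen, experiment_id=exp_id, truth=truth,
            rng=np.random.default_rng(seed),
        )
        experiments[exp_id] = exp
    return StudyBundle(experiments, annotation, truth, config)


def expected_log2fc(truth: pd.DataFrame, experiment: Experiment,
                    generation: Generation, config: SimulationConfig) -> pd.Series:
    """Planted log2(cell mean / P0 mean) per gene for one experiment/generation."""
    p0 = experiment.expected_means[experiment.condition_label_of(Generation.P0)]
    other = experiment.expected_means[experiment.condition_label_of(generation)]
    return pd.Series(np.log2(other.to_numpy() / p0.to_numpy()), index=truth.index)
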