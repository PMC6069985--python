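"""Core containers for the strain x environment x generation expression design.

Everything downstream of read alignment operates on three tabular artifacts:
a gene x sample FPKM matrix, a sample-metadata table, and a per-gene
annotation (biotype + confirmed/unconfirmed status).  The types here hold
those artifacts in validated form and define the closed vocabularies
(strains, environments, generations, biotypes) the pipeline accepts.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field, fields
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


class Strain(str, enum.Enum):
    N2 = "N2"
    AB1 = "AB1"


class Environment(str, enum.Enum):
    """Growth conditions of the study design.

    OP50_NGM is the laboratory standard (E. coli-seeded agar); CeHR is an
    axenic liquid medium; S_MEDIUM is a bacteria-containing liquid medium;
    REVERSION_AGAR is agar again after a liquid generation.  The enum is
    closed: unknown strings in metadata fail loudly rather than silently
    creating new conditions (typos may be mapped via an alias table).
    """

    OP50_NGM = "OP50_NGM"
    CEHR = "CeHR"
    S_MEDIUM = "S_MEDIUM"
    REVERSION_AGAR = "REVERSION_AGAR"


class Generation(str, enum.Enum):
    P0 = "P0"
    F1 = "F1"
    F2 = "F2"


class Biotype(str, enum.Enum):
    PROTEIN_CODING = "protein_coding"
    NCRNA = "ncRNA"
    MIRNA = "miRNA"
    PIRNA = "piRNA"
    RRNA = "rRNA"
    OTHER = "other"


#: biotypes discarded from ncRNA profiling (too short to be sampled reliably
#: by poly(A)-selected RNA-seq)
EXCLUDED_BIOTYPES = frozenset({Biotype.MIRNA, Biotype.PIRNA, Biotype.RRNA})

#: built-in spelling variants accepted for environments
DEFAULT_ENVIRONMENT_ALIASES: dict[str, Environment] = {
    "OP50-NGM": Environment.OP50_NGM,
    "OP50 NGM": Environment.OP50_NGM,
    "NGM": Environment.OP50_NGM,
    "cehr": Environment.CEHR,
    "CEHR": Environment.CEHR,
    "S-Medium": Environment.S_MEDIUM,
    "S_Medium": Environment.S_MEDIUM,
    "s-medium": Environment.S_MEDIUM,
    "reversion-agar": Environment.REVERSION_AGAR,
    "reversion": Environment.REVERSION_AGAR,
}


def parse_environment(value: str, aliases: Mapping[str, Environment] | None = None) -> Environment:
    """Map a metadata string to an :class:`Environment`, or fail loudly."""
    try:
        return Environment(value)
    except ValueError:
        pass
    table = dict(DEFAULT_ENVIRONMENT_ALIASES)
    if aliases:
        table.update(aliases)
    if value in table:
        return table[value]
    valid = sorted(e.value for e in Environment)
    raise ValueError(f"unknown environment {value!r}; valid values: {valid} (or a configured alias)")


def parse_strain(value: str) -> Strain:
    try:
        return Strain(value)
    except ValueError as exc:
        raise ValueError(f"unknown strain {value!r}; valid values: {[s.value for s in Strain]}") from exc


def parse_generation(value: str) -> Generation:
    try:
        return Generation(value)
    except ValueError as exc:
        raise ValueError(f"unknown generation {value!r}; valid values: {[g.value for g in Generation]}") from exc


def parse_biotype(value: str) -> Biotype:
    """Biotype is a total function over the annotation: unknowns map to OTHER."""
    try:
        return Biotype(value)
    except ValueError:
        return Biotype.OTHER


Condition = tuple[Strain, Environment, Generation]


def condition_label(strain: Strain, environment: Environment, generation: Generation) -> str:
    return f"{strain.value}:{environment.value}:{generation.value}"


def parse_condition_label(label: str) -> Condition:
    parts = label.split(":")
    if len(parts) != 3:
        raise ValueError(f"condition label {label!r} is not of the form strain:environment:generation")
    return parse_strain(parts[0]), parse_environment(parts[1]), parse_generation(parts[2])


@dataclass(frozen=True)
class SampleDescriptor:
    """One RNA-seq sample: which worms, where, which generation, which replicate."""

    sample_id: str
    strain: Strain
    environment: Environment
    generation: Generation
    replicate: int
    experiment_id: str = ""

    def __post_init__(self) -> None:
        if self.replicate < 1:
            raise ValueError(f"sample {self.sample_id!r}: replicate index must be >= 1, got {self.replicate}")

    @property
    def condition(self) -> Condition:
        return (self.strain, self.environment, self.generation)

    @property
    def condition_label(self) -> str:
        return condition_label(self.strain, self.environment, self.generation)


class ValidationError(ValueError):
    """Raised when an artifact violates its structural invariants."""


@dataclass
class ExpressionMatrix:
    """Dense gene x sample grid of FPKM values plus sample metadata.

    ``values`` is indexed by gene_id with one column per sample_id, in the
    same order as ``samples``.  All values must be finite and non-negative;
    gene ids must be unique.
    """

    values: pd.DataFrame
    samples: list[SampleDescriptor]

    def __post_init__(self) -> None:
        if not isinstance(self.values, pd.DataFrame):
            raise ValidationError("values must be a pandas DataFrame")
        sample_ids = [s.sample_id for s in self.samples]
        if len(set(sample_ids)) != len(sample_ids):
            dupes = sorted({s for s in sample_ids if sample_ids.count(s) > 1})
            raise ValidationError(f"duplicate sample ids: {dupes}")
        if list(self.values.columns) != sample_ids:
            raise ValidationError(
                "matrix columns do not match sample metadata: "
                f"columns={list(self.values.columns)[:5]}..., samples={sample_ids[:5]}..."
            )
        if self.values.index.has_duplicates:
            dupes = sorted(self.values.index[self.values.index.duplicated()].unique()[:10])
            raise ValidationError(f"duplicate gene ids: {dupes}")
        arr = self.values.to_numpy(dtype=float)
        bad = ~np.isfinite(arr) | (arr < 0)
        if bad.any():
            gi, si = np.argwhere(bad)[0]
            raise ValidationError(
                f"negative or non-finite FPKM: gene {self.values.index[gi]!r}, "
                f"sample {self.values.columns[si]!r}, value {arr[gi, si]!r}"
            )

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    def sample_table(self) -> pd.DataFrame:
        rows = [
            {
                "sample_id": s.sample_id,
                "strain": s.strain.value,
                "environment": s.environment.value,
                "generation": s.generation.value,
                "replicate": s.replicate,
                "experiment_id": s.experiment_id,
            }
            for s in self.samples
        ]
        return pd.DataFrame(rows)

    def condition_columns(self) -> dict[str, list[str]]:
        """Map condition label -> sample columns, preserving sample order.

        Samples from different experiments that share a (strain, environment,
        generation) cell are pooled under one condition.
        """
        out: dict[str, list[str]] = {}
        for s in self.samples:
            out.setdefault(s.condition_label, []).append(s.sample_id)
        return out

    def condition_means(self) -> pd.DataFrame:
        """Arithmetic mean of replicate FPKMs per (strain, environment, generation)."""
        cols = self.condition_columns()
        data = {label: self.values[ids].mean(axis=1) for label, ids in cols.items()}
        return pd.DataFrame(data, index=self.values.index)

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        keep = [s for s in self.samples if s.sample_id in set(sample_ids)]
        return ExpressionMatrix(self.values[[s.sample_id for s in keep]], keep)


@dataclass
class GeneAnnotation:
    """Per-gene biotype and confirmed/unconfirmed status.

    ``table`` is indexed by gene_id with columns ``biotype`` (a
    :class:`Biotype`) and ``confirmed`` (bool; True = prior EST/cDNA
    transcript evidence exists).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            dupes = sorted(self.table.index[self.table.index.duplicated()].unique()[:10])
            raise ValidationError(f"duplicate gene ids in annotation: {dupes}")
        missing = {"biotype", "confirmed"} - set(self.table.columns)
        if missing:
            raise ValidationError(f"annotation missing columns: {sorted(missing)}")
        if self.table["biotype"].isna().any():
            raise ValidationError("annotation biotype must be total (no missing values)")

    @property
    def gene_ids(self) -> pd.Index:
        return self.table.index

    def biotype_of(self, gene_id: str) -> Biotype:
        return self.table.at[gene_id, "biotype"]

    @property
    def ncrna_ids(self) -> set[str]:
        return set(self.table.index[self.table["biotype"] == Biotype.NCRNA])

    @property
    def excluded_small_rna_ids(self) -> set[str]:
        mask = self.table["biotype"].isin(EXCLUDED_BIOTYPES)
        return set(self.table.index[mask])

    @property
    def unconfirmed_ids(self) -> set[str]:
        return set(self.table.index[~self.table["confirmed"].astype(bool)])

    def check_covers(self, gene_ids: Iterable[str]) -> list[str]:
        """Return (do not drop) the gene ids absent from the annotation."""
        known = set(self.table.index)
        return sorted(g for g in gene_ids if g not in known)


@dataclass
class RunConfig:
    """Thresholds applied by the analysis stages.

    expressed_threshold
        FPKM above which a gene is called expressed (lenient rule,
        condition mean strictly greater than the threshold).
    stringent_threshold
        FPKM anchor of the housekeeping gene pmp-3; used for the
        genotype/environment/interaction classification where weak signal
        is excluded outright.
    log2fc_threshold
        |log2 fold change| required for differential expression.  The
        default 1.0 is the two-fold rule; ``RunConfig.fourfold()`` gives the
        stricter log2FC > 2 reading.
    fdr_alpha
        Benjamini-Hochberg adjusted p-value cutoff.
    pseudocount
        Added to FPKM before log transforms for fold-change stability near
        zero.
    """

    expressed_threshold: float = 1.0
    stringent_threshold: float = 21.0
    log2fc_threshold: float = 1.0
    fdr_alpha: float = 0.05
    pseudocount: float = 1.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("expressed_threshold", "stringent_threshold", "log2fc_threshold", "pseudocount"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0, got {getattr(self, name)}")
        if not (0.0 < self.fdr_alpha < 1.0):
            raise ValidationError(f"fdr_alpha must lie in (0, 1), got {self.fdr_alpha}")

    @classmethod
    def fourfold(cls, **overrides) -> "RunConfig":
        """Preset using the literal log2 fold change > 2 (four-fold) reading."""
        overrides.setdefault("log2fc_threshold", 2.0)
        return cls(**overrides)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, data: Mapping) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown RunConfig keys: {sorted(unknown)}")
        return cls(**dict(data))
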