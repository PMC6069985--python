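"""Reading and writing the pipeline's tabular artifacts.

Everything is tab-separated UTF-8 with one header row and ``gene_id`` (or
``sample_id``) as the first column, so every artifact stays diffable and
spreadsheet-openable.  Floats are rendered with Python's shortest
round-trip repr, which makes write-then-read bit-exact.
"""
from __future__ import annotations

import os
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .datatypes import (
    Biotype,
    ExpressionMatrix,
    GeneAnnotation,
    RunConfig,
    SampleDescriptor,
    ValidationError,
    parse_biotype,
    parse_environment,
    parse_generation,
    parse_strain,
)
from .simulate import Experiment, SimulationConfig, StudyBundle, annotation_from_truth


class LoadError(ValidationError):
    """A file failed validation on load."""


def write_sample_metadata(samples: list[SampleDescriptor], path) -> None:
    rows = [
        {
            "sample_id": s.sample_id,
            "strain": s.strain.value,
            "environment": s.environment.value,
            "generation": s.generation.value,
            "replicate": s.replicate,
            "experiment_id": s.experiment_id,
        }
        for s in samples
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_sample_metadata(path, aliases: Mapping | None = None) -> list[SampleDescriptor]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "strain", "environment", "generation", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise LoadError(f"{path}: metadata missing columns {sorted(missing)}")
    samples = []
    for _, row in df.iterrows():
        samples.append(
            SampleDescriptor(
                sample_id=row["sample_id"],
                strain=parse_strain(row["strain"]),
                environment=parse_environment(row["environment"], aliases),
                generation=parse_generation(row["generation"]),
                replicate=int(row["replicate"]),
                experiment_id=row.get("experiment_id", "") if isinstance(row.get("experiment_id", ""), str) else "",
            )
        )
    return samples


def write_expression_matrix(matrix: ExpressionMatrix, matrix_path, metadata_path) -> None:
    out = matrix.values.copy()
    out.index.name = "gene_id"
    out.to_csv(matrix_path, sep="\t")
    write_sample_metadata(matrix.samples, metadata_path)


def read_expression_matrix(matrix_path, metadata_path, aliases: Mapping | None = None) -> ExpressionMatrix:
    """Load a gene x sample FPKM matrix plus its metadata, validating both.

    Fatal conditions: a matrix column absent from the metadata (named in
    the error), a metadata sample absent from the matrix, duplicate gene
    ids, and any negative or non-finite value (named by gene and sample).
    """
    for p in (matrix_path, metadata_path):
        if not os.path.exists(p):
            raise LoadError(f"no such file: {p}")
    samples = read_sample_metadata(metadata_path, aliases)
    by_id = {s.sample_id: s for s in samples}
    df = pd.read_csv(matrix_path, sep="\t", index_col=0, float_precision="round_trip")
    df.index = df.index.astype(str)
    if df.index.has_duplicates:
        dupes = sorted(df.index[df.index.duplicated()].unique()[:10])
        raise LoadError(f"{matrix_path}: duplicate gene ids {dupes}")
    unknown = [c for c in df.columns if c not in by_id]
    if unknown:
        raise LoadError(f"{matrix_path}: sample column {unknown[0]!r} absent from metadata")
    absent = [sid for sid in by_id if sid not in set(df.columns)]
    if absent:
        raise LoadError(f"{metadata_path}: sample {absent[0]!r} has no matrix column")
    try:
        values = df.astype(float)
    except ValueError as exc:
        raise LoadError(f"{matrix_path}: non-numeric value ({exc})") from exc
    arr = values.to_numpy()
    bad = ~np.isfinite(arr) | (arr < 0)
    if bad.any():
        report = [
            f"gene {values.index[gi]!r}, sample {values.columns[si]!r}, value {arr[gi, si]!r}"
            for gi, si in np.argwhere(bad)[:10]
        ]
        raise LoadError(f"{matrix_path}: negative or non-finite FPKM: " + "; ".join(report))
    ordered = [by_id[c] for c in values.columns]
    return ExpressionMatrix(values, ordered)


def write_annotation(annotation: GeneAnnotation, path) -> None:
    out = pd.DataFrame(
        {
            "biotype": [b.value for b in annotation.table["biotype"]],
            "confirmed": annotation.table["confirmed"].astype(bool),
        },
        index=annotation.table.index,
    )
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


def read_annotation(path) -> GeneAnnotation:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if "biotype" not in df.columns or "confirmed" not in df.columns:
        raise LoadError(f"{path}: annotation needs 'biotype' and 'confirmed' columns")
    df.index = df.index.astype(str)
    table = pd.DataFrame(
        {
            "biotype": [parse_biotype(str(b)) for b in df["biotype"]],
            "confirmed": df["confirmed"].astype(bool),
        },
        index=df.index,
    )
    return GeneAnnotation(table)


def write_truth(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t")


def read_truth(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, keep_default_na=False,
                     dtype={"transmitted": bool, "is_ncrna": bool, "is_unconfirmed": bool})
    df.index = df.index.astype(str)
    return df


def write_yaml_config(config, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


def read_run_config(path) -> RunConfig:
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig.from_dict(data)


def read_simulation_config(path) -> SimulationConfig:
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    return SimulationConfig.from_dict(data)


# ---------------------------------------------------------------------------
# study-bundle layout: one directory per experiment plus shared tables
#
#   bundle/
#     study_config.yaml
#     annotation.tsv
#     truth.tsv
#     <experiment_id>/matrix.tsv, samples.tsv, expected_means.tsv
# ---------------------------------------------------------------------------

def write_bundle(bundle: StudyBundle, directory) -> None:
    root = Path(directory)
    root.mkdir(parents=True, exist_ok=True)
    write_yaml_config(bundle.config, root / "study_config.yaml")
    write_annotation(bundle.annotation, root / "annotation.tsv")
    write_truth(bundle.truth, root / "truth.tsv")
    for exp_id, exp in bundle.experiments.items():
        exp_dir = root / exp_id
        exp_dir.mkdir(exist_ok=True)
        write_expression_matrix(exp.matrix, exp_dir / "matrix.tsv", exp_dir / "samples.tsv")
        expected = exp.expected_means.copy()
        expected.index.name = "gene_id"
        expected.to_csv(exp_dir / "expected_means.tsv", sep="\t")


def read_bundle(directory) -> StudyBundle:
    root = Path(directory)
    config = read_simulation_config(root / "study_config.yaml")
    annotation = read_annotation(root / "annotation.tsv")
    truth = read_truth(root / "truth.tsv")
    experiments: dict[str, Experiment] = {}
    for exp_dir in sorted(p for p in root.iterdir() if p.is_dir()):
        matrix = read_expression_matrix(exp_dir / "matrix.tsv", exp_dir / "samples.tsv")
        expected = pd.read_csv(exp_dir / "expected_means.tsv", sep="\t", index_col=0, float_precision="round_trip")
        expected.index = expected.index.astype(str)
        strains = {s.strain for s in matrix.samples}
        if len(strains) != 1:
            raise LoadError(f"{exp_dir}: one experiment must use a single strain, found {sorted(s.value for s in strains)}")
        environments = {s.generation: s.environment for s in matrix.samples}
        experiments[exp_dir.name] = Experiment(
            exp_dir.name, next(iter(strains)), environments, matrix, expected
        )
    if not experiments:
        raise LoadError(f"{directory}: bundle contains no experiment directories")
    return StudyBundle(experiments, annotation, truth, config)
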