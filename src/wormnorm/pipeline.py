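"""End-to-end orchestration: run every analysis stage and write a run directory.

Stage order mirrors the analysis narrative: expression calling and
per-condition summaries, Jensen-Shannon clustering, per-experiment Venn
partitioning with ncRNA profiling, cross-experiment conserved ncRNAs,
unconfirmed-gene evidence, the pooled and per-generation G/E/GxE tables,
per-experiment F1-vs-P0 and F2-vs-P0 differential expression, and the
transmission summary.  The resolved configuration is echoed verbatim to the
run directory and every threshold actually applied is appended to
``thresholds.log``.  A stage failure aborts with the stage name and leaves
a ``PARTIAL`` marker naming the completed stages.
"""
from __future__ import annotations

from pathlib import Path

import pandas as pd

from . import io as wio
from .categorize import (
    condition_specific_genes,
    conserved_ncrna,
    gxe_classification,
    ncrna_profile,
    unconfirmed_evidence,
    venn_partition,
)
from .datatypes import Generation, RunConfig, ValidationError
from .degs import call_degs
from .expression import call_expression, cluster_conditions, summarize_expression
from .simulate import GENERATIONS, StudyBundle
from .transmission import transmission, transmission_table


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


def validate_design(bundle: StudyBundle) -> None:
    """Check that every design cell has samples and >= 2 replicates for contrasts."""
    for exp in bundle.experiments.values():
        counts: dict[str, int] = {}
        for s in exp.matrix.samples:
            counts[s.condition_label] = counts.get(s.condition_label, 0) + 1
        for gen in GENERATIONS:
            label = exp.condition_label_of(gen)
            if counts.get(label, 0) == 0:
                raise ValidationError(
                    f"design cell {label!r} of experiment {exp.experiment_id!r} has no samples"
                )
        if set(bundle.truth.index) != set(exp.matrix.gene_ids):
            raise ValidationError(
                f"experiment {exp.experiment_id!r} does not share the study gene universe"
            )


def run_pipeline(bundle: StudyBundle, config: RunConfig, out_dir) -> dict:
    """Run all stages on a study bundle; returns the in-memory results.

    Writes, under ``out_dir``: config.yaml, thresholds.log, summary.tsv,
    distances.tsv, tree.nwk, condition_specific.tsv, unconfirmed_evidence.tsv,
    conserved_ncrna.tsv, gxe_pooled.tsv, gxe_<generation>.tsv and, per
    experiment, venn.tsv, ncrna_profile.tsv, deg_F1_vs_P0.tsv,
    deg_F2_vs_P0.tsv and transmission.tsv.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []
    done: list[str] = []
    results: dict = {"experiments": {}}

    def log(msg: str) -> None:
        log_lines.append(msg)

    wio.write_yaml_config(config, out / "config.yaml")
    stage = "validate_design"
    try:
        validate_design(bundle)
        done.append(stage)

        stage = "expression_calls"
        combined = bundle.combined_matrix()
        lenient = call_expression(combined, config.expressed_threshold)
        stringent = call_expression(combined, config.stringent_threshold)
        log(f"expression call (lenient): condition mean FPKM > {config.expressed_threshold}")
        log(f"expression call (stringent): condition mean FPKM > {config.stringent_threshold}")
        results["lenient_calls"] = lenient
        results["stringent_calls"] = stringent
        summary = summarize_expression(combined, config.expressed_threshold)
        summary.to_csv(out / "summary.tsv", sep="\t")
        results["summary"] = summary
        done.append(stage)

        stage = "clustering"
        clustering = cluster_conditions(combined, method="average")
        log("clustering: Jensen-Shannon distance (base-2, sqrt), average linkage, per-condition profiles")
        clustering.distance.to_frame().to_csv(out / "distances.tsv", sep="\t")
        (out / "tree.nwk").write_text(clustering.newick + "\n", encoding="utf-8")
        results["clustering"] = clustering
        done.append(stage)

        stage = "condition_specific"
        cond_specific = condition_specific_genes(lenient)
        cond_specific.to_csv(out / "condition_specific.tsv", sep="\t")
        log(f"condition-specific list: lenient-expressed in exactly 1 of {len(lenient.condition_labels)} conditions")
        results["condition_specific"] = cond_specific
        done.append(stage)

        stage = "venn"
        partitions = []
        for exp_id, exp in bundle.experiments.items():
            exp_out = out / exp_id
            exp_out.mkdir(exist_ok=True)
            exp_calls = call_expression(exp.matrix, config.expressed_threshold)
            part = venn_partition(exp_calls, experiment_id=exp_id)
            part.to_frame().to_csv(exp_out / "venn.tsv", sep="\t")
            profile = ncrna_profile(part, bundle.annotation)
            profile.to_csv(exp_out / "ncrna_profile.tsv", sep="\t")
            partitions.append(part)
            results["experiments"].setdefault(exp_id, {})["venn"] = part
            results["experiments"][exp_id]["ncrna_profile"] = profile
        log("venn partition: per-experiment, lenient threshold; ncRNA percentages after miRNA/piRNA/rRNA exclusion")
        results["partitions"] = partitions
        done.append(stage)

        stage = "conserved_ncrna"
        conserved = conserved_ncrna(partitions, bundle.annotation)
        rows = [{"experiment_id": e, "n_all_generation_ncrna": len(s),
                 "fraction_shared": conserved["fractions"][e]}
                for e, s in conserved["per_experiment_sets"].items()]
        pd.DataFrame(rows).set_index("experiment_id").to_csv(out / "conserved_ncrna.tsv", sep="\t")
        results["conserved_ncrna"] = conserved
        done.append(stage)

        stage = "unconfirmed_evidence"
        evidence = unconfirmed_evidence([lenient], bundle.annotation)
        pd.DataFrame({"gene_id": sorted(evidence["evidenced"])}).to_csv(
            out / "unconfirmed_evidence.tsv", sep="\t", index=False
        )
        log(f"unconfirmed evidence: lenient-expressed in >= 1 condition; {evidence['pct_evidenced']:.1f}% of the unconfirmed list covered")
        results["unconfirmed"] = evidence
        done.append(stage)

        stage = "gxe"
        pooled = gxe_classification(stringent, mode="pooled")
        flat = pooled.copy()
        flat.to_csv(out / "gxe_pooled.tsv", sep="\t")
        per_gen = gxe_classification(stringent, mode="per_generation")
        for gen, table in per_gen.items():
            table.to_csv(out / f"gxe_{gen}.tsv", sep="\t")
        skipped = [g.value for g in Generation if g.value not in per_gen]
        if skipped:
            log(f"gxe per-generation slices skipped (grid < 2 strains x 2 environments): {skipped}")
        log(f"gxe classification: stringent threshold {config.stringent_threshold}, precedence INTERACTION > GENOTYPE_SPECIFIC > ENVIRONMENT_SPECIFIC")
        results["gxe_pooled"] = pooled
        results["gxe_per_generation"] = per_gen
        done.append(stage)

        stage = "differential_expression"
        for exp_id, exp in bundle.experiments.items():
            exp_out = out / exp_id
            p0 = exp.condition_label_of(Generation.P0)
            degs = {}
            for gen in (Generation.F1, Generation.F2):
                table = call_degs(exp.matrix, p0, exp.condition_label_of(gen), config)
                table.to_csv(exp_out / f"deg_{gen.value}_vs_P0.tsv", sep="\t")
                degs[gen.value] = table
            results["experiments"][exp_id]["degs"] = degs
        log(f"DEG criteria: expression gate FPKM > {config.expressed_threshold} in >= 1 condition; "
            f"|log2FC| >= {config.log2fc_threshold} (pseudocount {config.pseudocount}); BH q <= {config.fdr_alpha}")
        done.append(stage)

        stage = "transmission"
        for exp_id, exp in bundle.experiments.items():
            degs = results["experiments"][exp_id]["degs"]
            res = transmission(degs["F1"], degs["F2"], experiment_id=exp_id)
            transmission_table(res).to_csv(out / exp_id / "transmission.tsv", sep="\t")
            results["experiments"][exp_id]["transmission"] = res
        log("transmission universe: genes passing the expression gate in either contrast")
        done.append(stage)
    except Exception as exc:
        (out / "PARTIAL").write_text(
            "run aborted in stage: " + stage + "\ncompleted stages: " + ", ".join(done) + "\n",
            encoding="utf-8",
        )
        (out / "thresholds.log").write_text("\n".join(log_lines) + "\n", encoding="utf-8")
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    (out / "thresholds.log").write_text("\n".join(log_lines) + "\n", encoding="utf-8")
    return results
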