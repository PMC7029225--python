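"""End-to-end orchestration: simulate -> databases -> classify -> quantify
-> differential tests -> exon usage -> enrichment & network.

Every stage writes its intermediates under the run directory and the run
ends with a structured JSON report plus a human-readable summary.  Reports
are reproducible: identical config + seed give byte-identical JSON apart
from the two timestamp fields.  Stages whose outputs already exist can be
resumed from disk (``resume=True``), which re-reads the written FASTA / GTF
/ VCF / TSV files instead of regenerating them — deliberately exercising the
I/O round trip.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from varipept import __version__
from varipept.digest import (
    CATEGORIES,
    CATEGORY_NONREF_NOVEL_ISOFORM,
    CATEGORY_NONREF_SAAV,
    DigestionParams,
    classify_peptides,
    read_classifications_tsv,
    write_classifications_tsv,
)
from varipept.diffexpr import concordance, de_table
from varipept.exon_usage import test_novel_exon_usage
from varipept.genome import read_fasta, read_gtf
from varipept.network import (
    EdgeList,
    connectivity_permutation_test,
    enrichment_table,
    hypergeom_enrich,
    induced_subgraph_degrees,
)
from varipept.quant import (
    CountMatrix,
    GroupDesign,
    exclusive_nonref_peptides,
    filter_consistent,
    gene_count_matrix,
    peptide_count_matrix,
    upper_quartile_normalize,
)
from varipept.sample_db import (
    build_sample_database,
    read_database_fasta,
    read_events_tsv,
    read_vcf,
    write_database_fasta,
)
from varipept.simulate import GroundTruth, SimulationConfig, simulate_study

logger = logging.getLogger("varipept.pipeline")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    ``sim`` controls the synthetic study; the remaining fields are the
    analysis thresholds (presence filter, exclusivity rule, FDR cutoffs,
    permutation count).  ``resume`` reuses stage outputs already present in
    the run directory.
    """

    sim: SimulationConfig = field(default_factory=SimulationConfig)
    digestion: DigestionParams = field(default_factory=DigestionParams)
    min_psm: int = 3
    min_case: int = 5
    min_control: int = 4
    excl_min_total: int = 5
    excl_min_samples: int = 4
    de_alpha: float = 0.05
    network_fdr: float = 0.01
    concordance_p: float = 0.05
    n_perm: int = 999
    resume: bool = False

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "RunConfig":
        data = dict(data)
        if "sim" in data and isinstance(data["sim"], dict):
            sim = dict(data["sim"])
            for key in ("protein_length_range", "exons_per_gene", "intron_length_range"):
                if key in sim and isinstance(sim[key], list):
                    sim[key] = tuple(sim[key])
            data["sim"] = SimulationConfig(**sim)
        if "digestion" in data and isinstance(data["digestion"], dict):
            data["digestion"] = DigestionParams(**data["digestion"])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)


def _stage(name: str):
    """Decorator: log the stage and wrap failures with its name."""

    def wrap(fn):
        def inner(*args, **kwargs):
            logger.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - rewrapped with stage name
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            logger.info("stage %s: done", name)
            return out

        return inner

    return wrap


@_stage("simulate")
def _stage_simulate(config: RunConfig, outdir: Path):
    gt_path = outdir / "ground_truth.json"
    if config.resume and gt_path.exists():
        logger.info("resuming simulate stage from %s", outdir)
        genome = read_fasta(outdir / "genome.fa")
        models = read_gtf(outdir / "annotation.gtf")
        variants = read_vcf(outdir / "variants.vcf")
        events = read_events_tsv(outdir / "novel_exons.tsv")
        psm = pd.read_csv(outdir / "psm.tsv", sep="\t")
        transcript_counts = CountMatrix.from_tsv(outdir / "transcript_counts.tsv")
        usage = pd.read_csv(outdir / "usage.tsv", sep="\t")
        design = GroupDesign.from_tsv(outdir / "design.tsv")
        edges = EdgeList.from_tsv(outdir / "edges.tsv")
        gene_sets = pd.read_csv(outdir / "gene_sets.tsv", sep="\t")
        ground_truth = GroundTruth.from_json(gt_path)
        return (genome, models, variants, events[0], psm, transcript_counts, usage,
                design, edges, gene_sets, ground_truth)
    study = simulate_study(config.sim, outdir, params=config.digestion)
    edges = EdgeList(
        {
            (a, b): ev
            for a, b, ev in zip(
                study.edges["gene_a"], study.edges["gene_b"], study.edges["evidence"]
            )
        }
    )
    return (
        study.genome,
        study.models,
        study.variants,
        study.event,
        study.psm,
        study.transcript_counts,
        study.usage_counts,
        config.sim.design(),
        edges,
        study.gene_sets,
        study.ground_truth,
    )


@_stage("build_db")
def _stage_build_db(config: RunConfig, outdir: Path, genome, models, variants, event, design):
    db_dir = outdir / "dbs"
    db_dir.mkdir(exist_ok=True)
    databases = {}
    canonical_path = db_dir / "reference.fa"
    if config.resume and canonical_path.exists():
        canonical = read_database_fasta(canonical_path)
    else:
        canonical = build_sample_database(models, genome)
        write_database_fasta(canonical, canonical_path)
    for sample in design.samples:
        path = db_dir / f"{sample}.fa"
        if config.resume and path.exists():
            databases[sample] = read_database_fasta(path)
            continue
        databases[sample] = build_sample_database(
            models, genome, variants, [event], sample_id=sample
        )
        write_database_fasta(databases[sample], path)
    return canonical, databases


@_stage("classify")
def _stage_classify(config: RunConfig, outdir: Path, psm, databases, canonical):
    path = outdir / "classifications.tsv"
    if config.resume and path.exists():
        return read_classifications_tsv(path)
    peptides = sorted(psm["peptide"].unique())
    classifications = classify_peptides(peptides, databases, canonical, config.digestion)
    write_classifications_tsv(classifications, path)
    return classifications


@_stage("quantify")
def _stage_quantify(config: RunConfig, outdir: Path, psm, classifications, design):
    genes = gene_count_matrix(psm, classifications, design)
    genes.to_tsv(outdir / "gene_counts.tsv")
    filtered = filter_consistent(
        genes, design, config.min_psm, config.min_case, config.min_control
    )
    filtered = upper_quartile_normalize(filtered)
    filtered.to_tsv(outdir / "gene_counts_filtered.tsv")
    filtered.scale_factors.rename("scale_factor").to_csv(
        outdir / "scale_factors.tsv", sep="\t", index_label="sample"
    )
    nonref = classifications[
        classifications["category"].isin(
            [CATEGORY_NONREF_SAAV, CATEGORY_NONREF_NOVEL_ISOFORM]
        )
    ]["peptide"].tolist()
    nonref_matrix = peptide_count_matrix(psm, nonref, design)
    nonref_matrix.to_tsv(outdir / "nonref_peptide_counts.tsv")
    case_excl, control_excl = exclusive_nonref_peptides(
        nonref_matrix, design, config.excl_min_total, config.excl_min_samples
    )
    return genes, filtered, nonref_matrix, case_excl, control_excl


@_stage("diffexpr")
def _stage_diffexpr(config: RunConfig, outdir: Path, filtered, transcript_counts, design):
    protein_de = de_table(filtered, design, alpha=config.de_alpha)
    protein_de.to_csv(outdir / "protein_de.tsv", sep="\t", index=False)
    tx_filtered = upper_quartile_normalize(transcript_counts)
    transcript_de = de_table(tx_filtered, design, alpha=config.de_alpha)
    transcript_de.to_csv(outdir / "transcript_de.tsv", sep="\t", index=False)
    concordant = concordance(
        protein_de, transcript_de, fdr_threshold=config.de_alpha,
        p_threshold=config.concordance_p,
    )
    return protein_de, transcript_de, concordant


@_stage("usage")
def _stage_usage(config: RunConfig, outdir: Path, usage_counts, design):
    result = test_novel_exon_usage(usage_counts, design)
    payload = {
        "u_statistic": result.u_statistic,
        "p_value": result.p_value,
        "median_case": result.median_case,
        "median_control": result.median_control,
        "direction": result.direction,
        "per_sample_usage": {
            k: (None if pd.isna(v) else v) for k, v in sorted(result.per_sample_usage.items())
        },
    }
    with open(outdir / "usage_result.json", "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return result


@_stage("network_enrich")
def _stage_network(config: RunConfig, outdir: Path, protein_de, filtered, edges, gene_sets):
    universe = list(filtered.feature_ids)
    de_set = set(protein_de.loc[protein_de["fdr"] < config.de_alpha, "feature"]) & set(universe)
    sets = {
        set_id: set(group["gene_id"])
        for set_id, group in gene_sets.groupby("set_id")
    }
    enrich_rows = (
        hypergeom_enrich(de_set, sets, universe) if de_set else []
    )
    enrichment_table(enrich_rows).to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
    net_set = set(protein_de.loc[protein_de["fdr"] < config.network_fdr, "feature"]) & set(universe)
    degrees = induced_subgraph_degrees(net_set, edges) if net_set else {}
    if len(net_set) >= 2:
        observed, perm_p = connectivity_permutation_test(
            net_set, edges, universe, n_perm=config.n_perm, seed=config.sim.seed
        )
    else:
        observed, perm_p = 0, None
    payload = {
        "de_set_size": len(de_set),
        "network_set_size": len(net_set),
        "observed_internal_edges": observed,
        "permutation_p": perm_p,
        "within_set_degrees": dict(sorted(degrees.items())),
    }
    with open(outdir / "network.json", "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return enrich_rows, degrees, observed, perm_p, de_set, net_set


def run_pipeline(config: RunConfig, outdir: str | Path, seed: int | None = None) -> dict:
    """Run every stage in dependency order and return the report dict.

    ``seed`` overrides ``config.sim.seed``.  The report is written to
    ``report.json`` (machine-readable, deterministic apart from timestamps)
    and ``report.txt`` (human-readable).
    """
    if seed is not None:
        config = dataclasses.replace(
            config, sim=dataclasses.replace(config.sim, seed=seed)
        )
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    started = time.strftime("%Y-%m-%dT%H:%M:%S")

    (genome, models, variants, event, psm, transcript_counts, usage_counts,
     design, edges, gene_sets, ground_truth) = _stage_simulate(config, outdir)
    canonical, databases = _stage_build_db(
        config, outdir, genome, models, variants, event, design
    )
    classifications = _stage_classify(config, outdir, psm, databases, canonical)
    genes, filtered, nonref_matrix, case_excl, control_excl = _stage_quantify(
        config, outdir, psm, classifications, design
    )
    protein_de, transcript_de, concordant = _stage_diffexpr(
        config, outdir, filtered, transcript_counts, design
    )
    usage_result = _stage_usage(config, outdir, usage_counts, design)
    enrich_rows, degrees, observed_edges, perm_p, de_set, net_set = _stage_network(
        config, outdir, protein_de, filtered, edges, gene_sets
    )

    by_category = {c: 0 for c in CATEGORIES}
    by_category.update(classifications["category"].value_counts().to_dict())
    n_de = int((protein_de["fdr"] < config.de_alpha).sum())
    n_up = int(
        ((protein_de["fdr"] < config.de_alpha) & (protein_de["log2fc"] > 0)).sum()
    )
    n_down = int(
        ((protein_de["fdr"] < config.de_alpha) & (protein_de["log2fc"] < 0)).sum()
    )
    max_degree_gene = max(degrees, key=lambda g: (degrees[g], g)) if degrees else None

    config_echo = config.to_dict()
    config_echo.pop("resume", None)  # execution mode, not an analysis parameter
    report = {
        "version": __version__,
        "config": config_echo,
        "peptides": {
            "total_classified": int(len(classifications)),
            "by_category": {k: int(v) for k, v in sorted(by_category.items())},
        },
        "proteins": {
            "quantified_genes": int(len(genes.feature_ids)),
            "after_filter": int(len(filtered.feature_ids)),
        },
        "diffexpr": {
            "n_tested": int(len(protein_de)),
            "de_at_alpha": n_de,
            "up": n_up,
            "down": n_down,
            "de_at_network_fdr": int((protein_de["fdr"] < config.network_fdr).sum()),
            "concordant_with_transcripts": sorted(concordant),
        },
        "exclusive_peptides": {
            "case": sorted(case_excl),
            "control": sorted(control_excl),
        },
        "usage": {
            "p_value": usage_result.p_value,
            "u_statistic": usage_result.u_statistic,
            "median_case": usage_result.median_case,
            "median_control": usage_result.median_control,
            "direction": usage_result.direction,
        },
        "enrichment": {
            "top": [
                {
                    "set_id": r.set_id,
                    "overlap": r.overlap,
                    "set_size": r.set_size,
                    "p_value": r.p_value,
                    "fdr": r.fdr,
                }
                for r in enrich_rows[:5]
            ],
        },
        "network": {
            "set_size": len(net_set),
            "observed_internal_edges": observed_edges,
            "permutation_p": perm_p,
            "max_within_degree": max(degrees.values()) if degrees else 0,
            "hub_gene": max_degree_gene,
        },
        "started_at": started,
        "finished_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }

    # internal consistency is asserted, not just printed
    assert sum(report["peptides"]["by_category"].values()) == report["peptides"]["total_classified"]
    assert report["diffexpr"]["up"] + report["diffexpr"]["down"] == report["diffexpr"]["de_at_alpha"]
    assert set(case_excl).isdisjoint(control_excl)

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    _write_text_report(report, outdir / "report.txt")
    return report


def _write_text_report(report: dict, path: Path) -> None:
    lines = [
        f"varipept {report['version']} run report",
        "",
        f"peptides classified: {report['peptides']['total_classified']}",
    ]
    for cat, n in report["peptides"]["by_category"].items():
        lines.append(f"  {cat}: {n}")
    lines += [
        f"genes quantified: {report['proteins']['quantified_genes']} "
        f"({report['proteins']['after_filter']} after presence filter)",
        f"differential proteins: {report['diffexpr']['de_at_alpha']} "
        f"({report['diffexpr']['up']} up, {report['diffexpr']['down']} down)",
        f"transcript-concordant: {len(report['diffexpr']['concordant_with_transcripts'])}",
        f"case-exclusive non-reference peptides: {len(report['exclusive_peptides']['case'])}",
        f"control-exclusive non-reference peptides: {len(report['exclusive_peptides']['control'])}",
        f"novel-exon usage: p={report['usage']['p_value']:.3g} "
        f"({report['usage']['direction']}; medians "
        f"{report['usage']['median_case']:.3f} vs {report['usage']['median_control']:.3f})",
        f"network: {report['network']['observed_internal_edges']} internal edges, "
        f"permutation p={report['network']['permutation_p']}, "
        f"hub {report['network']['hub_gene']} "
        f"(degree {report['network']['max_within_degree']})",
    ]
    if report["enrichment"]["top"]:
        top = report["enrichment"]["top"][0]
        lines.append(
            f"top enriched set: {top['set_id']} "
            f"(overlap {top['overlap']}/{top['set_size']}, FDR {top['fdr']:.3g})"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
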