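"""Synthetic proteogenomic study generator.

Emulates a two-group lung-tissue cohort — 10 cases vs 8 controls by default
— end to end: a toy genome with multi-exon protein-coding genes (at least
one on the minus strand), sample-private non-synonymous SNVs, one in-frame
novel-exon event planted in an intron of a minus-strand gene (default
length 714 nt, i.e. a 238-residue insertion), a PSM identification table
drawn from in-silico digests of each sample's own protein database,
negative-binomial transcript counts with configurable protein/transcript
direction concordance, junction-read usage counts for the novel exon, and a
generic interaction network plus gene-set annotations with planted
structure.  Every planted event is recorded in a :class:`GroundTruth`
object, so downstream claims can be checked against what was simulated.

All outputs are pure functions of ``(config, seed)``; the same seed yields
byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from varipept.digest import (
    DigestionParams,
    build_peptide_index,
    digest,
    peptides_for_novel_exon,
)
from varipept.genome import (
    TranscriptModel,
    complement,
    reverse_complement,
    write_fasta,
    write_gtf,
)
from varipept.quant import CountMatrix, GroupDesign, GROUP_CASE, GROUP_CONTROL
from varipept.sample_db import (
    NovelExonEvent,
    ProteinRecord,
    VariantRecord,
    build_sample_database,
    spliced_cds_sequence,
    translate,
    write_database_fasta,
    write_events_tsv,
    write_vcf,
)

_TABLE = CodonTable.unambiguous_dna_by_id[1]
SENSE_CODONS = tuple(sorted(_TABLE.forward_table))
STOP_CODONS = tuple(sorted(_TABLE.stop_codons))
CODON_TO_AA = dict(_TABLE.forward_table)
AA_TO_CODONS: dict[str, tuple[str, ...]] = {}
for codon in SENSE_CODONS:
    AA_TO_CODONS.setdefault(CODON_TO_AA[codon], ())
    AA_TO_CODONS[CODON_TO_AA[codon]] += (codon,)

_BASES = ("A", "C", "G", "T")
EVIDENCE_CHOICES = ("database", "experimental", "both")


class SimulationError(RuntimeError):
    pass


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic study, validated at construction.

    The defaults mirror the emulated study design: 10 cases vs 8 controls,
    negative-binomial PSM counts (variance mu + phi mu^2) around 20 PSMs per
    peptide with dispersion 0.3, a two-fold-change-squared (|log2fc| = 2)
    effect on 15% of genes, sample-private coding SNVs, and one in-frame
    714-nt novel exon included in 90% of case samples and 10% of controls.
    """

    n_case: int = 10
    n_control: int = 8
    n_genes: int = 30
    frac_de: float = 0.15
    log2fc_magnitude: float = 2.0
    nb_mean: float = 20.0
    nb_dispersion: float = 0.3
    variant_rate: float = 0.25
    inclusion_bias: float = 0.9
    concordant_fraction: float = 0.5
    novel_exon_length: int = 714
    peptides_per_gene: int = 3
    protein_length_range: tuple[int, int] = (120, 220)
    exons_per_gene: tuple[int, int] = (2, 4)
    intron_length_range: tuple[int, int] = (100, 400)
    intergenic_gap: int = 300
    usage_depth_mean: float = 60.0
    included_usage: float = 0.45
    background_usage: float = 0.02
    edge_density: float = 0.08
    n_gene_sets: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_case, self.n_control, self.n_genes) < 1:
            raise ValueError("n_case, n_control and n_genes must be >= 1")
        for name in ("frac_de", "variant_rate", "inclusion_bias", "concordant_fraction",
                     "included_usage", "background_usage", "edge_density"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if self.nb_mean <= 0 or self.usage_depth_mean <= 0:
            raise ValueError("means must be positive")
        if self.novel_exon_length % 3 != 0 or self.novel_exon_length < 9:
            raise ValueError("novel_exon_length must be a positive multiple of 3")
        if not np.isfinite(self.log2fc_magnitude) or self.log2fc_magnitude == 0:
            raise ValueError("log2fc_magnitude must be finite and nonzero")

    @property
    def case_samples(self) -> tuple[str, ...]:
        return tuple(f"case_{i + 1:02d}" for i in range(self.n_case))

    @property
    def control_samples(self) -> tuple[str, ...]:
        return tuple(f"control_{i + 1:02d}" for i in range(self.n_control))

    @property
    def samples(self) -> tuple[str, ...]:
        return self.case_samples + self.control_samples

    def design(self) -> GroupDesign:
        assignment = {s: GROUP_CASE for s in self.case_samples}
        assignment.update({s: GROUP_CONTROL for s in self.control_samples})
        return GroupDesign(assignment)


@dataclass
class GroundTruth:
    """Everything that was planted, recoverable without rerunning anything."""

    group_assignment: dict[str, str]
    de_proteins: dict[str, float] = field(default_factory=dict)
    saav_events: list[dict] = field(default_factory=list)
    novel_exon: dict | None = None
    transcript_lfc: dict[str, float] = field(default_factory=dict)
    concordant_genes: list[str] = field(default_factory=list)
    novel_peptides: list[str] = field(default_factory=list)
    enriched_set: str | None = None
    clique_genes: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def nb_draw(rng: np.random.Generator, mean: float, dispersion: float, size=None):
    """Negative-binomial draws under the mean/dispersion parameterization.

    variance = mean + dispersion * mean^2; dispersion -> 0 is the Poisson
    limit and is drawn as Poisson directly.
    """
    if mean < 0:
        raise ValueError("mean must be >= 0")
    if dispersion < 1e-12:
        return rng.poisson(mean, size=size)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size=size)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def _random_sense_codons(rng: np.random.Generator, n: int) -> list[str]:
    idx = rng.integers(0, len(SENSE_CODONS), size=n)
    return [SENSE_CODONS[i] for i in idx]


# ---------------------------------------------------------------------------
# Genome and annotation


def generate_genome(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[dict[str, str], list[TranscriptModel]]:
    """Generate a toy genome and one coding transcript model per gene.

    Each gene has 2-4 coding exons split at codon boundaries, a CDS that
    starts with ATG and ends with a stop codon, and no internal stops.
    Every third gene (including the first, which later hosts the novel
    exon) is on the minus strand.  The first gene gets one intron long
    enough to host the default novel exon.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    parts: list[str] = []
    pos = 0
    models: list[TranscriptModel] = []
    chrom = "chr1"
    lo, hi = config.protein_length_range
    exlo, exhi = config.exons_per_gene
    ilo, ihi = config.intron_length_range
    for i in range(config.n_genes):
        gap = _random_seq(rng, config.intergenic_gap)
        parts.append(gap)
        pos += len(gap)
        strand = "-" if i % 3 == 0 else "+"
        plen = int(rng.integers(lo, hi + 1))
        codons = ["ATG"] + _random_sense_codons(rng, plen - 1)
        codons.append(STOP_CODONS[rng.integers(0, len(STOP_CODONS))])
        ncod = len(codons)
        n_exons = int(rng.integers(exlo, exhi + 1))
        n_exons = min(n_exons, ncod - 1)
        cuts = sorted(rng.choice(np.arange(1, ncod), size=n_exons - 1, replace=False))
        chunk_bounds = [0] + [int(c) for c in cuts] + [ncod]
        chunks = [
            "".join(codons[a:b]) for a, b in zip(chunk_bounds[:-1], chunk_bounds[1:])
        ]
        intron_lens = [int(rng.integers(ilo, ihi + 1)) for _ in range(n_exons - 1)]
        if i == 0 and intron_lens:
            intron_lens[0] = config.novel_exon_length + 200
        introns = [_random_seq(rng, L) for L in intron_lens]
        pre = chunks[0]
        tx_offsets = [(0, len(chunks[0]))]
        for chunk, intron in zip(chunks[1:], introns):
            pre += intron
            start = len(pre)
            pre += chunk
            tx_offsets.append((start, start + len(chunk)))
        gstart = pos
        if strand == "+":
            seg = pre
            exons = tuple((gstart + a, gstart + b) for a, b in tx_offsets)
        else:
            seg = reverse_complement(pre)
            L = len(pre)
            exons = tuple(
                sorted((gstart + L - b, gstart + L - a) for a, b in tx_offsets)
            )
        parts.append(seg)
        pos += len(seg)
        models.append(
            TranscriptModel(
                transcript_id=f"tx_{i + 1:03d}",
                gene_id=f"gene_{i + 1:03d}",
                chrom=chrom,
                strand=strand,
                exons=exons,
            )
        )
    parts.append(_random_seq(rng, config.intergenic_gap))
    return {chrom: "".join(parts)}, models


# ---------------------------------------------------------------------------
# Variants


def generate_variants(
    models: Sequence[TranscriptModel],
    genome: Mapping[str, str],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list[VariantRecord], list[dict]]:
    """Plant sample-private non-synonymous coding SNVs.

    Each (sample, gene) pair receives a variant with probability
    ``variant_rate``.  The alternate codon is always a sense codon encoding
    a different, MS-distinguishable residue (no stop gains, no isobaric
    I<->L swaps), so every emitted variant is non-synonymous, non-truncating
    and detectable at the peptide level by construction; the expected
    single-amino-acid variant is recorded in the ground truth.
    """
    if not models:
        raise ValueError("no transcript models")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    variants: list[VariantRecord] = []
    saav_events: list[dict] = []
    for sample in config.samples:
        for model in models:
            if rng.random() >= config.variant_rate:
                continue
            cds = spliced_cds_sequence(model, genome)
            ncod = len(cds) // 3
            c = int(rng.integers(1, ncod - 1))  # skip start and stop codons
            codon = cds[3 * c : 3 * c + 3]
            placed = False
            for within in rng.permutation(3):
                for alt_base in rng.permutation(_BASES):
                    if alt_base == codon[within]:
                        continue
                    new_codon = codon[:within] + alt_base + codon[within + 1 :]
                    # require a sense codon, a different residue, and an
                    # MS-visible change (I<->L is isobaric and undetectable)
                    if (
                        new_codon in CODON_TO_AA
                        and CODON_TO_AA[new_codon] != CODON_TO_AA[codon]
                        and {CODON_TO_AA[new_codon], CODON_TO_AA[codon]} != {"I", "L"}
                    ):
                        cds_offset = 3 * c + int(within)
                        gpos = model.transcript_to_genomic(cds_offset)
                        ref_g = genome[model.chrom][gpos]
                        alt_g = alt_base if model.strand == "+" else complement(alt_base)
                        variants.append(
                            VariantRecord(
                                chrom=model.chrom,
                                pos=gpos,
                                ref=ref_g,
                                alt=alt_g,
                                sample_id=sample,
                            )
                        )
                        saav_events.append(
                            {
                                "sample": sample,
                                "gene": model.gene_id,
                                "transcript": model.transcript_id,
                                "residue": c + 1,
                                "ref_aa": CODON_TO_AA[codon],
                                "alt_aa": CODON_TO_AA[new_codon],
                            }
                        )
                        placed = True
                        break
                if placed:
                    break
    return variants, saav_events


# ---------------------------------------------------------------------------
# Novel exon


def _tryptic_block_protein(rng: np.random.Generator, n_residues: int) -> str:
    """Amino-acid sequence built from 8-12 residue blocks ending in K/R.

    Block structure guarantees tryptic peptides of observable length fall
    fully inside the insertion and across its junctions.
    """
    out: list[str] = []
    aas = [a for a in AA_TO_CODONS if a not in ("K", "R", "P")]
    while len(out) < n_residues:
        block_len = int(rng.integers(8, 13))
        block_len = min(block_len, n_residues - len(out))
        body = [aas[i] for i in rng.integers(0, len(aas), size=max(block_len - 1, 0))]
        if block_len >= 1:
            body.append("K" if rng.random() < 0.5 else "R")
        out.extend(body)
    return "".join(out[:n_residues])


def generate_novel_exon(
    models: Sequence[TranscriptModel],
    genome: dict[str, str],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[NovelExonEvent, dict[str, str], dict[str, bool]]:
    """Plant one in-frame novel exon in an intron of the first gene.

    The exon encodes ``novel_exon_length / 3`` residues arranged in tryptic
    blocks (see :func:`_tryptic_block_protein`) so junction-spanning
    peptides of admissible length exist.  Inclusion flags are Bernoulli with
    probability ``inclusion_bias`` for cases and ``1 - inclusion_bias`` for
    controls.  Returns the event, the updated genome, and per-sample flags.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    host = models[0]
    need = config.novel_exon_length
    candidates = [(s, e) for s, e in host.introns() if e - s >= need + 40]
    if not candidates:
        raise SimulationError(
            f"gene {host.gene_id}: no intron long enough to host a {need}-nt exon"
        )
    istart, iend = max(candidates, key=lambda x: x[1] - x[0])
    start = istart + 20
    interval = (start, start + need)
    protein_part = _tryptic_block_protein(rng, need // 3)
    codons = [
        AA_TO_CODONS[a][rng.integers(0, len(AA_TO_CODONS[a]))] for a in protein_part
    ]
    exon_tx_seq = "".join(codons)
    genomic_seq = exon_tx_seq if host.strand == "+" else reverse_complement(exon_tx_seq)
    chrom_seq = genome[host.chrom]
    genome = dict(genome)
    genome[host.chrom] = (
        chrom_seq[:start] + genomic_seq + chrom_seq[start + need :]
    )
    insertion_index = sum(1 for s, _ in host.exons if s < start)
    inclusion: dict[str, bool] = {}
    for sample in config.case_samples:
        inclusion[sample] = bool(rng.random() < config.inclusion_bias)
    for sample in config.control_samples:
        inclusion[sample] = bool(rng.random() < 1 - config.inclusion_bias)
    event = NovelExonEvent(
        gene_id=host.gene_id,
        host_transcript=host.transcript_id,
        chrom=host.chrom,
        exon_interval=interval,
        insertion_index=insertion_index,
        samples_present=frozenset(s for s, f in inclusion.items() if f),
    )
    return event, genome, inclusion


# ---------------------------------------------------------------------------
# PSM table


def generate_psm_table(
    sample_databases: Mapping[str, Sequence[ProteinRecord]],
    canonical_records: Sequence[ProteinRecord],
    event: NovelExonEvent | None,
    ground_truth: GroundTruth,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    params: DigestionParams = DigestionParams(),
) -> tuple[pd.DataFrame, list[str]]:
    """Draw a PSM identification table from the sample databases.

    Reference evidence: up to ``peptides_per_gene`` gene-unique tryptic
    peptides per canonical protein, with per-sample counts
    NB(nb_mean * 2^(group * log2fc), dispersion).  Variant evidence: up to
    two peptides per planted SAAV, counted only in the carrying sample.
    Novel-isoform evidence: every peptide unique to the novel isoform,
    counted only in samples whose database contains it.  Zero draws are
    omitted (an unobserved peptide has no row).  Every emitted peptide is a
    digestion product of the emitting sample's own database.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    design = config.design()
    canonical_index = build_peptide_index({"reference": canonical_records}, params)
    rows: list[tuple[str, str, int]] = []

    def emit(pep: str, sample: str, mean: float) -> None:
        c = int(nb_draw(rng, mean, config.nb_dispersion))
        if c > 0:
            rows.append((pep, sample, c))

    for record in canonical_records:
        peps = digest(record.sequence, params.missed_cleavages, params.min_len, params.max_len)
        unique = [
            p for p in peps if canonical_index.lookup(p).genes == {record.gene_id}
        ]
        chosen = unique[: config.peptides_per_gene]
        lfc = ground_truth.de_proteins.get(record.gene_id, 0.0)
        for pep in chosen:
            for sample in config.samples:
                mean = config.nb_mean * (
                    2.0**lfc if design.assignment[sample] == GROUP_CASE else 1.0
                )
                emit(pep, sample, mean)

    for ev in ground_truth.saav_events:
        sample = ev["sample"]
        saav_records = [
            r
            for r in sample_databases.get(sample, [])
            if r.provenance == "saav" and r.source_transcript == ev["transcript"]
        ]
        for record in saav_records:
            novel = [
                p
                for p in digest(
                    record.sequence, params.missed_cleavages, params.min_len, params.max_len
                )
                if canonical_index.lookup(p) is None
            ]
            for pep in novel[:2]:
                emit(pep, sample, config.nb_mean)

    novel_peptides: list[str] = []
    if event is not None:
        novel_peptides = peptides_for_novel_exon(event, sample_databases, params)
        for pep in novel_peptides:
            for sample in sorted(event.samples_present):
                emit(pep, sample, config.nb_mean)

    df = pd.DataFrame(rows, columns=["peptide", "sample", "psm_count"])
    df = (
        df.groupby(["peptide", "sample"], as_index=False)["psm_count"]
        .sum()
        .sort_values(["peptide", "sample"], kind="mergesort")
        .reset_index(drop=True)
    )
    return df, novel_peptides


# ---------------------------------------------------------------------------
# Transcript counts, usage counts, network inputs


def generate_transcript_counts(
    models: Sequence[TranscriptModel],
    ground_truth: GroundTruth,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[CountMatrix, dict[str, float], list[str]]:
    """NB transcript counts with controlled protein/transcript concordance.

    A ``concordant_fraction`` of true differential proteins get a
    transcript-level fold change of the same sign; the rest get the opposite
    sign, so concordance is exactly controllable at both extremes.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    design = config.design()
    de_genes = sorted(ground_truth.de_proteins)
    k = int(round(config.concordant_fraction * len(de_genes)))
    order = list(rng.permutation(len(de_genes)))
    concordant = sorted(de_genes[i] for i in order[:k])
    transcript_lfc: dict[str, float] = {}
    for gene in de_genes:
        sign = np.sign(ground_truth.de_proteins[gene])
        transcript_lfc[gene] = float(
            sign * config.log2fc_magnitude
            if gene in concordant
            else -sign * config.log2fc_magnitude
        )
    data = {}
    genes = [m.gene_id for m in models]
    for sample in config.samples:
        is_case = design.assignment[sample] == GROUP_CASE
        means = np.array(
            [
                config.nb_mean * (2.0 ** transcript_lfc.get(g, 0.0) if is_case else 1.0)
                for g in genes
            ]
        )
        data[sample] = np.array(
            [int(nb_draw(rng, m, config.nb_dispersion)) for m in means]
        )
    counts = pd.DataFrame(data, index=pd.Index(genes, name="feature"))
    return CountMatrix(counts=counts), transcript_lfc, concordant


def generate_usage_counts(
    inclusion_flags: Mapping[str, bool],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Junction-read usage counts for the novel-exon locus.

    Per sample: total locus reads ~ Poisson(usage_depth_mean) and inclusion
    reads ~ Binomial(total, p) with p = ``included_usage`` when the sample
    carries the exon and ``background_usage`` otherwise (stray evidence of
    low-level inclusion in non-carrying tissue).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    rows = []
    for sample in config.samples:
        total = int(rng.poisson(config.usage_depth_mean))
        p = config.included_usage if inclusion_flags.get(sample, False) else config.background_usage
        inclusion = int(rng.binomial(total, p)) if total > 0 else 0
        rows.append({"sample": sample, "inclusion": inclusion, "total": total})
    return pd.DataFrame(rows, columns=["sample", "inclusion", "total"])


def generate_network_inputs(
    models: Sequence[TranscriptModel],
    ground_truth: GroundTruth,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, list[str], str]:
    """Random interaction edges with a planted clique, plus gene sets.

    The clique spans up to 8 true differential genes (excess internal
    connectivity to detect); one gene set collects all true differential
    genes plus a few bystanders (the over-represented set).  Returns
    (edges frame, gene-set frame, clique genes, enriched set id).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    genes = sorted(m.gene_id for m in models)
    edges: dict[tuple[str, str], str] = {}
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            if rng.random() < config.edge_density:
                evidence = EVIDENCE_CHOICES[rng.integers(0, len(EVIDENCE_CHOICES))]
                edges[(genes[i], genes[j])] = evidence
    de_genes = sorted(ground_truth.de_proteins)
    clique = de_genes[:8]
    for i in range(len(clique)):
        for j in range(i + 1, len(clique)):
            edges[(clique[i], clique[j])] = "database"
    edge_df = pd.DataFrame(
        [(a, b, ev) for (a, b), ev in sorted(edges.items())],
        columns=["gene_a", "gene_b", "evidence"],
    )
    non_de = [g for g in genes if g not in set(de_genes)]
    extra = [non_de[i] for i in rng.permutation(len(non_de))[:3]] if non_de else []
    enriched_set = "set_01"
    set_rows = [(enriched_set, g) for g in sorted(set(de_genes) | set(extra))]
    remaining = [g for g in genes if g not in set(de_genes) | set(extra)]
    shuffled = [remaining[i] for i in rng.permutation(len(remaining))]
    n_other = max(config.n_gene_sets - 1, 1)
    for idx, gene in enumerate(shuffled):
        set_rows.append((f"set_{2 + idx % n_other:02d}", gene))
    set_df = pd.DataFrame(sorted(set_rows), columns=["set_id", "gene_id"])
    return edge_df, set_df, clique, enriched_set


# ---------------------------------------------------------------------------
# Full study


@dataclass
class SimulatedStudy:
    """In-memory handles plus file paths of one simulated study."""

    config: SimulationConfig
    outdir: Path
    genome: dict[str, str]
    models: list[TranscriptModel]
    variants: list[VariantRecord]
    event: NovelExonEvent
    sample_databases: dict[str, list[ProteinRecord]]
    canonical_records: list[ProteinRecord]
    psm: pd.DataFrame
    transcript_counts: CountMatrix
    usage_counts: pd.DataFrame
    edges: pd.DataFrame
    gene_sets: pd.DataFrame
    ground_truth: GroundTruth

    @property
    def paths(self) -> dict[str, Path]:
        d = self.outdir
        return {
            "genome": d / "genome.fa",
            "gtf": d / "annotation.gtf",
            "vcf": d / "variants.vcf",
            "events": d / "novel_exons.tsv",
            "psm": d / "psm.tsv",
            "transcript_counts": d / "transcript_counts.tsv",
            "usage": d / "usage.tsv",
            "design": d / "design.tsv",
            "edges": d / "edges.tsv",
            "gene_sets": d / "gene_sets.tsv",
            "ground_truth": d / "ground_truth.json",
        }


def _pick_de_genes(
    models: Sequence[TranscriptModel], config: SimulationConfig, rng: np.random.Generator
) -> dict[str, float]:
    genes = [m.gene_id for m in models]
    n_de = int(round(config.frac_de * len(genes)))
    chosen = sorted(np.array(genes, dtype=object)[rng.permutation(len(genes))[:n_de]])
    out = {}
    for i, gene in enumerate(chosen):
        sign = 1.0 if rng.random() < 0.5 else -1.0
        out[gene] = float(sign * config.log2fc_magnitude)
    return out


def simulate_study(
    config: SimulationConfig,
    outdir: str | Path,
    params: DigestionParams = DigestionParams(),
) -> SimulatedStudy:
    """Generate and write a complete synthetic study.

    Deterministic in ``config`` (including its seed): independent RNG
    substreams are spawned per stage so changing one stage's parameters
    never reshuffles another stage's draws.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    (
        rng_genome,
        rng_de,
        rng_variants,
        rng_exon,
        rng_psm,
        rng_tx,
        rng_usage,
        rng_net,
    ) = (np.random.default_rng(child) for child in ss.spawn(8))

    genome, models = generate_genome(config, rng_genome)
    design = config.design()
    ground_truth = GroundTruth(group_assignment=dict(design.assignment))
    ground_truth.de_proteins = _pick_de_genes(models, config, rng_de)

    variants, saav_events = generate_variants(models, genome, config, rng_variants)
    ground_truth.saav_events = saav_events

    event, genome, inclusion = generate_novel_exon(models, genome, config, rng_exon)
    host = models[0]
    ground_truth.novel_exon = {
        "gene": event.gene_id,
        "transcript": event.host_transcript,
        "chrom": event.chrom,
        "start": event.exon_interval[0],
        "end": event.exon_interval[1],
        "insertion_index": event.insertion_index,
        "inclusion": inclusion,
        "added_residues": event.length // 3,
    }

    canonical_records = build_sample_database(models, genome)
    sample_databases = {
        sample: build_sample_database(
            models, genome, variants, [event], sample_id=sample
        )
        for sample in config.samples
    }

    psm, novel_peptides = generate_psm_table(
        sample_databases, canonical_records, event, ground_truth, config, rng_psm, params
    )
    ground_truth.novel_peptides = novel_peptides

    transcript_counts, transcript_lfc, concordant = generate_transcript_counts(
        models, ground_truth, config, rng_tx
    )
    ground_truth.transcript_lfc = transcript_lfc
    ground_truth.concordant_genes = concordant

    usage_counts = generate_usage_counts(inclusion, config, rng_usage)
    edges, gene_sets, clique, enriched_set = generate_network_inputs(
        models, ground_truth, config, rng_net
    )
    ground_truth.clique_genes = clique
    ground_truth.enriched_set = enriched_set

    study = SimulatedStudy(
        config=config,
        outdir=outdir,
        genome=genome,
        models=models,
        variants=variants,
        event=event,
        sample_databases=sample_databases,
        canonical_records=canonical_records,
        psm=psm,
        transcript_counts=transcript_counts,
        usage_counts=usage_counts,
        edges=edges,
        gene_sets=gene_sets,
        ground_truth=ground_truth,
    )

    paths = study.paths
    write_fasta(genome, paths["genome"])
    write_gtf(models, paths["gtf"])
    write_vcf(
        variants,
        {chrom: len(seq) for chrom, seq in genome.items()},
        list(config.samples),
        paths["vcf"],
    )
    write_events_tsv([event], paths["events"])
    psm.to_csv(paths["psm"], sep="\t", index=False)
    transcript_counts.to_tsv(paths["transcript_counts"])
    usage_counts.to_csv(paths["usage"], sep="\t", index=False)
    design.to_tsv(paths["design"])
    edges.to_csv(paths["edges"], sep="\t", index=False)
    gene_sets.to_csv(paths["gene_sets"], sep="\t", index=False)
    ground_truth.to_json(paths["ground_truth"])
    return study
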