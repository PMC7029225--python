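"""Sample-specific protein databases.

The core proteogenomic step: take reference transcript models, apply a
sample's genomic variants and novel splice events, translate, and emit a
protein database in which every record carries machine-readable provenance
(``canonical``, ``saav`` for single-amino-acid variants, or
``novel_isoform``).  The canonical proteome is always a subset of every
sample database — augmentation is strictly additive.

Only single-nucleotide variants are supported; indels are rejected.  When
several variants hit the same codon they are applied jointly before
translation, so the emitted codon reflects all substitutions.  A variant
that introduces a premature stop truncates the protein with an explicit
warning rather than aborting: peptide evidence upstream of the stop is still
informative and is retained.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pysam
from Bio.Seq import Seq

from varipept.genome import (
    MalformedModelError,
    TranscriptModel,
    complement,
    reverse_complement,
)

PROVENANCE_CANONICAL = "canonical"
PROVENANCE_SAAV = "saav"
PROVENANCE_NOVEL_ISOFORM = "novel_isoform"
# Reserved label for externally confirmed gene models; never emitted by
# this module but accepted on input for forward compatibility.
PROVENANCE_CONFIRMED = "confirmed_gene_model"

_PROVENANCES = {
    PROVENANCE_CANONICAL,
    PROVENANCE_SAAV,
    PROVENANCE_NOVEL_ISOFORM,
    PROVENANCE_CONFIRMED,
}

NOVEL_ISOFORM_SUFFIX = "_ne"


class ReferenceMismatchError(ValueError):
    """A variant's REF base disagrees with the genome/CDS sequence."""


class InvalidEventError(ValueError):
    """A novel-exon event is inconsistent with its host transcript."""


class PrematureStopWarning(UserWarning):
    """Translation hit an internal stop codon; the protein was truncated."""


class VariantOutsideCdsWarning(UserWarning):
    """A variant fell outside the coding exons and was skipped."""


@dataclass(frozen=True)
class VariantRecord:
    """A single-nucleotide variant carried by one sample.

    ``pos`` is 0-based genomic (converted from the 1-based VCF coordinate at
    the I/O boundary).  ``ref`` and ``alt`` are single plus-strand bases.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    sample_id: str

    def __post_init__(self) -> None:
        if len(self.ref) != 1 or len(self.alt) != 1:
            raise ValueError(
                f"only SNVs are supported, got ref={self.ref!r} alt={self.alt!r} "
                f"at {self.chrom}:{self.pos + 1}"
            )
        if self.ref == self.alt:
            raise ValueError(f"ref == alt at {self.chrom}:{self.pos + 1}")
        if self.pos < 0:
            raise ValueError("negative genomic position")


@dataclass(frozen=True)
class NovelExonEvent:
    """An unannotated exon inside an intron of a host transcript.

    ``exon_interval`` is 0-based half-open genomic; ``insertion_index`` is
    the position the exon takes in the genomically sorted exon chain.
    ``samples_present`` lists the samples whose RNA evidence supports the
    event, i.e. the samples whose database receives the novel isoform.
    """

    gene_id: str
    host_transcript: str
    chrom: str
    exon_interval: tuple[int, int]
    insertion_index: int
    samples_present: frozenset[str]

    @property
    def length(self) -> int:
        return self.exon_interval[1] - self.exon_interval[0]

    @property
    def in_frame(self) -> bool:
        return self.length % 3 == 0


@dataclass(frozen=True)
class ProteinRecord:
    """A translated protein with provenance.

    ``annotations`` holds ``(residue_position_1based, ref_aa, alt_aa)``
    triples for SAAV records (``alt_aa`` is ``"*"`` for a truncating stop
    gain).  ``sample_id`` is ``"reference"`` for canonical records.
    """

    protein_id: str
    sequence: str
    provenance: str
    source_transcript: str
    gene_id: str
    sample_id: str = "reference"
    annotations: tuple[tuple[int, str, str], ...] = ()

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.protein_id}: empty protein sequence")
        if "*" in self.sequence:
            raise ValueError(f"{self.protein_id}: stop symbol inside sequence")
        if self.provenance not in _PROVENANCES:
            raise ValueError(f"{self.protein_id}: unknown provenance {self.provenance!r}")
        if self.provenance == PROVENANCE_SAAV and not self.annotations:
            raise ValueError(f"{self.protein_id}: saav record without annotations")
        if self.provenance == PROVENANCE_CANONICAL and self.annotations:
            raise ValueError(f"{self.protein_id}: canonical record with annotations")


# ---------------------------------------------------------------------------
# Sequence operations


def spliced_cds_sequence(model: TranscriptModel, genome: Mapping[str, str]) -> str:
    """Spliced coding sequence of a transcript, 5'->3'.

    Exon segments are concatenated in genomic order and reverse complemented
    for minus-strand transcripts.  The result must be a whole number of
    codons, otherwise the model is malformed.
    """
    chrom_seq = genome[model.chrom]
    if model.cds_span[1] > len(chrom_seq):
        raise MalformedModelError(
            f"{model.transcript_id}: exon beyond end of {model.chrom}"
        )
    seq = "".join(chrom_seq[s:e] for s, e in model.exons)
    if model.strand == "-":
        seq = reverse_complement(seq)
    if len(seq) % 3 != 0:
        raise MalformedModelError(
            f"{model.transcript_id}: spliced CDS length {len(seq)} is not a "
            "multiple of 3"
        )
    return seq


def apply_variants(
    cds: str,
    model: TranscriptModel,
    variants: Sequence[VariantRecord],
) -> str:
    """Substitute sample variants into a spliced CDS.

    Genomic positions are projected into transcript coordinates; on the
    minus strand the ALT base is complemented.  A REF mismatch raises; a
    variant outside the coding exons is skipped with a warning.
    """
    out = list(cds)
    for v in variants:
        if v.chrom != model.chrom:
            warnings.warn(
                f"{v.chrom}:{v.pos + 1} not on {model.transcript_id}'s chromosome; skipped",
                VariantOutsideCdsWarning,
                stacklevel=2,
            )
            continue
        offset = model.genomic_to_transcript(v.pos)
        if offset is None:
            warnings.warn(
                f"variant {v.chrom}:{v.pos + 1} {v.ref}>{v.alt} outside coding "
                f"exons of {model.transcript_id}; skipped",
                VariantOutsideCdsWarning,
                stacklevel=2,
            )
            continue
        expected = v.ref if model.strand == "+" else complement(v.ref)
        if cds[offset] != expected:
            raise ReferenceMismatchError(
                f"variant {v.chrom}:{v.pos + 1}: REF {v.ref!r} does not match "
                f"transcript base {cds[offset]!r} of {model.transcript_id}"
            )
        out[offset] = v.alt if model.strand == "+" else complement(v.alt)
    return "".join(out)


def insert_novel_exon(model: TranscriptModel, event: NovelExonEvent) -> TranscriptModel:
    """Return a new model with the event's exon spliced into the chain.

    The exon must lie strictly inside an intron of the host.  The new
    transcript id is suffixed so the isoform is distinguishable from its
    host.
    """
    s, e = event.exon_interval
    if event.host_transcript != model.transcript_id:
        raise InvalidEventError(
            f"event targets {event.host_transcript}, not {model.transcript_id}"
        )
    for xs, xe in model.exons:
        if s < xe and xs < e:
            raise InvalidEventError(
                f"novel exon ({s}, {e}) overlaps exon ({xs}, {xe}) of "
                f"{model.transcript_id}"
            )
    inside_intron = any(istart < s and e < iend for istart, iend in model.introns())
    if not inside_intron:
        raise InvalidEventError(
            f"novel exon ({s}, {e}) is not strictly inside an intron of "
            f"{model.transcript_id}"
        )
    exons = sorted(model.exons + ((s, e),))
    idx = exons.index((s, e))
    if idx != event.insertion_index:
        raise InvalidEventError(
            f"insertion index {event.insertion_index} inconsistent with exon "
            f"chain of {model.transcript_id} (expected {idx})"
        )
    return TranscriptModel(
        transcript_id=model.transcript_id + NOVEL_ISOFORM_SUFFIX,
        gene_id=model.gene_id,
        chrom=model.chrom,
        strand=model.strand,
        exons=tuple(exons),
    )


def remove_novel_exon(model: TranscriptModel, event: NovelExonEvent) -> TranscriptModel:
    """Inverse of :func:`insert_novel_exon` (round-trip identity)."""
    exons = tuple(x for x in model.exons if x != event.exon_interval)
    if len(exons) != len(model.exons) - 1:
        raise InvalidEventError(
            f"exon {event.exon_interval} not present exactly once in "
            f"{model.transcript_id}"
        )
    tid = model.transcript_id
    if tid.endswith(NOVEL_ISOFORM_SUFFIX):
        tid = tid[: -len(NOVEL_ISOFORM_SUFFIX)]
    return TranscriptModel(
        transcript_id=tid,
        gene_id=model.gene_id,
        chrom=model.chrom,
        strand=model.strand,
        exons=exons,
    )


def translate(cds: str, require_start: bool = True) -> str:
    """Translate a CDS with the standard genetic code.

    Translation stops at the first stop codon and the stop symbol is never
    included.  An internal (premature) stop truncates the protein and emits
    :class:`PrematureStopWarning` instead of failing silently or aborting.
    """
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise MalformedModelError(
            f"CDS length {len(cds)} is not a multiple of 3"
        )
    if require_start and not cds.startswith("ATG"):
        raise MalformedModelError("CDS does not start with ATG")
    aa = str(Seq(cds).translate())
    if aa.endswith("*"):
        aa = aa[:-1]
    if "*" in aa:
        aa = aa.split("*", 1)[0]
        warnings.warn(
            f"premature stop codon after {len(aa)} residues; protein truncated",
            PrematureStopWarning,
            stacklevel=2,
        )
    return aa


def _protein_diffs(reference: str, variant: str) -> tuple[tuple[int, str, str], ...]:
    """Residue-level differences as (1-based position, ref_aa, alt_aa)."""
    diffs = [
        (i + 1, a, b)
        for i, (a, b) in enumerate(zip(reference, variant))
        if a != b
    ]
    if len(variant) < len(reference):
        # truncation by a stop gain
        diffs.append((len(variant) + 1, reference[len(variant)], "*"))
    return tuple(diffs)


# ---------------------------------------------------------------------------
# Database construction


def build_sample_database(
    models: Sequence[TranscriptModel],
    genome: Mapping[str, str],
    variants: Sequence[VariantRecord] = (),
    events: Sequence[NovelExonEvent] = (),
    sample_id: str = "reference",
) -> list[ProteinRecord]:
    """Build one sample's protein database.

    The result is the canonical proteome, plus one ``saav`` record per
    transcript hit by at least one non-synonymous variant of this sample,
    plus one ``novel_isoform`` record per event listing the sample.
    Synonymous-only transcripts add nothing: non-synonymy is decided on the
    translated product, not the nucleotide change.
    """
    records: list[ProteinRecord] = []
    sample_variants = [v for v in variants if v.sample_id == sample_id]

    for model in models:
        cds = spliced_cds_sequence(model, genome)
        protein = translate(cds)
        records.append(
            ProteinRecord(
                protein_id=model.transcript_id,
                sequence=protein,
                provenance=PROVENANCE_CANONICAL,
                source_transcript=model.transcript_id,
                gene_id=model.gene_id,
                sample_id="reference",
            )
        )
        if sample_id == "reference":
            continue
        mine = [
            v
            for v in sample_variants
            if v.chrom == model.chrom
            and model.genomic_to_transcript(v.pos) is not None
        ]
        if mine:
            var_cds = apply_variants(cds, model, mine)
            var_protein = translate(var_cds)
            annotations = _protein_diffs(protein, var_protein)
            if annotations:
                records.append(
                    ProteinRecord(
                        protein_id=f"{model.transcript_id}_saav_{sample_id}",
                        sequence=var_protein,
                        provenance=PROVENANCE_SAAV,
                        source_transcript=model.transcript_id,
                        gene_id=model.gene_id,
                        sample_id=sample_id,
                        annotations=annotations,
                    )
                )

    if sample_id != "reference":
        model_by_id = {m.transcript_id: m for m in models}
        for event in events:
            if sample_id not in event.samples_present:
                continue
            host = model_by_id[event.host_transcript]
            iso_model = insert_novel_exon(host, event)
            iso_protein = translate(spliced_cds_sequence(iso_model, genome))
            records.append(
                ProteinRecord(
                    protein_id=f"{iso_model.transcript_id}_{sample_id}",
                    sequence=iso_protein,
                    provenance=PROVENANCE_NOVEL_ISOFORM,
                    source_transcript=event.host_transcript,
                    gene_id=event.gene_id,
                    sample_id=sample_id,
                )
            )
    return records


# ---------------------------------------------------------------------------
# I/O: protein FASTA with provenance headers, VCF, events TSV

_HEADER_SEP = "|"


def _format_annotations(annotations: tuple[tuple[int, str, str], ...]) -> str:
    return ",".join(f"{pos}:{ref}>{alt}" for pos, ref, alt in annotations)


def _parse_annotations(text: str) -> tuple[tuple[int, str, str], ...]:
    out = []
    for item in text.split(","):
        pos, rest = item.split(":")
        ref, alt = rest.split(">")
        out.append((int(pos), ref, alt))
    return tuple(out)


def write_database_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write protein records with machine-readable provenance headers.

    Header grammar:
    ``>{protein_id}|{provenance}|{source_transcript}|{gene_id}|{sample_id}[|{annotations}]``
    """
    with open(path, "w") as fh:
        for r in records:
            fields = [r.protein_id, r.provenance, r.source_transcript, r.gene_id, r.sample_id]
            if r.annotations:
                fields.append(_format_annotations(r.annotations))
            fh.write(">" + _HEADER_SEP.join(fields) + "\n")
            for i in range(0, len(r.sequence), 60):
                fh.write(r.sequence[i : i + 60] + "\n")


def read_database_fasta(path: str | Path) -> list[ProteinRecord]:
    records = []
    header: list[str] | None = None
    chunks: list[str] = []

    def flush() -> None:
        if header is None:
            return
        annotations = _parse_annotations(header[5]) if len(header) > 5 else ()
        records.append(
            ProteinRecord(
                protein_id=header[0],
                provenance=header[1],
                source_transcript=header[2],
                gene_id=header[3],
                sample_id=header[4],
                sequence="".join(chunks),
                annotations=annotations,
            )
        )

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].split(_HEADER_SEP)
                chunks = []
            else:
                chunks.append(line)
    flush()
    return records


def write_vcf(
    variants: Sequence[VariantRecord],
    contig_lengths: Mapping[str, int],
    samples: Sequence[str],
    path: str | Path,
) -> None:
    """Write a multi-sample VCF v4.2; carriers are genotyped 0/1."""
    keyed: dict[tuple[str, int, str, str], set[str]] = {}
    for v in variants:
        keyed.setdefault((v.chrom, v.pos, v.ref, v.alt), set()).add(v.sample_id)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, length in contig_lengths.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for chrom, pos, ref, alt in sorted(keyed):
            carriers = keyed[(chrom, pos, ref, alt)]
            gts = ["0/1" if s in carriers else "0/0" for s in samples]
            fh.write(
                f"{chrom}\t{pos + 1}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )


def read_vcf(path: str | Path) -> list[VariantRecord]:
    """Read a VCF into per-sample variant records (carriers only)."""
    out: list[VariantRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            alt = rec.alts[0] if rec.alts else None
            if alt is None:
                continue
            for sample in rec.samples:
                gt = rec.samples[sample].get("GT", (0, 0))
                if gt and any(a == 1 for a in gt if a is not None):
                    out.append(
                        VariantRecord(
                            chrom=rec.chrom,
                            pos=rec.start,
                            ref=rec.ref,
                            alt=alt,
                            sample_id=sample,
                        )
                    )
    return out


def write_events_tsv(events: Sequence[NovelExonEvent], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "gene_id\thost_transcript\tchrom\tstart\tend\tinsertion_index\tsamples\n"
        )
        for ev in events:
            s, e = ev.exon_interval
            fh.write(
                f"{ev.gene_id}\t{ev.host_transcript}\t{ev.chrom}\t{s + 1}\t{e}\t"
                f"{ev.insertion_index}\t{','.join(sorted(ev.samples_present))}\n"
            )


def read_events_tsv(path: str | Path) -> list[NovelExonEvent]:
    events = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("gene_id"):
            raise ValueError(f"{path}: unexpected events header")
        for line in fh:
            gene, tx, chrom, start, end, idx, samples = line.rstrip("\n").split("\t")
            events.append(
                NovelExonEvent(
                    gene_id=gene,
                    host_transcript=tx,
                    chrom=chrom,
                    exon_interval=(int(start) - 1, int(end)),
                    insertion_index=int(idx),
                    samples_present=frozenset(
                        s for s in samples.split(",") if s
                    ),
                )
            )
    return events
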