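"""Genomic sequences and transcript models.

All coordinates inside the package are 0-based, half-open.  GTF is written
and read as 1-based inclusive and VCF as 1-based; the conversion happens at
the I/O boundary only, so no other module ever handles a 1-based number.

Transcript models here carry the *coding* exon chain: every exon listed is
part of the CDS, which is the substrate for variant application, novel-exon
insertion and translation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import gffutils
import pyfaidx

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def complement(base: str) -> str:
    return base.translate(_COMPLEMENT)


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (ACGTN, case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


class MalformedModelError(ValueError):
    """A transcript model is inconsistent with the genome or with itself."""


@dataclass(frozen=True)
class TranscriptModel:
    """A transcript's coding exon chain on the genome.

    Parameters
    ----------
    transcript_id, gene_id, chrom
        Identifiers; ``chrom`` must name a sequence in the genome FASTA.
    strand
        ``"+"`` or ``"-"``.  On the minus strand the spliced transcript is
        the reverse complement of the concatenated genomic exon sequence.
    exons
        Coding exons as ``(start, end)`` 0-based half-open intervals, sorted
        by genomic start and non-overlapping.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise MalformedModelError(
                f"{self.transcript_id}: strand must be '+' or '-', got {self.strand!r}"
            )
        if not self.exons:
            raise MalformedModelError(f"{self.transcript_id}: no exons")
        exons = tuple((int(s), int(e)) for s, e in self.exons)
        object.__setattr__(self, "exons", exons)
        prev_end = None
        for s, e in exons:
            if e <= s or s < 0:
                raise MalformedModelError(
                    f"{self.transcript_id}: invalid exon interval ({s}, {e})"
                )
            if prev_end is not None and s < prev_end:
                raise MalformedModelError(
                    f"{self.transcript_id}: exons overlap or are unsorted at ({s}, {e})"
                )
            prev_end = e

    @property
    def cds_span(self) -> tuple[int, int]:
        """Genomic span covered by the coding exon chain."""
        return (self.exons[0][0], self.exons[-1][1])

    @property
    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def introns(self) -> list[tuple[int, int]]:
        """Genomic gaps between consecutive exons (0-based half-open)."""
        return [
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        ]

    def genomic_to_transcript(self, pos: int) -> int | None:
        """Project a genomic position into the spliced transcript.

        Returns the 0-based offset in the spliced (5'->3') transcript, or
        ``None`` when the position falls outside every exon.
        """
        plus_offset = 0
        hit = None
        for s, e in self.exons:
            if s <= pos < e:
                hit = plus_offset + (pos - s)
                break
            plus_offset += e - s
        if hit is None:
            return None
        if self.strand == "+":
            return hit
        return self.spliced_length - 1 - hit

    def transcript_to_genomic(self, offset: int) -> int:
        """Inverse of :meth:`genomic_to_transcript` for a valid offset."""
        if not 0 <= offset < self.spliced_length:
            raise ValueError(
                f"{self.transcript_id}: transcript offset {offset} out of range"
            )
        plus_offset = offset if self.strand == "+" else self.spliced_length - 1 - offset
        for s, e in self.exons:
            if plus_offset < e - s:
                return s + plus_offset
            plus_offset -= e - s
        raise AssertionError("unreachable")


# ---------------------------------------------------------------------------
# FASTA


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name in sequences:
            fh.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    fa = pyfaidx.Fasta(str(path))
    try:
        return {name: str(fa[name][:]) for name in fa.keys()}
    finally:
        fa.close()


# ---------------------------------------------------------------------------
# GTF


def write_gtf(models: Iterable[TranscriptModel], path: str | Path) -> None:
    """Write transcript models as GTF (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        for m in models:
            attrs = f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}";'
            span = m.cds_span
            rows = [("transcript", span[0], span[1])]
            for s, e in m.exons:
                rows.append(("exon", s, e))
                rows.append(("CDS", s, e))
            for feature, s, e in rows:
                fh.write(
                    "\t".join(
                        [
                            m.chrom,
                            "varipept",
                            feature,
                            str(s + 1),
                            str(e),
                            ".",
                            m.strand,
                            ".",
                            attrs,
                        ]
                    )
                    + "\n"
                )


def read_gtf(path: str | Path) -> list[TranscriptModel]:
    """Read transcript models back from GTF written by :func:`write_gtf`."""
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    models = []
    for tx in db.features_of_type("transcript"):
        exons = sorted(
            (f.start - 1, f.end) for f in db.children(tx, featuretype="exon")
        )
        models.append(
            TranscriptModel(
                transcript_id=tx.attributes["transcript_id"][0],
                gene_id=tx.attributes["gene_id"][0],
                chrom=tx.seqid,
                strand=tx.strand,
                exons=tuple(exons),
            )
        )
    models.sort(key=lambda m: m.transcript_id)
    return models
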