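"""In-silico tryptic digestion and peptide-to-database classification.

Peptides observed by shotgun MS are matched against the canonical proteome
and against the union of sample-specific databases.  A peptide found in the
canonical digest is *reference* (unique or ambiguous by gene count); a
peptide absent from the canonical digest but present in at least one sample
database is *non-reference*, split into single-amino-acid-variant evidence
(``nonref_saav``) and novel-isoform evidence (``nonref_novel_isoform``).

Matching convention: isoleucine and leucine are isobaric and cannot be
distinguished by standard MS, so by default they are collapsed before any
reference/non-reference decision.  Collapsing can only merge a would-be
novel peptide into the reference set, never the reverse, which protects
against false novelty claims; strict matching is available as a flag.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from varipept.sample_db import (
    NovelExonEvent,
    ProteinRecord,
    PROVENANCE_CANONICAL,
    PROVENANCE_NOVEL_ISOFORM,
    PROVENANCE_SAAV,
)

CATEGORY_REFERENCE_UNIQUE = "reference_unique"
CATEGORY_REFERENCE_AMBIGUOUS = "reference_ambiguous"
CATEGORY_NONREF_SAAV = "nonref_saav"
CATEGORY_NONREF_NOVEL_ISOFORM = "nonref_novel_isoform"
CATEGORY_UNMATCHED = "unmatched"

CATEGORIES = (
    CATEGORY_REFERENCE_UNIQUE,
    CATEGORY_REFERENCE_AMBIGUOUS,
    CATEGORY_NONREF_SAAV,
    CATEGORY_NONREF_NOVEL_ISOFORM,
    CATEGORY_UNMATCHED,
)

_CLEAVAGE_RE = re.compile(r"[KR](?!P)")
_VALID_PEPTIDE_RE = re.compile(r"^[ACDEFGHIKLMNPQRSTVWY]+$")


class PeptideValidationError(ValueError):
    """Peptide contains symbols outside the 20 standard amino acids."""


@dataclass(frozen=True)
class DigestionParams:
    """Tryptic digestion settings.

    Defaults are field-standard shotgun settings: trypsin (cleave C-terminal
    to K/R except before proline), at most 2 missed cleavages, peptide
    length 7-35, and I/L collapsed for matching.
    """

    missed_cleavages: int = 2
    min_len: int = 7
    max_len: int = 35
    collapse_il: bool = True

    def __post_init__(self) -> None:
        if self.missed_cleavages < 0:
            raise ValueError("missed_cleavages must be >= 0")
        if not 1 <= self.min_len <= self.max_len:
            raise ValueError("need 1 <= min_len <= max_len")


def xle_collapse(peptide: str) -> str:
    """Map isoleucine to leucine (the MS-indistinguishable pair)."""
    return peptide.replace("I", "L")


def digest(
    protein: str,
    missed_cleavages: int = 2,
    min_len: int = 7,
    max_len: int = 35,
) -> list[str]:
    """Tryptic peptides of a protein, deduplicated, in positional order.

    Cleaves C-terminal to K or R except when the next residue is P.  Returns
    every fragment spanning at most ``missed_cleavages`` internal cleavage
    sites whose length is within ``[min_len, max_len]``; duplicates keep
    their first (most N-terminal, then shortest) occurrence.
    """
    DigestionParams(missed_cleavages, min_len, max_len)  # validate bounds
    if not protein:
        return []
    sites = [m.end() for m in _CLEAVAGE_RE.finditer(protein) if m.end() < len(protein)]
    bounds = [0] + sites + [len(protein)]
    seen: set[str] = set()
    peptides: list[str] = []
    for i in range(len(bounds) - 1):
        for j in range(i + 1, min(i + 2 + missed_cleavages, len(bounds))):
            pep = protein[bounds[i] : bounds[j]]
            if min_len <= len(pep) <= max_len and pep not in seen:
                seen.add(pep)
                peptides.append(pep)
    return peptides


@dataclass
class IndexEntry:
    genes: set[str] = field(default_factory=set)
    provenances: set[str] = field(default_factory=set)
    samples: set[str] = field(default_factory=set)


class PeptideIndex:
    """Hash index from (convention-collapsed) peptide to its origins."""

    def __init__(self, collapse_il: bool = True) -> None:
        self.collapse_il = collapse_il
        self._entries: dict[str, IndexEntry] = {}

    def key(self, peptide: str) -> str:
        return xle_collapse(peptide) if self.collapse_il else peptide

    def add(self, peptide: str, gene: str, provenance: str, sample: str) -> None:
        entry = self._entries.setdefault(self.key(peptide), IndexEntry())
        entry.genes.add(gene)
        entry.provenances.add(provenance)
        entry.samples.add(sample)

    def lookup(self, peptide: str) -> IndexEntry | None:
        return self._entries.get(self.key(peptide))

    def __contains__(self, peptide: str) -> bool:
        return self.key(peptide) in self._entries

    def __len__(self) -> int:
        return len(self._entries)

    def peptide_keys(self) -> list[str]:
        return sorted(self._entries)


def build_peptide_index(
    databases: Mapping[str, Sequence[ProteinRecord]],
    params: DigestionParams = DigestionParams(),
) -> PeptideIndex:
    """Index every digestion product of every record in every database.

    ``databases`` maps a database label (usually the sample id) to its
    protein records.  Canonical records are attributed to the sample
    ``"reference"`` regardless of which database carries them.
    """
    index = PeptideIndex(collapse_il=params.collapse_il)
    for label, records in databases.items():
        for record in records:
            sample = (
                "reference"
                if record.provenance == PROVENANCE_CANONICAL
                else (record.sample_id if record.sample_id != "reference" else label)
            )
            for pep in digest(
                record.sequence, params.missed_cleavages, params.min_len, params.max_len
            ):
                index.add(pep, record.gene_id, record.provenance, sample)
    return index


@dataclass(frozen=True)
class PeptideClassification:
    """Classification of one observed peptide.

    ``mapped_genes`` is the gene set the peptide's sequence matches under
    the active convention; ``supporting_samples`` is the set of samples
    whose database contains the peptide.
    """

    peptide: str
    category: str
    mapped_genes: frozenset[str]
    supporting_samples: frozenset[str]


def classify_peptide(
    peptide: str,
    sample_index: PeptideIndex,
    canonical_index: PeptideIndex,
) -> PeptideClassification:
    """Classify an observed peptide against canonical and sample indexes.

    Present in the canonical digest -> reference (unique vs ambiguous by the
    number of mapped genes).  Absent from canonical but present in a sample
    database -> non-reference; a peptide explainable by both a SAAV record
    and a novel isoform is labelled ``nonref_novel_isoform`` (the isoform
    label wins ties so each peptide gets exactly one deterministic label).
    Absent everywhere -> ``unmatched``.
    """
    if not _VALID_PEPTIDE_RE.match(peptide):
        raise PeptideValidationError(
            f"peptide {peptide!r} contains non-amino-acid symbols"
        )
    canonical = canonical_index.lookup(peptide)
    if canonical is not None:
        category = (
            CATEGORY_REFERENCE_UNIQUE
            if len(canonical.genes) == 1
            else CATEGORY_REFERENCE_AMBIGUOUS
        )
        entry = sample_index.lookup(peptide)
        samples = entry.samples if entry is not None else canonical.samples
        return PeptideClassification(
            peptide=peptide,
            category=category,
            mapped_genes=frozenset(canonical.genes),
            supporting_samples=frozenset(samples),
        )
    entry = sample_index.lookup(peptide)
    if entry is None:
        return PeptideClassification(
            peptide=peptide,
            category=CATEGORY_UNMATCHED,
            mapped_genes=frozenset(),
            supporting_samples=frozenset(),
        )
    if PROVENANCE_NOVEL_ISOFORM in entry.provenances:
        category = CATEGORY_NONREF_NOVEL_ISOFORM
    elif entry.provenances <= {PROVENANCE_SAAV}:
        category = CATEGORY_NONREF_SAAV
    else:
        # canonical provenance without a canonical-index hit cannot happen
        # when both indexes share one digestion convention
        category = CATEGORY_NONREF_SAAV
    return PeptideClassification(
        peptide=peptide,
        category=category,
        mapped_genes=frozenset(entry.genes),
        supporting_samples=frozenset(entry.samples),
    )


def classify_peptides(
    peptides: Iterable[str],
    sample_databases: Mapping[str, Sequence[ProteinRecord]],
    canonical_records: Sequence[ProteinRecord],
    params: DigestionParams = DigestionParams(),
) -> pd.DataFrame:
    """Classify many peptides; returns a tidy frame, one row per peptide."""
    canonical_index = build_peptide_index({"reference": canonical_records}, params)
    sample_index = build_peptide_index(sample_databases, params)
    rows = []
    for pep in peptides:
        c = classify_peptide(pep, sample_index, canonical_index)
        rows.append(
            {
                "peptide": c.peptide,
                "category": c.category,
                "genes": ",".join(sorted(c.mapped_genes)),
                "n_supporting_samples": len(c.supporting_samples),
            }
        )
    return pd.DataFrame(rows, columns=["peptide", "category", "genes", "n_supporting_samples"])


def peptides_for_novel_exon(
    event: NovelExonEvent,
    sample_databases: Mapping[str, Sequence[ProteinRecord]],
    params: DigestionParams = DigestionParams(),
) -> list[str]:
    """Digested peptides unique to the event's novel isoform.

    Returns peptides of the novel-isoform protein(s) that are absent, under
    the matching convention, from every canonical and every SAAV protein in
    the given databases — the peptides whose observation is evidence for the
    unannotated exon.
    """
    other_keys: set[str] = set()
    novel_records: list[ProteinRecord] = []
    keyfn = xle_collapse if params.collapse_il else (lambda p: p)
    for records in sample_databases.values():
        for record in records:
            if (
                record.provenance == PROVENANCE_NOVEL_ISOFORM
                and record.source_transcript == event.host_transcript
            ):
                novel_records.append(record)
            else:
                for pep in digest(
                    record.sequence,
                    params.missed_cleavages,
                    params.min_len,
                    params.max_len,
                ):
                    other_keys.add(keyfn(pep))
    out: list[str] = []
    seen: set[str] = set()
    for record in novel_records:
        for pep in digest(
            record.sequence, params.missed_cleavages, params.min_len, params.max_len
        ):
            k = keyfn(pep)
            if k not in other_keys and k not in seen:
                seen.add(k)
                out.append(pep)
    return out


def write_classifications_tsv(classifications: pd.DataFrame, path: str | Path) -> None:
    classifications.to_csv(path, sep="\t", index=False)


def read_classifications_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"peptide": str, "category": str}, keep_default_na=False)
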