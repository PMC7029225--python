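"""Tryptic digestion and peptide classification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from varipept.digest import (
    CATEGORY_NONREF_NOVEL_ISOFORM,
    CATEGORY_NONREF_SAAV,
    CATEGORY_REFERENCE_AMBIGUOUS,
    CATEGORY_REFERENCE_UNIQUE,
    CATEGORY_UNMATCHED,
    DigestionParams,
    PeptideValidationError,
    build_peptide_index,
    classify_peptide,
    classify_peptides,
    digest,
    peptides_for_novel_exon,
)
from varipept.sample_db import NovelExonEvent, ProteinRecord

from helpers import brute_force_digest

AA20 = "ACDEFGHIKLMNPQRSTVWY"


class TestDigest:
    def test_no_cleavage_before_proline(self):
        assert digest("MKRPTIDE", 0, 1, 50) == ["MK", "RPTIDE"]

    def test_missed_cleavage_adds_spanning_peptide(self):
        assert digest("MKRPTIDE", 1, 1, 50) == ["MK", "MKRPTIDE", "RPTIDE"]

    def test_empty_protein(self):
        assert digest("", 2, 1, 50) == []

    def test_length_bounds_filter(self):
        assert digest("MKRPTIDE", 1, 3, 7) == ["RPTIDE"]

    @settings(derandomize=True, max_examples=150)
    @given(
        protein=st.text(alphabet=AA20, min_size=1, max_size=30),
        mc=st.integers(0, 2),
    )
    def test_equals_brute_force_enumeration(self, protein, mc):
        assert set(digest(protein, mc, 1, 30)) == brute_force_digest(protein, mc, 1, 30)

    def test_agrees_with_pyteomics_cleave(self):
        pyteomics_parser = pytest.importorskip("pyteomics.parser")
        rng = np.random.default_rng(3)
        for _ in range(20):
            protein = "".join(
                AA20[i] for i in rng.integers(0, 20, size=int(rng.integers(5, 60)))
            )
            ours = set(digest(protein, 2, 1, 1000))
            theirs = set(
                pyteomics_parser.cleave(protein, r"[KR](?!P)", missed_cleavages=2)
            )
            assert ours == theirs


def record(seq, provenance="canonical", gene="geneA", tx="txA", sample="reference", ann=()):
    return ProteinRecord(f"{tx}_{provenance}_{sample}", seq, provenance, tx, gene, sample, ann)


PARAMS = DigestionParams(missed_cleavages=0, min_len=5, max_len=30)


class TestClassification:
    canonical = [
        record("MVVVVKGGGGR", gene="geneA", tx="txA"),
        record("MWWWWKGGGGR", gene="geneB", tx="txB"),
    ]
    sample_dbs = {
        "s1": canonical
        + [record("MVVVYKGGGGR", "saav", "geneA", "txA", "s1", ((5, "V", "Y"),))],
        "s2": canonical
        + [record("MCCCCKDDDDK", "novel_isoform", "geneC", "txC", "s2")],
    }

    def classify(self, pep):
        canonical_index = build_peptide_index({"reference": self.canonical}, PARAMS)
        sample_index = build_peptide_index(self.sample_dbs, PARAMS)
        return classify_peptide(pep, sample_index, canonical_index)

    def test_unique_reference_peptide(self):
        c = self.classify("MVVVVK")
        assert c.category == CATEGORY_REFERENCE_UNIQUE
        assert c.mapped_genes == {"geneA"}

    def test_shared_peptide_is_ambiguous(self):
        c = self.classify("GGGGR")
        assert c.category == CATEGORY_REFERENCE_AMBIGUOUS
        assert c.mapped_genes == {"geneA", "geneB"}

    def test_variant_peptide_is_nonref_saav(self):
        c = self.classify("MVVVYK")
        assert c.category == CATEGORY_NONREF_SAAV
        assert c.supporting_samples == {"s1"}

    def test_novel_isoform_peptide(self):
        c = self.classify("MCCCCK")
        assert c.category == CATEGORY_NONREF_NOVEL_ISOFORM
        assert c.supporting_samples == {"s2"}

    def test_unmatched_reported_not_classified(self):
        assert self.classify("HHHHHHH").category == CATEGORY_UNMATCHED

    def test_invalid_symbols_rejected(self):
        with pytest.raises(PeptideValidationError):
            self.classify("MKB*")

    def test_isoform_wins_tie_with_saav(self):
        # the same peptide explainable by a saav record and a novel isoform
        dbs = {
            "s1": [record("MEEEEKFFFFK", "saav", "geneA", "txA", "s1", ((2, "V", "E"),))],
            "s2": [record("MEEEEKGGGGK", "novel_isoform", "geneC", "txC", "s2")],
        }
        canonical_index = build_peptide_index({"reference": self.canonical}, PARAMS)
        sample_index = build_peptide_index(dbs, PARAMS)
        c = classify_peptide("MEEEEK", sample_index, canonical_index)
        assert c.category == CATEGORY_NONREF_NOVEL_ISOFORM
        assert c.supporting_samples == {"s1", "s2"}

    def test_il_collapse_folds_novelty_into_reference(self):
        # variant I->L (or L->I) is invisible to MS: peptide must stay reference
        canonical = [record("MVVVIKGGGGR", gene="geneA", tx="txA")]
        dbs = {
            "s1": canonical
            + [record("MVVVLKGGGGR", "saav", "geneA", "txA", "s1", ((5, "I", "L"),))]
        }
        canonical_index = build_peptide_index({"reference": canonical}, PARAMS)
        sample_index = build_peptide_index(dbs, PARAMS)
        c = classify_peptide("MVVVLK", sample_index, canonical_index)
        assert c.category == CATEGORY_REFERENCE_UNIQUE

    def test_soundness_no_canonical_peptide_is_nonreference(self, study):
        """Exhaustively: digestion products of canonical proteins are reference."""
        params = DigestionParams()
        canonical_index = build_peptide_index(
            {"reference": study.canonical_records}, params
        )
        sample_index = build_peptide_index(study.sample_databases, params)
        for rec in study.canonical_records:
            for pep in digest(rec.sequence):
                c = classify_peptide(pep, sample_index, canonical_index)
                assert c.category in (
                    CATEGORY_REFERENCE_UNIQUE,
                    CATEGORY_REFERENCE_AMBIGUOUS,
                ), pep

    def test_il_convention_never_increases_nonreference_calls(self, study):
        peptides = sorted(study.psm["peptide"].unique())
        strict = classify_peptides(
            peptides,
            study.sample_databases,
            study.canonical_records,
            DigestionParams(collapse_il=False),
        )
        collapsed = classify_peptides(
            peptides,
            study.sample_databases,
            study.canonical_records,
            DigestionParams(collapse_il=True),
        )
        nonref = {CATEGORY_NONREF_SAAV, CATEGORY_NONREF_NOVEL_ISOFORM}
        n_strict = strict["category"].isin(nonref).sum()
        n_collapsed = collapsed["category"].isin(nonref).sum()
        assert n_collapsed <= n_strict


class TestNovelExonPeptides:
    def test_every_planted_saav_in_reach_yields_a_nonref_call(self, study):
        """Each variant residue inside an admissible tryptic peptide is found."""
        params = DigestionParams()
        canonical_index = build_peptide_index(
            {"reference": study.canonical_records}, params
        )
        sample_index = build_peptide_index(study.sample_databases, params)
        canonical_by_tx = {
            r.source_transcript: r.sequence for r in study.canonical_records
        }
        found, reachable = 0, 0
        for db in study.sample_databases.values():
            for rec in db:
                if rec.provenance != "saav":
                    continue
                variant_positions = {pos - 1 for pos, _, _ in rec.annotations}
                covering = [
                    pep
                    for pep in digest(rec.sequence)
                    for start in [rec.sequence.find(pep)]
                    if any(start <= p < start + len(pep) for p in variant_positions)
                ]
                if not covering:
                    continue
                reachable += 1
                cats = {
                    classify_peptide(p, sample_index, canonical_index).category
                    for p in covering
                }
                if CATEGORY_NONREF_SAAV in cats:
                    found += 1
        assert reachable > 0 and found == reachable

    def test_junction_spanning_peptide_exists(self, study):
        peps = peptides_for_novel_exon(
            study.event, study.sample_databases, DigestionParams()
        )
        assert peps
        # reconstruct the insertion window in protein coordinates
        host = next(
            r.sequence
            for r in study.canonical_records
            if r.source_transcript == study.event.host_transcript
        )
        novel = next(
            r.sequence
            for db in study.sample_databases.values()
            for r in db
            if r.provenance == "novel_isoform"
        )
        added = study.event.length // 3
        k = next(
            i for i in range(len(host) + 1) if novel[:i] + novel[i + added :] == host
        )
        spans_junction = [
            pep
            for pep in peps
            for start in [novel.find(pep)]
            if start < k < start + len(pep) or start < k + added < start + len(pep)
        ]
        assert spans_junction

    def test_duplicated_segment_is_not_unique(self):
        canonical = [record("MVVVVKGGGGR", gene="geneA", tx="txA")]
        dbs = {
            "s1": canonical
            + [record("MPPPPKGGGGRWWWWK", "novel_isoform", "geneC", "txH", "s1")]
        }
        ev = NovelExonEvent("geneC", "txH", "chrT", (0, 9), 1, frozenset({"s1"}))
        peps = peptides_for_novel_exon(ev, dbs, PARAMS)
        assert "GGGGR" not in peps
        assert "WWWWK" in peps

    def test_empty_databases(self):
        ev = NovelExonEvent("geneC", "txH", "chrT", (0, 9), 1, frozenset())
        assert peptides_for_novel_exon(ev, {}, PARAMS) == []
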