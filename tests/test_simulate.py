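"""Synthetic-study generator: structure, determinism, planted ground truth."""

import json

import numpy as np
import pytest

from varipept.digest import DigestionParams, build_peptide_index
from varipept.genome import read_fasta, read_gtf, reverse_complement
from varipept.sample_db import (
    apply_variants,
    build_sample_database,
    insert_novel_exon,
    read_vcf,
    spliced_cds_sequence,
    translate,
)
from varipept.simulate import (
    GroundTruth,
    SimulationConfig,
    generate_genome,
    generate_novel_exon,
    generate_transcript_counts,
    generate_variants,
    nb_draw,
    simulate_study,
)

STOPS = {"TAA", "TAG", "TGA"}


class TestGenomeGeneration:
    def test_gene_structure_contract(self):
        config = SimulationConfig(seed=1, n_genes=5)
        genome, models = generate_genome(config)
        assert len(models) == 5
        assert any(m.strand == "-" for m in models)
        for m in models:
            assert len(m.exons) >= 2
            cds = spliced_cds_sequence(m, genome)
            assert len(cds) % 3 == 0
            assert cds.startswith("ATG")
            assert cds[-3:] in STOPS
            translate(cds)  # no premature stop may be raised as a warning

    def test_minus_strand_is_reverse_complement_of_genomic_exons(self):
        config = SimulationConfig(seed=2, n_genes=4)
        genome, models = generate_genome(config)
        minus = next(m for m in models if m.strand == "-")
        genomic = "".join(genome[minus.chrom][s:e] for s, e in minus.exons)
        assert spliced_cds_sequence(minus, genome) == reverse_complement(genomic)

    def test_same_seed_means_byte_identical_outputs(self, tmp_path):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        cfg = SimulationConfig(seed=5, n_genes=10)
        s1 = simulate_study(cfg, d1)
        s2 = simulate_study(cfg, d2)
        for name, p1 in s1.paths.items():
            p2 = s2.paths[name]
            assert p1.read_bytes() == p2.read_bytes(), name

    def test_written_files_round_trip(self, study):
        genome = read_fasta(study.paths["genome"])
        assert genome == study.genome
        models = read_gtf(study.paths["gtf"])
        assert models == sorted(study.models, key=lambda m: m.transcript_id)
        variants = read_vcf(study.paths["vcf"])
        assert sorted(variants, key=lambda v: (v.pos, v.alt, v.sample_id)) == sorted(
            study.variants, key=lambda v: (v.pos, v.alt, v.sample_id)
        )


class TestVariants:
    def test_zero_rate_gives_no_variants(self):
        config = SimulationConfig(seed=1, n_genes=4, variant_rate=0.0)
        genome, models = generate_genome(config)
        variants, events = generate_variants(models, genome, config)
        assert variants == [] and events == []

    def test_each_variant_changes_exactly_one_residue(self):
        config = SimulationConfig(seed=3, n_genes=6, variant_rate=0.4)
        genome, models = generate_genome(config)
        variants, saav = generate_variants(models, genome, config)
        assert variants
        by_tx = {m.transcript_id: m for m in models}
        for ev, v in zip(saav, variants):
            m = by_tx[ev["transcript"]]
            cds = spliced_cds_sequence(m, genome)
            mutated = apply_variants(cds, m, [v])
            ref_protein = translate(cds)
            alt_protein = translate(mutated)
            diffs = [
                (i + 1, a, b)
                for i, (a, b) in enumerate(zip(ref_protein, alt_protein))
                if a != b
            ]
            assert diffs == [(ev["residue"], ev["ref_aa"], ev["alt_aa"])]


class TestNovelExon:
    def test_deterministic_inclusion_at_extreme_bias(self):
        config = SimulationConfig(seed=4, inclusion_bias=1.0)
        genome, models = generate_genome(config)
        event, genome, inclusion = generate_novel_exon(models, genome, config)
        assert all(inclusion[s] for s in config.case_samples)
        assert not any(inclusion[s] for s in config.control_samples)
        assert event.samples_present == frozenset(config.case_samples)

    def test_in_frame_insertion_adds_expected_residues(self):
        config = SimulationConfig(seed=4)
        genome, models = generate_genome(config)
        event, genome, _ = generate_novel_exon(models, genome, config)
        host = models[0]
        host_protein = translate(spliced_cds_sequence(host, genome))
        iso = insert_novel_exon(host, event)
        iso_protein = translate(spliced_cds_sequence(iso, genome))
        assert len(iso_protein) - len(host_protein) == 238
        assert event.length == 714

    def test_exon_chain_stays_sorted(self):
        config = SimulationConfig(seed=4)
        genome, models = generate_genome(config)
        event, genome, _ = generate_novel_exon(models, genome, config)
        iso = insert_novel_exon(models[0], event)
        starts = [s for s, _ in iso.exons]
        assert starts == sorted(starts)
        assert iso.exons[event.insertion_index] == event.exon_interval


class TestCounts:
    def test_poisson_limit_of_nb_draws(self):
        rng = np.random.default_rng(40)
        draws = np.asarray(nb_draw(rng, 20.0, 1e-13, size=5000), dtype=float)
        assert abs(draws.var() / draws.mean() - 1.0) < 0.10

    def test_nb_moments_match_parameterization(self):
        rng = np.random.default_rng(41)
        mu, phi = 20.0, 0.5
        draws = np.asarray(nb_draw(rng, mu, phi, size=20000), dtype=float)
        assert draws.mean() == pytest.approx(mu, rel=0.05)
        assert draws.var() == pytest.approx(mu + phi * mu * mu, rel=0.10)

    def test_null_genes_have_unit_count_ratio(self, tmp_path):
        """With no fold change, case/control peptide means agree over >=200 features."""
        config = SimulationConfig(seed=42, n_genes=70, frac_de=0.0)
        study = simulate_study(config, tmp_path)
        design = config.design()
        wide = (
            study.psm.pivot_table(
                index="peptide", columns="sample", values="psm_count", fill_value=0
            )
            .reindex(columns=list(design.samples), fill_value=0)
        )
        # restrict to reference peptides: present in nearly all samples
        wide = wide[(wide > 0).sum(axis=1) >= 16]
        assert len(wide) >= 200
        ratio = (
            wide[list(design.cases)].mean(axis=1)
            / wide[list(design.controls)].mean(axis=1)
        )
        assert np.mean(ratio) == pytest.approx(1.0, abs=0.05)

    def test_transcript_concordance_extremes(self):
        config = SimulationConfig(seed=6, n_genes=20, concordant_fraction=1.0)
        genome, models = generate_genome(config)
        gt = GroundTruth(group_assignment=dict(config.design().assignment))
        gt.de_proteins = {"gene_003": 2.0, "gene_007": -2.0, "gene_011": 2.0}
        _, lfc, concordant = generate_transcript_counts(models, gt, config)
        assert set(concordant) == set(gt.de_proteins)
        assert all(np.sign(lfc[g]) == np.sign(gt.de_proteins[g]) for g in gt.de_proteins)

        config0 = SimulationConfig(seed=6, n_genes=20, concordant_fraction=0.0)
        _, lfc0, concordant0 = generate_transcript_counts(models, gt, config0)
        assert concordant0 == []
        assert all(np.sign(lfc0[g]) == -np.sign(gt.de_proteins[g]) for g in gt.de_proteins)

    def test_transcript_matrix_shape(self, study):
        m = study.transcript_counts
        cfg = study.config
        assert m.counts.shape == (cfg.n_genes, cfg.n_case + cfg.n_control)


class TestConsistency:
    def test_every_psm_peptide_comes_from_its_samples_database(self, study):
        params = DigestionParams()
        per_sample_index = {
            s: build_peptide_index({s: db}, params)
            for s, db in study.sample_databases.items()
        }
        for row in study.psm.itertuples():
            assert row.peptide in per_sample_index[row.sample], (
                row.peptide,
                row.sample,
            )

    def test_ground_truth_json_round_trip(self, study, tmp_path):
        path = tmp_path / "gt.json"
        study.ground_truth.to_json(path)
        loaded = GroundTruth.from_json(path)
        assert loaded == study.ground_truth

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_case=0)
        with pytest.raises(ValueError):
            SimulationConfig(frac_de=1.5)
        with pytest.raises(ValueError):
            SimulationConfig(nb_dispersion=-0.1)
        with pytest.raises(ValueError):
            SimulationConfig(novel_exon_length=100)
        with pytest.raises(ValueError):
            SimulationConfig(log2fc_magnitude=0.0)
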