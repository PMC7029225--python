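"""Count matrices, presence/exclusivity filters, upper-quartile normalization."""

import numpy as np
import pandas as pd
import pytest

from varipept.digest import CATEGORY_REFERENCE_UNIQUE
from varipept.quant import (
    CountMatrix,
    GroupDesign,
    NormalizationError,
    ValidationError,
    exclusive_nonref_peptides,
    filter_consistent,
    gene_count_matrix,
    nonzero_upper_quartile,
    peptide_count_matrix,
    upper_quartile_normalize,
)


def classifications(rows):
    return pd.DataFrame(rows, columns=["peptide", "category", "genes", "n_supporting_samples"])


def psm(rows):
    return pd.DataFrame(rows, columns=["peptide", "sample", "psm_count"])


SMALL_DESIGN = GroupDesign({"c1": "case", "c2": "case", "k1": "control", "k2": "control"})


class TestGeneCountMatrix:
    cls = classifications(
        [
            ("PEPA", CATEGORY_REFERENCE_UNIQUE, "geneA", 4),
            ("PEPB", CATEGORY_REFERENCE_UNIQUE, "geneA", 4),
            ("PEPC", "reference_ambiguous", "geneA,geneB", 4),
            ("PEPD", CATEGORY_REFERENCE_UNIQUE, "geneB", 4),
        ]
    )

    def test_unique_peptides_sum_per_gene(self):
        table = psm([("PEPA", "c1", 3), ("PEPB", "c1", 4), ("PEPD", "c1", 2)])
        m = gene_count_matrix(table, self.cls, SMALL_DESIGN)
        assert m.counts.loc["geneA", "c1"] == 7
        assert m.counts.loc["geneB", "c1"] == 2

    def test_ambiguous_peptide_counts_for_no_gene(self):
        table = psm([("PEPC", "c1", 50)])
        m = gene_count_matrix(table, self.cls, SMALL_DESIGN)
        assert m.counts.to_numpy().sum() == 0

    def test_empty_psm_gives_zero_matrix_over_gene_universe(self):
        m = gene_count_matrix(psm([]), self.cls, SMALL_DESIGN)
        assert m.feature_ids == ["geneA", "geneB"]
        assert (m.counts.to_numpy() == 0).all()

    def test_unknown_sample_rejected(self):
        with pytest.raises(ValidationError):
            gene_count_matrix(psm([("PEPA", "nope", 1)]), self.cls, SMALL_DESIGN)

    def test_count_conservation(self, study):
        """Gene-matrix total equals the PSM total of uniquely mapping peptides."""
        from varipept.digest import classify_peptides

        cls = classify_peptides(
            sorted(study.psm["peptide"].unique()),
            study.sample_databases,
            study.canonical_records,
        )
        design = study.config.design()
        m = gene_count_matrix(study.psm, cls, design)
        unique_peps = set(cls.loc[cls["category"] == CATEGORY_REFERENCE_UNIQUE, "peptide"])
        expected = study.psm.loc[study.psm["peptide"].isin(unique_peps), "psm_count"].sum()
        assert m.counts.to_numpy().sum() == expected


def matrix_10v8(rows, features=None):
    cases = [f"case_{i + 1:02d}" for i in range(10)]
    controls = [f"control_{i + 1:02d}" for i in range(8)]
    df = pd.DataFrame(rows, columns=cases + controls)
    if features is not None:
        df.index = features
    return CountMatrix(counts=df)


class TestPresenceFilter:
    def test_boundary_cases_of_the_presence_rule(self, design_10v8):
        rows = [
            [3] * 5 + [0] * 5 + [0] * 8,   # >=3 PSMs in exactly 5 cases -> kept
            [3] * 4 + [0] * 6 + [3] * 3 + [0] * 5,  # 4 cases, 3 controls -> dropped
            [0] * 18,                       # all zero -> dropped
            [0] * 10 + [3] * 4 + [0] * 4,   # 4 controls -> kept
            [2] * 10 + [2] * 8,             # abundant but below min_psm -> dropped
        ]
        m = matrix_10v8(rows, features=["keep5c", "drop43", "zero", "keep4k", "low"])
        out = filter_consistent(m, design_10v8, min_psm=3, min_case=5, min_control=4)
        assert out.feature_ids == ["keep5c", "keep4k"]

    def test_threshold_validation(self, design_10v8):
        m = matrix_10v8([[1] * 18])
        with pytest.raises(ValidationError):
            filter_consistent(m, design_10v8, min_psm=0)
        with pytest.raises(ValidationError):
            filter_consistent(m, design_10v8, min_case=11)

    def test_raising_thresholds_is_monotone(self, design_10v8):
        rng = np.random.default_rng(5)
        m = matrix_10v8(rng.poisson(3, size=(60, 18)),
                        features=[f"f{i}" for i in range(60)])
        kept = {}
        for min_psm in (1, 2, 4):
            for min_case, min_control in ((2, 2), (5, 4), (8, 6)):
                kept[(min_psm, min_case, min_control)] = set(
                    filter_consistent(m, design_10v8, min_psm, min_case, min_control).feature_ids
                )
        assert kept[(2, 5, 4)] <= kept[(1, 5, 4)]
        assert kept[(4, 5, 4)] <= kept[(2, 5, 4)]
        assert kept[(2, 8, 6)] <= kept[(2, 5, 4)] <= kept[(2, 2, 2)]


class TestExclusivity:
    def test_boundary_of_exclusive_rule(self, design_10v8):
        rows = [
            [2, 1, 1, 1] + [0] * 6 + [0] * 8,  # 4 cases, total 5 -> case-exclusive
            [2, 1, 1, 1] + [0] * 6 + [1] + [0] * 7,  # present in a control -> neither
            [5, 0, 0, 0] + [0] * 6 + [0] * 8,  # total 5 but 1 sample -> neither
            [1, 1, 1, 0] + [0] * 6 + [0] * 8,  # 3 samples, total 3 -> neither
            [0] * 10 + [2, 2, 2, 2, 0, 0, 0, 0],  # control-exclusive
        ]
        m = matrix_10v8(rows, features=["case5", "leaky", "single", "weak", "ctrl8"])
        case_excl, control_excl = exclusive_nonref_peptides(m, design_10v8, 5, 4)
        assert case_excl == {"case5"}
        assert control_excl == {"ctrl8"}
        assert case_excl.isdisjoint(control_excl)

    def test_planted_novel_peptides_are_case_exclusive(self, tmp_path):
        from varipept.digest import classify_peptides
        from varipept.simulate import SimulationConfig, simulate_study

        study = simulate_study(
            SimulationConfig(seed=13, inclusion_bias=1.0), tmp_path
        )
        design = study.config.design()
        cls = classify_peptides(
            sorted(study.psm["peptide"].unique()),
            study.sample_databases,
            study.canonical_records,
        )
        nonref = cls.loc[
            cls["category"].isin(["nonref_saav", "nonref_novel_isoform"]), "peptide"
        ].tolist()
        m = peptide_count_matrix(study.psm, nonref, design)
        case_excl, control_excl = exclusive_nonref_peptides(m, design)
        planted = set(study.ground_truth.novel_peptides)
        observed = planted & set(study.psm["peptide"])
        assert observed and observed <= case_excl


class TestUpperQuartile:
    def test_equal_samples_get_unit_factors(self):
        m = CountMatrix(pd.DataFrame({"a": [1, 2, 3, 4], "b": [1, 2, 3, 4]}))
        out = upper_quartile_normalize(m)
        assert np.allclose(out.scale_factors, 1.0)

    def test_hand_computed_nonzero_quartile(self):
        assert nonzero_upper_quartile(np.array([1, 2, 3, 4, 0])) == pytest.approx(3.25)

    def test_scaling_one_sample_leaves_normalized_ratios_invariant(self):
        base = pd.DataFrame({"a": [1, 5, 3, 9], "b": [2, 4, 8, 6]})
        scaled = base.copy()
        scaled["b"] = scaled["b"] * 7
        r1 = upper_quartile_normalize(CountMatrix(base)).normalized
        r2 = upper_quartile_normalize(CountMatrix(scaled)).normalized
        ratio1 = r1["a"] / r1["b"]
        ratio2 = r2["a"] / r2["b"]
        assert np.allclose(ratio1, ratio2)

    def test_idempotent_on_normalized_view(self):
        rng = np.random.default_rng(2)
        m = CountMatrix(
            pd.DataFrame(
                rng.poisson([5, 10, 20, 40], size=(50, 4)).astype(float),
                columns=list("abcd"),
            )
        )
        once = upper_quartile_normalize(m)
        again = upper_quartile_normalize(CountMatrix(once.normalized))
        assert np.abs(again.scale_factors.to_numpy() - 1.0).max() < 1e-12

    def test_all_zero_sample_is_an_error_naming_the_sample(self):
        m = CountMatrix(pd.DataFrame({"good": [1, 2], "empty": [0, 0]}))
        with pytest.raises(NormalizationError, match="empty"):
            upper_quartile_normalize(m)
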