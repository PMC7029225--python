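"""Spectral-count matrices, presence filters and normalization.

Gene-level counts sum the PSMs of peptides that map uniquely to one gene;
ambiguous and non-reference peptides are excluded from gene quantification.
Presence filtering and group exclusivity operate on *raw* integer PSM
counts; upper-quartile normalization feeds the downstream statistics only.

Upper-quartile normalization: the per-sample scale factor is proportional to
the 75th percentile of that sample's nonzero counts (linear/type-7
interpolation), rescaled so the factors have geometric mean one.  Using
nonzero counts makes the factor insensitive to the sparsity of spectral
count data; the geometric-mean-one constraint keeps normalized values on the
scale of the raw counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from varipept.digest import CATEGORY_REFERENCE_UNIQUE

GROUP_CASE = "case"
GROUP_CONTROL = "control"


class ValidationError(ValueError):
    pass


class NormalizationError(ValueError):
    pass


@dataclass(frozen=True)
class GroupDesign:
    """Two-group study design: sample id -> "case" | "control"."""

    assignment: Mapping[str, str]

    def __post_init__(self) -> None:
        bad = {g for g in self.assignment.values() if g not in (GROUP_CASE, GROUP_CONTROL)}
        if bad:
            raise ValidationError(f"unknown group labels: {sorted(bad)}")
        object.__setattr__(self, "assignment", dict(self.assignment))
        if not self.cases or not self.controls:
            raise ValidationError("both groups must be non-empty")

    @property
    def cases(self) -> tuple[str, ...]:
        return tuple(s for s, g in self.assignment.items() if g == GROUP_CASE)

    @property
    def controls(self) -> tuple[str, ...]:
        return tuple(s for s, g in self.assignment.items() if g == GROUP_CONTROL)

    @property
    def samples(self) -> tuple[str, ...]:
        return tuple(self.assignment)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("sample\tgroup\n")
            for s, g in self.assignment.items():
                fh.write(f"{s}\t{g}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GroupDesign":
        df = pd.read_csv(path, sep="\t", dtype=str)
        return cls(dict(zip(df["sample"], df["group"])))


@dataclass
class CountMatrix:
    """Features x samples count matrix with an optional normalized view.

    ``counts`` holds raw values (integral when built from PSM tables);
    ``scale_factors`` is set by :func:`upper_quartile_normalize` and the
    ``normalized`` property divides each sample column by its factor.
    """

    counts: pd.DataFrame
    scale_factors: pd.Series | None = None

    def __post_init__(self) -> None:
        values = self.counts.to_numpy()
        if values.size and ((values < 0).any() or not np.isfinite(values).all()):
            raise ValidationError("counts must be finite and non-negative")
        if self.scale_factors is not None:
            if (self.scale_factors <= 0).any():
                raise ValidationError("scale factors must be positive")
            if list(self.scale_factors.index) != list(self.counts.columns):
                raise ValidationError("scale factors must align with sample columns")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def normalized(self) -> pd.DataFrame:
        if self.scale_factors is None:
            raise ValidationError("matrix is not normalized; call upper_quartile_normalize")
        return self.counts.div(self.scale_factors, axis=1)

    def to_tsv(self, path: str | Path) -> None:
        self.counts.to_csv(path, sep="\t", index_label="feature")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CountMatrix":
        df = pd.read_csv(path, sep="\t", index_col="feature")
        return cls(counts=df)


# ---------------------------------------------------------------------------
# Matrix construction


def _validate_psm_table(psm: pd.DataFrame, design: GroupDesign) -> None:
    required = {"peptide", "sample", "psm_count"}
    if not required <= set(psm.columns):
        raise ValidationError(f"PSM table must have columns {sorted(required)}")
    unknown = set(psm["sample"]) - set(design.samples)
    if unknown:
        raise ValidationError(f"unknown sample ids in PSM table: {sorted(unknown)}")


def gene_count_matrix(
    psm: pd.DataFrame,
    classifications: pd.DataFrame,
    design: GroupDesign,
) -> CountMatrix:
    """Gene x sample PSM counts from uniquely mapping reference peptides.

    Only peptides classified ``reference_unique`` contribute; a peptide
    mapping to several genes contributes to none of them.  The gene universe
    is every gene with at least one uniquely mapping classified peptide, so
    unobserved genes appear as all-zero rows rather than vanishing.
    """
    _validate_psm_table(psm, design)
    unique = classifications[
        classifications["category"] == CATEGORY_REFERENCE_UNIQUE
    ]
    pep_to_gene = dict(zip(unique["peptide"], unique["genes"]))
    genes = sorted(set(pep_to_gene.values()))
    merged = psm[psm["peptide"].isin(pep_to_gene)].copy()
    merged["gene"] = merged["peptide"].map(pep_to_gene)
    table = (
        merged.groupby(["gene", "sample"])["psm_count"].sum().unstack(fill_value=0)
        if len(merged)
        else pd.DataFrame(index=pd.Index([], name="gene"))
    )
    table = table.reindex(index=genes, columns=list(design.samples), fill_value=0)
    return CountMatrix(counts=table.astype(int))


def peptide_count_matrix(
    psm: pd.DataFrame,
    peptides: Sequence[str],
    design: GroupDesign,
) -> CountMatrix:
    """Peptide x sample PSM counts restricted to the given peptides."""
    _validate_psm_table(psm, design)
    sub = psm[psm["peptide"].isin(set(peptides))]
    table = (
        sub.groupby(["peptide", "sample"])["psm_count"].sum().unstack(fill_value=0)
        if len(sub)
        else pd.DataFrame(index=pd.Index([], name="peptide"))
    )
    table = table.reindex(index=sorted(set(peptides)), columns=list(design.samples), fill_value=0)
    return CountMatrix(counts=table.astype(int))


# ---------------------------------------------------------------------------
# Filters


def filter_consistent(
    matrix: CountMatrix,
    design: GroupDesign,
    min_psm: int = 3,
    min_case: int = 5,
    min_control: int = 4,
) -> CountMatrix:
    """Keep features consistently expressed in at least one group.

    A feature survives when it has ``>= min_psm`` counts in at least
    ``min_case`` case samples OR in at least ``min_control`` control
    samples.  Feature order is preserved.  Thresholds apply to raw counts.
    """
    if min(min_psm, min_case, min_control) < 1:
        raise ValidationError("filter thresholds must be >= 1")
    if min_case > len(design.cases) or min_control > len(design.controls):
        raise ValidationError(
            f"thresholds exceed group sizes: min_case={min_case} vs "
            f"{len(design.cases)} cases, min_control={min_control} vs "
            f"{len(design.controls)} controls"
        )
    counts = matrix.counts
    case_hits = (counts[list(design.cases)] >= min_psm).sum(axis=1)
    control_hits = (counts[list(design.controls)] >= min_psm).sum(axis=1)
    keep = (case_hits >= min_case) | (control_hits >= min_control)
    return CountMatrix(counts=counts.loc[keep].copy())


def exclusive_nonref_peptides(
    matrix: CountMatrix,
    design: GroupDesign,
    min_psm_total: int = 5,
    min_samples: int = 4,
) -> tuple[set[str], set[str]]:
    """Group-exclusive peptides among a non-reference peptide matrix.

    A peptide is case-exclusive when every control sample has zero counts,
    it is present (count > 0) in at least ``min_samples`` case samples, and
    its total PSM count is at least ``min_psm_total``; symmetrically for
    control-exclusive.  The two sets are disjoint by construction.
    """
    counts = matrix.counts
    case_cols, control_cols = list(design.cases), list(design.controls)
    total = counts.sum(axis=1)
    case_present = (counts[case_cols] > 0).sum(axis=1)
    control_present = (counts[control_cols] > 0).sum(axis=1)
    case_excl = counts.index[
        (control_present == 0) & (case_present >= min_samples) & (total >= min_psm_total)
    ]
    control_excl = counts.index[
        (case_present == 0) & (control_present >= min_samples) & (total >= min_psm_total)
    ]
    return set(case_excl), set(control_excl)


# ---------------------------------------------------------------------------
# Normalization


def nonzero_upper_quartile(values: np.ndarray) -> float:
    """75th percentile (linear interpolation) of the nonzero entries."""
    nz = np.asarray(values, dtype=float)
    nz = nz[nz > 0]
    if nz.size == 0:
        raise NormalizationError("no nonzero counts")
    return float(np.percentile(nz, 75))


def upper_quartile_normalize(matrix: CountMatrix) -> CountMatrix:
    """Upper-quartile normalization with geometric-mean-one factors."""
    raw_factors = {}
    for sample in matrix.sample_ids:
        try:
            raw_factors[sample] = nonzero_upper_quartile(matrix.counts[sample].to_numpy())
        except NormalizationError:
            raise NormalizationError(
                f"sample {sample!r} has no nonzero counts; cannot normalize"
            ) from None
    factors = pd.Series(raw_factors, dtype=float).reindex(matrix.sample_ids)
    factors /= np.exp(np.log(factors).mean())
    return CountMatrix(counts=matrix.counts.copy(), scale_factors=factors)
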