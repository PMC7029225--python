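"""Gene-set over-representation and interaction-network connectivity.

Over-representation uses the one-sided hypergeometric upper tail against a
background universe (by default the post-filter quantified genes, which
corrects for detection bias) with Benjamini-Hochberg adjustment across the
tested sets.  Network statistics work on a generic undirected edge list with
per-edge evidence labels: within-set degrees of the differential set's
induced subgraph, and a permutation test asking whether the set is more
internally connected than equally sized random draws from the universe.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from varipept.diffexpr import bh_adjust

EVIDENCE_LABELS = ("database", "experimental", "both")


@dataclass(frozen=True)
class EdgeList:
    """Undirected interactions stored as canonical (sorted) gene pairs."""

    edges: Mapping[tuple[str, str], str]

    def __post_init__(self) -> None:
        canonical: dict[tuple[str, str], str] = {}
        for (a, b), evidence in self.edges.items():
            if a == b:
                raise ValueError(f"self-edge on {a!r}")
            key = (a, b) if a < b else (b, a)
            canonical[key] = evidence
        object.__setattr__(self, "edges", canonical)

    def __len__(self) -> int:
        return len(self.edges)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        a, b = pair
        return ((a, b) if a < b else (b, a)) in self.edges

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("gene_a\tgene_b\tevidence\n")
            for (a, b) in sorted(self.edges):
                fh.write(f"{a}\t{b}\t{self.edges[(a, b)]}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "EdgeList":
        df = pd.read_csv(path, sep="\t", dtype=str)
        return cls({(a, b): ev for a, b, ev in zip(df["gene_a"], df["gene_b"], df["evidence"])})

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        for (a, b), evidence in self.edges.items():
            g.add_edge(a, b, evidence=evidence)
        return g


@dataclass(frozen=True)
class EnrichmentRow:
    set_id: str
    overlap: int
    set_size: int
    universe_size: int
    de_size: int
    p_value: float
    fdr: float


def hypergeom_enrich(
    de_set: Iterable[str],
    gene_sets: Mapping[str, Iterable[str]],
    universe: Iterable[str],
) -> list[EnrichmentRow]:
    """One-sided hypergeometric over-representation of each gene set.

    Gene sets are intersected with the universe before testing; sets
    disjoint from the universe are excluded with a warning.  Rows come back
    sorted by p-value with BH adjustment across all tested sets.
    """
    universe = set(universe)
    de = set(de_set)
    if not universe or not de:
        raise ValueError("universe and differential set must be non-empty")
    if not de <= universe:
        raise ValueError("differential set must be a subset of the universe")
    rows = []
    for set_id in sorted(gene_sets):
        members = set(gene_sets[set_id]) & universe
        if not members:
            warnings.warn(
                f"gene set {set_id!r} is disjoint from the universe; excluded",
                stacklevel=2,
            )
            continue
        overlap = len(members & de)
        p = float(stats.hypergeom.sf(overlap - 1, len(universe), len(members), len(de)))
        rows.append((set_id, overlap, len(members), p))
    if not rows:
        return []
    fdr = bh_adjust([r[3] for r in rows])
    out = [
        EnrichmentRow(
            set_id=set_id,
            overlap=overlap,
            set_size=set_size,
            universe_size=len(universe),
            de_size=len(de),
            p_value=p,
            fdr=float(q),
        )
        for (set_id, overlap, set_size, p), q in zip(rows, fdr)
    ]
    out.sort(key=lambda r: (r.p_value, r.set_id))
    return out


def enrichment_table(rows: Sequence[EnrichmentRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "set_id": r.set_id,
                "overlap": r.overlap,
                "set_size": r.set_size,
                "universe_size": r.universe_size,
                "de_size": r.de_size,
                "p_value": r.p_value,
                "fdr": r.fdr,
            }
            for r in rows
        ]
    )


def induced_subgraph_degrees(de_set: Iterable[str], edges: EdgeList) -> dict[str, int]:
    """Within-set degree of every member of the differential set."""
    de = set(de_set)
    g = nx.Graph()
    g.add_nodes_from(de)
    for a, b in edges.edges:
        if a in de and b in de:
            g.add_edge(a, b)
    return {gene: int(deg) for gene, deg in g.degree()}


def _internal_edge_count(members: set[str], edges: EdgeList) -> int:
    return sum(1 for a, b in edges.edges if a in members and b in members)


def connectivity_permutation_test(
    de_set: Iterable[str],
    edges: EdgeList,
    universe: Iterable[str],
    n_perm: int = 999,
    seed: int = 0,
) -> tuple[int, float]:
    """Permutation test for excess internal connectivity.

    The null resamples uniformly chosen subsets of the universe with the
    same size as the differential set and counts their internal edges.  The
    add-one estimator ``p = (1 + #{null >= observed}) / (n_perm + 1)`` never
    returns zero.
    """
    de = sorted(set(de_set))
    universe = sorted(set(universe))
    if len(de) > len(universe):
        raise ValueError("differential set larger than the universe")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    observed = _internal_edge_count(set(de), edges)
    rng = np.random.default_rng(seed)
    universe_arr = np.array(universe, dtype=object)
    exceed = 0
    for _ in range(n_perm):
        subset = set(rng.choice(universe_arr, size=len(de), replace=False))
        if _internal_edge_count(subset, edges) >= observed:
            exceed += 1
    p = (1 + exceed) / (n_perm + 1)
    return observed, float(p)
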