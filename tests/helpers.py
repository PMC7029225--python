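"""Independent oracles used by the tests.

Everything here is implemented from first principles — brute-force
enumeration, closed forms, literal lookup tables — and never calls into the
code paths it checks.
"""

from __future__ import annotations

import math
from itertools import combinations, product


def brute_force_digest(protein: str, missed_cleavages: int, min_len: int, max_len: int) -> set[str]:
    """All substrings satisfying the tryptic cleavage predicate.

    A boundary is valid at position i when i == 0, i == len, or the residue
    before i is K/R and the residue at i is not P.  A fragment is admissible
    when both ends are valid boundaries, it spans at most ``missed_cleavages``
    internal valid boundaries, and its length is within bounds.
    """

    def is_boundary(i: int) -> bool:
        if i == 0 or i == len(protein):
            return True
        return protein[i - 1] in "KR" and protein[i] != "P"

    out = set()
    n = len(protein)
    for start in range(n):
        for end in range(start + 1, n + 1):
            if not (is_boundary(start) and is_boundary(end)):
                continue
            internal = sum(1 for i in range(start + 1, end) if is_boundary(i))
            if internal <= missed_cleavages and min_len <= end - start <= max_len:
                out.add(protein[start:end])
    return out


# Standard genetic code, table 1, spelled out by the canonical TCAG ordering.
_BASES = "TCAG"
_AA = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
CODON_TABLE = {
    "".join(codon): aa
    for codon, aa in zip(product(_BASES, repeat=3), _AA)
}


def lookup_translate(cds: str) -> str:
    """Codon-by-codon translation stopping at the first stop codon."""
    out = []
    for i in range(0, len(cds), 3):
        aa = CODON_TABLE[cds[i : i + 3].upper()]
        if aa == "*":
            break
        out.append(aa)
    return "".join(out)


def enumerate_mwu(group_a, group_b) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney by enumerating all label assignments.

    U for group_a counts pairs (a, b) with a > b (+0.5 for ties); the
    two-sided p doubles the smaller tail of the permutation distribution of
    U, capped at 1.
    """

    def u_stat(a, b):
        return sum(
            1.0 if x > y else (0.5 if x == y else 0.0) for x in a for y in b
        )

    pooled = list(group_a) + list(group_b)
    n = len(group_a)
    u_obs = u_stat(group_a, group_b)
    us = []
    for idx in combinations(range(len(pooled)), n):
        a = [pooled[i] for i in idx]
        b = [pooled[i] for i in range(len(pooled)) if i not in set(idx)]
        us.append(u_stat(a, b))
    total = len(us)
    lower = sum(1 for u in us if u <= u_obs) / total
    upper = sum(1 for u in us if u >= u_obs) / total
    return u_obs, min(1.0, 2 * min(lower, upper))


def hypergeom_sf_comb(k: int, universe: int, set_size: int, draws: int) -> float:
    """P(overlap >= k) via binomial coefficients."""
    num = 0
    for i in range(k, min(set_size, draws) + 1):
        num += math.comb(set_size, i) * math.comb(universe - set_size, draws - i)
    return num / math.comb(universe, draws)


def binomial_minlik_p(a: int, total: int, p_a: float) -> float:
    """Two-sided minimum-likelihood binomial p for an observed split."""
    pmf = [
        math.comb(total, k) * p_a**k * (1 - p_a) ** (total - k)
        for k in range(total + 1)
    ]
    obs = pmf[a]
    return min(1.0, sum(q for q in pmf if q <= obs * (1 + 1e-9)))
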