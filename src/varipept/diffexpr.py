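"""Count-based two-group differential expression.

The model is a negative binomial (NB) with variance mu + phi * mu^2.
Per-feature dispersion is estimated by the method of moments on
library-size-adjusted counts, pooled within groups, and shrunk toward the
trimmed mean of all raw estimates; the two-group comparison is a conditional
exact test on the case/control split of the feature's total count, with
per-sample depth entering through the normalization scale factors.  At
phi = 0 the conditional distribution reduces to a binomial, so the test
degrades gracefully to the classical Poisson-count exact test.

Two-sided p-values use minimum-likelihood ordering: sum the probabilities of
every split at most as probable as the observed one.  This is well defined
for asymmetric discrete nulls and symmetric under label exchange.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from varipept.quant import CountMatrix, GroupDesign, upper_quartile_normalize

DIRECTION_UP = "up"
DIRECTION_DOWN = "down"
DIRECTION_NONE = "none"


@dataclass(frozen=True)
class DEResult:
    feature_id: str
    log2fc: float
    p_value: float
    fdr: float
    direction: str


def estimate_dispersion(
    matrix: CountMatrix,
    design: GroupDesign,
    shrink_weight: float = 0.5,
    trim: float = 0.1,
) -> pd.Series:
    """Moment-based per-feature NB dispersion with global shrinkage.

    For each feature the raw estimate is ``max(0, (s2 - mu) / mu^2)`` where
    ``mu`` is the pooled within-group mean and ``s2`` the pooled
    within-group variance of depth-adjusted counts.  Each raw estimate is
    then averaged with the trimmed mean of all raw estimates using
    ``shrink_weight`` on the global component, which stabilises the noisy
    per-feature moments at these group sizes.
    """
    if len(design.cases) < 2 or len(design.controls) < 2:
        raise ValueError("dispersion estimation needs >= 2 samples per group")
    if not 0 <= shrink_weight <= 1:
        raise ValueError("shrink_weight must be in [0, 1]")
    if matrix.scale_factors is None:
        matrix = upper_quartile_normalize(matrix)
    x = matrix.normalized
    n_a, n_b = len(design.cases), len(design.controls)
    xa, xb = x[list(design.cases)], x[list(design.controls)]
    m_a, m_b = xa.mean(axis=1), xb.mean(axis=1)
    v_a, v_b = xa.var(axis=1, ddof=1), xb.var(axis=1, ddof=1)
    mu = (n_a * m_a + n_b * m_b) / (n_a + n_b)
    s2 = ((n_a - 1) * v_a + (n_b - 1) * v_b) / (n_a + n_b - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(mu > 0, np.maximum(0.0, s2 - mu) / np.square(mu), 0.0)
    raw = pd.Series(raw, index=x.index)
    global_phi = float(stats.trim_mean(raw, trim)) if len(raw) else 0.0
    return (1 - shrink_weight) * raw + shrink_weight * global_phi


def _conditional_split_pmf(
    total: int,
    lib_a: float,
    lib_b: float,
    n_a: int,
    n_b: int,
    dispersion: float,
) -> np.ndarray:
    """PMF over case-sum splits k = 0..total of the group totals given the total."""
    k = np.arange(total + 1)
    if dispersion < 1e-12:
        return stats.binom.pmf(k, total, lib_a / (lib_a + lib_b))
    lam = total / (lib_a + lib_b)
    mu_a, mu_b = lam * lib_a, lam * lib_b
    r_a, r_b = n_a / dispersion, n_b / dispersion
    logpmf = stats.nbinom.logpmf(k, r_a, r_a / (r_a + mu_a)) + stats.nbinom.logpmf(
        total - k, r_b, r_b / (r_b + mu_b)
    )
    logpmf -= logpmf.max()
    pmf = np.exp(logpmf)
    return pmf / pmf.sum()


def exact_test(
    counts: pd.Series,
    design: GroupDesign,
    dispersion: float,
    scale_factors: pd.Series,
) -> float:
    """Two-sided NB conditional exact test for one feature.

    ``counts`` are the feature's raw counts indexed by sample.  The group
    sums are compared against their conditional distribution given the
    feature total, with effective library sizes taken from the scale
    factors.  A zero total returns p = 1 by convention.
    """
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    a = int(counts[list(design.cases)].sum())
    b = int(counts[list(design.controls)].sum())
    total = a + b
    if total == 0:
        return 1.0
    lib_a = float(scale_factors[list(design.cases)].sum())
    lib_b = float(scale_factors[list(design.controls)].sum())
    pmf = _conditional_split_pmf(
        total, lib_a, lib_b, len(design.cases), len(design.controls), dispersion
    )
    p_obs = pmf[a]
    p = float(pmf[pmf <= p_obs * (1 + 1e-9)].sum())
    return min(1.0, p)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (FDR)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def de_table(
    matrix: CountMatrix,
    design: GroupDesign,
    alpha: float = 0.05,
    shrink_weight: float = 0.5,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Full differential-expression table for a count matrix.

    Returns one row per feature with ``log2fc`` (case over control on
    normalized group means with a pseudo-count), ``p_value`` from the NB
    conditional exact test, BH ``fdr`` and the fold-change ``direction``.
    """
    if matrix.scale_factors is None:
        matrix = upper_quartile_normalize(matrix)
    phi = estimate_dispersion(matrix, design, shrink_weight=shrink_weight)
    norm = matrix.normalized
    mean_case = norm[list(design.cases)].mean(axis=1)
    mean_control = norm[list(design.controls)].mean(axis=1)
    log2fc = np.log2((mean_case + pseudocount) / (mean_control + pseudocount))
    pvals = np.array(
        [
            exact_test(matrix.counts.loc[f], design, float(phi[f]), matrix.scale_factors)
            for f in matrix.feature_ids
        ]
    )
    fdr = bh_adjust(pvals) if len(pvals) else pvals
    direction = np.where(log2fc > 0, DIRECTION_UP, np.where(log2fc < 0, DIRECTION_DOWN, DIRECTION_NONE))
    return pd.DataFrame(
        {
            "feature": matrix.feature_ids,
            "log2fc": log2fc.to_numpy(),
            "p_value": pvals,
            "fdr": fdr,
            "direction": direction,
        }
    )


def concordance(
    protein_de: pd.DataFrame,
    transcript_de: pd.DataFrame,
    fdr_threshold: float = 0.05,
    p_threshold: float = 0.05,
) -> set[str]:
    """Proteins whose transcript changes in the same direction.

    A feature qualifies when its protein FDR is below ``fdr_threshold``, its
    transcript (unadjusted) p-value is below ``p_threshold``, and the two
    log2 fold-changes share a sign.
    """
    t = transcript_de.set_index("feature")
    out = set()
    for _, row in protein_de.iterrows():
        f = row["feature"]
        if row["fdr"] >= fdr_threshold or f not in t.index:
            continue
        trow = t.loc[f]
        if trow["p_value"] < p_threshold and np.sign(trow["log2fc"]) == np.sign(row["log2fc"]) != 0:
            out.add(f)
    return out
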