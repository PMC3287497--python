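"""Rank-based statistical battery.

All genome-wide comparisons in this package reduce to a handful of
nonparametric procedures: Spearman's rank correlation (with a Fisher-z
confidence interval), a first-order partial Spearman correlation used to
remove the contribution of a covariate (typically gene expression level),
the Mann-Whitney U test for group comparisons, Fisher's exact test on 2x2
site-count tables, and Pearson's chi-square. Missing values are removed
complete-case per test and the effective n is always reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as _ss

__all__ = [
    "CorrelationResult",
    "spearman",
    "partial_spearman",
    "mann_whitney",
    "fisher_exact_2x2",
    "chi_square_2x2",
    "per_tissue_correlation",
]


@dataclass
class CorrelationResult:
    """A (partial) rank correlation with its provenance.

    ``ci_low``/``ci_high`` bracket ``rho`` (95%, Fisher z-transform with the
    Fieller-adjusted standard error 1.03/sqrt(n-3) appropriate for Spearman's
    rho). ``conditioned_on`` names the covariate for partial correlations.
    """

    rho: float
    n: int
    p_value: float
    ci_low: float
    ci_high: float
    conditioned_on: str | None = None
    label: str | None = None


def _complete_cases(*cols):
    arrs = [np.asarray(c, dtype=float) for c in cols]
    n = {a.shape[0] for a in arrs}
    if len(n) != 1:
        raise ValueError("input vectors differ in length")
    mask = np.ones(arrs[0].shape[0], dtype=bool)
    for a in arrs:
        mask &= np.isfinite(a)
    return [a[mask] for a in arrs]


def _fisher_z_ci(rho: float, n: int, denom_offset: int = 3) -> tuple[float, float]:
    if n - denom_offset <= 0 or abs(rho) >= 1.0:
        return (rho, rho)
    z = np.arctanh(rho)
    se = 1.03 / np.sqrt(n - denom_offset)
    return (float(np.tanh(z - 1.959963984540054 * se)),
            float(np.tanh(z + 1.959963984540054 * se)))


def spearman(x, y, label: str | None = None) -> CorrelationResult:
    """Spearman rank correlation on midranks with a t-approximation p-value.

    Raises ``ValueError`` for constant input ("zero variance") or fewer than
    three complete pairs.
    """
    x, y = _complete_cases(x, y)
    n = x.shape[0]
    if n < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance input")
    rho, p = _ss.spearmanr(x, y)
    lo, hi = _fisher_z_ci(float(rho), n, 3)
    return CorrelationResult(float(rho), n, float(p), lo, hi, None, label)


def _spearman_rho(x, y) -> float:
    rho, _ = _ss.spearmanr(x, y)
    return float(rho)


def partial_spearman(x, y, z, conditioned_on: str = "z",
                     label: str | None = None) -> CorrelationResult:
    """First-order partial Spearman correlation rho_xy.z.

    rho_xy.z = (rho_xy - rho_xz * rho_yz) / sqrt((1-rho_xz^2)(1-rho_yz^2)),
    computed on the three pairwise Spearman correlations; the p-value uses
    t = rho * sqrt((n-3)/(1-rho^2)) on n-3 degrees of freedom.
    """
    x, y, z = _complete_cases(x, y, z)
    n = x.shape[0]
    if n < 4:
        raise ValueError("need at least 4 complete triples")
    for v in (x, y, z):
        if np.ptp(v) == 0:
            raise ValueError("zero variance input")
    r_xy = _spearman_rho(x, y)
    r_xz = _spearman_rho(x, z)
    r_yz = _spearman_rho(y, z)
    if min(1 - r_xz ** 2, 1 - r_yz ** 2) <= 1e-12:
        raise ValueError("degenerate conditioning")
    rho = (r_xy - r_xz * r_yz) / np.sqrt((1 - r_xz ** 2) * (1 - r_yz ** 2))
    rho = float(np.clip(rho, -1.0, 1.0))
    df = n - 3
    if abs(rho) >= 1.0:
        p = 0.0
    else:
        t = rho * np.sqrt(df / (1 - rho ** 2))
        p = float(2 * _ss.t.sf(abs(t), df))
    lo, hi = _fisher_z_ci(rho, n, 4)
    return CorrelationResult(rho, n, p, lo, hi, conditioned_on, label)


def mann_whitney(a, b, alternative: str = "two-sided") -> tuple[float, float]:
    """Mann-Whitney U with midrank ties.

    Exact null distribution when min(n_a, n_b) <= 8 and there are no ties;
    normal approximation with tie correction otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (min(a.size, b.size) <= 8 and no_ties) else "asymptotic"
    res = _ss.mannwhitneyu(a, b, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)


def fisher_exact_2x2(table, alternative: str = "two-sided"
                     ) -> tuple[float, float, bool]:
    """Hypergeometric exact test on a 2x2 table of non-negative counts.

    Returns ``(sample_odds_ratio, p, degenerate_margin)``: with a zero row or
    column margin the test is undefined and p = 1.0 is returned flagged.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a non-negative 2x2 table")
    a, b_, c, d = t.ravel()
    if b_ * c == 0:
        odds = np.inf if a * d > 0 else np.nan
    else:
        odds = a * d / (b_ * c)
    if 0 in t.sum(axis=0) or 0 in t.sum(axis=1):
        return float(odds), 1.0, True
    _, p = _ss.fisher_exact(t, alternative=alternative)
    return float(odds), float(p), False


def chi_square_2x2(table, correction: bool = False) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table, 1 df, no continuity correction by
    default. Raises on a zero expected count."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a non-negative 2x2 table")
    row = t.sum(axis=1, keepdims=True)
    col = t.sum(axis=0, keepdims=True)
    expected = row @ col / t.sum()
    if (expected <= 0).any():
        raise ValueError("zero expected cell")
    stat, p, _, _ = _ss.chi2_contingency(t, correction=correction)
    return float(stat), float(p)


def per_tissue_correlation(feature, matrix, tissue_classes=None):
    """Spearman of a per-gene feature against each tissue's expression column.

    ``feature`` is a pandas Series indexed by gene_id; ``matrix`` a genes x
    samples DataFrame. Returns a DataFrame (sample, tissue_class, rho, n, p,
    ci_low, ci_high) sorted ascending by rho, mirroring a bar-per-tissue
    correlation profile.
    """
    import pandas as pd

    rows = []
    common = matrix.index.intersection(feature.index)
    f = feature.loc[common]
    for sample in matrix.columns:
        res = spearman(f.to_numpy(), matrix.loc[common, sample].to_numpy(),
                       label=sample)
        cls = "unknown" if tissue_classes is None else tissue_classes.get(
            sample, "unknown")
        rows.append({
            "sample": sample,
            "tissue_class": cls,
            "rho": res.rho, "n": res.n, "p_value": res.p_value,
            "ci_low": res.ci_low, "ci_high": res.ci_high,
        })
    out = pd.DataFrame(rows).sort_values("rho", kind="mergesort")
    return out.reset_index(drop=True)
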