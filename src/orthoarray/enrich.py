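"""Signed fold changes and hypergeometric gene-set enrichment with FDR.

Fold changes use the signed convention common in microarray reporting:
with r = 2^(mean log2 treated − mean log2 control), the reported value
is r when r ≥ 1 and −1/r otherwise, so values never fall in (−1, 1) and
no-change is exactly 1.  Enrichment of a differential gene list against
GMT gene sets uses the upper hypergeometric tail P(X ≥ k) computed in
log space, with Benjamini–Hochberg control of the false discovery rate
(significance at adjusted p < 0.05).
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

__all__ = [
    "fold_change",
    "select_differential",
    "hypergeom_upper",
    "bh_adjust",
    "enrich",
]


def fold_change(
    expr: pd.DataFrame,
    treated: Sequence[str],
    control: Sequence[str],
) -> pd.Series:
    """Signed fold change per row of a log2 expression matrix.

    ``treated`` and ``control`` name the sample columns of the two
    groups; both must be non-empty.
    """
    treated, control = list(treated), list(control)
    if not treated or not control:
        raise ValueError("both groups need at least one sample")
    for col in treated + control:
        if col not in expr.columns:
            raise KeyError(f"sample {col!r} not in expression matrix")
    diff = expr[treated].mean(axis=1) - expr[control].mean(axis=1)
    r = np.power(2.0, diff)
    fc = np.where(r >= 1.0, r, -1.0 / r)
    return pd.Series(fc, index=expr.index, name="fold_change")


def select_differential(fc: pd.Series, threshold: float) -> list[str]:
    """Genes with |FC| ≥ threshold, in deterministic (index) order."""
    if threshold < 1.0:
        raise ValueError("fold-change threshold must be >= 1")
    return [g for g, v in fc.items() if abs(v) >= threshold]


def hypergeom_upper(N: int, K: int, n: int, k: int) -> float:
    """P(X ≥ k) for X ~ Hypergeometric(N, K, n), log-space summation.

    N: background size, K: set members in background, n: foreground
    size, k: observed overlap.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"invalid hypergeometric parameters N={N}, K={K}, n={n}")
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"overlap k={k} outside [0, min(K={K}, n={n})]")
    if k == 0:
        return 1.0
    hi = min(K, n)
    lo = max(0, n - (N - K))
    support = np.arange(max(k, lo), hi + 1)
    log_pmf = (
        gammaln(K + 1) - gammaln(support + 1) - gammaln(K - support + 1)
        + gammaln(N - K + 1) - gammaln(n - support + 1) - gammaln(N - K - n + support + 1)
        - (gammaln(N + 1) - gammaln(n + 1) - gammaln(N - n + 1))
    )
    return float(min(1.0, np.exp(logsumexp(log_pmf))))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich(
    gene_sets: Mapping[str, Iterable[str]],
    foreground: Iterable[str],
    background: Iterable[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric enrichment of every gene set, FDR across all sets.

    Sets are intersected with the background before counting; the
    foreground must be a subset of the background.  Result rows are
    sorted by raw p-value then set name.
    """
    bg = set(background)
    fg = set(foreground)
    stray = sorted(fg - bg)
    if stray:
        raise ValueError(f"foreground genes absent from background: {stray[:5]}")
    names = list(gene_sets)
    rows = []
    for name in names:
        members = set(gene_sets[name]) & bg
        K = len(members)
        k = len(members & fg)
        p = hypergeom_upper(len(bg), K, len(fg), k)
        rows.append((name, len(bg), K, len(fg), k, p))
    table = pd.DataFrame(rows, columns=["set", "N", "K", "n", "k", "p_value"])
    table["fdr_adjusted_p"] = bh_adjust(table["p_value"]) if len(table) else []
    table["significant"] = table["fdr_adjusted_p"] < alpha
    table = table.sort_values(["p_value", "set"], kind="stable").reset_index(drop=True)
    return table
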