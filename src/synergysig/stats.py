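"""Shared statistical primitives.

The tests named in the source figures are implemented from their textbook
formulas — Benjamini–Hochberg step-up adjustment, the tie-corrected
Kruskal–Wallis H, Dunn's joint-rank post test, iterative two-sided Grubbs
outlier removal, and classical one-way ANOVA.  scipy supplies distribution
functions and the correlation coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "bh_adjust",
    "kruskal_wallis",
    "dunn_posttest",
    "grubbs_iterative",
    "anova_oneway",
    "correlation",
    "KruskalResult",
    "AnovaResult",
    "GrubbsResult",
]


@dataclass(frozen=True)
class KruskalResult:
    statistic: float
    df: int
    pvalue: float


@dataclass(frozen=True)
class AnovaResult:
    statistic: float
    df_between: int
    df_within: int
    pvalue: float
    degenerate: bool = False


@dataclass(frozen=True)
class GrubbsResult:
    kept: np.ndarray
    removed: np.ndarray
    n_iterations: int = 0


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up FDR adjustment.

    Sorts p ascending, takes q_(i) = min_{j>=i} p_(j)·m/j capped at 1, and
    restores the original order.  Accepts any 1-d sequence; returns ndarray.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("pvalues must be a non-empty 1-d sequence")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.clip(q, 0.0, 1.0)
    out = np.empty(m)
    out[order] = q
    return out


def _as_groups(groups) -> dict[str, np.ndarray]:
    if isinstance(groups, Mapping):
        items = groups.items()
    else:
        items = ((f"group{i}", g) for i, g in enumerate(groups))
    out = {}
    for name, values in items:
        arr = np.asarray(values, dtype=float).ravel()
        if name in out:
            raise ValueError(f"duplicate group name {name!r}")
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"group {name!r} contains non-finite values")
        out[str(name)] = arr
    return out


def _tie_term(pooled: np.ndarray) -> float:
    """Sum of t^3 - t over tied groups."""
    _, counts = np.unique(pooled, return_counts=True)
    return float(np.sum(counts.astype(float) ** 3 - counts))


def kruskal_wallis(groups) -> KruskalResult:
    """Tie-corrected Kruskal–Wallis H test across named groups.

    H = [12/(N(N+1))] Σ n_i (R̄_i − (N+1)/2)², divided by the tie
    correction 1 − Σ(t³−t)/(N³−N); p from chi-square with k−1 df.
    """
    g = _as_groups(groups)
    if len(g) < 2:
        raise ValueError("need at least 2 groups")
    sizes = [len(v) for v in g.values()]
    if any(s == 0 for s in sizes):
        raise ValueError("empty group")
    pooled = np.concatenate(list(g.values()))
    n_total = pooled.size
    if n_total < 2:
        raise ValueError("need at least 2 observations in total")
    ranks = sps.rankdata(pooled)
    h = 0.0
    start = 0
    for n_i in sizes:
        r_bar = ranks[start : start + n_i].mean()
        h += n_i * (r_bar - (n_total + 1) / 2.0) ** 2
        start += n_i
    h *= 12.0 / (n_total * (n_total + 1))
    correction = 1.0 - _tie_term(pooled) / (n_total**3 - n_total)
    if correction <= 0:  # every observation identical
        return KruskalResult(0.0, len(g) - 1, 1.0)
    h /= correction
    df = len(g) - 1
    return KruskalResult(float(h), df, float(sps.chi2.sf(h, df)))


def dunn_posttest(
    groups,
    comparisons: Sequence[tuple[str, str]] | None = None,
    adjustment: str = "bonferroni",
) -> pd.DataFrame:
    """Dunn's post test on joint ranks for selected pairs.

    z_ij = (R̄_i − R̄_j) / sqrt([N(N+1)/12 − Σ(t³−t)/(12(N−1))]·(1/n_i + 1/n_j))
    with two-sided normal p, multiplicity-adjusted over the pairs actually
    compared (Bonferroni default, Holm available).
    """
    g = _as_groups(groups)
    names = list(g)
    if comparisons is None:
        comparisons = [(a, b) for i, a in enumerate(names) for b in names[i + 1 :]]
    for a, b in comparisons:
        if a not in g or b not in g:
            raise KeyError(f"unknown group in comparison ({a!r}, {b!r})")
        if len(g[a]) == 0 or len(g[b]) == 0:
            raise ValueError("empty group")
    pooled = np.concatenate(list(g.values()))
    n_total = pooled.size
    ranks = sps.rankdata(pooled)
    mean_rank = {}
    start = 0
    for name in names:
        n_i = len(g[name])
        mean_rank[name] = ranks[start : start + n_i].mean()
        start += n_i
    tie = _tie_term(pooled)
    var_base = n_total * (n_total + 1) / 12.0 - tie / (12.0 * (n_total - 1))
    rows = []
    for a, b in comparisons:
        se = np.sqrt(var_base * (1.0 / len(g[a]) + 1.0 / len(g[b])))
        z = 0.0 if se == 0 else (mean_rank[a] - mean_rank[b]) / se
        p = 2.0 * sps.norm.sf(abs(z))
        rows.append((a, b, z, min(p, 1.0)))
    table = pd.DataFrame(rows, columns=["group1", "group2", "z", "p"])
    k = len(table)
    if adjustment == "bonferroni":
        table["p_adj"] = np.minimum(table["p"] * k, 1.0)
    elif adjustment == "holm":
        order = np.argsort(table["p"].to_numpy(), kind="mergesort")
        adj = np.empty(k)
        running = 0.0
        for rank_idx, idx in enumerate(order):
            running = max(running, table["p"].iloc[idx] * (k - rank_idx))
            adj[idx] = min(running, 1.0)
        table["p_adj"] = adj
    else:
        raise ValueError(f"unknown adjustment {adjustment!r}")
    return table


def grubbs_iterative(
    values, alpha: float = 0.1, max_removals: int = 2
) -> GrubbsResult:
    """Iterative two-sided Grubbs outlier removal.

    Each pass computes G = max|x − x̄|/s and removes the most extreme value
    iff G exceeds the two-sided critical value
    G_crit = ((n−1)/√n)·sqrt(t²/(n−2+t²)), t the upper α/(2n) t-quantile
    with n−2 df.  Stops when nothing is removed, n < 3, or ``max_removals``
    is reached.
    """
    x = list(np.asarray(values, dtype=float).ravel())
    if len(x) < 3:
        raise ValueError("Grubbs test needs at least 3 observations")
    removed: list[float] = []
    iterations = 0
    while len(x) >= 3 and len(removed) < max_removals:
        arr = np.array(x)
        mean = arr.mean()
        sd = arr.std(ddof=1)
        if sd == 0:
            break
        dev = np.abs(arr - mean)
        idx = int(np.argmax(dev))
        g = dev[idx] / sd
        n = arr.size
        t_crit = sps.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
        g_crit = ((n - 1) / np.sqrt(n)) * np.sqrt(
            t_crit**2 / (n - 2 + t_crit**2)
        )
        if g > g_crit:
            removed.append(x.pop(idx))
            iterations += 1
        else:
            break
    return GrubbsResult(np.array(x), np.array(removed), iterations)


def anova_oneway(groups) -> AnovaResult:
    """Classical one-way ANOVA (between/within mean-square ratio)."""
    g = _as_groups(groups)
    if len(g) < 2:
        raise ValueError("need at least 2 groups")
    sizes = np.array([len(v) for v in g.values()])
    if np.any(sizes == 0):
        raise ValueError("empty group")
    n_total = int(sizes.sum())
    k = len(g)
    df_within = n_total - k
    if df_within < 1:
        raise ValueError("no residual degrees of freedom")
    grand = np.concatenate(list(g.values())).mean()
    ss_between = sum(len(v) * (v.mean() - grand) ** 2 for v in g.values())
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in g.values())
    if ss_within == 0:
        if ss_between == 0:
            return AnovaResult(0.0, k - 1, df_within, 1.0, degenerate=True)
        return AnovaResult(np.inf, k - 1, df_within, 0.0, degenerate=True)
    f = (ss_between / (k - 1)) / (ss_within / df_within)
    p = float(sps.f.sf(f, k - 1, df_within))
    return AnovaResult(float(f), k - 1, df_within, p)


def correlation(x, y, method: str = "pearson") -> float:
    """Pearson or Spearman correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d and of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance input")
    if method == "pearson":
        return float(sps.pearsonr(x, y).statistic)
    if method == "spearman":
        return float(sps.spearmanr(x, y).statistic)
    raise ValueError(f"unknown method {method!r}")
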