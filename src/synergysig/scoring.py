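"""Rank-based single-sample scoring, tertile survival stratification, and
preranked gene-set enrichment.

The single-sample score is the centered normalized mean rank of the set
genes within one sample: with N genes ranked ascending by expression
(average ranks on ties) and n_G set genes with mean rank R̄,

    score = (R̄ − R̄_min)/(R̄_max − R̄_min) − 1/2,
    R̄_min = (n_G + 1)/2,   R̄_max = N − (n_G − 1)/2,

so the score lies in [−1/2, 1/2] and a high score means high expression
of the set.  Cohorts are split into tertiles of the score and the extreme
tertiles compared by Kaplan–Meier / log-rank (via lifelines).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

from .stats import correlation

__all__ = [
    "singscore",
    "assign_tertiles",
    "km_estimate",
    "logrank_test",
    "preranked_gsea",
    "stratify_and_compare",
    "GSEAResult",
    "LogrankResult",
    "CohortStratificationResult",
]


def singscore(
    expr: pd.DataFrame, gene_set, orientation: str = "expression"
) -> pd.DataFrame:
    """Centered normalized mean-rank score per sample.

    ``expr`` is genes × samples.  ``orientation="expression"`` (default)
    gives high scores to samples expressing the set highly; ``"inverse"``
    negates.  Returns a DataFrame indexed by sample with columns
    ``score`` and ``n_set_genes_used``.
    """
    genes_present = [g for g in gene_set if g in expr.index]
    n_g = len(genes_present)
    n_total = expr.shape[0]
    if n_g == 0:
        raise ValueError("no gene-set members present in the expression matrix")
    if n_g == n_total:
        raise ValueError("gene set covers the whole matrix; score undefined")
    if orientation not in ("expression", "inverse"):
        raise ValueError(f"unknown orientation {orientation!r}")
    ranks = expr.rank(axis=0, method="average")
    mean_rank = ranks.loc[genes_present].mean(axis=0)
    r_min = (n_g + 1) / 2.0
    r_max = n_total - (n_g - 1) / 2.0
    score = (mean_rank - r_min) / (r_max - r_min) - 0.5
    if orientation == "inverse":
        score = -score
    out = pd.DataFrame({"score": score, "n_set_genes_used": n_g})
    out.index.name = "sample"
    return out


def assign_tertiles(scores) -> pd.Series:
    """Split samples into bottom/middle/top tertiles of the score.

    Bottom gets the first ceil(n/3) samples in ascending score order, top
    the last floor(n/3); ties broken by stable (score, sample id) sort.
    For n = 62 this gives the 21/20 bottom/top split.
    """
    if isinstance(scores, pd.DataFrame):
        scores = scores["score"]
    s = pd.Series(scores)
    n = len(s)
    if n < 3:
        raise ValueError("need at least 3 samples for tertiles")
    order = s.reset_index()
    order.columns = ["sample", "score"]
    order = order.sort_values(["score", "sample"], kind="mergesort")
    n_bottom = int(np.ceil(n / 3))
    n_top = n // 3
    labels = np.array(["middle"] * n, dtype=object)
    labels[:n_bottom] = "bottom"
    labels[n - n_top :] = "top"
    return pd.Series(labels, index=order["sample"].to_numpy(), name="tertile").loc[
        s.index
    ]


def km_estimate(time, event) -> pd.DataFrame:
    """Product-limit survival estimate.

    Returns one row per distinct event time with the number at risk just
    before it and S(t) just after; censored times shrink the risk set
    without a step.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if time.size == 0:
        raise ValueError("no records")
    if np.any(time < 0) or np.any(~np.isfinite(time)):
        raise ValueError("times must be finite and non-negative")
    kmf = KaplanMeierFitter()
    kmf.fit(time, event)
    event_times = np.unique(time[event == 1])
    surv = kmf.survival_function_at_times(event_times).to_numpy()
    at_risk = np.array([(time >= t).sum() for t in event_times])
    n_events = np.array([((time == t) & (event == 1)).sum() for t in event_times])
    return pd.DataFrame(
        {"time": event_times, "n_at_risk": at_risk, "n_events": n_events, "survival": surv}
    )


@dataclass(frozen=True)
class LogrankResult:
    chi2: float
    df: int
    pvalue: float


def logrank_test(time_a, event_a, time_b, event_b) -> LogrankResult:
    """Two-group log-rank (Mantel–Cox) test, chi-square with 1 df."""
    time_a = np.asarray(time_a, dtype=float)
    time_b = np.asarray(time_b, dtype=float)
    event_a = np.asarray(event_a, dtype=int)
    event_b = np.asarray(event_b, dtype=int)
    if time_a.size == 0 or time_b.size == 0:
        raise ValueError("both groups must be non-empty")
    if event_a.sum() + event_b.sum() == 0:
        warnings.warn("no events in either group; log-rank p set to 1")
        return LogrankResult(0.0, 1, 1.0)
    res = _ll_logrank(time_a, time_b, event_observed_A=event_a, event_observed_B=event_b)
    return LogrankResult(float(res.test_statistic), 1, float(res.p_value))


@dataclass(frozen=True)
class GSEAResult:
    es: float
    nes: float
    pvalue: float
    n_perm: int
    seed: int
    n_set_genes_used: int


def _running_es(hit_mask: np.ndarray, weights: np.ndarray) -> float:
    """Extremum of the weighted Kolmogorov–Smirnov running sum."""
    n = hit_mask.size
    n_hit = int(hit_mask.sum())
    n_miss = n - n_hit
    hit_w = np.abs(weights) * hit_mask
    total = hit_w.sum()
    if total == 0:  # all-zero metric inside the set: fall back to unweighted
        hit_w = hit_mask.astype(float)
        total = hit_w.sum()
    steps = hit_w / total - (~hit_mask.astype(bool)).astype(float) / n_miss
    running = np.cumsum(steps)
    return float(running[np.argmax(np.abs(running))])


def preranked_gsea(
    metric: pd.Series,
    gene_set,
    weight: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
) -> GSEAResult:
    """Preranked GSEA with gene-set permutation.

    ``metric`` maps gene → signed ranking statistic (e.g. the moderated
    t).  Genes are ordered descending by the metric; hits advance the
    running sum ∝ |metric|^weight, misses retreat uniformly; ES is the
    extremum.  The null is built from ``n_perm`` size-matched random gene
    sets; NES = ES / mean(|ES*|) over same-signed permutations and the
    permutation p-value is one-sided.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    metric = metric.sort_values(ascending=False, kind="mergesort")
    genes = metric.index.to_numpy()
    values = np.abs(metric.to_numpy(dtype=float)) ** weight
    in_set = np.isin(genes, list(gene_set))
    n_hit = int(in_set.sum())
    if n_hit == 0:
        raise ValueError("gene set does not intersect the ranked list")
    if n_hit == len(genes):
        raise ValueError("gene set covers the entire ranked list")
    es = _running_es(in_set, values)
    rng = np.random.default_rng(seed)
    es_null = np.empty(n_perm)
    idx = np.arange(len(genes))
    for b in range(n_perm):
        perm_mask = np.zeros(len(genes), dtype=bool)
        perm_mask[rng.choice(idx, size=n_hit, replace=False)] = True
        es_null[b] = _running_es(perm_mask, values)
    same_sign = es_null * np.sign(es) > 0
    if same_sign.any():
        denom = np.abs(es_null[same_sign]).mean()
        nes = es / denom if denom > 0 else np.sign(es) * np.inf
        p = (1 + (np.abs(es_null[same_sign]) >= abs(es)).sum()) / (1 + same_sign.sum())
    else:
        nes = np.sign(es) * np.inf
        p = 1.0 / (1 + n_perm)
    return GSEAResult(es, float(nes), float(p), n_perm, seed, n_hit)


@dataclass(frozen=True)
class CohortStratificationResult:
    """Report of score → tertile → survival analysis of one cohort."""

    scores: pd.DataFrame
    tertiles: pd.Series
    km_bottom: pd.DataFrame
    km_top: pd.DataFrame
    logrank: LogrankResult
    score_correlation: dict | None = None

    def summary(self) -> str:
        counts = self.tertiles.value_counts()
        lines = [
            f"Cohort stratification: n = {len(self.tertiles)} patients",
            "  tertile sizes: bottom = {b}, middle = {m}, top = {t}".format(
                b=counts.get("bottom", 0), m=counts.get("middle", 0), t=counts.get("top", 0)
            ),
            f"  log-rank (bottom vs top): chi2 = {self.logrank.chi2:.3f},"
            f" p = {self.logrank.pvalue:.4g}",
        ]
        if self.score_correlation is not None:
            lines.append(
                "  score correlation (set1 vs set2): R = {pearson:.3f}"
                " (Pearson), rho = {spearman:.3f} (Spearman)".format(**self.score_correlation)
            )
        return "\n".join(lines)


def stratify_and_compare(
    expr: pd.DataFrame,
    gene_set,
    survival: pd.DataFrame,
    second_gene_set=None,
) -> CohortStratificationResult:
    """Score a cohort, split into tertiles, and compare extreme tertiles'
    survival by Kaplan–Meier and the log-rank test.

    ``survival`` needs columns sample, time, event.  With
    ``second_gene_set`` the Pearson/Spearman correlation between the two
    sets' scores is reported as well.
    """
    surv = survival.set_index("sample")
    shared = [s for s in expr.columns if s in surv.index]
    if len(shared) < 3:
        raise ValueError("fewer than 3 patients shared between expression and survival")
    expr = expr[shared]
    surv = surv.loc[shared]
    scores = singscore(expr, gene_set)
    tertiles = assign_tertiles(scores)
    groups = {}
    for label in ("bottom", "top"):
        ids = tertiles.index[tertiles == label]
        groups[label] = surv.loc[ids]
    km_bottom = km_estimate(groups["bottom"]["time"], groups["bottom"]["event"])
    km_top = km_estimate(groups["top"]["time"], groups["top"]["event"])
    lr = logrank_test(
        groups["bottom"]["time"],
        groups["bottom"]["event"],
        groups["top"]["time"],
        groups["top"]["event"],
    )
    corr = None
    if second_gene_set is not None:
        scores2 = singscore(expr, second_gene_set)
        corr = {
            "pearson": correlation(scores["score"], scores2["score"], "pearson"),
            "spearman": correlation(scores["score"], scores2["score"], "spearman"),
        }
    return CohortStratificationResult(scores, tertiles, km_bottom, km_top, lr, corr)
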