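"""Combination-specific gene-signature extraction and synergy quantification.

The signature is derived from four differential-expression contrasts by
three overlap analyses: genes responding to the combination over each
monotherapy, minus genes already responding to the other monotherapy
alone, intersected::

    list1 = DEG(AB vs A) \\ DEG(B vs ctrl)
    list2 = DEG(AB vs B) \\ DEG(A vs ctrl)
    signature = list1 ∩ list2

Synergy is judged against the additive expectation: per gene the sum of
the two monotherapy log2 fold-changes versus control.  A gene is flagged
synergistic when the combination effect exceeds the additive expectation
in magnitude with concordant sign (for a downregulated gene,
lfc_AB < lfc_A + lfc_B).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stats import dunn_posttest, kruskal_wallis

__all__ = [
    "DEGSet",
    "CombinationSignature",
    "deg_set",
    "extract_combination_signature",
    "split_by_direction",
    "threshold_signature",
    "build_synergy_table",
    "synergy_test",
    "run_signature_pipeline",
    "SynergyReport",
]


@dataclass(frozen=True)
class DEGSet:
    """Genes significant in one contrast at BH-adjusted p < alpha."""

    contrast: str
    genes: frozenset
    alpha: float
    universe: frozenset = frozenset()

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.universe and not self.genes <= self.universe:
            raise ValueError("DEG set contains genes outside its universe")


def deg_set(
    de_table: pd.DataFrame, alpha: float = 0.05, contrast: str | None = None
) -> DEGSet:
    """Select DEGs (adjusted p < alpha) from a DE table indexed by gene."""
    if contrast is None:
        contrast = de_table.attrs.get("contrast", "unnamed")
    sig = de_table.index[de_table["adj_p"] < alpha]
    return DEGSet(contrast, frozenset(sig), alpha, frozenset(de_table.index))


@dataclass(frozen=True)
class CombinationSignature:
    """The three-overlap result: list1, list2 and their intersection."""

    list1: frozenset
    list2: frozenset
    signature: frozenset
    direction: dict = field(default_factory=dict)  # gene -> 'up' | 'down' | 'zero'
    counts: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (self.signature <= self.list1 and self.signature <= self.list2):
            raise ValueError("signature must be a subset of both lists")

    @property
    def up(self) -> frozenset:
        return frozenset(g for g, d in self.direction.items() if d == "up")

    @property
    def down(self) -> frozenset:
        return frozenset(g for g, d in self.direction.items() if d == "down")


def extract_combination_signature(
    deg_ab_vs_a: DEGSet,
    deg_b_vs_ctrl: DEGSet,
    deg_ab_vs_b: DEGSet,
    deg_a_vs_ctrl: DEGSet,
) -> CombinationSignature:
    """Three overlap analyses on four DEG sets.

    All four sets must share alpha and the post-filter gene universe;
    a universe mismatch is an error, never a silent intersection.  An
    empty signature is returned with a warning, not raised.
    """
    sets = (deg_ab_vs_a, deg_b_vs_ctrl, deg_ab_vs_b, deg_a_vs_ctrl)
    alphas = {s.alpha for s in sets}
    if len(alphas) != 1:
        raise ValueError(f"DEG sets computed at different alphas: {sorted(alphas)}")
    universes = {s.universe for s in sets if s.universe}
    if len(universes) > 1:
        raise ValueError("DEG sets computed over different gene universes")
    list1 = deg_ab_vs_a.genes - deg_b_vs_ctrl.genes
    list2 = deg_ab_vs_b.genes - deg_a_vs_ctrl.genes
    signature = list1 & list2
    if not signature:
        warnings.warn("combination signature is empty")
    counts = {
        "deg_AB_vs_A": len(deg_ab_vs_a.genes),
        "deg_B_vs_ctrl": len(deg_b_vs_ctrl.genes),
        "deg_AB_vs_B": len(deg_ab_vs_b.genes),
        "deg_A_vs_ctrl": len(deg_a_vs_ctrl.genes),
        "list1": len(list1),
        "list2": len(list2),
        "signature": len(signature),
    }
    return CombinationSignature(frozenset(list1), frozenset(list2), frozenset(signature), {}, counts)


def split_by_direction(
    sig: CombinationSignature, de_ab_vs_ctrl: pd.DataFrame
) -> CombinationSignature:
    """Attach up/down direction from the combination-vs-control logFC.

    Genes with logFC exactly 0 are labelled ``'zero'`` and belong to
    neither partition.
    """
    missing = sig.signature - set(de_ab_vs_ctrl.index)
    if missing:
        raise KeyError(f"signature genes missing from DE table: {sorted(missing)[:5]}")
    direction = {}
    for g in sig.signature:
        lfc = de_ab_vs_ctrl.loc[g, "logFC"]
        direction[g] = "down" if lfc < 0 else ("up" if lfc > 0 else "zero")
    return CombinationSignature(sig.list1, sig.list2, sig.signature, direction, dict(sig.counts))


def threshold_signature(
    de_table: pd.DataFrame,
    p_thr: float = 0.05,
    lfc_thr: float = 1.5,
    direction: str = "both",
) -> frozenset:
    """Threshold-derived gene set: adjusted p < p_thr and the directional
    logFC rule (up: logFC > lfc_thr; down: logFC < −lfc_thr; both: either)."""
    if p_thr <= 0 or lfc_thr < 0:
        raise ValueError("thresholds must be positive")
    sig_p = de_table["adj_p"] < p_thr
    lfc = de_table["logFC"]
    if direction == "up":
        rule = lfc > lfc_thr
    elif direction == "down":
        rule = lfc < -lfc_thr
    elif direction == "both":
        rule = (lfc > lfc_thr) | (lfc < -lfc_thr) if lfc_thr > 0 else lfc.notna()
    else:
        raise ValueError(f"unknown direction {direction!r}")
    return frozenset(de_table.index[sig_p & rule])


def _synergy_flag(lfc_ab: float, lfc_add: float) -> bool:
    if lfc_ab < 0:
        return lfc_ab < lfc_add
    if lfc_ab > 0:
        return lfc_ab > lfc_add
    return False


def build_synergy_table(
    de_a_vs_ctrl: pd.DataFrame,
    de_b_vs_ctrl: pd.DataFrame,
    de_ab_vs_ctrl: pd.DataFrame,
    genes,
) -> pd.DataFrame:
    """Per-gene additive-expectation table.

    Columns: lfc_A, lfc_B, lfc_AB, lfc_add = lfc_A + lfc_B,
    excess = lfc_AB − lfc_add, and a boolean synergy flag (stronger than
    additive, concordant sign).
    """
    genes = list(genes)
    for name, table in (
        ("A_vs_ctrl", de_a_vs_ctrl),
        ("B_vs_ctrl", de_b_vs_ctrl),
        ("AB_vs_ctrl", de_ab_vs_ctrl),
    ):
        missing = set(genes) - set(table.index)
        if missing:
            raise KeyError(f"{name}: missing genes {sorted(missing)[:5]}")
    out = pd.DataFrame(index=pd.Index(genes, name="gene"))
    out["lfc_A"] = de_a_vs_ctrl.loc[genes, "logFC"].to_numpy()
    out["lfc_B"] = de_b_vs_ctrl.loc[genes, "logFC"].to_numpy()
    out["lfc_AB"] = de_ab_vs_ctrl.loc[genes, "logFC"].to_numpy()
    out["lfc_add"] = out["lfc_A"] + out["lfc_B"]
    out["excess"] = out["lfc_AB"] - out["lfc_add"]
    out["synergy"] = [
        _synergy_flag(ab, add) for ab, add in zip(out["lfc_AB"], out["lfc_add"])
    ]
    return out


@dataclass(frozen=True)
class SynergyReport:
    kruskal_h: float
    kruskal_p: float
    dunn: pd.DataFrame
    fraction_synergistic: float
    n_genes: int

    def summary(self) -> str:
        ab_add = self.dunn[
            (self.dunn["group1"] == "lfc_AB") & (self.dunn["group2"] == "lfc_add")
        ]
        p_ab_add = float(ab_add["p_adj"].iloc[0]) if len(ab_add) else float("nan")
        return (
            f"Synergy report over {self.n_genes} genes\n"
            f"  Kruskal-Wallis across (A, B, AB, additive): H = {self.kruskal_h:.3f},"
            f" p = {self.kruskal_p:.3g}\n"
            f"  Dunn AB vs additive: adjusted p = {p_ab_add:.3g}\n"
            f"  fraction of genes beyond the additive expectation:"
            f" {self.fraction_synergistic:.3f}"
        )


def run_signature_pipeline(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    alpha: float = 0.05,
    min_cpm: float = 10.0,
    min_samples: int | None = None,
    moderate: bool = True,
):
    """Counts → DE → three-overlap signature with directions.

    The low-count filter keeps genes quantifiable (CPM ≥ ``min_cpm``) in
    at least three quarters of the samples — i.e. in three of the four
    treatment cells of a balanced factorial — so every contrast rests on
    well-measured expression on at least one side even for strongly
    suppressed genes.  Returns (CombinationSignature, results, contrast
    tables dict).
    """
    from .diffexpr import ModeratedLinearModel

    if min_samples is None:
        min_samples = int(np.ceil(0.75 * counts.shape[1]))
    model = ModeratedLinearModel.from_counts(
        counts, design, min_cpm=min_cpm, min_samples=min_samples
    )
    res = model.fit(moderate=moderate)
    names = ("AB_vs_A", "B_vs_ctrl", "AB_vs_B", "A_vs_ctrl", "AB_vs_ctrl")
    tables = {n: res.contrast(n) for n in names}
    sig = extract_combination_signature(
        deg_set(tables["AB_vs_A"], alpha),
        deg_set(tables["B_vs_ctrl"], alpha),
        deg_set(tables["AB_vs_B"], alpha),
        deg_set(tables["A_vs_ctrl"], alpha),
    )
    sig = split_by_direction(sig, tables["AB_vs_ctrl"])
    return sig, res, tables


def synergy_test(table: pd.DataFrame) -> SynergyReport:
    """Kruskal–Wallis across the four per-gene logFC groups plus Dunn's
    comparison of the combination against the additive expectation."""
    if len(table) < 5:
        raise ValueError("need at least 5 genes for the group test")
    groups = {
        "lfc_A": table["lfc_A"].to_numpy(),
        "lfc_B": table["lfc_B"].to_numpy(),
        "lfc_AB": table["lfc_AB"].to_numpy(),
        "lfc_add": table["lfc_add"].to_numpy(),
    }
    kw = kruskal_wallis(groups)
    dunn = dunn_posttest(groups, comparisons=[("lfc_AB", "lfc_add")])
    frac = float(table["synergy"].mean())
    return SynergyReport(kw.statistic, kw.pvalue, dunn, frac, len(table))
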