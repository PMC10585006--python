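"""Per-gene linear modelling with empirical-Bayes variance moderation.

The factorial RNA-seq design (control, A, B, A+B) is analysed gene-wise by
ordinary least squares on log2 counts-per-million, followed by shrinkage of
the residual variances toward a common prior estimated by moment matching
on log s² (digamma/trigamma inversion), and moderated-t contrast tests with
Benjamini–Hochberg adjustment.

The model/results pair mirrors the statsmodels idiom::

    model = ModeratedLinearModel.from_counts(counts, design)
    res = model.fit()
    table = res.contrast("AB_vs_A")        # gene, logFC, t, p, adj_p
    print(res.summary())
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats as sps

from .stats import bh_adjust

__all__ = [
    "filter_low_counts",
    "log_cpm",
    "validate_design",
    "build_design_matrix",
    "estimate_ebayes",
    "EBayesParams",
    "ModeratedLinearModel",
    "ModeratedLinearModelResults",
    "NAMED_CONTRASTS",
]

#: Named contrasts on the cell-means coefficients (ctrl, A, B, AB).
NAMED_CONTRASTS: dict[str, np.ndarray] = {
    "A_vs_ctrl": np.array([-1.0, 1.0, 0.0, 0.0]),
    "B_vs_ctrl": np.array([-1.0, 0.0, 1.0, 0.0]),
    "AB_vs_ctrl": np.array([-1.0, 0.0, 0.0, 1.0]),
    "AB_vs_A": np.array([0.0, -1.0, 0.0, 1.0]),
    "AB_vs_B": np.array([0.0, 0.0, -1.0, 1.0]),
    "interaction": np.array([1.0, -1.0, -1.0, 1.0]),
}


def validate_counts(counts: pd.DataFrame) -> None:
    if counts.index.duplicated().any():
        raise ValueError("duplicate gene ids in count matrix")
    if counts.columns.duplicated().any():
        raise ValueError("duplicate sample ids in count matrix")
    if counts.shape[1] < 2:
        raise ValueError("count matrix needs at least 2 samples")
    values = counts.to_numpy()
    if np.any(values < 0):
        raise ValueError("counts must be non-negative")


def validate_design(design: pd.DataFrame, sample_ids=None) -> pd.DataFrame:
    """Validate a design table (columns sample, treat_a, treat_b, ...)."""
    required = {"sample", "treat_a", "treat_b"}
    missing = required - set(design.columns)
    if missing:
        raise ValueError(f"design table missing columns: {sorted(missing)}")
    if design["sample"].duplicated().any():
        raise ValueError("duplicate sample ids in design table")
    for col in ("treat_a", "treat_b"):
        bad = ~design[col].isin([0, 1])
        if bad.any():
            row = design.index[bad][0]
            raise ValueError(
                f"design row {row!r}: {col} must be 0 or 1, "
                f"got {design.loc[row, col]!r}"
            )
    if sample_ids is not None:
        if set(design["sample"]) != set(sample_ids):
            raise ValueError("design samples do not match count matrix samples")
    return design


def filter_low_counts(
    counts: pd.DataFrame, min_cpm: float = 1.0, min_samples: int = 2
) -> pd.DataFrame:
    """Keep genes with CPM >= ``min_cpm`` in at least ``min_samples`` samples."""
    if min_cpm < 0 or min_samples < 0:
        raise ValueError("thresholds must be non-negative")
    validate_counts(counts)
    libsize = counts.sum(axis=0).to_numpy(dtype=float)
    if np.any(libsize == 0):
        raise ValueError("sample with zero library size")
    cpm = counts.to_numpy(dtype=float) / libsize * 1e6
    keep = (cpm >= min_cpm).sum(axis=1) >= min_samples
    if not keep.any():
        raise ValueError("low-count filter removed every gene")
    return counts.loc[keep]


def log_cpm(counts: pd.DataFrame, prior_count: float = 0.5) -> pd.DataFrame:
    """log2 counts-per-million with a prior count.

    value = log2((count + prior) / (libsize + 2·prior) × 1e6)
    """
    if prior_count <= 0:
        raise ValueError("prior_count must be positive")
    validate_counts(counts)
    libsize = counts.sum(axis=0).to_numpy(dtype=float)
    if np.any(libsize == 0):
        raise ValueError("sample with zero library size")
    values = np.log2(
        (counts.to_numpy(dtype=float) + prior_count)
        / (libsize + 2.0 * prior_count)
        * 1e6
    )
    return pd.DataFrame(values, index=counts.index, columns=counts.columns)


def build_design_matrix(
    design: pd.DataFrame, parameterization: str = "cell_means", block_time: bool = False
) -> pd.DataFrame:
    """Design matrix for the 2x2 factorial.

    ``cell_means`` gives one indicator per (treat_a, treat_b) cell, in the
    order ctrl, A, B, AB; ``factorial`` gives intercept, a, b, a:b.  With
    ``block_time`` the distinct time labels beyond the first enter as
    additive blocking dummies.
    """
    xa = design["treat_a"].to_numpy(dtype=float)
    xb = design["treat_b"].to_numpy(dtype=float)
    if parameterization == "cell_means":
        cols = {
            "ctrl": (1 - xa) * (1 - xb),
            "A": xa * (1 - xb),
            "B": (1 - xa) * xb,
            "AB": xa * xb,
        }
    elif parameterization == "factorial":
        cols = {"intercept": np.ones_like(xa), "a": xa, "b": xb, "a:b": xa * xb}
    else:
        raise ValueError(f"unknown parameterization {parameterization!r}")
    x = pd.DataFrame(cols, index=design["sample"].to_numpy())
    if block_time:
        if "time" not in design.columns:
            raise ValueError("block_time requested but design has no 'time' column")
        times = pd.unique(design["time"])
        for t in times[1:]:
            x[f"time[{t}]"] = (design["time"] == t).to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(x.to_numpy())
    if rank < x.shape[1]:
        raise ValueError("design matrix is rank deficient")
    if x.shape[0] - rank <= 0:
        raise ValueError("no residual degrees of freedom")
    return x


@dataclass(frozen=True)
class EBayesParams:
    """Hyperparameters of the scaled inverse-chi-square variance prior."""

    d0: float  # prior degrees of freedom, may be inf
    s0_2: float  # prior variance

    def posterior_var(self, s2: np.ndarray, df: float | np.ndarray) -> np.ndarray:
        """s̃² = (d0·s0² + d·s²)/(d0 + d); the d0=inf limit is s0²."""
        s2 = np.asarray(s2, dtype=float)
        if np.isinf(self.d0):
            return np.full_like(s2, self.s0_2)
        if self.d0 == 0:
            return s2.copy()
        return (self.d0 * self.s0_2 + df * s2) / (self.d0 + df)


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x <= 0:
        raise ValueError("trigamma inverse requires a positive target")
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def estimate_ebayes(s2, df, min_genes: int = 10) -> EBayesParams:
    """Moment-matching estimate of (d0, s0²) from residual variances.

    Matches the mean and variance of e_g = log s²_g − ψ(d_g/2) + log(d_g/2)
    to the theoretical moments of log of a scaled chi-square; d0 comes from
    inverting the trigamma equation, s0² from the corrected mean.  If the
    trigamma target is non-positive (observed spread no larger than chance)
    d0 is infinite: complete shrinkage to s0².
    """
    s2 = np.asarray(s2, dtype=float)
    df = np.broadcast_to(np.asarray(df, dtype=float), s2.shape)
    ok = (s2 > 0) & (df > 0)
    if not ok.any():
        warnings.warn("all residual variances are zero; d0 set to infinity")
        return EBayesParams(np.inf, float(np.mean(s2)) or 1.0)
    z = np.log(s2[ok])
    d = df[ok]
    e = z - special.digamma(d / 2.0) + np.log(d / 2.0)
    if ok.sum() < min_genes:
        # too few genes to estimate a prior spread: shrink completely
        s0_2 = float(np.exp(e.mean()))
        return EBayesParams(np.inf, s0_2)
    n = e.size
    target = e.var(ddof=1) * (n - 1) / n - special.polygamma(1, d / 2.0).mean()
    if target <= 0:
        s0_2 = float(np.exp(e.mean()))
        return EBayesParams(np.inf, s0_2)
    d0 = 2.0 * _trigamma_inverse(float(target))
    s0_2 = float(np.exp(e.mean() + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return EBayesParams(d0, s0_2)


class ModeratedLinearModel:
    """Gene-wise linear model of log-expression on a factorial design.

    Parameters
    ----------
    logexpr : DataFrame
        genes × samples matrix of log2-CPM values.
    design : DataFrame
        sample table with columns ``sample``, ``treat_a``, ``treat_b`` and
        optionally ``time`` / ``replicate``.
    parameterization : str
        ``"cell_means"`` (default) or ``"factorial"``.
    block_time : bool
        Include time labels as additive blocking dummies.
    """

    def __init__(
        self,
        logexpr: pd.DataFrame,
        design: pd.DataFrame,
        parameterization: str = "cell_means",
        block_time: bool = False,
    ):
        design = validate_design(design, sample_ids=logexpr.columns)
        # align sample order to the expression columns
        design = (
            design.set_index("sample")
            .loc[list(logexpr.columns)]
            .rename_axis("sample")
            .reset_index()
        )
        self.logexpr = logexpr
        self.design = design
        self.parameterization = parameterization
        self.exog = build_design_matrix(design, parameterization, block_time)

    @classmethod
    def from_counts(
        cls,
        counts: pd.DataFrame,
        design: pd.DataFrame,
        min_cpm: float = 1.0,
        min_samples: int = 2,
        prior_count: float = 0.5,
        **kwargs,
    ) -> "ModeratedLinearModel":
        """Filter low-count genes, convert to log2-CPM, and build the model."""
        filtered = filter_low_counts(counts, min_cpm, min_samples)
        return cls(log_cpm(filtered, prior_count), design, **kwargs)

    def fit(self, moderate: bool = True) -> "ModeratedLinearModelResults":
        """OLS per gene; optionally shrink variances by empirical Bayes.

        With ``moderate=False`` the prior df is zero and the contrast test
        reduces to the ordinary per-gene OLS t-test.
        """
        x = self.exog.to_numpy()
        y = self.logexpr.to_numpy(dtype=float)
        n, k = x.shape
        xtx_inv = np.linalg.inv(x.T @ x)
        beta = y @ (xtx_inv @ x.T).T  # genes × k
        resid = y - beta @ x.T
        df_resid = n - k
        s2 = (resid**2).sum(axis=1) / df_resid
        if moderate:
            eb = estimate_ebayes(s2, df_resid)
        else:
            eb = EBayesParams(0.0, float(np.median(s2[s2 > 0])) if (s2 > 0).any() else 1.0)
        return ModeratedLinearModelResults(self, beta, xtx_inv, s2, df_resid, eb)


class ModeratedLinearModelResults:
    """Fitted gene-wise linear models with moderated variances."""

    def __init__(self, model, beta, xtx_inv, s2, df_resid, eb: EBayesParams):
        self.model = model
        self.genes = model.logexpr.index
        self.coef_names = list(model.exog.columns)
        self.coef = pd.DataFrame(beta, index=self.genes, columns=self.coef_names)
        self._xtx_inv = xtx_inv
        self.s2 = pd.Series(s2, index=self.genes, name="s2")
        self.df_resid = df_resid
        self.ebayes = eb
        self.s2_post = pd.Series(
            eb.posterior_var(s2, df_resid), index=self.genes, name="s2_post"
        )

    @property
    def df_total(self) -> float:
        return self.ebayes.d0 + self.df_resid

    def _contrast_vector(self, contrast) -> np.ndarray:
        if isinstance(contrast, str):
            if contrast not in NAMED_CONTRASTS:
                raise KeyError(
                    f"unknown contrast {contrast!r}; known: {sorted(NAMED_CONTRASTS)}"
                )
            if self.model.parameterization != "cell_means":
                raise ValueError("named contrasts require the cell-means parameterization")
            c = NAMED_CONTRASTS[contrast]
            if len(self.coef_names) > 4:  # blocking covariates get zero weight
                c = np.concatenate([c, np.zeros(len(self.coef_names) - 4)])
            return c
        c = np.asarray(contrast, dtype=float)
        if c.shape != (len(self.coef_names),):
            raise ValueError(
                f"contrast length {c.size} != number of coefficients "
                f"{len(self.coef_names)}"
            )
        return c

    def contrast(self, contrast, name: str | None = None) -> pd.DataFrame:
        """Moderated-t test of a contrast; returns gene, logFC, t, p, adj_p."""
        c = self._contrast_vector(contrast)
        if name is None:
            name = contrast if isinstance(contrast, str) else "custom"
        logfc = self.coef.to_numpy() @ c
        u_c = float(np.sqrt(c @ self._xtx_inv @ c))
        if u_c == 0.0:
            t = np.zeros_like(logfc)
            p = np.ones_like(logfc)
        else:
            se = u_c * np.sqrt(self.s2_post.to_numpy())
            with np.errstate(divide="ignore", invalid="ignore"):
                t = np.where(se > 0, logfc / se, np.where(logfc == 0, 0.0, np.inf))
            df = self.df_total
            if np.isinf(df):
                p = 2.0 * sps.norm.sf(np.abs(t))
            else:
                p = 2.0 * sps.t.sf(np.abs(t), df)
        out = pd.DataFrame(
            {"logFC": logfc, "t": t, "p": p, "adj_p": bh_adjust(p)},
            index=self.genes,
        )
        out.index.name = "gene"
        out.attrs["contrast"] = name
        return out

    def summary(self, alpha: float = 0.05) -> str:
        """Plain-text overview of the fit and per-contrast DEG counts."""
        lines = [
            "Moderated linear model (gene-wise OLS + empirical-Bayes shrinkage)",
            f"  genes: {len(self.genes)}   samples: {self.model.exog.shape[0]}",
            f"  coefficients: {', '.join(self.coef_names)}",
            f"  residual df: {self.df_resid}   prior df d0: {self.ebayes.d0:.4g}"
            f"   prior variance s0^2: {self.ebayes.s0_2:.4g}",
        ]
        if self.model.parameterization == "cell_means":
            lines.append(f"  DEGs at BH-adjusted p < {alpha}:")
            for cname in NAMED_CONTRASTS:
                n_sig = int((self.contrast(cname)["adj_p"] < alpha).sum())
                lines.append(f"    {cname:12s} {n_sig}")
        return "\n".join(lines)
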