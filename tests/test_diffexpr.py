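"""Moderated linear model: filtering, normalization, OLS, shrinkage and
contrast tests against independent oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from synergysig.diffexpr import (
    EBayesParams,
    ModeratedLinearModel,
    build_design_matrix,
    estimate_ebayes,
    filter_low_counts,
    log_cpm,
)


class TestFilterLowCounts:
    def test_zero_threshold_is_identity(self, small_counts):
        counts, _ = small_counts
        pd.testing.assert_frame_equal(filter_low_counts(counts, 0.0, 0), counts)

    def test_all_zero_gene_removed(self):
        counts = pd.DataFrame(
            {"s1": [0, 5], "s2": [0, 7]}, index=["dead", "alive"]
        )
        out = filter_low_counts(counts, min_cpm=1.0, min_samples=1)
        assert list(out.index) == ["alive"]

    def test_matches_brute_force(self, rng):
        counts = pd.DataFrame(
            rng.poisson(5, size=(100, 6)),
            index=[f"g{i}" for i in range(100)],
            columns=[f"s{i}" for i in range(6)],
        )
        counts.iloc[0] += 10  # guard against the all-removed error
        min_cpm, min_samples = 1.2e4, 3
        lib = counts.sum(axis=0)
        expected = [
            g
            for g in counts.index
            if sum(
                counts.loc[g, s] / lib[s] * 1e6 >= min_cpm for s in counts.columns
            )
            >= min_samples
        ]
        got = filter_low_counts(counts, min_cpm, min_samples)
        assert list(got.index) == expected

    def test_all_removed_raises(self):
        counts = pd.DataFrame({"s1": [1, 1], "s2": [1, 1]}, index=["a", "b"])
        with pytest.raises(ValueError):
            filter_low_counts(counts, min_cpm=1e7, min_samples=2)


class TestLogCpm:
    def test_closed_form_zero_count(self):
        counts = pd.DataFrame(
            {"s": [0, 10**6], "s2": [10, 10]}, index=["g0", "g1"]
        )
        out = log_cpm(counts, prior_count=0.5)
        expected = np.log2(0.5 / (1e6 + 1.0) * 1e6)  # ≈ −1.0000014
        assert out.loc["g0", "s"] == pytest.approx(expected, abs=1e-12)

    def test_scale_invariance_up_to_prior(self, small_counts):
        counts, _ = small_counts
        a = log_cpm(counts, 0.5)
        b = log_cpm(counts * 2, 0.5)
        # doubling counts and libsizes changes values only through the prior
        assert np.abs(a.to_numpy() - b.to_numpy()).max() < 0.02

    def test_matches_spreadsheet_recomputation(self, rng):
        counts = pd.DataFrame(
            rng.poisson(30, size=(5, 4)),
            index=list("abcde"),
            columns=["s1", "s2", "s3", "s4"],
        )
        out = log_cpm(counts, prior_count=0.5)
        for g in counts.index:
            for s in counts.columns:
                lib = counts[s].sum()
                expected = np.log2((counts.loc[g, s] + 0.5) / (lib + 1.0) * 1e6)
                assert out.loc[g, s] == pytest.approx(expected, abs=1e-12)

    def test_finite_everywhere(self, small_counts):
        counts, _ = small_counts
        assert np.isfinite(log_cpm(counts).to_numpy()).all()


class TestGeneModels:
    def test_cell_means_equal_group_means(self, small_counts):
        counts, design = small_counts
        model = ModeratedLinearModel.from_counts(counts, design, min_cpm=0, min_samples=0)
        res = model.fit(moderate=False)
        expr = model.logexpr
        for cond, (xa, xb) in {"ctrl": (0, 0), "A": (1, 0), "B": (0, 1), "AB": (1, 1)}.items():
            cols = design.loc[
                (design.treat_a == xa) & (design.treat_b == xb), "sample"
            ]
            np.testing.assert_allclose(
                res.coef[cond].to_numpy(), expr[cols].mean(axis=1).to_numpy(), atol=1e-10
            )

    def test_zero_residual_when_replicates_identical(self):
        samples = [f"{c}_r{r}" for c in ("ctrl", "A", "B", "AB") for r in (1, 2)]
        design = pd.DataFrame(
            {
                "sample": samples,
                "treat_a": [0, 0, 1, 1, 0, 0, 1, 1],
                "treat_b": [0, 0, 0, 0, 1, 1, 1, 1],
            }
        )
        counts = pd.DataFrame(
            [[100, 100, 50, 50, 200, 200, 25, 25]], index=["g"], columns=samples
        )
        # identical libsizes guaranteed by a balancing second gene
        counts.loc["pad"] = 1000 - counts.loc["g"]
        model = ModeratedLinearModel.from_counts(counts, design, min_cpm=0, min_samples=0)
        res = model.fit(moderate=False)
        assert res.s2["g"] == pytest.approx(0.0, abs=1e-20)

    def test_single_gene_matches_normal_equations(self, rng):
        y = rng.normal(size=8)
        samples = [f"s{i}" for i in range(8)]
        design = pd.DataFrame(
            {
                "sample": samples,
                "treat_a": [0, 0, 1, 1, 0, 0, 1, 1],
                "treat_b": [0, 0, 0, 0, 1, 1, 1, 1],
            }
        )
        expr = pd.DataFrame([y], index=["g"], columns=samples)
        res = ModeratedLinearModel(expr, design).fit(moderate=False)
        x = build_design_matrix(design).to_numpy()
        beta = np.linalg.solve(x.T @ x, x.T @ y)
        np.testing.assert_allclose(res.coef.loc["g"].to_numpy(), beta, atol=1e-12)
        resid = y - x @ beta
        assert res.s2["g"] == pytest.approx(resid @ resid / 4, rel=1e-12)

    def test_permutation_invariance(self, small_counts):
        counts, design = small_counts
        perm = np.random.default_rng(0).permutation(len(design))
        counts2 = counts.iloc[:, perm]
        design2 = design.iloc[perm].reset_index(drop=True)
        r1 = ModeratedLinearModel.from_counts(counts, design, min_cpm=0, min_samples=0).fit()
        r2 = ModeratedLinearModel.from_counts(counts2, design2, min_cpm=0, min_samples=0).fit()
        pd.testing.assert_frame_equal(r1.coef, r2.coef)

    def test_rank_deficient_design_rejected(self):
        design = pd.DataFrame(
            {"sample": ["s1", "s2", "s3"], "treat_a": [0, 0, 0], "treat_b": [0, 0, 0]}
        )
        with pytest.raises(ValueError):
            build_design_matrix(design)


class TestEBayes:
    def test_homoscedastic_limit_shrinks_fully(self, rng):
        # all true variances equal: observed spread is pure chi-square noise,
        # so d0 should be large and posteriors near s0^2
        df = 8
        s2 = 2.0 * rng.chisquare(df, size=2000) / df
        eb = estimate_ebayes(s2, df)
        assert eb.d0 > 20
        post = eb.posterior_var(s2, df)
        assert np.abs(post - eb.s0_2).max() < np.abs(s2 - eb.s0_2).max()

    def test_d0_zero_means_no_moderation(self, rng):
        s2 = rng.chisquare(5, size=50)
        eb = EBayesParams(0.0, 1.0)
        np.testing.assert_allclose(eb.posterior_var(s2, 5), s2)

    def test_posterior_between_prior_and_sample(self, rng):
        s2 = rng.chisquare(6, size=300) / 6
        eb = estimate_ebayes(s2, 6)
        post = eb.posterior_var(s2, 6)
        lo = np.minimum(s2, eb.s0_2)
        hi = np.maximum(s2, eb.s0_2)
        assert np.all(post >= lo - 1e-12) and np.all(post <= hi + 1e-12)

    def test_posterior_monotone_in_s2(self):
        eb = EBayesParams(4.0, 2.0)
        s2 = np.linspace(0.1, 10, 50)
        assert np.all(np.diff(eb.posterior_var(s2, 8)) > 0)

    def test_parameter_recovery_scaled_inv_chisq(self):
        # variances from a scaled inverse-chi-square prior (d0=4, s0^2=2)
        d0_true, s02_true, dg, n = 4.0, 2.0, 8, 500
        d0s, s0s = [], []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            true_var = d0_true * s02_true / rng.chisquare(d0_true, n)
            s2 = true_var * rng.chisquare(dg, n) / dg
            eb = estimate_ebayes(s2, dg)
            d0s.append(eb.d0)
            s0s.append(eb.s0_2)
        assert abs(np.mean(d0s) - d0_true) / d0_true < 0.25
        assert abs(np.mean(s0s) - s02_true) / s02_true < 0.10


class TestContrast:
    def test_zero_contrast_gives_null_result(self, small_counts):
        counts, design = small_counts
        res = ModeratedLinearModel.from_counts(counts, design, min_cpm=0, min_samples=0).fit()
        out = res.contrast([0.0, 0.0, 0.0, 0.0])
        assert (out["logFC"] == 0).all() and (out["p"] == 1).all()

    def test_unmoderated_equals_ols_t(self, small_counts):
        """With d0 = 0 the moderated t reduces to the ordinary OLS t."""
        counts, design = small_counts
        model = ModeratedLinearModel.from_counts(counts, design, min_cpm=0, min_samples=0)
        res = model.fit(moderate=False)
        assert res.ebayes.d0 == 0.0
        out = res.contrast("AB_vs_ctrl")
        x = model.exog.to_numpy()
        c = np.array([-1.0, 0.0, 0.0, 1.0])
        xtx_inv = np.linalg.inv(x.T @ x)
        u = np.sqrt(c @ xtx_inv @ c)
        for g in model.logexpr.index[:10]:
            y = model.logexpr.loc[g].to_numpy()
            beta = xtx_inv @ x.T @ y
            resid = y - x @ beta
            s2 = resid @ resid / (len(y) - 4)
            t_ols = (c @ beta) / (u * np.sqrt(s2))
            assert out.loc[g, "t"] == pytest.approx(t_ols, abs=1e-10)

    def test_moderated_t_step_by_step_oracle(self, rng):
        """Full pipeline (fit → shrink → t) against an independent
        step-by-step recomputation."""
        genes = [f"g{i}" for i in range(50)]
        samples = [f"s{i}" for i in range(8)]
        design = pd.DataFrame(
            {
                "sample": samples,
                "treat_a": [0, 0, 1, 1, 0, 0, 1, 1],
                "treat_b": [0, 0, 0, 0, 1, 1, 1, 1],
            }
        )
        gene_sd = rng.uniform(0.5, 3.0, size=50)  # heteroscedastic: finite d0
        expr = pd.DataFrame(
            rng.normal(size=(50, 8)) * gene_sd[:, None], index=genes, columns=samples
        )
        res = ModeratedLinearModel(expr, design).fit(moderate=True)
        out = res.contrast("AB_vs_A")

        x = build_design_matrix(design).to_numpy()
        xtx_inv = np.linalg.inv(x.T @ x)
        c = np.array([0.0, -1.0, 0.0, 1.0])
        u = np.sqrt(c @ xtx_inv @ c)
        s2 = np.empty(50)
        logfc = np.empty(50)
        for i, g in enumerate(genes):
            y = expr.loc[g].to_numpy()
            beta = xtx_inv @ x.T @ y
            r = y - x @ beta
            s2[i] = r @ r / 4
            logfc[i] = c @ beta
        eb = estimate_ebayes(s2, 4)
        s2_post = (eb.d0 * eb.s0_2 + 4 * s2) / (eb.d0 + 4)
        t_expected = logfc / (u * np.sqrt(s2_post))
        np.testing.assert_allclose(out["t"].to_numpy(), t_expected, atol=1e-10)
        p_expected = 2 * sps.t.sf(np.abs(t_expected), eb.d0 + 4)
        np.testing.assert_allclose(out["p"].to_numpy(), p_expected, atol=1e-12)

    def test_interaction_contrast_self_consistency(self, small_counts):
        """(AB − A) − (B − ctrl) from cell means equals the interaction
        coefficient of the factorial parameterization."""
        counts, design = small_counts
        res_cm = ModeratedLinearModel.from_counts(
            counts, design, min_cpm=0, min_samples=0
        ).fit()
        res_fac = ModeratedLinearModel.from_counts(
            counts, design, min_cpm=0, min_samples=0, parameterization="factorial"
        ).fit()
        inter_cm = res_cm.contrast("interaction")["logFC"].to_numpy()
        inter_fac = res_fac.coef["a:b"].to_numpy()
        np.testing.assert_allclose(inter_cm, inter_fac, atol=1e-10)

    def test_null_pvalues_approximately_uniform(self):
        from synergysig import simulate

        cfg = simulate.FactorialSimConfig(n_genes=5000, program_sizes={}, seed=5)
        counts, design, _ = simulate.gen_factorial_counts(cfg)
        res = ModeratedLinearModel.from_counts(
            counts, design, min_cpm=10, min_samples=9
        ).fit()
        p = res.contrast("AB_vs_A")["p"].to_numpy()
        assert sps.kstest(p, "uniform").statistic < 0.03
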