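# synergysig

Tools for analysing **combination-treatment transcriptomics** and its
downstream biology: deriving a combination-specific ("synergy") gene
signature from a 2×2 factorial RNA-seq design, quantifying
super-additive expression changes, scoring patient cohorts by rank-based
single-sample enrichment with tertile survival stratification, and
quantifying DNA replication dynamics from dual-pulse DNA-fiber assays.

The package is aimed at computational biologists studying drug
combinations (the motivating setting is a microRNA mimic combined with a
kinase inhibitor in B-cell lymphoma, but nothing is lymphoma-specific):
treatment A and treatment B are abstract factorial arms. Every input the
pipeline consumes can be generated synthetically with planted ground
truth, so the whole analysis is testable end to end without any external
download.

## What it computes

**Moderated differential expression.** Counts are filtered, converted to
log2 counts-per-million, and modelled gene-wise by OLS on the four cells
of the design (ctrl, A, B, AB). Residual variances s²_g (d_g df) are
shrunk toward a common prior via the scaled inverse-chi-square
empirical-Bayes model: (d₀, s₀²) are estimated by moment matching on
log s²_g (digamma/trigamma inversion) and

&nbsp;&nbsp;&nbsp;&nbsp;s̃²_g = (d₀·s₀² + d_g·s²_g)/(d₀ + d_g),

with contrasts tested by the moderated t on d₀ + d_g df and
Benjamini–Hochberg adjustment.

**Combination signature (three overlap analyses).** With DEG sets at
BH-adjusted p < α,

&nbsp;&nbsp;&nbsp;&nbsp;list1 = DEG(AB vs A) \ DEG(B vs ctrl),
&nbsp;&nbsp;&nbsp;&nbsp;list2 = DEG(AB vs B) \ DEG(A vs ctrl),
&nbsp;&nbsp;&nbsp;&nbsp;signature = list1 ∩ list2,

split into up/down by the AB-vs-ctrl log2 fold-change. Synergy is judged
per gene against the additive expectation lfc_add = lfc_A + lfc_B: a
gene is synergistic when |lfc_AB| > |lfc_add| with concordant sign, and
the four per-gene groups (A, B, AB, additive) are compared by
Kruskal–Wallis with Dunn's post test of AB versus additive.

**Patient scoring and survival.** Each sample's signature score is the
centered normalized mean rank of the set genes
(score = (R̄ − R̄_min)/(R̄_max − R̄_min) − ½ ∈ [−½, ½]; high score =
high expression). Cohorts are split into score tertiles
(bottom = ⌈n/3⌉, top = ⌊n/3⌋) and the extreme tertiles compared by
Kaplan–Meier curves and the log-rank (Mantel–Cox) test. A preranked
GSEA (weighted running-sum ES, gene-set-permutation NES and p) is
included for signature enrichment testing.

**DNA-fiber replication dynamics.** Dual-pulse (red CldU then green
IdU) structures are classified by color pattern (red–green = ongoing
fork, green–red–green = first-label origin, red = terminated,
green = second-label only; direction-invariant). Fork rate = green
track µm × 2.59 kb/µm ÷ 20 min; origin firing = % first-label origins
among red-containing structures. Conditions are compared by
Kruskal–Wallis + Dunn (fork rates) and one-way ANOVA (replicate origin
percentages).

**Shared statistics** (implemented from their formulas): BH step-up
FDR, tie-corrected Kruskal–Wallis, Dunn's joint-rank post test,
iterative two-sided Grubbs outlier removal, one-way ANOVA; plus tumor
caliper arithmetic (volume = width² × length / 2, growth normalized to
baseline).

## Worked example

```python
from synergysig import simulate, scoring
from synergysig.signature import run_signature_pipeline, build_synergy_table, synergy_test

# factorial experiment with planted gene programs (50 combination-only,
# 50 additive, 50 per-monotherapy genes among 2000)
cfg = simulate.FactorialSimConfig(seed=1)
counts, design, truth = simulate.gen_factorial_counts(cfg)

sig, res, tables = run_signature_pipeline(counts, design)
print(res.summary())
```

```
Moderated linear model (gene-wise OLS + empirical-Bayes shrinkage)
  genes: 1258   samples: 12
  coefficients: ctrl, A, B, AB
  residual df: 8   prior df d0: 4.589   prior variance s0^2: 0.03263
  DEGs at BH-adjusted p < 0.05:
    A_vs_ctrl    54
    B_vs_ctrl    44
    AB_vs_ctrl   116
    AB_vs_A      84
    AB_vs_B      91
    interaction  35
```

1258 of 2000 genes survive the quantifiability filter; the shrinkage
prior is worth d₀ ≈ 4.6 extra degrees of freedom per gene. The
three-overlap extraction then yields a 35-gene signature, all
downregulated (`sig.counts` reports list1 = 40, list2 = 42,
signature = 35), dominated by the planted combination-only program.
Testing those genes against the additive expectation:

```python
tab = build_synergy_table(tables["A_vs_ctrl"], tables["B_vs_ctrl"],
                          tables["AB_vs_ctrl"], sorted(sig.down))
print(synergy_test(tab).summary())
```

```
Synergy report over 35 genes
  Kruskal-Wallis across (A, B, AB, additive): H = 78.689, p = 5.86e-17
  Dunn AB vs additive: adjusted p = 3.98e-14
  fraction of genes beyond the additive expectation: 1.000
```

Every signature gene changes more under the combination than the sum of
the monotherapy effects — the planted super-additive program. Scoring a
simulated 300-patient cohort whose hazard tracks signature expression:

```python
expr, surv, z = simulate.gen_patient_cohort(
    simulate.CohortSimConfig(n_patients=300, seed=7), sorted(sig.down), list(res.genes))
print(scoring.stratify_and_compare(expr, sorted(sig.down), surv).summary())
```

```
Cohort stratification: n = 300 patients
  tertile sizes: bottom = 100, middle = 100, top = 100
  log-rank (bottom vs top): chi2 = 85.067, p = 2.884e-20
```

Patients in the high-expression tertile fare significantly worse, as
planted. The same steps are available from the shell:
`synergysig simulate`, `synergysig de`, `synergysig signature`,
`synergysig synergy`, `synergysig score`, `synergysig fibers`,
`synergysig growth`, `synergysig stats`.

## Layout

- `synergysig.simulate` — generators with planted ground truth
- `synergysig.diffexpr` — `ModeratedLinearModel` / results, filtering, log-CPM
- `synergysig.signature` — three-overlap signature, synergy table and test
- `synergysig.scoring` — singscore, tertiles, KM/log-rank, preranked GSEA
- `synergysig.fibers` — structure classification, fork rate, origin firing
- `synergysig.stats` — BH, KW, Dunn, Grubbs, ANOVA, correlation
- `synergysig.growth`, `synergysig.io`, `synergysig.cli` — caliper math, file formats, CLI

See `docs/methods.md` for the modelling assumptions, parameter choices
and known limitations.
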