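# Methods

This note records the models behind each module, the defaults that
matter and why, the design choices made where the design was open, and
what the synthetic-data tests do and do not demonstrate about real data.

## Differential expression

Counts are normalized to log2 counts-per-million with a prior count of
0.5: value = log2((count + 0.5)/(libsize + 1) × 10⁶). Library-size
normalization only — no between-sample scaling factors (TMM-style);
users with composition-skewed libraries should pre-normalize (see
Limitations).

Each gene is fitted by OLS with one mean per (A, B) treatment cell
(ctrl, A, B, AB); time labels can enter as additive blocking dummies. A
`factorial` parameterization (intercept, a, b, a·b) is available and is
numerically equivalent: the cell-means contrast (AB − A) − (B − ctrl)
equals the interaction coefficient (asserted in tests to 1e-10).

Variance moderation follows the classical empirical-Bayes scheme: with
residual variances s²_g on d_g df, the prior scaled inverse-chi-square
(d₀, s₀²) is estimated by matching the mean and variance of
e_g = log s²_g − ψ(d_g/2) + log(d_g/2) to its theoretical moments; the
trigamma equation is inverted by Newton iteration. If the observed
spread of log-variances is no larger than chance (trigamma target ≤ 0),
or fewer than 10 genes are available, d₀ is set to infinity (complete
shrinkage). d₀ = 0 reproduces ordinary per-gene OLS t-tests exactly and
is exposed as `fit(moderate=False)` — the mode matching plain per-gene
ANOVA analyses of small designs. Moderated t statistics use d₀ + d_g
df; p-values are two-sided; BH adjustment is applied per contrast.

**Low-count filtering.** The generic filter keeps genes with
CPM ≥ min_cpm in ≥ min_samples samples (defaults 1.0 / 2). The
factorial signature pipeline defaults to CPM ≥ 10 in at least three
quarters of the samples — i.e. three of the four treatment cells of a
balanced design. Rationale: the signature procedure compares every pair
of cells, and a gene whose counts collapse in one cell (a strongly
suppressed target) should still be well measured in the remaining
cells; genes quantifiable in fewer than three cells contribute mostly
variance-inflation artifacts, which silence the monotherapy contrasts
while the large combination contrasts still fire, and thereby leak
additive-class genes into the signature.

## Signature extraction and synergy

The combination signature is pure set algebra on four DEG sets computed
at one α over one post-filter gene universe (a universe mismatch is an
error, never a silent intersection): list1 = DEG(AB vs A) \
DEG(B vs ctrl), list2 = DEG(AB vs B) \ DEG(A vs ctrl), signature =
list1 ∩ list2. DEG sets for extraction use adjusted p only; the
threshold-derived sets (`threshold_signature`) additionally apply a
directional |logFC| cutoff (default 1.5) for exported comparative gene
sets. Direction (up/down) comes from the AB-vs-ctrl logFC; exact zeros
are reported separately.

Synergy per gene is defined on magnitudes with concordant sign: a
downregulated gene is synergistic iff lfc_AB < lfc_A + lfc_B, an
upregulated one iff lfc_AB > lfc_A + lfc_B. For scatter plots of
downregulated genes (additive expectation on x, observed combination on
y) a stronger-than-additive effect therefore plots *below* the identity
line when signed values are drawn, and above it when magnitudes are
drawn; the table carries signed values and the flag, so either
convention can be rendered. The group-level test is Kruskal–Wallis
across {lfc_A, lfc_B, lfc_AB, lfc_add} with Dunn's post test of lfc_AB
versus lfc_add.

## Single-sample scoring and survival

The score of sample j for gene set G (|G| = n_G of N genes) is the
centered normalized mean rank: ranks ascending with average ties,
score = (R̄ − R̄_min)/(R̄_max − R̄_min) − ½ with R̄_min = (n_G+1)/2 and
R̄_max = N − (n_G−1)/2. This is the single-direction variant: no
bidirectional up/down combination and no dispersion component, because
the use case scores one (downregulated) set and interprets high score =
high expression. The score is invariant to any strictly monotone
per-sample transform.

Tertiles: stable sort by (score, sample id); bottom = first ⌈n/3⌉,
top = last ⌊n/3⌋ (n = 62 → 21/21/20). Survival comparison is between
extreme tertiles only, by Kaplan–Meier and the log-rank test (both via
lifelines behind the module's own surface, verified in tests against
hand-applied product-limit and (O−E)²/V computations).

Preranked GSEA: genes ordered descending by a signed metric (the
moderated t by default — the ranking metric is otherwise a free
choice); hits advance the running sum proportionally to |metric|^p
(default p = 1), misses retreat uniformly; ES is the extremum. Because
only a preranked list exists, the null is size-matched *gene-set*
permutation (default 1000 draws, seeded): NES = ES / mean |ES*| over
same-signed permutations, p one-sided.

## Fiber dynamics

Classification is a direction-invariant color-pattern match; structures
with more than three segments (e.g. sister forks on one fiber) are
ambiguous and excluded from both estimators but counted and reported.
Fork rate uses only the second-label (green) track of red–green
structures: rate = green µm × kb_per_um / pulse2_min with defaults
2.59 kb/µm and 20-minute pulses. Origin firing = percentage of
green–red–green structures among all structures containing red;
red-containing ambiguous structures are included in the denominator
(and reported separately), since they are replicative structures with a
first-label track. Input lengths are taken as given (post-ImageJ);
measurement noise is out of scope.

## Statistics primitives

BH, Kruskal–Wallis (tie-corrected), Dunn (joint-rank z with tie
correction; Bonferroni over the performed comparisons by default, Holm
available — the choice matches common "Dunn's post-test" software
behaviour), iterative two-sided Grubbs (α = 0.1 default, at most 2
removals by default), and classical one-way ANOVA are implemented from
their formulas; scipy supplies distribution functions and correlation
coefficients. Zero-within-variance ANOVA inputs are reported as
degenerate rather than given a fabricated p. All rank computations use
average ranks for ties.

## Synthetic-data generators

All generators draw from a `numpy.random.default_rng` stream seeded in
their config; identical config ⇒ bit-identical output; no global RNG
state.

**Factorial counts.** μ_gs = libsize_s · p_g · 2^(x_A a_g + x_B b_g +
x_A x_B i_g), counts negative-binomial with Var = μ + φμ². Defaults and
rationale:

- dispersion φ ~ Gamma(shape 2, scale 0.01), mean 0.02 (biological CV
  ≈ 14%) — typical of replicate cultures of an isogenic cell line, the
  experimental setting being emulated;
- baseline abundances log-uniform over 4 orders of magnitude, so
  low-count filtering is genuinely exercised;
- library sizes uniform on 2–4 × 10⁶: with a 2000-gene universe this
  reproduces the per-gene depth of a real ~2×10⁷-read, 20 000-gene
  library at desk scale;
- planted effects: a uniform 2-log2-unit (4-fold) magnitude for every
  responsive class, signed negative to mirror a predominantly
  downregulated combination program; combination-only genes carry the
  effect exclusively in the interaction term (a = b = 0, i ≠ 0), so
  they are exactly invisible in both monotherapies by construction;
- n = 3 replicates per cell, one time label (time points are treated as
  independent condition blocks; no time-course correlation is
  simulated).

**Patient cohort.** Latent factor z ~ N(0, sd²) per patient shifts the
expression of the signature genes (per-gene baselines N(0, 2²), unit
residual noise, arbitrary log-like units); event times are exponential
with hazard λ₀·exp(β·z) (defaults λ₀ = 0.1 per unit time, horizon 10,
giving roughly two-thirds events at β = 0), administratively censored
at the horizon. β = 1 with sd = 1 plants a strong, detectable
expression–survival link; β = 0 gives the null used for calibration.

**Fibers.** Per structure: green-only with probability p_green_only;
otherwise red-containing, of which a fraction `origin_fraction` are
green–red–green origins, and the rest split red-only vs red–green via
p_terminated. Each labelled segment's length is an independent
lognormal speed (median per condition, log-sd 0.25) times the pulse
duration converted at 2.59 kb/µm. The four-arm preset plants the
replication phenotype of the motivating experiment: treatment A halves
origin firing and doubles fork speed; B slows forks to 0.7× and raises
origins 1.2×; the combination keeps the origin reduction while the
fork-speed increase is attenuated by 35% (2× → 1.65×). The control
origin fraction (0.25) is a typical assay value, chosen here.

**Growth curves.** Volume V₀·exp(r·d) with lognormal noise on the log
scale after baseline; width/length back-calculated with length = 2 ×
width so that width²·length/2 reproduces the volume exactly.

What the generators do *not* emulate: read-level data, UMIs, batch
effects, single-cell counts, time-course autocorrelation, non-
exponential baseline hazards, informative censoring, fiber measurement
noise or fiber-breakage artifacts. Passing tests therefore demonstrate
the correctness and calibration of the estimators under their stated
models — not robustness to those real-data complications.

## Problem sizes used in tests and the acceptance script

Signature recovery: five 2000-gene experiments (50 genes per responsive
program, 3 replicates per cell). Null DE calibration: five 5000-gene
zero-effect experiments. Cohort power: 50 cohorts of n = 300; null
cohorts: 300 replicates of n = 120 (the non-significance rate is
asserted within ±0.04 of 0.95, three Monte-Carlo standard errors).
Grubbs null: 2000 replicates of n = 15. Fibers: ten single-replicate
sets of 500 structures per arm for recovery (estimates averaged over
seeds before comparison with truth, since a single 500-structure set
determines the origin percentage only to ±2 points), plus one
two-replicate set for the condition comparison.

## Known limitations

- **Composition bias.** With library-size-only normalization, a
  planted (or real) responsive program carrying a substantial share of
  library mass shifts all logFCs; at ~20% of mass the mean "excess"
  of truly additive genes reaches ≈ −0.13 log2 units. Under the default
  conditions (each program 2.5% of genes) the bias is negligible, but
  real composition-skewed data should be TMM/median-ratio normalized
  upstream.
- **Signature false inclusions.** Null genes can enter the signature
  through correlated type-I errors of the two combination contrasts
  (they share the AB samples); expect on the order of one such gene per
  2000-gene experiment at α = 0.05. Additive-gene leakage is controlled
  by the three-cell quantifiability filter (see above) but is a
  structural risk of the three-overlap procedure whenever a strongly
  suppressed cell is retained with inflated variance.
- **No count-model testing.** Inference is normal-theory on log-CPM;
  very low counts are handled by filtering, not by NB GLMs or precision
  weights (both out of scope).
- The singscore variant implemented is the single-direction centered
  mean rank; bidirectional and dispersion components are not included.
- Survival analysis offers no Cox regression, multivariable adjustment
  or competing risks; comparisons are extreme-tertile log-rank only.
- Growth analysis prepares per-tumor normalized series only; mixed-
  effects growth regression is out of scope.
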