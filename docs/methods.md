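# Methods

This note documents the models and procedures implemented in soilrisknet,
the defaults they ship with, and the choices made where the underlying
survey methodology left the design open.

## Ecological risk model

The Hakanson potential-ecological-risk framework scores each metal by its
contamination factor Cf = C_D/C_R (measured over background concentration,
both mg/kg dry soil) and weights it by a dimensionless toxic-response
factor Tr: Er = Tr·Cf, RI = ΣEr. All three are linear in concentration,
which gives two exact identities the test suite asserts: the site mean of
Er equals Tr·(site mean concentration)/C_R, and RI minus the sum of Er is
zero to rounding error.

Defaults: background values from the packaged regional soil table; Tr
ordering Zn 1, Cr 2, Cu/Pb/Ni 5, As 10, Cd 30. Both are configuration,
not code — any metal panel with positive backgrounds and Tr works.

Two deliberate quirks:

* **`ni2-compat` profile.** The published per-site risk table that the
  worked example reproduces is only arithmetically consistent with
  Tr(Ni) = 2 (2 × 34.17/29.9 = 2.29, the printed value), although the
  accompanying text states Ni = 5. Rather than guess the intent, both
  profiles ship; the golden tests use `ni2-compat` for Ni and the
  classical factors for everything else. The published Cd site means are
  not reproducible from the printed concentration means under any stated
  Tr/C_R combination (30 × 1.25/0.1 = 375 vs the printed 367.91,
  presumably rounding of the printed concentration mean), so Cd is
  excluded from the golden worked example.
* **Contribution column.** The percent contribution of metal *m* is
  100 × mean-over-sites(site-mean Er_m) / mean-over-sites(site-mean RI),
  each site counting once regardless of n. No formula is stated alongside
  the published table, but this unweighted ratio reproduces all seven
  printed percentages at 2 dp (they sum to 100.01% by rounding); a
  sample-weighted variant is available via `site_weights`.

Per-site dispersion is the sample standard deviation (ddof = 1); report
tables round half-up at 2 decimals for display only — internal values are
never rounded.

## Abundance processing

qPCR standard curves follow Ct = slope·log10(copies) + intercept with
slope < 0; copies = 10^((Ct−intercept)/slope) and amplification
efficiency 10^(−1/slope) − 1. Triplicates are collapsed to the mean of
the detected replicates; a sample-gene pair with fewer than `min_detect`
(default 2 of 3) amplified replicates is a non-detect. Whether the
original survey averaged Ct or copies is unstated; copies-averaging is
the default and Ct-averaging (average first, then convert, i.e. a
geometric mean of copies) is a flag.

Non-detects are explicit zeros with a boolean detect mask, never missing
values, so rank correlations stay computable downstream; a gene counts as
"detected at a site" when detected in at least one sample of that site.
Relative abundance divides each gene by the same sample's 16S rRNA
copies; zero or missing 16S is an error naming the sample. No per-gram
unit conversion is imposed — units are opaque metadata because every
downstream statistic is either rank-based or within-sample.

The log transform adds a pseudocount only when zeros are present,
defaulting to half the smallest nonzero value (logged); sqrt needs none.
Both are strictly monotone, so they change ANOVA inputs but not any rank
statistic.

## Group statistics

One-way ANOVA uses the classical between/within decomposition. Degenerate
conventions: zero between- and within-group variance gives F = 0, p = 1;
positive between with zero within gives F = ∞, p = 0.

Duncan's multiple range test compares ordered group means: a pair
spanning p consecutive ranked means differs when the difference exceeds
q(1−(1−α)^(p−1), p, df_error)·√(MSE/n_h), where q is the studentized
range quantile at Duncan's protection level (computed with scipy's
`studentized_range` distribution and memoized, as each numerical
inversion costs ~0.1 s) and n_h the harmonic mean group size — the
surveys this serves routinely have unequal n (e.g. 3 samples on a dam
top vs 9 elsewhere). A pair contained in a span already found
non-significant is non-significant without testing; this containment
rule makes significance an interval structure, so the compact letter
display (insert-and-absorb) yields contiguous letters with 'a' on the
largest mean. The test suite checks the matrix against an independent
recursive statement of the same rule and reconstructs the matrix from
the letters.

Spearman ρ is the product-moment correlation of average ranks. Two-tailed
p uses t = ρ√((n−2)/(1−ρ²)) with n−2 df; |ρ| = 1, where t degenerates, is
assigned the permutation bound 2/n!; and `method="exact"` enumerates all
n! orderings (n ≤ 9), verified against brute-force enumeration. Constant
variables have undefined ρ, reported as NaN rather than 0. No
multiple-testing correction is applied by default, matching common
practice for survey correlation tables; Benjamini–Hochberg is a flag.

## Co-occurrence network

Edges require |ρ| > 0.6 and p < 0.05, both strict, so a pair at exactly
the threshold is excluded. The absolute value is used because strong
negative correlations are biologically informative and are kept (sign is
an edge attribute). The variable set mirrors resistome survey practice:
the seven per-metal Er series plus total RI (category "RI") joined with
per-sample relative gene abundances, 37 variables for the default panel.
Correlations are computed on all samples pooled across sites; the
between-site gradient is part of the signal by design.

Modules maximize modularity on |ρ| weights via seeded Louvain
(`networkx.community.louvain_communities`); a deterministic greedy
agglomeration (`greedy_modularity_communities`) is available as a
seed-free cross-check. Isolated nodes form singleton modules. The hub of
each non-singleton module is the node of maximum within-module degree,
ties broken by larger within-module Σ|ρ|, then lexicographic id; the
tie-break path is logged. Exports (GraphML/GEXF/TSV) round-trip all
attributes; no layout or rendering is computed.

## Synthetic data generator

The generator emulates the study design of a four-site tailings gradient:
3 samples at TD0 and 9 at each of TD1–TD3 (30 total), seven metals with
per-site lognormal marginals moment-matched to the published site
means ± sd, and a 30-gene panel (10 MRGs, 17 ARGs, 2 MGEs, 16S) with
per-gene baselines and site multipliers that reproduce the survey's
qualitative gradient (most resistance genes and total bacteria peak at
the dam-foot site; copper-resistance genes and most ARGs increase
downstream). Gene marginals use a coefficient of variation of 0.5, a
typical spread for qPCR copy numbers across field replicates.

Dependence is a latent Gaussian copula: target Spearman blocks are
converted to latent Pearson correlations by r = 2·sin(πρ/6) (exact for
the bivariate normal), the implied matrix is checked for positive
definiteness (with a nearest-PD suggestion on failure), and samples are
drawn via Cholesky, then pushed through the per-site lognormal quantile
maps. Because the marginal maps are monotone, planted rank correlations
survive; integer rounding of copy numbers adds a small distortion covered
by the ±0.05 recovery tolerance at n = 1000. Structural zeros — e.g. the
default fixture's intI1 absent at TD0 — are applied after sampling and
are exactly zero in every replicate; planting one on 16S is rejected.

The default fixture plants an MRG block co-varying with Cd (ρ = 0.7,
with the sulfonamide gene sulII inside it) and an ARG block containing
the copper gene copB, mirroring the co-selection pattern the pipeline is
meant to detect, so module recovery has a known answer.

What the generator does **not** emulate: spatial autocorrelation along
the gradient (sites are exchangeable groups), compositional closure,
qPCR inhibition or efficiency drift, and detection-limit censoring other
than the planted structural zeros. Passing tests therefore demonstrate
correctness of the computations and recoverability of planted structure,
not robustness to those real-data pathologies.

## Problem sizes and numerics

Recovery experiments run at the smallest sizes that make their tolerances
meaningful: marginal moments at n = 10 000 (within 3 standard errors),
planted Spearman at n = 1000 (±0.05), planted-block module recovery as
mean adjusted Rand index ≥ 0.9 over 20 seeds on 3×8-node graphs, and
sulII-module recovery at 50 samples/site over 20 seeds. Exact Spearman
p-values are enumerated up to n = 7 against an independent oracle.
Duncan quantiles are cached; all pipeline randomness derives from one
master seed via per-stage `SeedSequence([seed, stage_index])`, so stages
are independently reproducible and any derived seed stays below 2^31.
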