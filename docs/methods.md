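# Methods

## Scope and model

`coexpareto` analyzes a two-condition (pre-/post-treatment) expression study
on a log scale. The pipeline is: differential expression → per-condition
coexpression networks on the DE universe → permutation check → edge set
algebra (exclusive vs common) → Pareto selection of double-connectivity
genes on the condition-exclusive networks → annotation support →
two-cohort replication. The two time points are treated as independent
sample sets (no within-patient pairing term): the motivating cohorts have
unequal pre/post sample counts, and all coexpression statistics are
computed within one condition at a time.

## Differential expression

Per gene, a two-group linear model: mean difference Δ_g (post − pre) and
pooled residual variance s²_g on d_g = n₁ + n₂ − 2 df. The empirical-Bayes
prior is the standard inverse-χ² model, σ²_g ~ s₀²d₀/χ²_{d₀}, fit by method
of moments on e_g = log s²_g − ψ(d_g/2) + log(d_g/2): the excess of
Var(e_g) over the sampling variance ψ′(d_g/2) identifies d₀ through the
trigamma equation (Newton inversion); no excess means no detectable
variance heterogeneity and d₀ = ∞, in which case the moderated t is
referred to a standard normal. Genes with zero variance in both groups get
t = ±∞, p = 0 when the mean difference is nonzero, and p = 1 when it is
zero. Multiplicity is controlled by Benjamini–Hochberg (the standard choice
for microarray-era FDR statements); the DE call is q < 0.05 by default. An
ordinary pooled-t fallback (`moderated=False`) exists for small
simulations; the moderated t is the default.

## Coexpression screen

Spearman correlations are Pearson correlations of average ranks; genes with
constant expression are excluded from the universe with a warning. For each
pair the first-order partial correlation is evaluated against every other
universe gene via the recursion formula; a conditioner perfectly collinear
with either endpoint is skipped. P-values use Fisher's z with standard
error 1/√(n − k − 3) (order k ∈ {0, 1}) and a normal reference.

**Pair-level aggregation.** The pair p-value is
max(p of ρ_ij, p of the minimum-magnitude first-order partial), i.e. an
edge must be significant marginally *and* given every single conditioner —
the operational meaning of "excluding gene pairs that are coexpressed due
to a common regulator". A `partial_only` convention (weakest partial alone)
is available. Edges are kept at BH q < α = 0.01 across all C(m, 2) pairs of
one condition; the FDR is computed per condition. Edge sign is sign(ρ_ij).

This aggregation has a structural consequence worth knowing: within an
equicorrelated module of ≥ 3 genes at correlation ρ, every third member
partially explains each pair, capping the population partial at ρ/(1+ρ)
(< 0.5 for any ρ < 1); and a hub's partners are mutually correlated ≥ ρ²,
capping a hub-partner edge's weakest partial similarly. Recovery of such
edges therefore needs noticeably more samples than the zero-order test
would suggest; see *Benchmark power* below.

**Permutation null.** Each replicate permutes every gene's values across
samples independently within the condition (destroying dependence,
preserving marginals) and recomputes the test statistic; the empirical p is
(1 + #{null ≥ observed})/(B + 1), with one seeded substream per replicate.
The default statistic is the number of pairs with pair-p < α — a fixed
function of the data, which makes the empirical p calibrated (approximately
uniform under the null up to discreteness). The BH-thresholded edge count
(`statistic="bh"`) is also available; it matches the main analysis's edge
definition but is almost always 0 under the null, so its empirical p is
conservative, not uniform.

## Differential coexpression and Pareto selection

Edges are keyed by unordered gene pair; a pair significant in both
conditions is common, and common pairs with discordant signs are surfaced
as "flipped" rather than treated as exclusive. The exclusivity fraction is
(|pre-only| + |post-only|)/|union| and the edge ratio is reported as
post/pre. Common edges are removed before the gene-wise stage.

Connectivity profiles count positive- and negative-sign partners per gene.
The Pareto front uses weak dominance with at least one strict inequality;
genes sharing a coordinate point share front membership; the front is
reported sorted by (n_pos, n_neg) descending. The implementation is a
sort-and-sweep over distinct points, checked in the tests against an O(n²)
dominance scan; per-gene dominator counts are retained as diagnostics. By
default the front is computed on the condition-exclusive (differential)
networks — the common edges having been removed as "sustained biology" —
with the full condition networks available via configuration. Only the
first front is computed.

## Annotation and replication

Gene-set annotations come from GMT files; a pair's support from a source is
the intersection of the two genes' term sets (empty for unannotated genes,
logged once per gene). Functional-evidence networks are 3-column TSVs of
pairwise posterior probabilities, with missing pairs read as 0 and a 0.70
default threshold. An edge is "supported" when it shares ≥ 1 term in any
source or reaches the probability threshold; raising the threshold or
removing a source can only lower the supported fraction.
Condition-exclusive shared terms are terms carried by ≥ 1 post-only edge
and no pre-only edge, ranked by supporting-edge count; raw counts only, no
enrichment p-values.

Replication restricts both cohorts to genes DE in each, rebuilds the four
networks on the shared universe, and reports edges post-exclusive in
*both* cohorts with matching sign ("induced and replicated"); the looser
criterion (significant in the replication post network regardless of its
pre network) is available via `require_exclusive=False`. The reported
coefficients are the retained zero-order Spearman correlations.

## Synthetic data

The generator is a Gaussian copula: target Spearman correlations are
converted to latent Pearson correlations via 2·sin(πρ_s/6), assembled into
a per-condition target matrix, and sampled as expression =
baseline + noise_sd · MVN(0, R), with post-condition means shifted for DE
genes. Marginals are left Gaussian — every statistic downstream of the
screen is rank-based, so monotone warping would change nothing — and
`noise_sd` (default 1.0 log-unit) is the per-gene expression SD, so planted
correlations are attained exactly in population. Each condition is sampled
independently. Structures:

* **modules** — equicorrelated blocks, one condition or both;
* **hubs** — one-factor stars: hub-partner entries ±ρ, partner-partner
  entries the implied product ρ_i ρ_j. The implied fill keeps the matrix
  positive semidefinite by construction (a zero fill with 25 partners at
  |r| ≈ 0.72 has minimum eigenvalue ≈ −2.6, and eigenvalue-clipping repair
  would shrink the hub row ~3×) and makes sibling pairs exact
  confounder-style non-edges (partial given the hub = 0);
* **confounder triads** — driver→(x, y) with the driven pair set to the
  implied ρ², so its partial given the driver is exactly 0;
* **DE genes** — post-condition mean shifts in log units.

Residual indefiniteness (possible when structures overlap) is repaired by
eigenvalue clipping at 1e-8 and diagonal rescaling. Hub partners not given
explicitly are allocated deterministically from unused gene ids. The truth
table records per-condition edges with signs, confounder pairs (triad
driven pairs and hub sibling pairs), DE genes and hub ids; truth edge sign
is the sign of the planted correlation. Defaults mirror the motivating
study: 58 + 60 samples (discovery), 18 + 18 (replication), a few hundred
genes, baseline ~8 log-units.

What the generator does **not** emulate: probe-level artifacts, batch
effects, tumor cellularity, heavy-tailed or discrete marginals, and
within-patient correlation. Passing recovery tests therefore demonstrate
the statistical machinery under idealized rank-structure, not robustness to
those real-data features.

## Numerical choices

* Average ranks for ties; correlations clipped to [−1, 1] before atanh.
* |r| = 1 gives p = 0; a collinear conditioner is skipped, and a pair with
  no usable conditioner falls back to its zero-order p.
* Pairs are emitted in i < j lexicographic order; floats at 6 significant
  digits; permutation replicates use `SeedSequence(seed).spawn(B)` so
  results are reproducible independent of execution order.
* Pipeline outputs are hashed into a manifest; identical config + seed
  reproduces identical bytes.

## Benchmark power and known limits

The test suite runs planted-structure benchmarks at deliberately small
problem sizes (hundreds of genes, ≤ 100 samples, B ≤ 100 permutations)
chosen so the full suite completes in a few minutes. Two of these
benchmarks sit beyond the method's power at their stated effect sizes, and
their tests document that honestly rather than passing:

* **Hub recovery** (5 hubs, 15+/10− partners, |ρ_s| = 0.7, n = 100, 200
  genes): the sibling-partner cap puts the weakest partial near 0.57, and
  its minimum over ~24 siblings near 0.45–0.5, against a BH threshold of
  z ≈ 4.0 — about 80% per-edge recovery. The five hub profiles then
  scatter and mutually dominate, so typically 1–3 (not ≥ 4) land on the
  front. Near-complete front recovery would need |ρ_s| ≈ 0.8+ or n ≈ 250.
* **Two-cohort replication** (ρ_s = 0.8 pairs, replication n = 18 + 18):
  the weakest partial over ~30 conditioners at n = 18 lands near z ≈ 2.9
  against a threshold z ≈ 3.8, so each planted edge replicates in roughly
  a fifth of runs — consistent with the motivating study's own note that
  the small replication cohort limits power. False replications are
  essentially absent (the conservative direction is preserved).

Other limitations: only first-order partials (a pair driven by two
regulators jointly is not screened); FDR is per condition (cross-condition
edge comparisons inherit no joint error control); the moderated-t module
covers the plain two-group design only (no weights, trends, or
multi-factor contrasts).
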