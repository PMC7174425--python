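# Methods

This note documents the statistical procedures implemented in `panarch`,
the conventions and numerical choices behind them, what the synthetic-data
generator does and does not emulate, and the known limitations.

## Input filtering

Genomes enter the analysis only if assembled into at most 300 contigs
(`filter_quality`, inclusive bound). Redundant genomes are removed when a
pair has core-genome nucleotide identity at or above a configurable
threshold (default 1.0) *and* gene-content Jaccard similarity above 0.99
(`dedup_genomes`); both conditions are required. Which member of a
redundant pair to drop is statistically arbitrary, so we process pairs in
lexicographic order and keep the smaller genome id — this makes the filter
deterministic and idempotent. Core identity is an input (computed upstream
from alignments), not derived here. A species is analysed only with at
least 10 genomes surviving these filters; `require_min_genomes` raises a
typed error carrying the count so pipelines can report exclusions.

## Pangenome partition

With `f` the fraction of genomes carrying a cluster: core means `f = 1`
exactly ("present in all strains"); extended core means `f > 0.90`
(strict, a superset of the core); cloud means `f < 0.15` (strict); shell
is the complement, so core + shell + cloud equals the pangenome size as an
identity, audited in tests. Unique genes are clusters in exactly one
genome.

## Rarefaction and saturation fits

Pan/core curves are means of cumulative union/intersection sizes over 30
random genome input orders (all `n!` orders optionally, for exact checks
at small n). The new-genes curve is the first difference of the pan curve;
its first point (a whole genome, not gene influx) is excluded from the
decay fit.

Fits use multi-start bounded nonlinear least squares (`scipy
least_squares`, ftol/xtol/gtol 1e-12, up to 10 starts). Starting values
come from log-log (power law) or semi-log (exponential) linear regressions
over a small grid of offset candidates `c`; `k` is constrained positive
where the start is positive. Three-parameter models need at least 4 curve
points, the two-parameter decay at least 3. A best-fit exponent with
magnitude below 1e-10 is reported as exactly 0: a flat curve satisfies the
model for any `k` at exponent 0, and snapping resolves that degeneracy in
favour of the saturated label. Openness: pan power law γ ≤ 0 closed,
0 < γ ≤ 1 open, γ > 1 undefined; new-genes decay α < 1 open, α > 1
closed, α = 1 undefined; unconverged fits are undefined.

## Scalar features

* **Fluidity** φ: mean over unordered genome pairs of
  `(U_i + U_j)/(M_i + M_j)`. Genomes with zero genes make a pair
  undefined and raise.
* **Chao lower bound**: `S_obs + Q1²/(2·Q2)`; when no doubletons exist the
  bias-corrected `S_obs + Q1(Q1−1)/2` is used (the standard small-sample
  form; the original ratio is undefined there).
* **Normalized sizes**: means of core/pan sizes over 30 distinct random
  9-genome subsets; when fewer than 30 subsets exist all are enumerated,
  which also makes the result seed-invariant.
* **Nucleotide diversity** π: mean over sequence pairs of differing sites
  per compared site. Gap/ambiguity columns (`- . N ?`) are excluded *per
  pair*, not listwise, to maximize usable sites; a site-wise
  heterozygosity estimator is available behind `method="sitewise"` for
  sensitivity analysis, since the literature uses several near-equivalent
  definitions.
* **Functional distance**: mean pairwise Jaccard distance between
  genomes' orthologous-group sets. Genomes without annotations are
  excluded with a warning rather than treated as empty sets — an empty
  set would force distance 1 for all its pairs and bias the mean upward.

All stochastic operations take explicit integer seeds;
`compute_feature_set` fans one species-level seed out to sub-operations
with fixed offsets.

## Habitat associations and ubiquity

Evidence is a sample × species incidence table with exactly one habitat
label per sample. Each (species, habitat) pair yields the 2×2 table
(present/absent × in-habitat/out-of-habitat) tested with Fisher's exact
test — two-sided by default, with positivity decided by odds ratio > 1; a
one-sided "greater" variant is available since either reading of
"positive association" is defensible. The reported odds ratio is the
sample cross-product ratio (declared in the docstring; infinite when
b·c = 0 with a·d > 0). BH adjustment runs once across all species ×
habitat tests, and the significance threshold 0.05 applies to the
*adjusted* values. Ubiquity is the count of positive associations.

Gene-catalogue evidence reduces to binary habitat presence by the rule "at
least 10 genes of the pangenome detected in at least one sample of the
habitat". Presence tables from multiple annotation sources merge under a
source-prefixed namespace (e.g. `atlas:soil`) so descriptor collisions
are impossible by construction and duplicates raise.

## Principal components and broken stick

The phylogenetic predictor matrix is the species × species cophenetic
(patristic) distance matrix; the habitat predictor matrix is the binary
species × habitat table. Both are decomposed by centered PCA with column
standardization on by default (matching correlation-PCA conventions);
constant columns are dropped with a warning. The default pipeline keeps
fixed counts — 5 phylogenetic and 10 habitat PCs — with broken-stick
selection (`b_k = (1/p)·Σ_{i=k..p} 1/i`, strict >, stop at first failure)
available as the principled alternative; the selection mode is recorded in
outputs. Whether to standardize a distance matrix before PCA is genuinely
ambiguous; both modes are exposed (`scale_columns`).

## Pagel's lambda and PGLS

The Brownian covariance `C[i,j]` is the shared root-to-MRCA path length
(root edge excluded). The λ transform scales off-diagonal entries only.
The trait likelihood is multivariate normal with mean μ and covariance
σ²·V(λ); μ and σ² are profiled analytically through the Cholesky factor
of V, and λ is maximized over `[0, λ_max]` where λ_max is the largest
value keeping V positive definite (found by bisection, at least 1, capped
at 10). Optimization is a bounded scalar search bracketed by an 11-point
grid (tolerance 1e-8). The 95% CI comes from the profile likelihood at
the χ²₁ cutoff; the test against λ = 0 is a likelihood-ratio test. On a
star phylogeny the likelihood is flat in λ and the result is flagged
degenerate with the full interval as CI. The implementation was verified
against an independent reference implementation on a fixed 8-tip fixture
(agreement ~1e-5 in λ̂, ~1e-8 in log-likelihood; frozen in the test
suite).

PGLS estimates `y = Xβ + ε`, `ε ~ N(0, σ²V(λ))`, with β profiled by
whitened least squares and λ by the same scalar ML search (or fixed by the
caller). Rank-deficient designs raise with the names of the dependent
columns. Partial R² for covariate j is
`(SSE_reduced(j) − SSE_full)/SSE_reduced(j)` computed in the V(λ̂)-whitened
space — one of several partial-R² conventions, declared here because no
single definition is canonical.

## CAR-score variance partition

Predictors are standardized to zero mean and unit variance;
`ω = R_XX^(−1/2)·r_Xy` with the inverse square root taken through the
symmetric eigendecomposition of the predictor correlation matrix. Near
singular correlation matrices (minimum eigenvalue < 1e-10) either raise
or, by default, receive an eigenvalue ridge of 1e-8 (declared in the
API). `Σω²` equals the least-squares R² (machine-precision identity,
tested to 1e-10), so block shares — sums of ω² over each block's
columns — decompose R² additively and order-independently. Three model
variants differ only in blocks: the base model (number of genomes +
phylogenetic PCs + habitat PCs) and two covariate-adjusted variants
adding mean genome size or core nucleotide diversity. Species with any
missing value are dropped listwise and counted. The permutation null
shuffles whole rows of the phylogenetic and habitat blocks (preserving
intra-block correlation), both blocks in the same run by default with
independent orders — separate per-block runs are available since either
protocol is defensible; empirical p-values are add-one corrected.

## Associations

Feature–feature correlations are pairwise-complete Spearman (mid-rank
ties, minimum 5 complete pairs); feature–habitat correlations are
point-biserial; BH runs once over the upper triangle, pooling both
families by default (a flag separates them). Feature clustering is
average-linkage (configurable) hierarchical clustering on `1 − |ρ|`,
processing labels in sorted order so results do not depend on input
column order; the default flat cut is two groups, reflecting the expected
size-like vs diversity-like split. Habitat contrasts of single features
use the tie-corrected two-group Kruskal–Wallis test.

## Synthetic worlds

The generator emulates the statistical structure the pipeline assumes,
with defaults chosen as realistic study conditions: ~150 species on a
birth–death tree; per-species genome counts uniform on 10–30; a core of
1,500 gene clusters; a 2,000-cluster accessory pool whose carriage
frequencies are Beta(0.3, 0.7) — giving the U-shaped gene-frequency
spectrum real pangenomes show — with each genome gaining Poisson(20)
never-seen-before genes (the influx that makes pangenomes open); core
alignments on a star genealogy solved to hit a target π of 0.02; 20
habitats with Bernoulli(0.25) species preferences; 50 samples per habitat
detected at 0.9 in-habitat vs 0.02 out-of-habitat. A latent species-level
size trait (Brownian with λ = 1 plus additive habitat effects plus noise)
modulates the accessory-pool size, so habitat and phylogeny propagate
into measurable features. Ground truth (realized, not merely configured:
variance decompositions are recomputed from the actual draws) is stored
with every world, and identical seeds give byte-identical worlds.

`simulate_partition_benchmark` builds the sharper calibration world for
the variance partition: the feature is an explicit linear combination of
the leading phylogenetic and habitat PC scores plus white noise, scaled
to target shares (defaults 0.2 phylogeny / 0.5 habitat), with realized
shares recorded. Recovery there is limited mainly by finite-sample
overfitting of R² (roughly p/n ≈ 0.1 spread over 16 predictors at
n = 150), visible as a small upward bias in the estimated shares.

What the generator does **not** emulate: gene gain/loss along the tree
between species (gene content is phylogenetically structured only through
the latent size trait), realistic sequence evolution (no rate
heterogeneity or GTR), habitat correlations between related species, and
multi-label samples. Passing recovery tests therefore demonstrate
correctness and calibration of the estimators under the stated model, not
robustness to every property of real survey data.

## Problem sizes in tests and the acceptance script

Exactness checks enumerate all genome orderings at n ≤ 5 and all 2×2
tables at small totals; recovery experiments use 100–200 replicates on
100-tip trees for λ, 20 worlds of 150 species for the variance partition
(200-permutation nulls), and 50–100 incidence replicates at 50 samples
per habitat for ubiquity. The demonstration world in the acceptance
script uses 30 species with 800 core + 1,200 accessory clusters and
2,000-site alignments — large enough for stable feature estimates while
keeping a full pipeline run in seconds.

## Known limitations

* The core-diversity estimator treats every column pair independently; it
  does not correct for multiple hits (no Jukes–Cantor correction), which
  is negligible at the within-species divergences it targets (π ≪ 0.1).
* λ_max is capped at 10; trees whose structure admits larger λ are
  clamped (irrelevant for inference bounded at 1 but reported λ̂ may sit
  on the cap for pathological trees).
* CAR shares inherit R² overfitting at small n/p; no small-sample
  adjustment is applied — the permutation null is the intended guard.
* The Fisher-based ubiquity definition cannot flag a habitat for species
  present in nearly all habitats (no out-habitat background to be
  enriched against); ubiquity is well defined only when habitat
  membership is sparse relative to the habitat vocabulary.
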