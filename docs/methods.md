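# Methods

## Model and procedure

`igan` treats cell–cell communication as a statistical dependence problem
between the transcriptomes of spatially adjacent cells. The pipeline has five
stages.

**Spatial adjacency.** Cells a and b are adjacent when 0 < d(a, b) ≤ τ in
the slide plane. For bead platforms τ is the 99th percentile (linear
interpolation between order statistics) of per-cell nearest-neighbor
distances, which tracks the packing scale while ignoring stray beads; for
regular grids τ is the minimum pairwise distance, i.e. the grid pitch.
Coincident cells are never adjacent; isolated cells are kept with t_a = 0
neighbors and zero activity.

**Pair scatters and the association test.** For an ordered type pair (A, B),
the n adjacent pairs (a_k, b_k) define, for each (source gene x, target gene
y), a scatter of x in the a-cells against y in the b-cells. The x-window of
focal pair k holds the ⌈b·n⌉ pairs nearest to x_k by value (default window
fraction b = 0.1), with ties broken by pair index and the focal pair always
included; the y-window is analogous. Under independence of x and y with
continuous values, window memberships on the two axes are independent given
the window sizes, so the joint occupancy satisfies exactly

    n_xy − 1 ~ Hypergeometric(n − 1, n_x − 1, n_y − 1).

The classical standardized statistic
ρ̂ = (n_xy/n − n_x n_y/n²) / sqrt(n_x n_y (n−n_x)(n−n_y)/(n⁴(n−1))) is
reported by `association_statistic`, but thresholding ρ̂ at the normal
quantile is anticonservative here: the focal pair counted in both windows
shifts the null mean of n_xy up by ≈ (1 − n_x/n)(1 − n_y/n), which is close
to one full pair, and a one-pair shift is ~0.4 standard deviations at the
default window size. The measured size of the normal rule at α = 0.01,
n = 500, b = 0.1 is 0.038. The default decision rule therefore uses the
exact hypergeometric tail (size 0.0044 under the same conditions —
conservative because the count is discrete); `null="normal"` restores the
normal-quantile rule for comparison with other window-statistic
implementations. The test is one-sided for excess co-occupancy; note that
any monotone relation, of either sign, concentrates the two windows on the
same pairs, so the upper tail detects negative as well as positive monotone
dependence. Tests run on normalized expression (library-size scaling to the
median depth, then log1p); genes constant across the pairs are degenerate
and never fire.

**Activity.** For cell a with t_a neighbors, sending activity on ligand i is
(Σ_k Σ_j H_ij^(a b_k)) / t_a and receiving activity is the same sum over
incoming networks H^(b_k a); CCC strength is the sum over ligands of both.
Cells with t_a = 0 have zero activity by convention. Neighbors whose
type-pair block was skipped (fewer than `min_pairs` pairs, default 10)
contribute nothing but still count in t_a, keeping t_a purely spatial.

**Pathways.** Downstream genes of a ligand are targets associated in more
than `frac`·N of the N tested pairs (strict inequality, default frac = 0.01).
Because the null association rate is close to the test level, this screen
only separates signal from noise when the per-test α sits well below frac;
the recovery experiments therefore screen at α = 0.001 while the package
default for exploratory network construction stays α = 0.01. Enrichment is
one-sided hypergeometric over-representation against the tested target genes
as universe (not the genome — the tested universe is already restricted),
with Benjamini–Hochberg correction at q < 0.05. A pathway enters the Sankey
graph only if it is enriched in a ligand's downstream genes and contains at
least one subunit of a receptor cognate to that ligand; the receptor→pathway
link weight is the number of downstream genes inside the pathway, drawn per
(ligand, receptor, pathway).

**Patterns and the benchmark.** The communication matrix C (cell types ×
ligands, one per direction) holds, for each type, the sum over partner types
of the mean per-pair associated-target load of each ligand. The
microenvironment matrix E tabulates cell types against microenvironment
categories obtained by k-means clustering of neighborhood cell-type
compositions (a deliberately simple composition-clustering stand-in for
dedicated microenvironment callers; the composition radius should be
regional, i.e. several adjacency thresholds, rather than the test adjacency
itself). Both matrices are column-scaled to max 1 and factorized with
multiplicative-update Frobenius NMF at a common rank k (seed-fixed random
init; `rank_scan` reports the error elbow). The consistency score is

    KL_w = Σ_i Σ_j W_type^i · W_pattern^j · Ea_ij · log(Ea_ij / Ca_ij)

with Ea, Ca the row-normalized type loadings (floor 1e−12), W_type the
cell-type proportions and W_pattern the E-basis row sums. NMF pattern order
is arbitrary, so C patterns are first aligned to E patterns by the
permutation minimizing the total score; the score is separable across
pattern columns, which makes the optimal alignment an assignment problem
solved exactly (and verified against exhaustive search for small k).
KL_w = 0 for identical aligned loadings and is invariant to any column
permutation of the C decomposition. It is not mathematically guaranteed
nonnegative for arbitrary pattern weights — a row's weighted sum can dip
below zero if large weights concentrate on terms where Ca exceeds Ea — but
it is nonnegative with large margin for decompositions drawn from
nonnegative random factors, and negative values did not occur in 2000
random draws.

## Synthetic data

The generator emulates the statistical structure the association test
assumes: independent baseline expression with planted dependence across
adjacent cells. Baselines are zero-inflated negative binomial per gene and
cell, with gene means spread lognormally (spread 0.3) around a common level.
Defaults — mean 10, dispersion 8, zero inflation 0 — describe a moderately
expressed curated panel at spot resolution; sparser data are available via
`zero_inflation`.

Couplings act through a Gaussian copula. Each source cell's count is mapped
to a latent standard normal score by randomized probability-integral
transform of its discrete marginal (exact uniforms); each target cell with
source-type neighbors re-draws its target-gene count from the quantile
function at Φ(r·z̄ + sqrt(1−r²)ε), where z̄ is the sqrt(t)-scaled mean of
its t source-neighbor scores. Marginals are preserved exactly, every
adjacent (source, target) pair carries rank correlation ≈ r/sqrt(t), and
the correlation equals r when each target has a single source neighbor.

Three preset geometries cover the test scenarios:

- `boundary` — two abutting strips; each interface cell has exactly one
  cross-type neighbor, so the planted pair correlation equals r. Used for
  calibration and recovery experiments (2 × 200 cells, one coupling at
  r = 0.9 by default).
- `checkerboard` — two interleaved types on a unit grid; each cell has up to
  four cross-type neighbors (pair correlation r/2 at full mixing).
- `blocks` — the benchmark fixture: a lattice of isolated signaling dimers
  (one primary-type cell and one shared partner cell, nearest-neighbor
  distance 1 within a dimer and > 1 between dimers, so each cell has exactly
  one adjacent cell and couplings act at full strength). Dimer columns form
  bands of unequal width whose primary types are staircase mixtures of the
  four primaries, and each primary signals to the partner type with a
  staircase ligand-intensity profile (4/2/1 coupled target genes). The
  staircase structure on both sides is deliberate: every cell type has a
  unique, overlapping band profile and a unique, overlapping ligand profile,
  so no row permutation of the communication matrix can be absorbed by the
  pattern-alignment step. Block-diagonal designs are not identifiable in
  this sense — for a permutation-matrix-like C, aligning patterns undoes any
  row shuffle exactly — and per-pair correlations diluted below ≈ 0.7 fall
  under the test's power floor, which is why the fixture pins t = 1.

What the generator does not emulate: segmentation errors, spatial expression
gradients within a type, platform-specific noise (bead sharing, diffusion),
ambient RNA, or receptor-level mechanisms — couplings are direct
gene-to-gene. Passing tests on these fixtures show that the statistics,
aggregations and benchmark behave as designed under their own assumptions,
not that the method resolves real tissue biology.

## Numerical and design choices

- **Window ties.** Nearest-by-value windows break ties by pair index,
  deterministically. With heavily tied values (zero-inflated counts) the
  shared index tie-break correlates the x- and y-windows of tied cells and
  inflates the null rate; normalization leaves ties only at zero, and the
  generator's default panel keeps zeros rare. This is a documented
  limitation for very sparse real data.
- **Repeated cells.** When a cell participates in several pairs, scatter
  points are dependent and the exact-null assumption bends; the measured
  background inflation is roughly two-fold on dense geometries. Quantities
  built from H (activity, C) inherit this as a roughly type-uniform offset.
- **Normalization interplay.** Library-size normalization divides out
  signal shared across many genes of a cell: if a large fraction of a cell's
  panel is driven by the same source, the planted association weakens after
  normalization. Synthetic panels keep coupled genes ≤ ~25% of the panel.
- **Screening level.** The downstream-gene rule (count > 0.01·N) equals the
  null expectation when tests run at α = 0.01, so screens use α = 0.001
  (chosen from the closed-form binomial analysis, where the null selection
  probability drops from ~5% to ~0.02% per gene).
- **Clustering.** Features are log1p-transformed, z-scored per feature, and
  reduced by PCA with component variances kept — scaling every PC to unit
  variance would amplify noise directions to signal level. For combined
  mode, each block of PCs (expression, CCC features) is normalized to unit
  mean squared norm and the CCC block scaled by the weight w (default 1.0).
  Communities come from Leiden modularity (RBConfiguration, fixed seed) on a
  Jaccard-weighted shared-nearest-neighbor graph. Discrete communication
  features produce many duplicate rows, and a kNN graph fragments once
  duplicate multiplicity exceeds k (no edge ever bridges two value levels);
  duplicates are therefore collapsed to single nodes with
  multiplicity-weighted edges and c(c−1)/2 self-loops, which is equivalent
  to modularity on the fully expanded per-cell graph and identical to the
  plain construction when all rows are unique. Per-cell communication
  features are sparse counts: with a p-ligand program firing at rate f per
  target, role separation scales like sqrt(#targets · f), so small planted
  programs yield partial role recovery (a mixed low-activity cluster) even
  when population means separate clearly.
- **Degenerate inputs.** Zero-threshold coordinates, all-zero matrices,
  empty pair sets and too-few-pairs scatters raise typed errors; the CLI
  maps them to exit code 4 (config errors 2, data errors 3).
- **Determinism.** All stochastic steps (simulation, k-means, NMF, Leiden)
  take explicit seeds; `run-all` with a fixed seed is byte-reproducible.

## Problem sizes

Unit and acceptance tests run on simulated fixtures sized to exercise the
statistics meaningfully: calibration on a 2 × 500 boundary strip with a
50 × 50 gene panel (1.25M tests), recovery on twenty 2 × 200 replicates,
the benchmark on twenty 28 × 20-dimer slides (1120 cells, 25 genes), and
consistency checks on 50–100-cell fixtures. The full suite and the
acceptance script each complete in well under a minute of compute per
experiment on a single CPU.

## Known limitations

- The exact conditional null assumes exchangeable distinct values; ties and
  repeated cells make it approximate (conservative overall in our
  experiments at the calibration scale, slightly inflated on dense
  geometries with heavy repetition).
- Power requires strong per-pair rank correlation (ρ ≳ 0.7–0.8 at n ≈ 200,
  b = 0.1); diffuse many-neighbor signaling dilutes per-pair correlation by
  1/sqrt(t) and can fall below the detection floor.
- The window statistic detects monotone dependence of either sign; the
  "sending" interpretation does not distinguish activation from repression.
- The microenvironment stand-in clusters one-hop (or user-radius) type
  compositions only; it is not a replacement for dedicated
  microenvironment callers.
- Enrichment uses the tested-gene universe; results are relative to the
  chosen panel, not the genome.
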