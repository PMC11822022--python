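# Methods

`cohortnet` compares the pairwise-association structure of two participant
cohorts measured on a mixed battery of binary, ordinal and continuous
variables. This note records the statistical model, the conventions the
implementation commits to, and what the synthetic test bed does and does
not establish.

## Association networks

Every pair of variables receives an unregularised, non-parametric
association coefficient chosen by the types of the pair:

| | binary | ordinal | continuous |
|---|---|---|---|
| **binary** | phi | point-biserial | point-biserial |
| **ordinal** | point-biserial | Spearman | Spearman |
| **continuous** | point-biserial | Spearman | Spearman |

All three are Pearson correlations on a coding: 0/1 values for phi and
point-biserial, mid-ranks (ties averaged) for Spearman. This equivalence is
what the test suite exploits (a plain Pearson oracle checks every
estimator) and what makes network construction fast: with complete data the
whole matrix is two `corrcoef` evaluations (raw and rank-transformed
columns) with per-pair selection. No partial correlations, no shrinkage:
edges are marginal associations, and the scientific questions are asked of
*differences* between cohorts, which cancels most scale concerns between
edge types.

Conventions the data do not dictate, fixed here once:

- **Missing data** are MCAR in the generator and handled by
  pairwise-complete deletion per edge; the per-edge complete count is kept
  in `n_effective`. When any missingness is present construction falls back
  to an exact per-pair loop (Spearman re-ranks within each complete pair
  subset).
- **Undefined edges** (a variable constant within a cohort or a permutation
  replicate) get weight 0 and a flag, with a warning naming the variable.
  This keeps matrices comparable across permutation replicates instead of
  dropping nodes mid-test.
- **Ordinal coding** is integer ranks 0..k−1 in declared category order.

## Graph measures

Strength (sum of incident |weights|), eigenvector centrality (principal
eigenvector of the |weight| matrix, nonnegative, unit L2 norm, dense
symmetric eigensolver) and the Onnela weighted clustering coefficient
(geometric mean of triangle weights, normalised by the network's maximum
|weight|; nodes with < 2 neighbours score 0). Global strength is the sum of
the |weight| upper triangle; global clustering the mean of nodal values.

All node-importance measures use **absolute** weights. The networks are
signed correlation matrices; standard weighted-graph routines assume
nonnegative input, and a single unsigned convention keeps the three
measures mutually comparable. This choice is recorded in every metrics
export (`weight_convention`). Network *distance* — the Euclidean norm of
the difference of the signed upper triangles — keeps signs, since it
compares networks rather than ranking nodes. No shortest-path measures are
offered: with three differently scaled edge types, path lengths have no
clean interpretation.

## Permutation inference

Cohort contrasts are label permutations preserving group sizes. The
observed statistic is always `stat(pain) − stat(nopain)`; both networks are
rebuilt from scratch in each of the `n_perm` (default 10,000) replicates.
Two-tailed p-values double the smaller tail: the count of null values at
least as extreme as the observed one on its own tail, divided by `n_perm`,
doubled and capped at 1. Per-tail doubling rather than |null| ≥ |observed|
was chosen because it stays well defined for asymmetric nulls (cluster
sizes, distances). The count is floored at 1 — the smallest reportable p is
2/n_perm (one-tailed 1/n_perm); a permutation test cannot certify p = 0.
95% percentile intervals of the null (2.5th/97.5th) accompany every test.
Nodal contrasts (strength, eigencentrality, clustering per node) are
corrected by Benjamini–Hochberg FDR at q = 0.05 (statsmodels
implementation, verified in tests against an independent sort-and-scan
oracle).

### Sample-size sufficiency

For each subsample size s, the distance between the network of s random
pain participants and the general (everyone) network is compared to the
band of the same distance over `n_perm` (default 1,000) random s-subsets of
all participants. The reported detection threshold is the smallest s whose
pain distance exceeds the 97.5th percentile of the random band; the
normalised curve subtracts the per-size random median.

### Edge-cluster statistic

The cluster statistic thresholds the absolute pain−nopain difference
matrix, keeps edges with |difference| > threshold, and scores the connected
component containing the most **edges** (edge counts, not node counts, per
the network-based-statistic family). Inference is one-tailed against the
largest-cluster sizes of label permutations. The threshold grid (default
0.025–0.05, step 0.001) shares a single permutation set across thresholds,
which removes Monte-Carlo noise from the sweep's shape; per-edge output is
the fraction of thresholds at which the edge sits inside a significant
(α = 0.05) cluster. Edge direction signs are taken from the observed
difference matrix only.

A scale caveat measured in the acceptance suite: the fixed 0.04 threshold
is calibrated to registry-scale cohorts (tens of thousands), where it sits
at ≈ 3 SEs of an edge difference. At the desk-scale defaults (thousands)
the same threshold admits ≈ 20% of null edges, the permutation null
becomes one giant component, and the test retains its type-I control but
loses most of its power. Threshold choice should track the edge-difference
standard error (≈ √(1/n₁ + 1/n₂)) if the method is applied at small n.

## Consensus communities and layout

Louvain (networkx implementation, resolution 1) is run `n_runs` (default
1,000) times on absolute weights with sub-seeds drawn from the master seed.
The co-assignment frequency matrix of the runs is thresholded at tau
(default 0.5, sub-threshold entries dropped) and re-clustered the same way,
iterating until every run returns the identical partition
(Lancichinetti–Fortunato consensus). The first-round consensus matrix is
kept for inspection. Node coordinates come from the Fruchterman–Reingold
layout (k = 0.03, seeded) with |weights| as attraction strengths.

## Synthetic cohorts

The generator is a latent Gaussian copula: each participant draws a latent
multivariate-normal vector with a cohort-specific correlation matrix;
discrete variables threshold their latent coordinate at fixed cutpoints
(binary: 1 cutpoint, k-level ordinal: k−1), continuous variables are the
latent coordinate itself. This produces exactly the margin types the
estimator grid expects with fully controllable dependence, and gives a
closed-form oracle for continuous pairs (Spearman = (6/π)·arcsin(ρ/2)).

The default "stated world":

- 30 variables: 10 binary (prevalences cycling 0.5/0.3/0.15), 10 four-level
  ordinal (cumulative level probabilities 0.4/0.7/0.9), 10 continuous.
- Three latent blocks in round-robin assignment (variable i in block i mod
  3), latent ρ = 0.35 within blocks, 0.05 between. Round-robin mixes the
  three variable types within every block so planted communities are not
  confounded with estimator type.
- Cohorts of 1,000 ("pain") and 2,500 ("nopain"), preserving the ≈ 1 : 2.5
  ratio of the motivating registry cohorts at desk scale.
- Between-cohort effects are planted by adding `effect_delta` to the latent
  correlations of a connected block of pairs — by default the clique over
  six ordinal/continuous members of block 0 — in the pain cohort only. The
  planted profile avoids binary variables because binary margins attenuate
  latent correlation differences the most; the motivating difference
  cluster is likewise dominated by scale-type items. The perturbed matrix
  is PSD-repaired by eigenvalue clipping (floor 1e−8); the repair must not
  move any non-planted entry by more than 1e−3, otherwise the spec is
  rejected.
- Missingness is MCAR at a configurable rate, default 0 (the motivating
  registry reports no missingness mechanism; tests exercise the
  pairwise-complete path explicitly).

What a green synthetic test establishes: correct arithmetic, exact
estimator/oracle agreement, seeded reproducibility, type-I control of the
permutation machinery, and recovery of planted dependence structure. What
it does not: realism of the 103-variable registry margins, informative
missingness, selection effects, or any claim about the real cohorts'
effect sizes.

## Numerical choices

- Nearest-PSD repair: eigenvalue clipping at 1e−8 with diagonal
  re-standardisation, iterated (≤ 50) until valid.
- Latent draws use an eigendecomposition factor rather than Cholesky, since
  repaired matrices may be exactly singular.
- Eigenvector centrality: dense `eigh`, sign fixed to the nonnegative
  orientation, numerical dust clipped at 0 before renormalising.
- Largest-cluster ties (equal edge counts) break toward the component
  containing the lexicographically smallest node label.
- Permutation sub-seeds derive from `numpy.random.default_rng(master_seed)`
  and stay below 2³¹.
- CSV round-trips write floats as `%.17g` and read with pandas'
  `round_trip` parser, so write→read is bit-exact including NA markers.

## Known limitations

- The multilayer nature of the edge set (phi vs Spearman scaling) is
  handled only by contrasting like with like across cohorts; no cross-type
  edge harmonisation is attempted.
- The mixed graphical model cross-estimate reported alongside the
  motivating analysis is out of scope.
- Pairwise-complete deletion can make the weight matrix slightly
  non-Gramian under heavy missingness; downstream measures tolerate this
  but no correction is applied.
- The cluster statistic's power depends sharply on threshold × sample-size
  calibration (see above).
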