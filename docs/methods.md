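# Methods

## Model

Scores for the 13 TGMD-3 skills are modelled jointly as a Gaussian
Graphical Model (GGM): a zero in the precision (inverse covariance)
matrix Θ means two skills are conditionally independent given all
others.  The reported network has edge weights

    w_ij = −Θ_ij / √(Θ_ii Θ_jj),

the partial correlations.  Θ is estimated by graphical lasso — penalized
maximum likelihood with an L1 penalty λ on the off-diagonal entries —
which produces exact zeros and hence a sparse, interpretable network.

Scores are bounded integers, not Gaussian; the pipeline follows the
common practice of applying the GGM to Pearson correlations of the raw
scores.  With 6–10 ordered categories per skill this attenuates
correlations only mildly (measured below 7% on the synthetic model);
polychoric correlations are a possible refinement and deliberately not
implemented in this version.

### Penalty selection

λ is selected on a descending log-spaced grid (`nlambda = 100`,
`min_ratio = 0.01`, from λ_max = max |off-diagonal correlation|) by
minimizing the Extended Bayesian Information Criterion,

    EBIC(λ) = −2 ℓ(Θ̂_λ) + E log n + 4 E γ log p,

with ℓ the profile log-likelihood (n/2)(log det Θ − tr(CΘ)), E the edge
count, and γ ≥ 0 trading fit against sparsity.  The default γ = 0.25 is
the moderate setting appropriate for panels with n ≫ p.  Ties in the
argmin resolve to the larger λ (the sparser model).

### Small-edge thresholding

EBIC selection under L1 shrinkage has a known bias: when true edges are
strong, the likelihood keeps improving as λ shrinks below the point
where the true support is recovered, so the selected model admits a few
near-zero noise edges (empirically 3–10 edges with |w| < 0.022 at
n = 5000 on the default synthetic model).  `select_network` therefore
zeroes edges of the selected network with

    |w_ij| < sqrt(log(p(p−1)/2) / n)

(≈ 0.03 at n = 5000, p = 13), the standard small-edge threshold for
EBIC-glasso networks.  On the default synthetic model this removes every
false edge while leaving all true edges (|pcor| ≥ 0.1) untouched.  Pass
`threshold=False` for the raw selected network (edges then defined by
|w| > 1e-8, the numeric noise floor).

### Solver

The graphical lasso is solved by block coordinate descent (column-wise
lasso subproblems solved by cyclic coordinate descent), jit-compiled
with numba and warm-started along the λ path, so a full 100-point path
on 13 variables takes ~3 ms.  Convergence uses the conventional
criterion: largest change in the working covariance below
`tol × mean |off-diagonal of C|`, with `tol = 1e-4`.  The test suite
cross-checks the solver against scikit-learn's `graphical_lasso`
(agreement ≈ 1e-4 elementwise) and against closed forms (λ = 0 →
matrix inversion; λ ≥ max |off-diagonal| → empty network).

## Centrality

All statistics use absolute edge weights.  Distances are Dijkstra
shortest paths on edge lengths 1/|w|.  Conventions:

- strength: Σ_j |w_ij|; bridge strength: the same sum restricted to the
  other community.
- closeness: inverse **sum** of distances to reachable nodes; bridge
  closeness: inverse **mean** distance to reachable out-community nodes.
  The asymmetry is deliberate and matches the bridge-centrality
  convention in the psychometric network literature.
- betweenness and bridge betweenness: Brandes accumulation with
  fractional credit on tied shortest paths (ties compared with relative
  tolerance 1e-12); bridge betweenness sums only over cross-community
  pairs.  An integer "count all" mode (full credit to every node on any
  tied path) exists for cross-checks, since the tie convention of
  legacy implementations is not always documented.
- unreachable nodes are excluded from sums; an isolated node scores 0.

Communities are fixed by the instrument (locomotor vs ball skills),
never inferred from data.

## Bootstraps

**Accuracy.** Nonparametric bootstrap (default B = 1000): resample rows
with replacement, re-run the entire estimation, record every edge weight
and every statistic; report replicate means and percentile CIs (2.5th /
97.5th quantiles, linear interpolation).  Replicates that fail
estimation (degenerate resample) are recorded and excluded, with a hard
10% failure ceiling.  *Interpretation caveat:* percentile CIs of
regularized edge weights describe sampling variability around the
L1-shrunk estimate; because shrinkage biases weights toward zero by
roughly λ, these intervals are not unbiased intervals for the
generating value and their coverage of the truth can be far below
nominal for strong edges.  CIs for centralities inherit the same
property.  This is a property of the method, not of the implementation.

**Stability.** Case-dropping subset bootstrap: for drop proportions
0.05–0.75 (step 0.05), draw `B_per_level` subsamples without
replacement, re-estimate, and correlate each statistic's per-node vector
with the full-sample vector (product-moment; Spearman could be added
behind the same interface).  The correlation stability coefficient
CS(cor = 0.70) is the largest drop proportion whose empirical 5th
percentile of correlations — and that of every smaller tabulated
proportion, a monotone qualification that prevents non-monotone noise
from inflating CS — is at least 0.70.  CS > 0.25 is reported as
acceptable.  `B_per_level` defaults to 250 to keep a full run
desk-scale; reference implementations often use more.

**Determinism.** Replicate r draws from a child seed derived from
(seed, r) via NumPy's `SeedSequence`, so results are bit-identical
regardless of execution order, and two pipeline runs with the same
config produce byte-identical output trees (the manifest stores no
wall-clock values or absolute paths).

## Group comparison

Two strata differ on a (statistic, node) cell when their bootstrap CIs
share no point; touching endpoints count as overlap.  Default contrasts
are the three age pairs (3–5 vs 6–8, 6–8 vs 9–11, 3–5 vs 9–11), marked
*, °, + in reports.  No multiple-testing correction is applied — the
criterion is already conservative — and reports carry the number of
comparisons.  Comparing bootstrap distributions from strata of very
different n does not fully account for differences in the weight
distributions across groups; the comparison should be read as
descriptive.

## Synthetic data generator

The generator emulates the structure of a large TGMD-3 assessment
campaign while keeping the generating network known exactly:

- **Precision matrix.** 13 nodes in two communities (6 locomotor, 7
  ball).  Within-community edges placed with density 0.4; magnitudes of
  the off-diagonal precision entries drawn from [0.15, 0.30] with 10%
  negative signs (skill relations are predominantly positive).  The
  cross-community backbone is fixed by design: running and two-hand
  catching are hubs carrying the largest cross-community weight totals
  (0.16–0.22 each to three partners), plus one weaker slide–underhand-
  throw edge; every hub has at least two cross-community partners.
  Positive definiteness is enforced by diagonal loading in steps of
  0.05 until the smallest eigenvalue is ≥ 0.05 (loading shrinks all
  implied partial correlations uniformly; the default spec needs none
  and has all true |pcor| between 0.10 and 0.30 by construction,
  verified at build time).
- **Scores.** Latents are zero-mean Gaussian with the spec's precision;
  each standardized latent is cut into `score_max + 1` equal-probability
  bins of the standard normal — a monotone, rank-preserving map onto
  0..score_max, so Pearson correlations of scores approximate the latent
  correlations.  Per-skill maxima default to (8,8,8,8,6,8) and
  (10,8,8,6,8,8,6): only the subscale totals (46 locomotor, 54 ball) are
  fixed by the instrument, so the split across skills is configurable.
- **Age strata.** One panel per age group at sizes 3525 / 7882 / 5582
  (the assessed cohort sizes), sharing structure but with off-diagonal
  precision entries multiplied by connectivity scales 1.0 / 0.7 / 0.5 —
  older children's skills decouple as abilities consolidate.  The age
  effect is connectivity-only (no mean shift) because the network
  pipeline is location- and scale-invariant, so mean effects would be
  invisible to every downstream statistic anyway.  Sex is Bernoulli
  with P(female) = 0.51.
- **Seeding.** All randomness flows from one integer seed; each age
  group consumes an independent `SeedSequence` child stream.

What the generator does **not** emulate: item-level (criterion-by-
criterion) scoring, rater disagreement, floor/ceiling skews of real
score distributions, age-related mean growth, and any non-Gaussian
dependence.  Passing tests therefore demonstrate that the pipeline
recovers networks of this Gaussian-copula form at these sample sizes —
not that the TGMD-3 itself has any particular structure.

## Numerical choices and test sizes

- Edge existence: |pcor| > 1e-8 after optional small-edge thresholding.
- Path-length ties: relative tolerance 1e-12.
- EBIC ties: larger λ wins.
- Degenerate inputs: constant score columns and near-singular
  correlation matrices (condition number > 1e12) raise typed errors that
  name the offender; strata with n ≤ p are skipped with a warning in
  pipeline runs rather than aborting the run.
- Heavy validation runs use 50 seeds for edge recovery (n = 5000),
  20 seeds × B = 200 for the developmental-trend comparison at the full
  stratum sizes, and 10 seeds × 100 subsamples per drop level for
  stability — sizes chosen so the whole suite completes on a laptop
  CPU in a few minutes while keeping the pass criteria strict
  (≥ 80–90% of seeds).

## Known limitations

- Pearson-on-ordinal input understates latent correlations slightly;
  polychoric input is not implemented.
- Bootstrap CIs inherit lasso shrinkage bias (see above); they support
  accuracy/stability statements, not unbiased effect estimation.
- The CS coefficient's 0.70/0.25 conventions are heuristics carried
  from the psychometric stability literature, not calibrated
  error rates.
- Betweenness on small dense networks is unstable under resampling;
  expect wide CIs and low CS for betweenness-type statistics.
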