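# Methods

## Model and procedure

`consentree` tests, for every node of a rooted phylogenetic tree, the
null hypothesis "the member OTUs of this branch have no consensus
differential abundance" against "there is a consensus response in one
direction".  The input is a per-tip one-sided p-value pᵢ from an
upstream test of μ_T = μ_C against μ_T > μ_C, so pᵢ near 0 means greater
abundance under treatment and pᵢ near 1 means lesser.  Because the
alternative's direction is a pure relabeling, flipping it maps p to
1 − p; the two-sided counterpart of a one-sided p is 2·min(p, 1−p), and
a two-sided p converts back given the sign of the observed mean
difference.

### Combination

Each member p-value is transformed to the standard-normal deviate Zᵢ
with upper-tail area pᵢ (Zᵢ = Φ⁻¹(1 − pᵢ)).  Stouffer's statistic is
Z_S = Σ Zᵢ/√k, with the branch p-value the upper-tail area of Z_S; under
independence of the pᵢ this is exact.  When tip p-values are dependent
through the phylogeny, Hartung's generalization estimates a common
correlation among the deviates, ρ̂ = 1 − s²(Z₁..Z_k) (sample variance,
denominator k−1), floors it at its admissible minimum
ρ̂* = max(−1/(k−1), ρ̂), and inflates the denominator:

    Z_H = Σ Zᵢ / √( k + (k²−k)·[ρ̂* + κ·√(2/(k+1))·(1−ρ̂*)] ),  κ = 0.2.

The κ term is a small-sample bias correction; κ·√(2/(k+1))·(1−ρ̂*) is
the published form and is the default.  Because the term is sometimes
typeset ambiguously, the alternative reading κ·√(2(1−ρ̂*)/(k+1)) is
available as `hartung(..., variant="sqrt-pooled")` rather than silently
chosen; the two coincide at ρ̂* ∈ {0, 1}, which covers the degenerate
test cases (zero-variance inputs return the common p; inputs whose
deviates sum to zero return 0.5 regardless of denominator).

Tip nodes pass their own p-value through (k = 1, where both combiners
are the identity); internal nodes need k ≥ 2 members with p-values and
are otherwise skipped with a log message.  P-values of exactly 0 or 1
are clamped to ε = 1e−15 before the quantile transform so deviates stay
finite while ordering is preserved.

### Choosing the combiner

Dependence is assessed by a permutation test in the PERMANOVA (adonis)
orientation: the patristic distance matrix D is the response and the tip
p-value vector x the single explanatory covariate.  With
G = −½·C·(D∘D)·C the Gower-centered matrix and H the hat matrix of the
design (intercept + x),

    F = tr(HGH) / [ tr((I−H)G(I−H)) / (n−2) ].

The implementation uses the rank-one identity tr(HGH) = x̃ᵀGx̃/x̃ᵀx̃
(x̃ centered; valid because G·1 = 0) to evaluate all permutations as
quadratic forms; the hat-matrix form is kept as the reference
implementation and the two are cross-checked in the tests, along with a
principal-coordinate regression oracle.  The Monte-Carlo p-value uses
the add-one estimator (1 + #{F_b ≥ F_obs})/(B + 1) over B = 999 seeded
permutations by default (so the p-value is never 0), with exhaustive
enumeration available for small n.  `method="auto"` selects Hartung iff
the permutation p ≤ α (boundary inclusive), else Stouffer.  Neither the
permutation count nor the orientation is prescribed by theory alone;
both are exposed in configuration.

### Multiplicity

All tested nodes — every tip plus every combined internal node — form a
single adjustment family by default: tree-wide error statements are the
product, and tips and branches are displayed on one adjusted scale.  A
branch-only scope is available via the `scope` argument.  Adjustment
operates on the two-sided scale (p₂ = 2·min(p₁, 1−p₁)), applies Hommel
(strong FWER control, valid under the Simes-type positive dependence
expected among nested branch tests; the default) or Benjamini–Yekutieli
(FDR under arbitrary dependence), and folds back: raw p₁ < 0.5 →
p₂_adj/2, raw p₁ > 0.5 → 1 − p₂_adj/2, raw p₁ = 0.5 → 0.5.  Declaring
significance at adjusted one-sided p < α/2 or > 1 − α/2 is then exactly
the two-sided α-level decision with the observed direction.  The
adjustments are computed by statsmodels; a brute-force closed-testing
procedure (all 2^m − 1 Simes intersection tests) and the explicit BY
step-up formula serve as independent oracles in the test suite.

### Colors and export

The one-sided scale is cut at thresholds {0.001, 0.01, 0.025, 0.975,
0.99, 0.999} into seven bins: three reds (dark → light) for consensus
increase, neutral grey over [0.025, 0.975) — the non-rejection region at
α = 0.05 — and three blues (light → dark) for consensus decrease.  Bins
are left-closed/right-open with the last bin closed, so every p has
exactly one color.  The hex values are package defaults chosen to read
naturally in FigTree and are fully user-overridable, as are the
thresholds.  Export writes a Nexus file whose tree statement embeds
`[&!color=#RRGGBB,p=…]` immediately after each node's label or closing
parenthesis and before its branch-length colon — the annotation position
FigTree parses — plus a per-branch CSV (node id, k, raw and adjusted p,
color, member tips).  A minimal matplotlib rendering of the colored tree
exists for smoke testing; publication graphics are FigTree's job.

## Trees

Parsing (Newick, and Nexus with translate tables) is delegated to
dendropy and converted to an immutable structure whose node ids are
assigned by post-order position, making all outputs reproducible across
runs.  Polytomies are preserved; a root with three or more children
(unrooted-style input) is accepted as a root polytomy.  Duplicate tip
labels are a hard validation error (all duplicates listed), as are
p-value table entries naming tips absent from the tree; tree tips
without p-values stay in the topology and are excluded from k with a
warning.  Trees without branch lengths get unit length on every edge for
distance purposes — topology-only trees built from taxonomy must remain
usable — and this fallback is logged.  Patristic distances are computed
by a post-order sweep (d(i,j) = depth_i + depth_j − 2·depth_LCA) and
checked in the tests against an explicit LCA path-walk oracle and the
four-point condition.

## Simulation study

The verification study uses a fixed tree outline: star subtrees A
(nA = 20 tips, positive response), B (nB tips, null), C (nC = 10,
negative response), D (nB, null), with E = A∪B, F = C∪D and root G.
Star construction within lettered subtrees is harmless because
combination depends only on descendant tip sets; edges carry unit
lengths.  Per replicate: every tip's control abundance is Normal(0, 1)
across n_subjects = 20 subjects; responsive tips draw a magnitude
mᵢ ~ Uniform(0.1, δ) and treatment abundance Normal(±mᵢ, 1); null tips
are Normal(0, 1).  A per-tip one-sided two-sample t-test (Welch by
default; the pooled-variance variant is a config switch since either
reading of "a t-test" is defensible) feeds Stouffer combination and
Hommel adjustment at FWER α = 0.05, and each labeled node is scored
significant up (adjusted p < α/2) or down (> 1 − α/2).

Replicate generators come from a counter-based seed sequence (master
seed, δ-index, nB-index, replicate), so cells are independently
reproducible and results do not depend on execution order.  The default
grid is the 3×3 desk-scale subset δ ∈ {0.1, 1.0, 2.0} × nB ∈ {2, 20,
100} at 500 replicates per cell (the corners and midpoints of the full
10×10 design, which is a cluster-scale computation); the full grid is
reachable by passing denser `deltas`/`nbs`.  Expected behavior, which
the acceptance tests check: power at A/C rises with δ and is essentially
flat in nB; power at E/F falls as nB grows (the null subtree drowns out
the consensus); the proportion of replicates declaring B or D
significant stays at or below 0.01 — conservative relative to the
nominal 0.05, because Hommel over the whole family is strict and the
null branches' Stouffer statistics are well-calibrated.

The fast per-cell runner vectorizes the t-tests and Stouffer sums over
precomputed member-index arrays; its equality with the generic
`combine_tree` + `adjust_directional` path is asserted in the test
suite, so the optimization cannot drift from the public semantics.

## Synthetic fixtures

The fixture generator produces random binary trees (sequential random
edge attachment), stars, caterpillars, and the simulation-study shape,
with branch lengths absent, unit, or exponential(1); and p-value styles
uniform (global null), directional-block (one clade enriched with
Uniform(0, 0.05)), and distance-correlated (rank transform of the
patristic distance to a reference tip plus Normal(0, 0.1) noise,
clipped).  These emulate the *structure* of real tip-level results —
directionality, clade enrichment, phylogenetic autocorrelation — but not
the distributional quirks of real abundance data (zero inflation,
library-size effects, discrete counts), which live upstream of this
package's inputs; passing tests demonstrate correctness of the
machinery, not robustness of any particular upstream test.  One known
limitation: under heavy-tailed (exponential) branch lengths, a long
pendant edge on the reference tip can make the distance-to-reference
ranks nearly uninformative about the overall distance structure, so the
distance-correlated style yields a weaker dependence signal than the
same construction on unit-length trees; the clean monotone-dependence
calibration fixture therefore uses unit lengths.

## Numerical choices and degenerate inputs

- Quantile clamp ε = 1e−15 for p ∈ {0, 1}; logged.
- Hommel for m = 1 is the identity; Hartung for k = 1 falls back to
  Stouffer (identity), logged.
- Tied treatment/control means (difference sign 0) map to p₁ = 0.5.
- Zero-variance tips in the simulation t-test get p = 0.5 with a
  warning rather than NaN.
- Dependence test requires n ≥ 3 tips with p-values and a non-constant
  p-value vector; B ≥ 99.
- Monotonicity checks on simulated power allow a slack of 0.03,
  about three binomial standard errors at 500 replicates.
- The CSV report writes p-values via `repr` (shortest round-tripping
  decimal) so re-reading reproduces them exactly.

## Known limitations

- Hommel and BY do not exploit the nested structure of the tree's
  hypothesis family; hierarchy-aware procedures are out of scope.
- Hartung assumes a single common correlation; it is used here as a
  robust fallback under the dependence the permutation test detects, not
  as a fitted dependence model.
- The dependence test uses one continuous covariate; multi-covariate
  designs, strata, and non-patristic dissimilarities are out of scope.
- Only the first tree of a Nexus trees block is read.
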