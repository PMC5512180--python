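# consentree

Branch-level consensus-response testing for phylogenetic trees.

Microbial community experiments routinely test hundreds or thousands of
OTUs (operational taxonomic units — the tips of a phylogenetic tree) for
differential abundance between a treatment and a control condition.
Beyond single OTUs, the scientifically interesting unit is often a
*branch*: an internal node together with all its descendant tips.  A
branch shows a **consensus response** when the overall direction of its
members' abundance shifts is the same, even if individual members
disagree.  `consentree` takes per-tip **one-sided** p-values from *any*
upstream test (Wilcoxon, moderated t, a mixed model contrast, …) and
turns them into multiplicity-adjusted, direction-aware p-values for
every branch of the tree, plus a FigTree-ready colored Nexus file.

It is aimed at microbiome and microbial-ecology researchers who already
have per-OTU test results and a tree, and want defensible branch-level
significance statements rather than a plain data-on-tree painting.

## The statistics

P-values are one-sided with a fixed convention: p ≈ 0 is evidence of
*greater* abundance under treatment, p ≈ 1 of *lesser* abundance.  A
two-sided p-value p₂ with observed difference sign s converts as
p₁ = p₂/2 (s > 0) or 1 − p₂/2 (s < 0).

For a branch with member p-values p₁, …, p_k, each is transformed to the
standard-normal deviate Zᵢ with upper-tail area pᵢ, and the branch
p-value is the upper-tail area of a combined statistic:

- **Stouffer** (independent tips): Z_S = Σ Zᵢ / √k.
- **Hartung** (correlated tips): Z_H = Σ Zᵢ / √( k + (k²−k)·[ρ̂* + κ·√(2/(k+1))·(1−ρ̂*)] ),
  with ρ̂ = 1 − sample variance of the Zᵢ, ρ̂* = max(−1/(k−1), ρ̂), κ = 0.2.

Whether tips are "correlated" is itself tested: a PERMANOVA-style
permutation test (the `adonis` orientation, distance matrix ~ p-value
covariate) asks whether differences among tip p-values are associated
with patristic distances.  In `--method auto` a significant permutation
p-value (≤ α) switches the combiner from Stouffer to Hartung.

All tested nodes — tips and branches — are then adjusted as one family
on the two-sided scale (Hommel for family-wise error control by default,
Benjamini–Yekutieli FDR as an option) and folded back to one-sided so
direction is preserved.  At α = 0.05 a branch is significantly *up* when
its adjusted one-sided p < 0.025 and *down* when it is > 0.975.

## Worked example

With `tree.nwk`:

```
(((t1:1,t2:1):1,(t3:1,t4:1):1):1,((t5:1,t6:1):1,(t7:1,t8:1):1):1);
```

and `pvalues.csv` (one-sided; t1–t4 tend up, t5–t8 tend down):

```
tip,p1
t1,0.0012
t2,0.0048
t3,0.0031
t4,0.0260
t5,0.7300
t6,0.9640
t7,0.9989
t8,0.9952
```

run

```bash
consentree --tree tree.nwk --pvalues pvalues.csv \
           --method auto --adjust hommel --seed 11 \
           --out-nexus annotated.nex --out-csv branches.csv
```

which prints

```
tips with p-values : 8
nodes tested       : 15
dependence test    : pseudo-F=8.452, perm p=0.005 (B=999, seed=11)
combination method : hartung (dependence perm p=0.005 <= alpha=0.05)
adjustment         : hommel
alpha              : 0.05
nexus written      : annotated.nex
csv written        : branches.csv
```

The dependence test is significant (perm p = 0.005 ≤ 0.05) — the
p-values track the tree — so Hartung's combiner is used.  `branches.csv`
then shows, for example, the `t1;t2` cherry with combined raw p =
0.00203 and Hommel-adjusted p = 0.0160 (< 0.025: a significant consensus
*increase*, colored red in the Nexus file), while the `t5;t6;t7;t8`
branch gets adjusted p = 0.99960 (> 0.975: a significant consensus
*decrease*, darkest blue).  The root, which mixes both directions, stays
neutral grey at adjusted p = 0.27.  Opening `annotated.nex` in FigTree
shows each branch pre-colored with its `[&!color=…,p=…]` annotation.

The same pipeline is available in Python:

```python
from consentree import RunConfig, run_pipeline
report = run_pipeline(RunConfig(
    tree_path="tree.nwk", pvalue_path="pvalues.csv",
    out_nexus="annotated.nex", out_csv="branches.csv",
    method="auto", adjust="hommel", seed=11,
))
print(report.summary())
```

## Simulation study

`consentree.run_study` re-creates the package's verification study: a
tree of four star subtrees — A (20 tips, responding up), C (10 tips,
responding down), and null subtrees B and D (nB tips each) — under
intermediate nodes E = A∪B, F = C∪D and root G.  Control abundances are
Normal(0, 1) over 20 subjects; responsive tips get a treatment shift
drawn per tip from Uniform(0.1, δ).  Per-tip Welch t-tests feed the full
pipeline and each labeled node's significance is recorded over
replicates, giving power (A, C, E, F, G) and empirical type-I error
(B, D) as a function of δ and nB.

```python
from consentree import run_study
df = run_study(deltas=(0.1, 1.0, 2.0), nbs=(2, 20, 100), n_sims=500, seed=1)
```

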