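"""Synthetic trees and p-value tables for tests and documentation.

All generators are pure functions of (spec, seed).  Topology styles:

- ``random``: random binary tree grown by sequential attachment — each
  new tip splits a uniformly chosen existing edge (or the root edge);
- ``star``: one root with all tips as children;
- ``caterpillar``: a pectinate chain;
- ``fig1``: the simulation-study tree (four star subtrees).

P-value styles:

- ``uniform``: i.i.d. Uniform(0, 1) (the global null);
- ``directional-block``: one chosen clade gets Uniform(0, 0.05), the rest
  Uniform(0, 1) — a localized consensus response;
- ``distance-correlated``: p is the rank-transform of the patristic
  distance to a reference tip plus seeded noise — the dependence pattern
  where closely related tips respond similarly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pvalue_transforms import TipResult
from .simulation import SimulationConfig, build_sim_tree
from .tree_core import PhyloTree, parse_tree, patristic_distances

__all__ = ["FixtureSpec", "make_tree", "make_pvalues"]


@dataclass(frozen=True)
class FixtureSpec:
    n_tips: int
    topology: str = "random"        #: random | star | caterpillar | fig1
    lengths: str = "unit"           #: none | unit | exponential
    pvalues: str = "uniform"        #: uniform | directional-block | distance-correlated
    seed: int = 0
    noise: float = 0.1              #: sd of noise for distance-correlated p-values

    def __post_init__(self) -> None:
        if self.n_tips < 1:
            raise ValueError("need at least one tip")
        if self.topology not in ("random", "star", "caterpillar", "fig1"):
            raise ValueError(f"unknown topology {self.topology!r}")
        if self.lengths not in ("none", "unit", "exponential"):
            raise ValueError(f"unknown length style {self.lengths!r}")
        if self.pvalues not in ("uniform", "directional-block", "distance-correlated"):
            raise ValueError(f"unknown p-value style {self.pvalues!r}")


def _tip_names(n: int) -> list[str]:
    return [f"t{i + 1}" for i in range(n)]


def _random_binary_newick(names: list[str], rng: np.random.Generator) -> str:
    # grow by splitting a uniformly chosen edge with a new cherry
    if len(names) == 1:
        return f"({names[0]})"
    topo: object = names[0]
    for name in names[1:]:
        # edges of the current subtree, as paths to nested lists
        edges: list[tuple] = []

        def collect(sub, path):
            edges.append(path)
            if isinstance(sub, list):
                for i, child in enumerate(sub):
                    collect(child, path + (i,))

        collect(topo, ())
        path = edges[rng.integers(len(edges))]
        if not path:
            topo = [topo, name]
            continue
        parent = topo
        for i in path[:-1]:
            parent = parent[i]
        parent[path[-1]] = [parent[path[-1]], name]

    def emit(sub) -> str:
        if isinstance(sub, list):
            return "(" + ",".join(emit(c) for c in sub) + ")"
        return sub

    return emit(topo)


def make_tree(spec: FixtureSpec) -> PhyloTree:
    """Deterministic synthetic tree for the given spec."""
    rng = np.random.default_rng(spec.seed)
    names = _tip_names(spec.n_tips)
    if spec.topology == "fig1":
        return build_sim_tree(SimulationConfig(nB=max(1, spec.n_tips)))
    if spec.topology == "star":
        skeleton = "(" + ",".join(names) + ")"
    elif spec.topology == "caterpillar":
        s = names[0]
        for name in names[1:]:
            s = f"({s},{name})"
        skeleton = s if spec.n_tips > 1 else f"({s})"
    else:
        skeleton = _random_binary_newick(names, rng)

    if spec.lengths == "none":
        return parse_tree(skeleton + ";")
    tree = parse_tree(skeleton + ";")
    if spec.lengths == "unit":
        lengths = {n: 1.0 for n in tree.parent}
    else:
        draws = rng.exponential(1.0, size=len(tree.parent))
        lengths = {n: float(d) for n, d in zip(sorted(tree.parent), draws)}
    return PhyloTree(
        root=tree.root, parent=tree.parent, children=tree.children,
        tip_labels=tree.tip_labels, edge_length=lengths,
        node_labels=tree.node_labels,
    )


def make_pvalues(tree: PhyloTree, spec: FixtureSpec) -> list[TipResult]:
    """Deterministic synthetic per-tip p-values in the style of the spec."""
    rng = np.random.default_rng(spec.seed + 1)
    labels = [tree.tip_labels[n] for n in tree.postorder() if tree.is_tip(n)]
    n = len(labels)
    if spec.pvalues == "uniform":
        p = rng.uniform(0.0, 1.0, size=n)
    elif spec.pvalues == "directional-block":
        internal = [v for v in tree.postorder()
                    if not tree.is_tip(v) and v != tree.root
                    and len(tree.tips_below(v)) >= 2]
        p = rng.uniform(0.0, 1.0, size=n)
        if internal:
            clade = internal[rng.integers(len(internal))]
            members = set(tree.tips_below(clade))
            mask = np.array([l in members for l in labels])
            p[mask] = rng.uniform(0.0, 0.05, size=int(mask.sum()))
    else:  # distance-correlated
        dm = patristic_distances(tree)
        ref = labels[int(rng.integers(n))]
        d = np.array([dm.matrix[dm.labels.index(l), dm.labels.index(ref)] for l in labels])
        ranks = np.argsort(np.argsort(d))
        p = (ranks + 0.5) / n + rng.normal(0.0, spec.noise, size=n)
        p = np.clip(p, 1e-6, 1.0 - 1e-6)
    return [TipResult(l, float(v)) for l, v in zip(labels, p)]
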