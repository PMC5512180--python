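"""Rooted phylogenetic trees: parsing, traversal, branch indexing, patristic distances.

A tree is the indexing structure for every branch-level test: each node
(tip or internal) defines a branch whose member OTUs are its descendant
tips.  Trees arrive as Newick or Nexus text; parsing is delegated to
dendropy and the result is converted to a light immutable structure with
deterministic integer node ids assigned in post-order, so downstream
outputs are reproducible across runs.
"""

from __future__ import annotations

import io
import logging
import re
from dataclasses import dataclass, field

import dendropy
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "PhyloTree",
    "BranchIndex",
    "DistanceMatrix",
    "TreeParseError",
    "TreeValidationError",
    "parse_tree",
    "serialize_newick",
    "branch_table",
    "patristic_distances",
]


class TreeParseError(ValueError):
    """Malformed Newick/Nexus input."""


class TreeValidationError(ValueError):
    """Structurally valid syntax but an invalid tree (e.g. duplicate tips)."""


@dataclass(frozen=True)
class PhyloTree:
    """A rooted tree with integer node ids assigned in post-order.

    ``parent`` excludes the root; ``children`` maps every internal node to
    its child ids in input order (polytomies preserved).  ``edge_length``
    is either populated for every non-root node or empty (topology-only
    tree).  ``tip_labels`` maps leaf ids to their unique labels;
    ``node_labels`` carries any internal-node labels from the source text.
    """

    root: int
    parent: dict[int, int]
    children: dict[int, tuple[int, ...]]
    tip_labels: dict[int, str]
    edge_length: dict[int, float] = field(default_factory=dict)
    node_labels: dict[int, str] = field(default_factory=dict)

    @property
    def nodes(self) -> list[int]:
        """All node ids in post-order (root last)."""
        return list(range(self.root + 1))

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    def is_tip(self, node: int) -> bool:
        return node in self.tip_labels

    def postorder(self) -> list[int]:
        # ids are assigned in post-order at construction, so this is just a range
        return list(range(self.root + 1))

    def label_of(self, node: int) -> str | None:
        return self.tip_labels.get(node) or self.node_labels.get(node)

    def tips_below(self, node: int) -> tuple[str, ...]:
        """Descendant tip labels of ``node`` in left-to-right input order."""
        if node in self.tip_labels:
            return (self.tip_labels[node],)
        out: list[str] = []
        stack = [node]
        while stack:
            v = stack.pop()
            if v in self.tip_labels:
                out.append(self.tip_labels[v])
            else:
                stack.extend(reversed(self.children[v]))
        return tuple(out)


@dataclass(frozen=True)
class BranchIndex:
    """One node's branch membership: descendant tip labels and the count
    ``k`` of those tips that carry a p-value."""

    node: int
    tips: tuple[str, ...]
    k: int


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric patristic (path-length) distance matrix over tip labels."""

    labels: tuple[str, ...]
    matrix: np.ndarray

    def submatrix(self, labels: list[str] | tuple[str, ...]) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(tuple(labels), self.matrix[np.ix_(idx, idx)])


def _looks_like_nexus(text: str) -> bool:
    return text.lstrip().upper().startswith("#NEXUS")


def parse_tree(text: str) -> PhyloTree:
    """Parse a Newick string or a Nexus document (first tree of the trees
    block, translate table honored) into a :class:`PhyloTree`.

    Raises :class:`TreeParseError` on malformed syntax and
    :class:`TreeValidationError` on duplicate tip labels (all duplicates
    listed) or mixed presence/absence of edge lengths.
    """
    schema = "nexus" if _looks_like_nexus(text) else "newick"
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema=schema,
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except dendropy.utility.error.DataParseError as exc:
        msg = str(exc)
        if "Duplicate taxon labels" in msg or "Multiple occurrences" in msg:
            raise TreeValidationError(_describe_duplicates(text, schema)) from exc
        raise TreeParseError(f"malformed {schema} input: {msg}") from exc
    except Exception as exc:  # dendropy raises plain ValueError for some defects
        raise TreeParseError(f"malformed {schema} input: {exc}") from exc
    return _from_dendropy(dtree)


def _describe_duplicates(text: str, schema: str) -> str:
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema=schema,
            suppress_internal_node_taxa=True,
            suppress_leaf_node_taxa=True,
            preserve_underscores=True,
        )
        labels = [lf.label for lf in dtree.leaf_node_iter()]
        seen: set[str] = set()
        dups = sorted({l for l in labels if l in seen or seen.add(l)})
    except Exception:
        dups = []
    return f"duplicate tip labels: {', '.join(dups) if dups else '(unrecoverable)'}"


def _from_dendropy(dtree: dendropy.Tree) -> PhyloTree:
    order = list(dtree.postorder_node_iter())
    ids = {id(nd): i for i, nd in enumerate(order)}
    root = ids[id(dtree.seed_node)]

    parent: dict[int, int] = {}
    children: dict[int, tuple[int, ...]] = {}
    tip_labels: dict[int, str] = {}
    node_labels: dict[int, str] = {}
    edge_length: dict[int, float] = {}
    n_with_len = 0

    for nd in order:
        i = ids[id(nd)]
        kids = nd.child_nodes()
        if kids:
            children[i] = tuple(ids[id(c)] for c in kids)
            if nd.label:
                node_labels[i] = nd.label
        else:
            label = nd.taxon.label if nd.taxon is not None else nd.label
            if not label:
                raise TreeValidationError("tip with empty label")
            tip_labels[i] = label
        if nd is not dtree.seed_node:
            parent[i] = ids[id(nd.parent_node)]
            if nd.edge.length is not None:
                edge_length[i] = float(nd.edge.length)
                n_with_len += 1

    labels = list(tip_labels.values())
    dup = sorted({l for l in labels if labels.count(l) > 1})
    if dup:
        raise TreeValidationError(f"duplicate tip labels: {', '.join(dup)}")
    if 0 < n_with_len < len(parent):
        raise TreeValidationError(
            f"edge lengths present on {n_with_len} of {len(parent)} edges; "
            "must be all or none"
        )
    if any(v < 0 for v in edge_length.values()):
        raise TreeValidationError("negative edge length")
    return PhyloTree(
        root=root,
        parent=parent,
        children=children,
        tip_labels=tip_labels,
        edge_length=edge_length,
        node_labels=node_labels,
    )


_NEEDS_QUOTE = re.compile(r"[\s()\[\]{}/\\,;:=*'\"`<>]")


def _fmt_label(label: str) -> str:
    if _NEEDS_QUOTE.search(label):
        return "'" + label.replace("'", "''") + "'"
    return label


def serialize_newick(tree: PhyloTree, decorate=None) -> str:
    """Canonical Newick serialization.

    ``decorate`` is an optional callable ``node_id -> str`` whose return
    value is inserted immediately after the node's label (tips) or closing
    parenthesis (internal nodes) and before the branch-length colon; this
    is the hook the Nexus exporter uses to embed FigTree annotations.
    """
    buf = io.StringIO()

    def write(node: int) -> None:
        if tree.is_tip(node):
            buf.write(_fmt_label(tree.tip_labels[node]))
        else:
            buf.write("(")
            for j, child in enumerate(tree.children[node]):
                if j:
                    buf.write(",")
                write(child)
            buf.write(")")
            if node in tree.node_labels:
                buf.write(_fmt_label(tree.node_labels[node]))
        if decorate is not None:
            ann = decorate(node)
            if ann:
                buf.write(ann)
        if node in tree.edge_length:
            buf.write(f":{tree.edge_length[node]:.10g}")

    write(tree.root)
    buf.write(";")
    return buf.getvalue()


def branch_table(tree: PhyloTree, available: set[str]) -> list[BranchIndex]:
    """One :class:`BranchIndex` per node (tips, internal nodes and root),
    in post-order.  ``k`` counts only descendant tips whose label is in
    ``available`` (the tips that carry p-values)."""
    unknown = available - set(tree.tip_labels.values())
    if unknown:
        raise TreeValidationError(
            f"labels not present in the tree: {', '.join(sorted(unknown))}"
        )
    tips_of: dict[int, tuple[str, ...]] = {}
    out: list[BranchIndex] = []
    for node in tree.postorder():
        if tree.is_tip(node):
            tips_of[node] = (tree.tip_labels[node],)
        else:
            acc: list[str] = []
            for child in tree.children[node]:
                acc.extend(tips_of[child])
            tips_of[node] = tuple(acc)
        k = sum(1 for t in tips_of[node] if t in available)
        out.append(BranchIndex(node, tips_of[node], k))
    return out


def patristic_distances(tree: PhyloTree) -> DistanceMatrix:
    """Pairwise path-length distances between all tips.

    Topology-only trees (no edge lengths anywhere) are handled by
    assigning unit length to every edge, so that distance reduces to the
    number of edges on the path; this keeps the dependence test available
    for trees built from taxonomy alone.
    """
    if tree.n_tips < 2:
        raise TreeValidationError("distance matrix undefined for a single-tip tree")
    if not tree.edge_length:
        logger.info("tree has no branch lengths; using unit edge lengths for distances")
        length = {n: 1.0 for n in tree.parent}
    else:
        length = tree.edge_length

    # depth of every node from the root, then d(i,j) = depth_i + depth_j - 2*depth_lca
    depth: dict[int, float] = {tree.root: 0.0}
    for node in reversed(tree.postorder()):
        if node != tree.root:
            depth[node] = depth[tree.parent[node]] + length.get(node, 0.0)

    # post-order DP: for each internal node, pair tips from distinct child subtrees
    tip_ids = [n for n in tree.postorder() if tree.is_tip(n)]
    labels = tuple(tree.tip_labels[n] for n in tip_ids)
    pos = {n: i for i, n in enumerate(tip_ids)}
    n = len(tip_ids)
    mat = np.zeros((n, n))
    below: dict[int, list[int]] = {}
    for node in tree.postorder():
        if tree.is_tip(node):
            below[node] = [node]
            continue
        groups = [below[c] for c in tree.children[node]]
        for a in range(len(groups)):
            for b in range(a + 1, len(groups)):
                for ti in groups[a]:
                    for tj in groups[b]:
                        d = depth[ti] + depth[tj] - 2.0 * depth[node]
                        mat[pos[ti], pos[tj]] = d
                        mat[pos[tj], pos[ti]] = d
        below[node] = [t for g in groups for t in g]
    return DistanceMatrix(labels, mat)
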