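"""Color assignment, FigTree-dialect Nexus export, and tabular reports.

The one-sided p-value scale is divided into ordered bins by user-defined
thresholds; each bin maps to a color.  The default scale has seven bins:
three reds (dark → light) for small p (consensus greater abundance under
treatment), a neutral grey mid-bin spanning the non-significant region
[0.025, 0.975) at α = 0.05, and three blues (light → dark) for large p
(consensus lesser abundance).  The annotated tree is written as a Nexus
file whose tree statement embeds ``[&!color=#RRGGBB,p=…]`` comments in
the position FigTree expects, so the file opens directly in FigTree with
branches pre-colored.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path

from .tree_core import PhyloTree, serialize_newick, _fmt_label

__all__ = [
    "ColorScale",
    "BranchReportRow",
    "assign_colors",
    "export_nexus",
    "export_table",
    "read_table",
    "render_tree",
]

_HEX = re.compile(r"^#[0-9a-fA-F]{6}$")

DEFAULT_THRESHOLDS = (0.001, 0.01, 0.025, 0.975, 0.99, 0.999)
DEFAULT_COLORS = (
    "#67000d",  # p < 0.001      strong consensus increase under treatment
    "#cb181d",  # 0.001–0.01
    "#fb6a4a",  # 0.01–0.025
    "#bdbdbd",  # 0.025–0.975    not significant at alpha = 0.05
    "#6baed6",  # 0.975–0.99
    "#2171b5",  # 0.99–0.999
    "#08306b",  # >= 0.999       strong consensus decrease under treatment
)


@dataclass(frozen=True)
class ColorScale:
    """Ordered p-value thresholds and the q+1 colors of the bins between
    them.  Bins are left-closed, right-open; the last bin is closed."""

    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    colors: tuple[str, ...] = DEFAULT_COLORS
    missing_color: str = "#000000"

    def __post_init__(self) -> None:
        t = self.thresholds
        if any(not 0.0 < v < 1.0 for v in t):
            raise ValueError("thresholds must lie strictly inside (0, 1)")
        if any(a >= b for a, b in zip(t, t[1:])):
            raise ValueError("thresholds must be strictly increasing")
        if len(self.colors) != len(t) + 1:
            raise ValueError(f"need {len(t) + 1} colors for {len(t)} thresholds")
        for c in (*self.colors, self.missing_color):
            if not _HEX.match(c):
                raise ValueError(f"invalid #RRGGBB color {c!r}")

    def color_of(self, p: float) -> str:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"p-value {p!r} outside [0, 1]")
        for t, c in zip(self.thresholds, self.colors):
            if p < t:
                return c
        return self.colors[-1]


@dataclass(frozen=True)
class BranchReportRow:
    node: int
    k: int
    p_raw: float
    p_adjusted: float
    color: str
    members: tuple[str, ...]


def assign_colors(
    pvalues: dict[int, float],
    scale: ColorScale = ColorScale(),
    nodes: list[int] | None = None,
) -> dict[int, str]:
    """Map each node's (adjusted) p-value to its bin color.  Nodes listed
    in ``nodes`` but absent from ``pvalues`` get the scale's neutral
    missing color."""
    out = {n: scale.color_of(p) for n, p in pvalues.items()}
    for n in nodes or ():
        out.setdefault(n, scale.missing_color)
    return out


def _nexus_quote(label: str) -> str:
    return _fmt_label(label)


def export_nexus(
    tree: PhyloTree,
    colors: dict[int, str],
    pvalues: dict[int, float],
    path: str | Path,
) -> Path:
    """Write a FigTree-compatible Nexus file: a taxa block and a trees
    block whose tree statement carries per-node ``[&!color=…,p=…]``
    annotations placed after the node label / closing parenthesis and
    before the branch-length colon."""
    unknown = (set(colors) | set(pvalues)) - set(tree.nodes)
    if unknown:
        raise ValueError(f"annotations for unknown node ids: {sorted(unknown)}")

    def decorate(node: int) -> str:
        parts = []
        if node in colors:
            parts.append(f"!color={colors[node]}")
        if node in pvalues:
            parts.append(f"p={pvalues[node]:.6g}")
        return f"[&{','.join(parts)}]" if parts else ""

    taxa = [tree.tip_labels[n] for n in tree.postorder() if tree.is_tip(n)]
    lines = [
        "#NEXUS",
        "begin taxa;",
        f"\tdimensions ntax={len(taxa)};",
        "\ttaxlabels",
        *[f"\t{_nexus_quote(t)}" for t in taxa],
        ";",
        "end;",
        "begin trees;",
        f"\ttree annotated = [&R] {serialize_newick(tree, decorate=decorate)}",
        "end;",
        "",
    ]
    path = Path(path)
    path.write_text("\n".join(lines))
    return path


CSV_HEADER = ["node_id", "k", "p_raw", "p_adjusted", "color", "members"]


def export_table(rows: list[BranchReportRow], path: str | Path) -> Path:
    """Write the per-branch report as CSV, one row per tested node in
    post-order: node id, member count k, raw and adjusted p, color, and
    the semicolon-joined member tip labels."""
    if not rows:
        raise ValueError("no rows to export")
    path = Path(path)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(CSV_HEADER)
        for r in sorted(rows, key=lambda r: r.node):
            w.writerow([r.node, r.k, repr(r.p_raw), repr(r.p_adjusted), r.color,
                        ";".join(r.members)])
    return path


def read_table(path: str | Path) -> list[BranchReportRow]:
    """Inverse of :func:`export_table`."""
    out = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        for rec in reader:
            out.append(
                BranchReportRow(
                    node=int(rec["node_id"]),
                    k=int(rec["k"]),
                    p_raw=float(rec["p_raw"]),
                    p_adjusted=float(rec["p_adjusted"]),
                    color=rec["color"],
                    members=tuple(rec["members"].split(";")),
                )
            )
    return out


def render_tree(
    tree: PhyloTree,
    colors: dict[int, str],
    path: str | Path,
    figsize: tuple[float, float] | None = None,
) -> Path:
    """Minimal colored-edge rendering for smoke tests; publication
    graphics are delegated to FigTree."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ylevel: dict[int, float] = {}
    next_y = [0.0]
    depth: dict[int, float] = {tree.root: 0.0}
    for node in reversed(tree.postorder()):
        if node != tree.root:
            depth[node] = depth[tree.parent[node]] + tree.edge_length.get(node, 1.0)
    for node in tree.postorder():
        if tree.is_tip(node):
            ylevel[node] = next_y[0]
            next_y[0] += 1.0
        else:
            kids = tree.children[node]
            ylevel[node] = sum(ylevel[c] for c in kids) / len(kids)

    fig, ax = plt.subplots(figsize=figsize or (6, 0.25 * tree.n_tips + 1))
    for node in tree.postorder():
        col = colors.get(node, "#000000")
        if node != tree.root:
            x0 = depth[tree.parent[node]]
            ax.plot([x0, depth[node]], [ylevel[node]] * 2, color=col, lw=1.5)
            ax.plot([x0, x0], [ylevel[tree.parent[node]], ylevel[node]], color=col, lw=0.8)
        if tree.is_tip(node):
            ax.text(depth[node], ylevel[node], " " + tree.tip_labels[node],
                    va="center", fontsize=7)
    ax.axis("off")
    path = Path(path)
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)
    return path
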