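"""End-to-end orchestration: tree + p-value table in, annotated tree +
report out.

Stage order: parse → (method "auto": dependence test → method choice) →
per-branch combination → direction-preserving multiplicity adjustment →
color assignment → Nexus and CSV export.  The run report records every
stage's parameters and results so a run is fully reproducible from
(inputs, config, seed).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

from .annotate_export import (
    BranchReportRow,
    ColorScale,
    assign_colors,
    export_nexus,
    export_table,
)
from .dependence import DEFAULT_PERMUTATIONS, choose_method, dependence_test
from .meta_combine import combine_tree
from .multiplicity import adjust_directional
from .pvalue_transforms import read_pvalue_table
from .tree_core import branch_table, parse_tree

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunReport", "run_pipeline"]


@dataclass(frozen=True)
class RunConfig:
    tree_path: str
    pvalue_path: str
    out_nexus: str
    out_csv: str
    two_sided_with_diff: bool = False
    method: str = "auto"          #: stouffer | hartung | auto
    adjust: str = "hommel"        #: hommel | by | none
    alpha: float = 0.05
    permutations: int = DEFAULT_PERMUTATIONS
    scale: ColorScale = ColorScale()
    seed: int | None = None
    hartung_variant: str = "published"

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.method not in ("stouffer", "hartung", "auto"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.adjust not in ("hommel", "by", "none"):
            raise ValueError(f"unknown adjustment {self.adjust!r}")
        if self.method == "auto" and self.permutations < 99:
            raise ValueError("method 'auto' needs at least 99 permutations")


@dataclass
class RunReport:
    config: RunConfig
    method_used: str
    method_reason: str
    dependence: object | None
    n_tips: int
    n_tested: int
    rows: list[BranchReportRow]
    out_nexus: Path
    out_csv: Path

    def summary(self) -> str:
        lines = [
            f"tips with p-values : {self.n_tips}",
            f"nodes tested       : {self.n_tested}",
            f"combination method : {self.method_used} ({self.method_reason})",
            f"adjustment         : {self.config.adjust}",
            f"alpha              : {self.config.alpha}",
        ]
        if self.dependence is not None:
            lines.insert(2, f"dependence test    : pseudo-F={self.dependence.pseudo_F:.4g}, "
                            f"perm p={self.dependence.perm_p:.4g} "
                            f"(B={self.dependence.B}, seed={self.dependence.seed})")
        lines += [f"nexus written      : {self.out_nexus}",
                  f"csv written        : {self.out_csv}"]
        return "\n".join(lines)


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
        return inner
    return wrap


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the full branch-testing pipeline; see module docstring for
    stage order.  Identical config and inputs produce byte-identical
    output files."""
    tree = _stage("parse-tree")(parse_tree)(Path(config.tree_path).read_text())
    tips = _stage("read-pvalues")(read_pvalue_table)(
        config.pvalue_path, config.two_sided_with_diff
    )
    logger.info("parsed tree with %d tips; %d p-values", tree.n_tips, len(tips))

    dep = None
    if config.method == "auto":
        dep = _stage("dependence-test")(dependence_test)(
            tree, tips, B=config.permutations, seed=config.seed
        )
        method = choose_method(dep, config.alpha)
        reason = (
            f"dependence perm p={dep.perm_p:.4g} "
            f"{'<=' if dep.perm_p <= config.alpha else '>'} alpha={config.alpha}"
        )
    else:
        method = config.method
        reason = "explicitly requested"
    logger.info("combination method: %s (%s)", method, reason)

    kwargs = {"variant": config.hartung_variant} if method == "hartung" else {}
    combined = _stage("combine")(combine_tree)(tree, tips, method=method, **kwargs)
    raw = {n: c.combined_p for n, c in combined.items()}
    adj = _stage("adjust")(adjust_directional)(raw, method=config.adjust)
    colors = assign_colors(adj.adjusted, config.scale, nodes=tree.nodes)

    by_tip = {t.tip for t in tips}
    rows = [
        BranchReportRow(
            node=e.node, k=e.k, p_raw=raw[e.node], p_adjusted=adj.adjusted[e.node],
            color=colors[e.node], members=e.tips,
        )
        for e in branch_table(tree, by_tip & set(tree.tip_labels.values()))
        if e.node in raw
    ]
    out_nexus = _stage("export-nexus")(export_nexus)(
        tree, colors, adj.adjusted, config.out_nexus
    )
    out_csv = _stage("export-table")(export_table)(rows, config.out_csv)
    return RunReport(
        config=config,
        method_used=method,
        method_reason=reason,
        dependence=dep,
        n_tips=len(tips),
        n_tested=len(rows),
        rows=rows,
        out_nexus=out_nexus,
        out_csv=out_csv,
    )
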