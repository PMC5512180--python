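"""Power and type-I-error simulation study for the branch-testing pipeline.

The study tree has four star subtrees under two intermediate nodes:

    ((A-tips)A, (B-tips)B)E, ((C-tips)C, (D-tips)D)F)G

Subtree A (20 tips) responds positively to treatment, subtree C (10
tips) negatively, and subtrees B and D (nB tips each) do not respond.
Each replicate simulates per-subject abundances for 20 subjects per
condition: control ~ Normal(0, 1) for every tip; treatment ~
Normal(±m_i, 1) for responsive tips, with the per-tip magnitude
m_i ~ Uniform(0.1, δ) redrawn every replicate, and Normal(0, 1) for null
tips.  A one-sided two-sample t-test per tip feeds the standard pipeline
(Stouffer combination, Hommel adjustment by default), and each labeled
node's significance (in either direction, at family-wise α) is recorded.

The proportion of replicates significant at A/C measures power; at B/D
it is the empirical type-I error rate of the branch test.

Each replicate draws its generator from a counter-based seed sequence
(master seed, cell indices, replicate index), so any cell can be re-run
independently and results do not depend on execution order.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import norm

from .meta_combine import P_CLAMP_EPS, combine_tree, hartung
from .multiplicity import adjust_directional
from .pvalue_transforms import TipResult
from .tree_core import PhyloTree, branch_table, parse_tree

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "SimulationSummary",
    "build_sim_tree",
    "simulate_dataset",
    "tip_pvalues_ttest",
    "run_study",
    "DEFAULT_DELTAS",
    "DEFAULT_NBS",
]

LABELED_NODES = ("A", "B", "C", "D", "E", "F", "G")

# desk-scale corners/midpoints of the full 10x10 study grid
DEFAULT_DELTAS = (0.1, 1.0, 2.0)
DEFAULT_NBS = (2, 20, 100)


@dataclass(frozen=True)
class SimulationConfig:
    """One grid cell of the simulation study."""

    nB: int = 2                #: tips in each null subtree (B and D)
    delta: float = 1.0         #: maximum possible response magnitude
    nA: int = 20               #: tips in the positively responsive subtree
    nC: int = 10               #: tips in the negatively responsive subtree
    n_subjects: int = 20       #: subjects per condition
    n_sims: int = 500          #: replicates per cell
    alpha: float = 0.05        #: family-wise significance level
    seed: int = 0
    method: str = "stouffer"
    adjust: str = "hommel"
    equal_var: bool = False    #: pooled-variance t-test instead of Welch

    def __post_init__(self) -> None:
        if self.nB < 1:
            raise ValueError("nB must be >= 1")
        if self.delta < 0.1:
            raise ValueError("delta must be >= 0.1 (the minimum response magnitude)")
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects per condition")
        if self.n_sims < 1:
            raise ValueError("n_sims must be >= 1")


@dataclass(frozen=True)
class SimulationSummary:
    """Per-cell, per-node, per-direction proportion of significant replicates."""

    delta: float
    nB: int
    node: str
    direction: str  # "up" | "down"
    proportion: float
    n_sims: int


@dataclass(frozen=True)
class SimDataset:
    labels: tuple[str, ...]
    control: np.ndarray    # (n_tips, n_subjects)
    treatment: np.ndarray  # (n_tips, n_subjects)
    shifts: np.ndarray     # per-tip treatment mean (0 for null tips)


def build_sim_tree(config: SimulationConfig) -> PhyloTree:
    """The study tree: four star subtrees labeled A–D under E, F and root G.

    Tips are labeled ``A1..A{nA}``, ``B1..B{nB}`` and so on; unit branch
    lengths are implied (no lengths are written)."""
    def star(letter: str, n: int) -> str:
        return "(" + ",".join(f"{letter}{i + 1}" for i in range(n)) + f"){letter}"

    newick = (
        f"(({star('A', config.nA)},{star('B', config.nB)})E,"
        f"({star('C', config.nC)},{star('D', config.nB)})F)G;"
    )
    return parse_tree(newick)


def _tip_order(config: SimulationConfig) -> tuple[str, ...]:
    return tuple(
        f"{letter}{i + 1}"
        for letter, n in (("A", config.nA), ("B", config.nB),
                          ("C", config.nC), ("D", config.nB))
        for i in range(n)
    )


def simulate_dataset(config: SimulationConfig, replicate_seed) -> SimDataset:
    """Simulate one replicate's subject-level abundances.

    ``replicate_seed`` is anything acceptable to
    :func:`numpy.random.default_rng` (an int or a sequence of ints).
    """
    rng = np.random.default_rng(replicate_seed)
    labels = _tip_order(config)
    n = len(labels)
    mA = rng.uniform(0.1, config.delta, size=config.nA)
    mC = rng.uniform(0.1, config.delta, size=config.nC)
    shifts = np.concatenate([mA, np.zeros(config.nB), -mC, np.zeros(config.nB)])
    control = rng.normal(0.0, 1.0, size=(n, config.n_subjects))
    treatment = rng.normal(0.0, 1.0, size=(n, config.n_subjects)) + shifts[:, None]
    return SimDataset(labels, control, treatment, shifts)


def tip_pvalues_ttest(dataset: SimDataset, equal_var: bool = False) -> list[TipResult]:
    """One-sided two-sample t-test per tip (Welch by default): small p ⇔
    treatment mean greater.  Tips with zero variance in both groups get
    p = 0.5 with a warning."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(
            dataset.treatment, dataset.control, axis=1,
            equal_var=equal_var, alternative="greater",
        )
        p = np.asarray(res.pvalue, dtype=float)
    bad = ~np.isfinite(p)
    if bad.any():
        logger.warning("%d tips with degenerate (zero-variance) data; p set to 0.5",
                       int(bad.sum()))
        p[bad] = 0.5
    return [TipResult(lbl, float(pv)) for lbl, pv in zip(dataset.labels, p)]


class _CellRunner:
    """Precomputed per-cell structures for fast replicate evaluation.

    Combination uses the same arithmetic as :func:`combine_tree` /
    :func:`adjust_directional` over precomputed member-index arrays; the
    equivalence is asserted in the test suite.
    """

    def __init__(self, config: SimulationConfig):
        self.config = config
        self.tree = build_sim_tree(config)
        labels = _tip_order(config)
        pos = {l: i for i, l in enumerate(labels)}
        self.internal: list[tuple[int, np.ndarray]] = []
        self.labeled: dict[str, int] = {}  # letter -> column in p_all
        n_tips = len(labels)
        self.tip_nodes: list[int] = []
        for entry in branch_table(self.tree, set(labels)):
            if self.tree.is_tip(entry.node):
                self.tip_nodes.append(entry.node)
            else:
                idx = np.array([pos[t] for t in entry.tips])
                col = n_tips + len(self.internal)
                self.internal.append((entry.node, idx))
                letter = self.tree.node_labels.get(entry.node)
                if letter in LABELED_NODES:
                    self.labeled[letter] = col
        self.sqrt_k = np.array([np.sqrt(len(idx)) for _, idx in self.internal])

    def replicate(self, rep_seed) -> np.ndarray:
        """Adjusted one-sided p-values: tips first (in tip order), then
        internal nodes in post-order."""
        cfg = self.config
        ds = simulate_dataset(cfg, rep_seed)
        p_tip = np.array([t.p1 for t in tip_pvalues_ttest(ds, cfg.equal_var)])
        z = norm.isf(np.clip(p_tip, P_CLAMP_EPS, 1 - P_CLAMP_EPS))
        if cfg.method == "stouffer":
            z_int = np.array([z[idx].sum() for _, idx in self.internal]) / self.sqrt_k
            p_int = norm.sf(z_int)
        else:
            p_int = np.array([
                hartung(p_tip[idx]).combined_p for _, idx in self.internal
            ])
        p_all = np.concatenate([p_tip, p_int])
        if cfg.adjust == "none":
            return p_all
        res = adjust_directional(dict(enumerate(p_all)), method=cfg.adjust)
        return np.array([res.adjusted[i] for i in range(len(p_all))])


def run_replicate_generic(config: SimulationConfig, rep_seed) -> dict[int, float]:
    """Reference replicate path through the public pipeline pieces
    (:func:`combine_tree` then :func:`adjust_directional`); used to
    validate the vectorized cell runner."""
    ds = simulate_dataset(config, rep_seed)
    tips = tip_pvalues_ttest(ds, config.equal_var)
    tree = build_sim_tree(config)
    combined = combine_tree(tree, tips, method=config.method)
    raw = {n: c.combined_p for n, c in combined.items()}
    return adjust_directional(raw, method=config.adjust).adjusted


def run_study(
    deltas=DEFAULT_DELTAS,
    nbs=DEFAULT_NBS,
    n_sims: int = 500,
    seed: int = 0,
    **config_kwargs,
) -> pd.DataFrame:
    """Run the simulation grid and summarize significance proportions.

    Returns a long-format frame with columns ``delta, nB, node,
    direction, proportion, n_sims`` covering the labeled nodes A–G, where
    ``direction`` is "up" (adjusted p < α/2) or "down" (adjusted p >
    1 − α/2).
    """
    if not len(deltas) or not len(nbs):
        raise ValueError("empty simulation grid")
    rows: list[SimulationSummary] = []
    for di, delta in enumerate(deltas):
        for ni, nb in enumerate(nbs):
            cfg = SimulationConfig(nB=int(nb), delta=float(delta), n_sims=n_sims,
                                   seed=seed, **config_kwargs)
            runner = _CellRunner(cfg)
            cols = runner.labeled
            up = dict.fromkeys(LABELED_NODES, 0)
            down = dict.fromkeys(LABELED_NODES, 0)
            null_union = 0  # replicates where B or D is significant either way
            half = cfg.alpha / 2.0
            for rep in range(n_sims):
                adj = runner.replicate([seed, di, ni, rep])
                hit = {}
                for letter, col in cols.items():
                    hit[letter] = adj[col] < half or adj[col] > 1.0 - half
                    if adj[col] < half:
                        up[letter] += 1
                    elif adj[col] > 1.0 - half:
                        down[letter] += 1
                if hit.get("B") or hit.get("D"):
                    null_union += 1
            for letter in LABELED_NODES:
                rows.append(SimulationSummary(delta, int(nb), letter, "up",
                                              up[letter] / n_sims, n_sims))
                rows.append(SimulationSummary(delta, int(nb), letter, "down",
                                              down[letter] / n_sims, n_sims))
            rows.append(SimulationSummary(delta, int(nb), "B|D", "either",
                                          null_union / n_sims, n_sims))
            logger.info("cell delta=%g nB=%d done (%d replicates)", delta, nb, n_sims)
    return pd.DataFrame([vars(r) for r in rows])
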