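"""Distance-based dependence test for tip p-values (PERMANOVA / adonis style).

Stouffer's combiner assumes the tip p-values in a branch are independent,
but closely related OTUs often respond similarly to a treatment, making
their p-values more alike.  This module tests whether differences among
tip p-values are associated with between-tip patristic distances: the
distance matrix is the response and the p-value vector the single
explanatory covariate, exactly the ``adonis(dist ~ p)`` orientation.  A
significant result is the cue to switch from Stouffer's to Hartung's
combiner.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np

from .pvalue_transforms import TipResult
from .tree_core import DistanceMatrix, PhyloTree, patristic_distances

logger = logging.getLogger(__name__)

__all__ = ["DependenceResult", "permanova_f", "dependence_test", "choose_method"]

DEFAULT_PERMUTATIONS = 999


@dataclass(frozen=True)
class DependenceResult:
    pseudo_F: float
    B: int
    perm_p: float
    seed: int | None
    exhaustive: bool = False


def _gower_center(D: np.ndarray) -> np.ndarray:
    n = D.shape[0]
    A = -0.5 * D * D
    C = np.eye(n) - np.full((n, n), 1.0 / n)
    return C @ A @ C


def permanova_f(D: DistanceMatrix | np.ndarray, x: np.ndarray) -> float:
    """Pseudo-F for a single continuous covariate against a distance matrix.

    With G the Gower-centered matrix −½·C·(D∘D)·C and H the hat matrix of
    the design (intercept + x):

        F = tr(H·G·H) / 1  ÷  tr((I−H)·G·(I−H)) / (n−2)
    """
    Dm = D.matrix if isinstance(D, DistanceMatrix) else np.asarray(D, dtype=float)
    x = np.asarray(x, dtype=float)
    n = Dm.shape[0]
    if n < 3:
        raise ValueError("need at least 3 observations for the pseudo-F")
    if x.shape != (n,):
        raise ValueError("covariate length must match distance matrix dimension")
    if np.ptp(x) == 0:
        raise ValueError("covariate has zero variance")
    G = _gower_center(Dm)
    X = np.column_stack([np.ones(n), x])
    H = X @ np.linalg.solve(X.T @ X, X.T)
    R = np.eye(n) - H
    ss_model = float(np.trace(H @ G @ H))
    ss_resid = float(np.trace(R @ G @ R))
    return (ss_model / 1.0) / (ss_resid / (n - 2))


def _f_batch(G: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Pseudo-F for each row of ``X`` against a fixed Gower-centered ``G``.

    Uses the rank-one identity for a centered covariate x̃:
    tr(HGH) = x̃ᵀGx̃ / x̃ᵀx̃ and tr((I−H)G(I−H)) = tr(G) − tr(HGH),
    which holds because G is double-centered (G·1 = 0).
    """
    n = G.shape[0]
    Xc = X - X.mean(axis=1, keepdims=True)
    num = np.einsum("bi,ij,bj->b", Xc, G, Xc)
    den = np.einsum("bi,bi->b", Xc, Xc)
    ss_model = num / den
    ss_resid = np.trace(G) - ss_model
    return ss_model / (ss_resid / (n - 2))


def dependence_test(
    tree: PhyloTree,
    tips: list[TipResult],
    B: int = DEFAULT_PERMUTATIONS,
    seed: int | None = None,
    exhaustive: bool = False,
) -> DependenceResult:
    """Permutation test of association between tip p-values and patristic
    distances.

    Tips without p-values are dropped from both the matrix and the
    covariate (logged).  The Monte-Carlo p-value uses the add-one rule
    (1 + #{F_b ≥ F_obs}) / (B + 1) over B seeded permutations of the
    p-value vector; with ``exhaustive`` all n! permutations (identity
    included) are enumerated instead, which is only feasible for small n.
    """
    by_tip = {t.tip: t.p1 for t in tips}
    dm = patristic_distances(tree)
    labels = [l for l in dm.labels if l in by_tip]
    dropped = len(dm.labels) - len(labels)
    if dropped:
        logger.info("dropping %d tips without p-values from the dependence test", dropped)
    if len(labels) < 3:
        raise ValueError("need at least 3 tips with p-values for the dependence test")
    sub = dm.submatrix(labels)
    x = np.array([by_tip[l] for l in labels])
    if np.ptp(x) == 0:
        raise ValueError("covariate has zero variance")

    G = _gower_center(sub.matrix)
    f_obs = float(_f_batch(G, x[None, :])[0])
    n = len(x)

    if exhaustive:
        perms = np.array(list(itertools.permutations(range(n))))
        fs = _f_batch(G, x[perms])
        perm_p = float(np.count_nonzero(fs >= f_obs) / math.factorial(n))
        return DependenceResult(f_obs, len(perms), perm_p, seed, exhaustive=True)

    if B < 99:
        raise ValueError("at least 99 permutations required")
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(n) for _ in range(B)])
    fs = _f_batch(G, x[perms])
    perm_p = float((1 + np.count_nonzero(fs >= f_obs)) / (B + 1))
    return DependenceResult(f_obs, B, perm_p, seed)


def choose_method(result: DependenceResult, alpha: float = 0.05) -> str:
    """Hartung when the dependence test is significant (perm_p ≤ α,
    boundary inclusive), Stouffer otherwise."""
    return "hartung" if result.perm_p <= alpha else "stouffer"
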