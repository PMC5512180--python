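"""Meta-analytic combination of one-sided p-values per branch.

Two combiners are provided.  Stouffer's method transforms each one-sided
p-value to the standard-normal deviate with that upper-tail area,

    Z_S = (Z_1 + … + Z_k) / √k,

and returns the upper-tail area of Z_S; it assumes the k p-values are
independent.  Hartung's method generalizes Stouffer to a common
correlation ρ among the deviates, estimated as

    ρ̂  = 1 − sample variance of Z_1..Z_k          (denominator k−1)
    ρ̂* = max(−1/(k−1), ρ̂)

and inflates the denominator:

    Z_H = Σ Z_i / √( k + (k²−k)·[ρ̂* + κ·√(2/(k+1))·(1−ρ̂*)] ),   κ = 0.2.

Both return one-sided branch p-values with the same direction semantics
as the inputs: near 0 ⇒ consensus greater abundance under treatment,
near 1 ⇒ consensus lesser abundance.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .pvalue_transforms import TipResult
from .tree_core import PhyloTree, branch_table

logger = logging.getLogger(__name__)

__all__ = ["CombinedResult", "z_from_p", "stouffer", "hartung", "combine_tree"]

#: clamp for p in {0, 1} before the normal-quantile transform; keeps Z finite
#: while preserving the ordering of extreme p-values
P_CLAMP_EPS = 1e-15

#: Hartung's recommended bias constant for the denominator correction
HARTUNG_KAPPA = 0.2


@dataclass(frozen=True)
class CombinedResult:
    """A branch-level combined p-value and its intermediate statistics."""

    node: int | None
    k: int
    z_values: tuple[float, ...]
    z_stat: float
    combined_p: float
    method: str
    rho_hat: float | None = None
    rho_star: float | None = None
    kappa: float | None = None


def z_from_p(p1: float) -> float:
    """Standard-normal deviate with upper-tail area ``p1`` (Z = Φ⁻¹(1−p1)).

    Values within ``P_CLAMP_EPS`` of 0 or 1 are clamped (logged) so the
    quantile stays finite.
    """
    if not 0.0 <= p1 <= 1.0:
        raise ValueError(f"p1={p1!r} outside [0, 1]")
    if p1 < P_CLAMP_EPS or p1 > 1.0 - P_CLAMP_EPS:
        logger.warning("clamping extreme p-value %g before quantile transform", p1)
        p1 = min(max(p1, P_CLAMP_EPS), 1.0 - P_CLAMP_EPS)
    return float(norm.isf(p1))


def stouffer(p1s: list[float] | np.ndarray, node: int | None = None) -> CombinedResult:
    """Combine one-sided p-values with Stouffer's (unweighted) method."""
    if len(p1s) == 0:
        raise ValueError("no p-values to combine")
    z = np.array([z_from_p(p) for p in p1s])
    k = len(z)
    z_stat = float(z.sum() / math.sqrt(k))
    return CombinedResult(
        node=node,
        k=k,
        z_values=tuple(z),
        z_stat=z_stat,
        combined_p=float(norm.sf(z_stat)),
        method="stouffer",
    )


def hartung(
    p1s: list[float] | np.ndarray,
    node: int | None = None,
    kappa: float = HARTUNG_KAPPA,
    variant: str = "published",
) -> CombinedResult:
    """Combine one-sided p-values with Hartung's correlation-adjusted method.

    ``variant`` selects the reading of the κ correction term:
    ``"published"`` uses κ·√(2/(k+1))·(1−ρ̂*) (Hartung's original form,
    the default); ``"sqrt-pooled"`` uses κ·√(2·(1−ρ̂*)/(k+1)).  The two
    coincide whenever ρ̂* ∈ {0, 1}.

    A single p-value has no estimable correlation, so k = 1 falls back to
    Stouffer (which is the identity there); this is logged.
    """
    if len(p1s) == 0:
        raise ValueError("no p-values to combine")
    if len(p1s) == 1:
        logger.info("hartung with k=1 falls back to stouffer")
        res = stouffer(p1s, node=node)
        return CombinedResult(
            node=node, k=1, z_values=res.z_values, z_stat=res.z_stat,
            combined_p=res.combined_p, method="hartung",
            rho_hat=None, rho_star=None, kappa=kappa,
        )
    z = np.array([z_from_p(p) for p in p1s])
    k = len(z)
    rho_hat = 1.0 - float(np.var(z, ddof=1))
    rho_star = max(-1.0 / (k - 1), rho_hat)
    one_minus = 1.0 - rho_star
    if variant == "published":
        correction = kappa * math.sqrt(2.0 / (k + 1)) * one_minus
    elif variant == "sqrt-pooled":
        correction = kappa * math.sqrt(2.0 * one_minus / (k + 1))
    else:
        raise ValueError(f"unknown hartung variant {variant!r}")
    radicand = k + (k * k - k) * (rho_star + correction)
    # rho_star >= -1/(k-1) makes k + (k^2-k)*rho_star >= 0; the kappa term
    # is non-negative, so the radicand can only vanish in the degenerate
    # perfectly-anticorrelated limit
    if radicand <= 0:
        raise ValueError("non-positive variance in Hartung denominator")
    z_stat = float(z.sum() / math.sqrt(radicand))
    return CombinedResult(
        node=node,
        k=k,
        z_values=tuple(z),
        z_stat=z_stat,
        combined_p=float(norm.sf(z_stat)),
        method="hartung",
        rho_hat=rho_hat,
        rho_star=rho_star,
        kappa=kappa,
    )


def combine_tree(
    tree: PhyloTree,
    tips: list[TipResult],
    method: str = "stouffer",
    **method_kwargs,
) -> dict[int, CombinedResult]:
    """Combine tip p-values for every branch of the tree.

    Tip nodes carry their own p-value through unchanged (k = 1); every
    internal node with k ≥ 2 member p-values gets a combined result;
    internal nodes with fewer are skipped (logged).  Tips present in the
    tree but absent from the table are retained in the topology and
    excluded from k.
    """
    if method not in ("stouffer", "hartung"):
        raise ValueError(f"unknown combination method {method!r}")
    by_tip = {t.tip: t.p1 for t in tips}
    overlap = set(by_tip) & set(tree.tip_labels.values())
    if not overlap:
        raise ValueError("no overlap between p-value table and tree tips")
    missing = set(tree.tip_labels.values()) - set(by_tip)
    if missing:
        logger.warning(
            "%d tree tips have no p-value and are excluded from combination", len(missing)
        )
    combiner = stouffer if method == "stouffer" else hartung
    out: dict[int, CombinedResult] = {}
    for entry in branch_table(tree, set(by_tip)):
        ps = [by_tip[t] for t in entry.tips if t in by_tip]
        if tree.is_tip(entry.node):
            if ps:
                out[entry.node] = CombinedResult(
                    node=entry.node, k=1, z_values=(z_from_p(ps[0]),),
                    z_stat=z_from_p(ps[0]), combined_p=ps[0], method=method,
                )
            continue
        if entry.k < 2:
            logger.info("skipping internal node %d with k=%d < 2", entry.node, entry.k)
            continue
        out[entry.node] = combiner(ps, node=entry.node, **method_kwargs)
    return out
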