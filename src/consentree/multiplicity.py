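"""Direction-preserving multiple-testing adjustment over tree nodes.

Both tips and combined branches are tested, potentially thousands of
hypotheses with nested (positively dependent) structure.  Adjustment is
performed on the two-sided scale: each one-sided p-value is collapsed to
2·min(p, 1−p), the chosen correction is applied jointly to the whole
family, and the adjusted value is folded back to the original side of
0.5 so that directional interpretation survives the correction.

Available corrections: Hommel (strong FWER control, valid under the
Simes-type positive dependence expected among nested branch tests) and
Benjamini–Yekutieli (FDR control under arbitrary dependence).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from statsmodels.stats.multitest import multipletests

__all__ = ["AdjustmentResult", "hommel_adjust", "by_adjust", "adjust_directional"]


@dataclass(frozen=True)
class AdjustmentResult:
    m: int
    method: str
    raw: dict[int, float]
    adjusted: dict[int, float]
    c_m: float | None = None  # harmonic constant sum(1/i), BY only


def _check_probs(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.size and (p.min() < 0 or p.max() > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return p


def hommel_adjust(p2s) -> np.ndarray:
    """Hommel adjusted p-values (closed testing with Simes local tests)."""
    p = _check_probs(p2s)
    if p.size == 1:
        return p.copy()
    return multipletests(p, method="hommel")[1]


def by_adjust(p2s) -> np.ndarray:
    """Benjamini–Yekutieli step-up adjusted p-values.

    For sorted p_(1) ≤ … ≤ p_(m):  adj_(i) = min_{j≥i} ( m·c(m)/j · p_(j) )
    capped at 1, with c(m) = Σ_{i=1..m} 1/i.
    """
    p = _check_probs(p2s)
    if p.size == 1:
        return p.copy()
    return multipletests(p, method="fdr_by")[1]


def adjust_directional(
    p1s: dict[int, float],
    method: str = "hommel",
    scope: set[int] | None = None,
) -> AdjustmentResult:
    """Adjust one-sided p-values jointly over ``scope`` (default: all keys),
    preserving direction.

    Back-conversion: a node with raw p1 < 0.5 gets adjusted p1 =
    p2_adj / 2; raw p1 > 0.5 gets 1 − p2_adj / 2; raw p1 = 0.5 stays 0.5.
    ``method="none"`` passes values through unchanged.
    """
    nodes = sorted(scope) if scope is not None else sorted(p1s)
    if not nodes:
        raise ValueError("empty adjustment scope")
    raw = {n: p1s[n] for n in nodes}
    m = len(nodes)
    if method == "none":
        return AdjustmentResult(m, "none", raw, dict(raw))
    p1 = np.array([raw[n] for n in nodes])
    p2 = 2.0 * np.minimum(p1, 1.0 - p1)
    if method == "hommel":
        p2_adj = hommel_adjust(p2)
        c_m = None
    elif method == "by":
        p2_adj = by_adjust(p2)
        c_m = float(np.sum(1.0 / np.arange(1, m + 1)))
    else:
        raise ValueError(f"unknown adjustment method {method!r}")
    p1_adj = np.where(p1 < 0.5, p2_adj / 2.0, np.where(p1 > 0.5, 1.0 - p2_adj / 2.0, 0.5))
    return AdjustmentResult(m, method, raw, dict(zip(nodes, p1_adj.tolist())), c_m=c_m)
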