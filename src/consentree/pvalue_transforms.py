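"""One-sided / two-sided p-value conversions with explicit direction semantics.

Throughout the package a one-sided p-value near 0 is evidence that the
treatment induces *greater* abundance than control, and a p-value near 1
is evidence of *lesser* abundance.  A two-sided p-value carries no
direction, so converting it to one-sided requires the sign of the
observed treatment-minus-control difference.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

__all__ = [
    "TipResult",
    "one_sided_from_two_sided",
    "two_sided_from_one_sided",
    "flip_direction",
    "read_pvalue_table",
]


@dataclass(frozen=True)
class TipResult:
    """One tip's one-sided p-value, optionally with its two-sided origin."""

    tip: str
    p1: float
    p2: float | None = None
    diff_sign: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p1 <= 1.0:
            raise ValueError(f"p-value {self.p1!r} for tip {self.tip!r} outside [0, 1]")

    @classmethod
    def from_two_sided(cls, tip: str, p2: float, diff: float) -> "TipResult":
        sign = 1 if diff > 0 else (-1 if diff < 0 else 0)
        return cls(tip, one_sided_from_two_sided(p2, sign), p2=p2, diff_sign=sign)


def _check_unit(p: float, name: str = "p") -> float:
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"{name}={p!r} outside [0, 1]")
    return float(p)


def one_sided_from_two_sided(p2: float, diff_sign: int) -> float:
    """Convert a two-sided p-value to one-sided given the sign of the
    observed treatment−control difference.

    A positive difference puts the evidence in the lower tail (p2/2); a
    negative difference mirrors it into the upper tail (1 − p2/2).  A tie
    (sign 0) carries no directional information and maps to 0.5.
    """
    _check_unit(p2, "p2")
    if diff_sign > 0:
        return p2 / 2.0
    if diff_sign < 0:
        return 1.0 - p2 / 2.0
    return 0.5


def two_sided_from_one_sided(p1: float) -> float:
    """Collapse a one-sided p-value to its two-sided counterpart, 2·min(p1, 1−p1)."""
    _check_unit(p1, "p1")
    return 2.0 * min(p1, 1.0 - p1)


def flip_direction(p1: float) -> float:
    """Reverse the alternative-hypothesis direction: p1 → 1 − p1 (involution)."""
    _check_unit(p1, "p1")
    return 1.0 - p1


def read_pvalue_table(path: str | Path, two_sided_with_diff: bool = False) -> list[TipResult]:
    """Read a delimited (CSV/TSV, sniffed) table of tip p-values.

    Expected columns: ``tip,p1`` — or ``tip,p2,diff`` when
    ``two_sided_with_diff`` is set, where only the sign of ``diff``
    (observed treatment−control difference) is used.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    df.columns = [c.strip().lower() for c in df.columns]
    if two_sided_with_diff:
        missing = {"tip", "p2", "diff"} - set(df.columns)
        if missing:
            raise ValueError(f"p-value table missing columns: {sorted(missing)}")
        return [
            TipResult.from_two_sided(str(r.tip), float(r.p2), float(r.diff))
            for r in df.itertuples()
        ]
    missing = {"tip", "p1"} - set(df.columns)
    if missing:
        raise ValueError(f"p-value table missing columns: {sorted(missing)}")
    return [TipResult(str(r.tip), float(r.p1)) for r in df.itertuples()]
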