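"""Mendelian segregation tests, marker polymorphism rates, and fine-mapping
interval arithmetic.

Segregation goodness-of-fit is a Pearson chi-square against an integer
expected ratio (e.g. 3:1), without continuity correction — with Yates'
correction a 59:18 F2 would give ~0.04 rather than the textbook 0.11.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "SegregationResult",
    "Marker",
    "MarkerInterval",
    "segregation_chi_square",
    "polymorphism_rate",
    "interval_from_markers",
    "intersect_intervals",
]


@dataclass(frozen=True)
class SegregationResult:
    chi2: float
    p_value: float
    df: int
    observed: tuple[int, ...]
    expected: tuple[float, ...]

    def display(self) -> str:
        return f"chi2 = {self.chi2:.2f}, p = {self.p_value:.2f}"


@dataclass(frozen=True)
class Marker:
    name: str
    chrom: str
    pos: int  # 1-based bp


@dataclass(frozen=True)
class MarkerInterval:
    """Physical interval between two markers on one chromosome."""

    chrom: str
    left: Marker
    right: Marker

    @property
    def start(self) -> int:
        return self.left.pos

    @property
    def end(self) -> int:
        return self.right.pos

    @property
    def length_bp(self) -> int:
        return self.right.pos - self.left.pos

    @property
    def length_mb(self) -> float:
        return self.length_bp / 1e6

    def display_mb(self, decimals: int = 2) -> float:
        return round(self.length_mb, decimals)


def segregation_chi_square(observed, ratio) -> SegregationResult:
    """Pearson chi-square of observed class counts against an integer ratio.

    ``observed`` and ``ratio`` are per-class sequences of equal length, e.g.
    ``(59, 18)`` against ``(3, 1)``.  No continuity correction; p is the
    chi-square upper tail with df = k - 1.
    """
    observed = np.asarray(observed, dtype=float)
    ratio = np.asarray(ratio, dtype=float)
    if observed.shape != ratio.shape:
        raise ValueError("observed and ratio must have equal length")
    if np.any(observed < 0) or observed.sum() <= 0:
        raise ValueError("observed counts must be >= 0 with positive total")
    if np.any(ratio <= 0):
        raise ValueError("ratio terms must be positive")
    expected = observed.sum() * ratio / ratio.sum()
    chi2, p = stats.chisquare(observed, f_exp=expected)
    return SegregationResult(
        chi2=float(chi2),
        p_value=float(p),
        df=len(observed) - 1,
        observed=tuple(int(o) for o in observed),
        expected=tuple(float(e) for e in expected),
    )


def polymorphism_rate(n_polymorphic: int, n_total: int) -> float:
    """Percent of screened markers that are polymorphic, to one decimal."""
    if n_total <= 0:
        raise ValueError("n_total must be > 0")
    if not (0 <= n_polymorphic <= n_total):
        raise ValueError("require 0 <= n_polymorphic <= n_total")
    return round(100.0 * n_polymorphic / n_total, 1)


def interval_from_markers(a: Marker, b: Marker) -> MarkerInterval:
    """Interval between two flanking markers; markers are auto-ordered."""
    if a.chrom != b.chrom:
        raise ValueError(
            f"markers on different chromosomes: {a.chrom} vs {b.chrom}"
        )
    left, right = (a, b) if a.pos <= b.pos else (b, a)
    return MarkerInterval(chrom=a.chrom, left=left, right=right)


def intersect_intervals(
    a: MarkerInterval, b: MarkerInterval
) -> MarkerInterval | None:
    """Strict set intersection of two marker intervals; None when disjoint."""
    if a.chrom != b.chrom:
        logger.warning(
            "intervals on different chromosomes (%s vs %s); empty intersection",
            a.chrom,
            b.chrom,
        )
        return None
    left = a.left if a.start >= b.start else b.left
    right = a.right if a.end <= b.end else b.right
    if left.pos > right.pos:
        return None
    return MarkerInterval(chrom=a.chrom, left=left, right=right)
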