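"""Summary statistics recomputable from printed study numbers.

Fisher's exact test on a 2×2 incidence table (by hypergeometric
enumeration), Pearson correlation, a rounded upregulation proportion, and
the ellipsoid xenograft tumor-volume formula.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
from scipy import stats

POINT_PROB_RTOL = 1e-7  # tie tolerance when comparing hypergeometric masses


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts [[a, b], [c, d]]: rows are groups, columns event / no event."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.total == 0:
            raise ValueError("table must contain at least one observation")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


def _hypergeom_pmf_all(t: ContingencyTable2x2) -> tuple[np.ndarray, np.ndarray]:
    """Support and pmf of the cell-a count with the table's margins fixed."""
    n = t.total
    row1 = t.a + t.b
    col1 = t.a + t.c
    lo = max(0, col1 - (n - row1))
    hi = min(row1, col1)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, n, row1, col1)
    return support, pmf


def fisher_exact_two_sided(
    t: ContingencyTable2x2, convention: str = "point"
) -> float:
    """Two-sided Fisher's exact p by hypergeometric enumeration.

    ``point`` (default): sum of the probabilities of all tables with the
    same margins that are no more probable than the observed one, with a
    relative tie tolerance of ``POINT_PROB_RTOL``.  ``doubling``: twice the
    smaller one-sided tail, capped at 1.
    """
    if convention not in ("point", "doubling"):
        raise ValueError(f"convention must be point or doubling, got {convention!r}")
    support, pmf = _hypergeom_pmf_all(t)
    observed = pmf[support == t.a][0]
    if convention == "point":
        p = float(pmf[pmf <= observed * (1.0 + POINT_PROB_RTOL)].sum())
    else:
        lower = float(pmf[support <= t.a].sum())
        upper = float(pmf[support >= t.a].sum())
        p = 2.0 * min(lower, upper)
    return min(p, 1.0)


def fisher_exact_one_sided(t: ContingencyTable2x2, alternative: str = "greater") -> float:
    """One-sided Fisher's exact p for cell a (greater or less)."""
    if alternative not in ("greater", "less"):
        raise ValueError("alternative must be greater or less")
    support, pmf = _hypergeom_pmf_all(t)
    mask = support >= t.a if alternative == "greater" else support <= t.a
    return min(float(pmf[mask].sum()), 1.0)


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Sample Pearson correlation coefficient of two equal-length vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one of the vectors")
    return float(stats.pearsonr(x, y).statistic)


def proportion_upregulated(n_up: int, n_total: int) -> float:
    """Percentage n_up/n_total, rounded half-up to one decimal (98/151 → 64.9)."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not (0 <= n_up <= n_total):
        raise ValueError("need 0 <= n_up <= n_total")
    pct = Decimal(100 * n_up) / Decimal(n_total)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def tumor_volume(length_mm: float, width_mm: float) -> float:
    """Xenograft volume in mm³: length × width² / 2.

    By convention width ≤ length; the reversed ordering is accepted with a
    warning since the formula is not symmetric in its arguments.
    """
    if length_mm <= 0 or width_mm <= 0:
        raise ValueError("length and width must be positive")
    if width_mm > length_mm:
        warnings.warn("width exceeds length; check measurement order", stacklevel=2)
    return length_mm * width_mm**2 / 2.0
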