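"""Chou–Talalay median-effect analysis and combination-index computation.

The median-effect equation fa/(1−fa) = (D/Dm)^m linearises to
log10(fa/(1−fa)) = m·log10 D − m·log10 Dm, so a least-squares line through
the transformed dose–response points yields the sigmoidicity m, the
median-effect dose Dm (the IC50 when fa is 1 − relative viability), and the
correlation r of the linearised fit.  For a two-drug combination observed at
fraction affected fa, the combination index is

    CI = d1 / Dx1(fa) + d2 / Dx2(fa),

where Dx_i(fa) = Dm_i (fa/(1−fa))^(1/m_i) is the single-agent dose of drug i
that alone produces fa.  CI < 1 indicates synergism, CI = 1 an additive
(Loewe) interaction and CI > 1 antagonism.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

FA_CLAMP_DELTA = 1e-4


@dataclass(frozen=True)
class DoseResponseCurve:
    """Single-agent dose–response: doses and fraction affected per dose.

    fa values of exactly 0 or 1 (possible in viability assays) are clamped
    into (0, 1) by ``FA_CLAMP_DELTA`` with a warning, or rejected when
    ``strict``.
    """

    doses: tuple[float, ...]
    fa: tuple[float, ...]

    def __init__(self, doses: Sequence[float], fa: Sequence[float], strict: bool = False):
        doses = tuple(float(d) for d in doses)
        fa_in = tuple(float(f) for f in fa)
        if len(doses) != len(fa_in):
            raise ValueError("doses and fa must have equal length")
        if len(doses) < 3:
            raise ValueError("need at least 3 dose–response points")
        if len(set(doses)) < 2:
            raise ValueError("need at least 2 distinct doses")
        if any(d <= 0 for d in doses):
            raise ValueError("doses must be positive")
        if any(not (0.0 <= f <= 1.0) for f in fa_in):
            raise ValueError("fraction affected must lie in [0, 1]")
        boundary = [f for f in fa_in if f in (0.0, 1.0)]
        if boundary and strict:
            raise ValueError("fa exactly 0 or 1 rejected in strict mode")
        if boundary:
            warnings.warn(
                f"{len(boundary)} fa value(s) at 0 or 1 clamped by {FA_CLAMP_DELTA}",
                stacklevel=2,
            )
        clamped = tuple(
            min(max(f, FA_CLAMP_DELTA), 1.0 - FA_CLAMP_DELTA) for f in fa_in
        )
        object.__setattr__(self, "doses", doses)
        object.__setattr__(self, "fa", clamped)


@dataclass(frozen=True)
class MedianEffectFit:
    """Median-effect parameters: slope m, median-effect dose Dm, fit r."""

    m: float
    dm: float
    r: float

    def __post_init__(self) -> None:
        if self.dm <= 0:
            raise ValueError("dm must be positive")
        if abs(self.r) > 1 + 1e-12:
            raise ValueError("|r| cannot exceed 1")


@dataclass(frozen=True)
class ComboMeasurement:
    """A combination dose pair and its observed fraction affected."""

    d1: float
    d2: float
    fa: float

    def __post_init__(self) -> None:
        if self.d1 < 0 or self.d2 < 0 or (self.d1 == 0 and self.d2 == 0):
            raise ValueError("doses must be non-negative and not both zero")
        if not (0.0 < self.fa < 1.0):
            raise ValueError("fa must lie strictly inside (0, 1)")


def fit_median_effect(curve: DoseResponseCurve) -> MedianEffectFit:
    """Least-squares median-effect fit on the linearised scale.

    Regresses log10(fa/(1−fa)) on log10(dose); m is the slope and
    Dm = 10^(−intercept/m).
    """
    x = np.log10(np.asarray(curve.doses, dtype=float))
    fa = np.asarray(curve.fa, dtype=float)
    y = np.log10(fa / (1.0 - fa))
    res = stats.linregress(x, y)
    if res.slope <= 0:
        raise ValueError(
            "non-positive median-effect slope: curve is not monotone increasing"
        )
    dm = 10.0 ** (-res.intercept / res.slope)
    r = float(np.clip(res.rvalue, -1.0, 1.0))
    return MedianEffectFit(m=float(res.slope), dm=float(dm), r=r)


def dose_for_effect(fit: MedianEffectFit, fa: float) -> float:
    """Dose producing fraction affected fa: Dx = Dm (fa/(1−fa))^(1/m)."""
    if not (0.0 < fa < 1.0):
        raise ValueError(f"fa must lie in (0, 1), got {fa}")
    return fit.dm * (fa / (1.0 - fa)) ** (1.0 / fit.m)


def fa_at_dose(fit: MedianEffectFit, dose: float) -> float:
    """Fraction affected at a dose under the fitted median-effect model."""
    if dose <= 0:
        raise ValueError("dose must be positive")
    ratio = (dose / fit.dm) ** fit.m
    return ratio / (1.0 + ratio)


def ic50(fit: MedianEffectFit) -> float:
    """IC50 ≡ the median-effect dose Dm (the dose with fa = 0.5)."""
    return dose_for_effect(fit, 0.5)


def combination_index(
    combo: ComboMeasurement, fit1: MedianEffectFit, fit2: MedianEffectFit
) -> float:
    """Chou–Talalay CI at the combination's observed fraction affected."""
    dx1 = dose_for_effect(fit1, combo.fa)
    dx2 = dose_for_effect(fit2, combo.fa)
    return combo.d1 / dx1 + combo.d2 / dx2


def classify_ci(ci: float, epsilon: float = 0.05) -> str:
    """Trichotomy: synergism (CI < 1), additive effect (CI = 1), antagonism.

    A tolerance band of ±epsilon around 1 absorbs assay noise; epsilon = 0
    degenerates to the strict trichotomy.
    """
    if ci <= 0:
        raise ValueError("CI must be positive")
    if ci < 1.0 - epsilon:
        return "synergism"
    if ci > 1.0 + epsilon:
        return "antagonism"
    return "additive effect"


def isobologram_points(
    fit1: MedianEffectFit, fit2: MedianEffectFit, fa: float
) -> tuple[float, float]:
    """Axis intercepts (Dx1(fa), Dx2(fa)) of the additivity line.

    A combination point below the line joining the intercepts has CI < 1;
    a point on the line has CI = 1 exactly.
    """
    return dose_for_effect(fit1, fa), dose_for_effect(fit2, fa)
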