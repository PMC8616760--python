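"""Quantitative logic of the bench validation assays.

Three pieces: IUPAC consensus scanning of promoter/probe sequences for a
core binding motif (e.g. TTTCCT), design of consecutive tiling windows for
ChIP-qPCR primer walking across a promoter, and percent-input /
fold-enrichment arithmetic for ChIP-qPCR Ct tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from .genomic_io import SequenceRecord, reverse_complement

IUPAC = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}


@dataclass(frozen=True)
class MotifHit:
    """A motif occurrence, reported in forward-strand coordinates."""

    position: int
    strand: str
    matched: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be + or -")


@dataclass(frozen=True)
class CtMeasurement:
    """One ChIP-qPCR measurement: IP and input Ct with the input dilution."""

    ct_ip: float
    ct_input: float
    input_fraction: float
    label: str = ""

    def __post_init__(self) -> None:
        if not (0 < self.input_fraction <= 1):
            raise ValueError(
                f"input_fraction must lie in (0, 1], got {self.input_fraction}"
            )


def _check_motif(motif: str) -> str:
    motif = motif.upper()
    bad = set(motif) - set(IUPAC)
    if bad:
        raise ValueError(f"invalid IUPAC symbols in motif: {sorted(bad)}")
    if not motif:
        raise ValueError("motif must be non-empty")
    return motif


def _scan_one_strand(seq: str, motif: str) -> list[int]:
    # A sequence 'N' is unknown base and never matches, even against motif N.
    n, m = len(seq), len(motif)
    hits = []
    for i in range(n - m + 1):
        window = seq[i : i + m]
        if all(c != "N" and c in IUPAC[mc] for c, mc in zip(window, motif)):
            hits.append(i)
    return hits


def scan_motif(
    seq: SequenceRecord | str, motif: str, both_strands: bool = False
) -> list[MotifHit]:
    """All exact IUPAC matches of a motif, ascending by position.

    With ``both_strands``, reverse-complement matches are reported with
    strand '−' at the forward-strand coordinate of the match start;
    overlapping matches are allowed.
    """
    s = seq.seq if isinstance(seq, SequenceRecord) else SequenceRecord("q", seq).seq
    motif = _check_motif(motif)
    hits = [MotifHit(i, "+", s[i : i + len(motif)]) for i in _scan_one_strand(s, motif)]
    if both_strands:
        rc_motif = reverse_complement(motif)
        for i in _scan_one_strand(s, rc_motif):
            hits.append(MotifHit(i, "-", s[i : i + len(motif)]))
    return sorted(hits, key=lambda h: (h.position, h.strand))


def tiling_windows(
    region_start: int, region_end: int, width: int = 500
) -> list[tuple[int, int]]:
    """Consecutive left-aligned windows partitioning [region_start, region_end).

    Coordinates are signed offsets relative to the TSS; the last window is
    truncated when the width does not divide the span.  A −5000..0 promoter
    at 500-bp width yields the canonical ten primer-pair windows.
    """
    if width <= 0:
        raise ValueError(f"width must be positive, got {width}")
    if region_start > region_end:
        raise ValueError("region_start must not exceed region_end")
    out = []
    pos = region_start
    while pos < region_end:
        out.append((pos, min(pos + width, region_end)))
        pos += width
    return out


def percent_input(m: CtMeasurement) -> float:
    """ChIP-qPCR percent input.

    The input Ct is first adjusted to its 100% equivalent by subtracting
    log2(1/input_fraction) (e.g. 6.644 cycles for a 1% input aliquot), then
    the IP quantity relative to that adjusted input is expressed as a
    percentage:  100 × 2^(adjusted_input_Ct − IP_Ct).
    """
    adjusted_input = m.ct_input - math.log2(1.0 / m.input_fraction)
    return 100.0 * 2.0 ** (adjusted_input - m.ct_ip)


def enrichment_vs_control(ab: float, igg: float) -> float:
    """Fold enrichment of the antibody percent-input over the IgG control."""
    if igg <= 0:
        raise ValueError(f"control percent-input must be positive, got {igg}")
    return ab / igg


def percent_input_table(measurements: Sequence[CtMeasurement]) -> list[dict]:
    """Percent input per measurement with a flag for pathological (>100%) values."""
    out = []
    for m in measurements:
        pct = percent_input(m)
        out.append(
            {"label": m.label, "percent_input": pct, "exceeds_input": pct > 100.0}
        )
    return out
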