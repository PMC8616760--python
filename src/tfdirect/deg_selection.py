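"""Differential-expression selection under fold-change and adjusted-P cuts.

The default thresholds encode a 1.5-fold change on the log2 scale
(|log2FC| > 0.585) at adjusted P < 0.05, applied with strict inequalities,
so boundary genes are excluded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

from .genomic_io import DEGRecord


@dataclass(frozen=True)
class DEGCriteria:
    """Fold-change (log2) and adjusted-P thresholds, both strict."""

    lfc_threshold: float = 0.585
    padj_threshold: float = 0.05

    def __post_init__(self) -> None:
        if self.lfc_threshold <= 0:
            raise ValueError("lfc_threshold must be positive")
        if not (0 < self.padj_threshold <= 1):
            raise ValueError("padj_threshold must lie in (0, 1]")


@dataclass(frozen=True)
class DEGPartition:
    """Disjoint up/down/unchanged gene sets covering the input table."""

    up: frozenset[str]
    down: frozenset[str]
    unchanged: frozenset[str]

    def sign(self, gene_id: str) -> str:
        if gene_id in self.up:
            return "+"
        if gene_id in self.down:
            return "-"
        raise KeyError(f"{gene_id} is not a selected DEG")


def select_degs(
    table: Sequence[DEGRecord], criteria: DEGCriteria = DEGCriteria()
) -> DEGPartition:
    """Partition a DE table into up / down / unchanged gene sets.

    up: log2fc > lfc_threshold and padj < padj_threshold;
    down: log2fc < −lfc_threshold and padj < padj_threshold; strict
    inequalities throughout, so a gene sitting exactly on either threshold is
    unchanged.
    """
    if not table:
        raise ValueError("DE table must be nonempty")
    up, down, unchanged = set(), set(), set()
    for rec in table:
        if rec.padj < criteria.padj_threshold and rec.log2fc > criteria.lfc_threshold:
            up.add(rec.gene_id)
        elif rec.padj < criteria.padj_threshold and rec.log2fc < -criteria.lfc_threshold:
            down.add(rec.gene_id)
        else:
            unchanged.add(rec.gene_id)
    return DEGPartition(frozenset(up), frozenset(down), frozenset(unchanged))


def lfc_for_fold(fold: float) -> float:
    """log2 of a linear fold change; lfc_for_fold(1.5) ≈ 0.585."""
    if fold <= 1:
        raise ValueError(f"fold must exceed 1, got {fold}")
    return math.log2(fold)
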