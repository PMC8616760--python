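"""Intersect TSS-proximal TF binding with concordant differential expression.

A gene is a candidate direct target when (a) at least one ChIP-seq peak lies
within a window of its TSS (default 5000 bp, symmetric) and (b) it passed
differential-expression selection under TF perturbation.  The sign of the
expression change relative to the perturbation design labels each candidate
transactivated (the TF increases its expression) or repressed:  under a
knockdown, a transactivated target goes down.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

from .deg_selection import DEGPartition
from .genomic_io import DEGRecord, GeneModel, Peak
from .peak_annotation import tss_distance


class PerturbationDesign(str, Enum):
    """How the TF was perturbed for the RNA-seq arm."""

    knockdown = "knockdown"
    overexpression = "overexpression"


REGULATIONS = ("transactivated", "repressed")


@dataclass(frozen=True)
class CandidateTarget:
    """A gene passing both the binding-proximity and expression filters."""

    gene_id: str
    regulation: str
    n_peaks: int
    min_abs_tss_distance: int
    log2fc: float
    padj: float

    def __post_init__(self) -> None:
        if self.regulation not in REGULATIONS:
            raise ValueError(f"unknown regulation {self.regulation!r}")
        if self.n_peaks < 1:
            raise ValueError("a candidate needs at least one qualifying peak")


@dataclass(frozen=True)
class IntegrationResult:
    """Candidates plus bookkeeping on universe mismatches."""

    candidates: tuple[CandidateTarget, ...]
    bound_not_assayed: tuple[str, ...]  # proximal peak but no DE record
    n_de_without_gene_model: int  # selected DEGs absent from gene models


def regulation_class(log2fc_sign: str, design: PerturbationDesign) -> str:
    """Map the DE sign and perturbation design to a regulation label.

    Knockdown: a gene that drops when the TF is removed was transactivated
    by it; overexpression mirrors the mapping.
    """
    if log2fc_sign not in ("+", "-"):
        raise ValueError(f"sign must be '+' or '-', got {log2fc_sign!r}")
    design = PerturbationDesign(design)
    if design is PerturbationDesign.knockdown:
        return "transactivated" if log2fc_sign == "-" else "repressed"
    return "transactivated" if log2fc_sign == "+" else "repressed"


def proximal_genes_per_peak(
    peak: Peak,
    genes: Sequence[GeneModel],
    window: int,
    anchor: str = "summit",
) -> list[tuple[str, int]]:
    """All (gene_id, signed distance) pairs within the TSS window of a peak.

    Every qualifying gene is kept — a single peak may support several genes —
    unlike the single-gene assignment used for feature summaries.
    """
    out = []
    for g in genes:
        if g.body.chrom != peak.interval.chrom:
            continue
        d = tss_distance(peak, g, anchor=anchor)
        if abs(d) <= window:
            out.append((g.gene_id, d))
    return out


def integrate(
    peaks: Sequence[Peak],
    genes: Sequence[GeneModel],
    deg_partition: DEGPartition,
    design: PerturbationDesign,
    de_table: Sequence[DEGRecord] | None = None,
    window: int = 5000,
    keep: str = "both",
    anchor: str = "summit",
) -> IntegrationResult:
    """Call candidate direct targets of the TF.

    Parameters
    ----------
    de_table
        Used to attach log2fc/padj to candidates; when omitted they are
        reported as NaN.
    keep
        ``transactivated``, ``repressed`` or ``both``; restricting to
        transactivated reproduces the final filter of a knockdown screen
        focused on genes the TF switches on.
    """
    if keep not in ("transactivated", "repressed", "both"):
        raise ValueError(f"keep must be transactivated/repressed/both, got {keep!r}")
    design = PerturbationDesign(design)
    gene_ids = {g.gene_id for g in genes}
    de_by_gene = {r.gene_id: r for r in de_table} if de_table else {}

    # gene -> (n qualifying peaks, min |TSS distance|)
    hits: dict[str, list[int]] = {}
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.body.chrom, []).append(g)
    for p in peaks:
        for gid, d in proximal_genes_per_peak(
            p, by_chrom.get(p.interval.chrom, ()), window, anchor=anchor
        ):
            hits.setdefault(gid, []).append(abs(d))

    selected = set(deg_partition.up) | set(deg_partition.down)
    n_dropped = len(selected - gene_ids)

    candidates = []
    for gid, dists in hits.items():
        if gid not in selected:
            continue
        sign = "+" if gid in deg_partition.up else "-"
        reg = regulation_class(sign, design)
        if keep != "both" and reg != keep:
            continue
        rec = de_by_gene.get(gid)
        candidates.append(
            CandidateTarget(
                gene_id=gid,
                regulation=reg,
                n_peaks=len(dists),
                min_abs_tss_distance=min(dists),
                log2fc=rec.log2fc if rec else float("nan"),
                padj=rec.padj if rec else float("nan"),
            )
        )
    candidates.sort(key=lambda c: (c.regulation, c.min_abs_tss_distance, c.gene_id))

    assayed = selected | set(deg_partition.unchanged) if deg_partition else selected
    bound_not_assayed = tuple(
        sorted(gid for gid in hits if de_by_gene and gid not in de_by_gene)
        if de_by_gene
        else sorted(gid for gid in hits if gid not in assayed)
    )
    return IntegrationResult(tuple(candidates), bound_not_assayed, n_dropped)
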