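"""Strand-aware annotation of ChIP-seq peaks against gene models.

Each peak receives a signed TSS distance (negative = upstream in the gene's
own orientation) and one of four feature classes — promoter, exon, intron,
intergenic — with promoter > exon > intron priority and a configurable
promoter half-width (default 5000 bp around the TSS).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Sequence

from .genomic_io import GeneModel, Peak

ANCHORS = ("summit", "midpoint", "nearest_edge")
FEATURE_CLASSES = ("promoter", "exon", "intron", "intergenic")


@dataclass(frozen=True)
class PeakAnnotation:
    """One peak's assignment to a gene and genomic feature class."""

    peak_index: int
    gene_id: str | None
    tss_distance: int | None
    feature_class: str

    def __post_init__(self) -> None:
        if self.feature_class not in FEATURE_CLASSES:
            raise ValueError(f"unknown feature_class {self.feature_class!r}")
        if (self.gene_id is None) != (self.feature_class == "intergenic"):
            raise ValueError("gene_id must be None exactly for intergenic peaks")
        if (self.gene_id is None) != (self.tss_distance is None):
            raise ValueError("tss_distance defined iff a gene is assigned")


def tss_of(gene: GeneModel) -> int:
    """Transcription start site: body.start on +, body.end − 1 on −."""
    return gene.body.start if gene.body.strand == "+" else gene.body.end - 1


def anchor_position(peak: Peak, anchor: str = "summit") -> int:
    """Resolve a peak to a single representative base.

    ``summit`` falls back to the midpoint when no summit was recorded (the
    fallback every anchor-based computation in the package uses).
    """
    if anchor == "summit":
        return peak.summit if peak.summit is not None else peak.midpoint
    if anchor == "midpoint":
        return peak.midpoint
    raise ValueError(f"anchor must resolve to a point, got {anchor!r}")


def tss_distance(peak: Peak, gene: GeneModel, anchor: str = "summit") -> int:
    """Signed peak-to-TSS distance in the gene's orientation.

    Negative means the peak lies upstream of the TSS.  With
    ``anchor='nearest_edge'`` a peak overlapping the TSS has distance 0.
    """
    if anchor not in ANCHORS:
        raise ValueError(f"anchor must be one of {ANCHORS}, got {anchor!r}")
    if peak.interval.chrom != gene.body.chrom:
        raise ValueError(
            f"peak on {peak.interval.chrom} vs gene {gene.gene_id} on "
            f"{gene.body.chrom}: prefilter by chromosome"
        )
    tss = tss_of(gene)
    if anchor == "nearest_edge":
        if peak.interval.contains(tss):
            raw = 0
        elif peak.interval.start > tss:
            raw = peak.interval.start - tss
        else:
            raw = (peak.interval.end - 1) - tss
    else:
        raw = anchor_position(peak, anchor) - tss
    return raw if gene.body.strand == "+" else -raw


def _feature_for(
    peak: Peak,
    gene: GeneModel,
    promoter_halfwidth: int,
    anchor: str,
    upstream_only: bool,
) -> tuple[str, int] | None:
    """Feature class and TSS distance of one peak relative to one gene.

    Returns None when the peak is unrelated to the gene (intergenic w.r.t. it).
    Membership in exon/intron is judged at the peak's point anchor.
    """
    if peak.interval.chrom != gene.body.chrom:
        return None
    d = tss_distance(peak, gene, anchor=anchor)
    in_promoter = (
        (-promoter_halfwidth <= d <= 0)
        if upstream_only
        else (abs(d) <= promoter_halfwidth)
    )
    if in_promoter:
        return ("promoter", d)
    pos = anchor_position(peak, "summit" if anchor == "nearest_edge" else anchor)
    if gene.body.contains(pos):
        if any(ex.contains(pos) for ex in gene.exons):
            return ("exon", d)
        return ("intron", d)
    return None


def classify_peak(
    peak: Peak,
    genes: Sequence[GeneModel],
    promoter_halfwidth: int = 5000,
    anchor: str = "summit",
    upstream_only: bool = False,
    peak_index: int = 0,
) -> PeakAnnotation:
    """Classify one peak against a gene set.

    Priority promoter > exon > intron > intergenic; within a class the gene
    with the smallest |TSS distance| wins, ties broken by gene_id.
    """
    best: dict[str, tuple[int, str, int]] = {}
    for gene in genes:
        res = _feature_for(peak, gene, promoter_halfwidth, anchor, upstream_only)
        if res is None:
            continue
        fclass, d = res
        key = (abs(d), gene.gene_id)
        if fclass not in best or key < (abs(best[fclass][0]), best[fclass][1]):
            best[fclass] = (d, gene.gene_id, abs(d))
    for fclass in ("promoter", "exon", "intron"):
        if fclass in best:
            d, gid, _ = best[fclass]
            return PeakAnnotation(peak_index, gid, d, fclass)
    return PeakAnnotation(peak_index, None, None, "intergenic")


def annotate_peaks(
    peaks: Sequence[Peak],
    genes: Sequence[GeneModel],
    promoter_halfwidth: int = 5000,
    anchor: str = "summit",
    upstream_only: bool = False,
) -> list[PeakAnnotation]:
    """Annotate every peak; genes are pre-bucketed by chromosome."""
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.body.chrom, []).append(g)
    out = []
    for i, p in enumerate(peaks):
        out.append(
            classify_peak(
                p,
                by_chrom.get(p.interval.chrom, ()),
                promoter_halfwidth=promoter_halfwidth,
                anchor=anchor,
                upstream_only=upstream_only,
                peak_index=i,
            )
        )
    return out


def feature_class_counts(annotations: Sequence[PeakAnnotation]) -> dict[str, int]:
    """Counts per feature class, all four classes always present."""
    counts = Counter(a.feature_class for a in annotations)
    return {fc: counts.get(fc, 0) for fc in FEATURE_CLASSES}
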