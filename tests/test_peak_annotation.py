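"""TSS distances and feature classification, checked against brute force."""

import numpy as np
import pytest

from tfdirect.genomic_io import GeneModel, GenomicInterval, Peak
from tfdirect.peak_annotation import (
    annotate_peaks,
    classify_peak,
    feature_class_counts,
    tss_distance,
    tss_of,
)


def make_gene(gene_id, start, end, strand, exons=(), chrom="chr1"):
    return GeneModel(
        gene_id, gene_id, GenomicInterval(chrom, start, end, strand),
        tuple(GenomicInterval(chrom, s, e, strand) for s, e in exons),
    )


class TestTss:
    def test_plus_strand_tss_is_start(self):
        assert tss_of(make_gene("g", 100, 500, "+")) == 100

    def test_minus_strand_tss_is_last_base(self):
        assert tss_of(make_gene("g", 100, 500, "-")) == 499

    def test_tss_ignores_exons(self):
        bare = make_gene("g", 100, 500, "+")
        with_exons = make_gene("g", 100, 500, "+", [(100, 200), (300, 500)])
        assert tss_of(bare) == tss_of(with_exons)


class TestTssDistance:
    def test_downstream_of_plus_gene(self, peak_at):
        gene = make_gene("g", 100, 5000, "+")
        assert tss_distance(peak_at(900), gene) == 800

    def test_upstream_of_minus_gene(self, peak_at):
        gene = make_gene("g", 100, 500, "-")  # TSS 499
        assert tss_distance(peak_at(900), gene) == -401

    def test_chromosome_mismatch_errors(self, peak_at):
        gene = make_gene("g", 100, 500, "+", chrom="chr2")
        with pytest.raises(ValueError, match="chr"):
            tss_distance(peak_at(900), gene)

    def test_nearest_edge_zero_on_overlap(self):
        gene = make_gene("g", 1000, 5000, "+")  # TSS 1000
        peak = Peak(GenomicInterval("chr1", 900, 1100))
        assert tss_distance(peak, gene, anchor="nearest_edge") == 0

    def test_agrees_with_per_base_brute_force(self):
        """nearest_edge distance equals the min over every base of the peak."""
        rng = np.random.default_rng(7)
        for _ in range(200):
            start = int(rng.integers(0, 5000))
            width = int(rng.integers(1, 300))
            peak = Peak(GenomicInterval("chr1", start, start + width))
            gstart = int(rng.integers(0, 5000))
            glen = int(rng.integers(100, 2000))
            strand = "+" if rng.random() < 0.5 else "-"
            gene = make_gene("g", gstart, gstart + glen, strand)
            tss = tss_of(gene)
            base_d = min(
                (abs(pos - tss), pos - tss)
                for pos in range(peak.interval.start, peak.interval.end)
            )[1]
            expected = base_d if strand == "+" else -base_d
            assert tss_distance(peak, gene, anchor="nearest_edge") == expected

    def test_summit_falls_back_to_midpoint(self):
        gene = make_gene("g", 0, 100, "+")
        peak = Peak(GenomicInterval("chr1", 200, 300))  # no summit
        assert tss_distance(peak, gene, anchor="summit") == peak.midpoint


def brute_force_classify(peak, genes, halfwidth, anchor="summit"):
    """Independent per-pair classification: exhaustive, no bucketing."""
    from tfdirect.peak_annotation import anchor_position

    per_class = {"promoter": [], "exon": [], "intron": []}
    for g in genes:
        if g.body.chrom != peak.interval.chrom:
            continue
        d = tss_distance(peak, g, anchor=anchor)
        pos = anchor_position(peak, anchor)
        if abs(d) <= halfwidth:
            per_class["promoter"].append((abs(d), g.gene_id, d))
        elif g.body.start <= pos < g.body.end:
            if any(e.start <= pos < e.end for e in g.exons):
                per_class["exon"].append((abs(d), g.gene_id, d))
            else:
                per_class["intron"].append((abs(d), g.gene_id, d))
    for fc in ("promoter", "exon", "intron"):
        if per_class[fc]:
            absd, gid, d = min(per_class[fc])
            return fc, gid, d
    return "intergenic", None, None


class TestClassify:
    def test_promoter_within_halfwidth(self, peak_at):
        gene = make_gene("g", 10_000, 20_000, "+")
        ann = classify_peak(peak_at(8_800), [gene])  # 1200 bp upstream
        assert ann.feature_class == "promoter" and ann.tss_distance == -1200

    def test_exon_beyond_promoter_window(self, peak_at):
        gene = make_gene("g", 10_000, 20_000, "+", [(16_800, 17_400)])
        ann = classify_peak(peak_at(17_000), [gene])  # 7000 bp from TSS
        assert ann.feature_class == "exon" and ann.gene_id == "g"

    def test_intron_beyond_promoter_window(self, peak_at):
        gene = make_gene("g", 10_000, 20_000, "+", [(10_000, 10_100)])
        ann = classify_peak(peak_at(17_000), [gene])
        assert ann.feature_class == "intron"

    def test_empty_gene_list_gives_intergenic(self, peak_at):
        ann = classify_peak(peak_at(1_000), [])
        assert ann.feature_class == "intergenic" and ann.gene_id is None

    def test_boundary_inclusive(self, peak_at):
        gene = make_gene("g", 50_000, 60_000, "+")
        assert classify_peak(peak_at(45_000), [gene]).feature_class == "promoter"
        assert classify_peak(peak_at(44_999), [gene]).feature_class == "intergenic"

    def test_upstream_only_mode(self, peak_at):
        gene = make_gene("g", 50_000, 60_000, "+")
        down = peak_at(53_000)  # +3000, inside gene
        assert classify_peak(down, [gene], upstream_only=True).feature_class != "promoter"
        up = peak_at(47_000)
        assert classify_peak(up, [gene], upstream_only=True).feature_class == "promoter"

    def test_nearest_gene_wins_ties_by_id(self, peak_at):
        g1 = make_gene("gB", 10_000, 12_000, "+")
        g2 = make_gene("gA", 6_000, 8_000, "-")  # TSS 7999, |d| 1001 from 9000
        peak = peak_at(9_000)
        ann = classify_peak(peak, [g1, g2])
        assert ann.gene_id == "gB"  # |d|=1000 < 1001
        g3 = make_gene("gC", 11_000, 13_000, "+")  # also |d|=2000? pick equal case
        gx = make_gene("gX", 8_000, 9_500, "+")  # TSS 8000, |d| = 1000 ties with gB
        ann = classify_peak(peak, [g1, gx])
        assert ann.gene_id == "gB"  # lexicographic tie-break

    def test_matches_exhaustive_oracle_on_random_instances(self):
        rng = np.random.default_rng(13)
        genes = []
        for i in range(50):
            start = int(rng.integers(0, 200_000))
            length = int(rng.integers(500, 8_000))
            strand = "+" if rng.random() < 0.5 else "-"
            n_ex = int(rng.integers(0, 3))
            exons = []
            if n_ex:
                cuts = np.sort(
                    rng.choice(np.arange(start + 1, start + length), 2 * n_ex, replace=False)
                )
                exons = [(int(cuts[2 * k]), int(cuts[2 * k + 1])) for k in range(n_ex)]
            genes.append(make_gene(f"g{i:02d}", start, start + length, strand, exons))
        for _ in range(200):
            s = int(rng.integers(0, 210_000))
            w = int(rng.integers(50, 1_000))
            peak = Peak(GenomicInterval("chr1", s, s + w), int(rng.integers(0, w)))
            ann = classify_peak(peak, genes, promoter_halfwidth=5000)
            fc, gid, d = brute_force_classify(peak, genes, 5000)
            assert (ann.feature_class, ann.gene_id, ann.tss_distance) == (fc, gid, d)


class TestProperties:
    def _random_scene(self, seed, shift=0, mirror=False, span=300_000):
        rng = np.random.default_rng(seed)
        genes, peaks = [], []
        for i in range(20):
            start = int(rng.integers(0, span))
            length = int(rng.integers(500, 6_000))
            strand = "+" if rng.random() < 0.5 else "-"
            s, e = start, start + length
            if mirror:
                s, e = span - e, span - s
                strand = "-" if strand == "+" else "+"
            genes.append(make_gene(f"g{i:02d}", s + shift, e + shift, strand))
        for _ in range(60):
            ps = int(rng.integers(0, span))
            w = int(rng.integers(50, 800))
            off = int(rng.integers(0, w))
            s, e = ps, ps + w
            if mirror:
                s, e = span - e, span - s
                off = (w - 1) - off
            peaks.append(Peak(GenomicInterval("chr1", s + shift, e + shift), off))
        return genes, peaks

    def test_translation_invariance(self):
        g0, p0 = self._random_scene(5)
        g1, p1 = self._random_scene(5, shift=12_345)
        a0 = annotate_peaks(p0, g0)
        a1 = annotate_peaks(p1, g1)
        assert [(a.feature_class, a.gene_id, a.tss_distance) for a in a0] == [
            (a.feature_class, a.gene_id, a.tss_distance) for a in a1
        ]

    def test_strand_mirror_preserves_class_and_magnitude(self):
        g0, p0 = self._random_scene(9)
        g1, p1 = self._random_scene(9, mirror=True)
        a0 = annotate_peaks(p0, g0)
        a1 = annotate_peaks(p1, g1)
        for x, y in zip(a0, a1):
            assert x.feature_class == y.feature_class
            if x.tss_distance is not None:
                assert abs(x.tss_distance) == abs(y.tss_distance)

    def test_partition_counts_sum_to_peak_count(self):
        g, p = self._random_scene(21)
        counts = feature_class_counts(annotate_peaks(p, g))
        assert sum(counts.values()) == len(p)
        assert set(counts) == {"promoter", "exon", "intron", "intergenic"}
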