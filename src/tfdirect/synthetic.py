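"""Synthetic inputs with planted ground truth for every pipeline stage.

The generator emulates the data a TF direct-target study consumes: a genome
with non-overlapping annotated genes, ChIP-seq peaks planted near the TSS of
designated target genes (plus intergenic background peaks kept ≥ 10 kb from
every TSS so that specificity tests are exact), a differential-expression
table in which targets carry sign-concordant effects, and median-effect
dose–response curves with known (m, Dm).  One global seed fans out to fixed,
labelled substreams, so regenerating one component never perturbs another.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .genomic_io import (
    DEGRecord,
    GeneModel,
    GenomicInterval,
    Peak,
    SequenceRecord,
    write_deg_table,
    write_fasta,
    write_gene_models,
    write_peaks,
)
from .peak_annotation import tss_of
from .synergy import ComboMeasurement, DoseResponseCurve, MedianEffectFit, dose_for_effect
from .target_integration import PerturbationDesign

CORE_MOTIF = "TTTCCT"
TSS_EXCLUSION_BP = 10_000  # background peaks stay this far from every TSS


def substream(seed: int, label: str) -> np.random.Generator:
    """A named, reproducible child stream of the global seed."""
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(zlib.crc32(label.encode()),))
    )


@dataclass
class SimulationTruth:
    """Planted ground truth: targets, peak provenance, and parameters."""

    targets: dict[str, str]  # gene_id -> regulation label
    peak_to_gene: dict[int, str | None]  # peak index -> planted gene (None = background)
    params: dict = field(default_factory=dict)
    seed: int = 0

    def to_json(self, path: str | Path) -> None:
        payload = {
            "targets": self.targets,
            "peak_to_gene": {str(k): v for k, v in self.peak_to_gene.items()},
            "params": self.params,
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            targets=d["targets"],
            peak_to_gene={int(k): v for k, v in d["peak_to_gene"].items()},
            params=d.get("params", {}),
            seed=d.get("seed", 0),
        )


# ---------------------------------------------------------------------------
# genome and genes


def generate_genome(
    n_genes: int,
    chrom_length_bp: int = 10_000_000,
    min_gene_len: int = 2_000,
    max_gene_len: int = 10_000,
    seed: int = 0,
    chrom: str = "chr1",
    max_exons: int = 3,
) -> tuple[list[GeneModel], SequenceRecord]:
    """Place non-overlapping genes uniformly on a random genome.

    Gene starts are rejection-sampled against previously placed genes
    (bounded retries, error on infeasible packing); strands are fair coin
    flips; the genome sequence is i.i.d. uniform over {A, C, G, T}.
    """
    if chrom_length_bp <= 0 or min_gene_len <= 0 or max_gene_len < min_gene_len:
        raise ValueError("invalid genome parameters")
    rng = substream(seed, "genome")
    seq_codes = rng.integers(0, 4, size=chrom_length_bp, dtype=np.uint8)
    genome_seq = seq_codes.choose(np.frombuffer(b"ACGT", dtype=np.uint8)).tobytes().decode()
    genome = SequenceRecord(chrom, genome_seq)

    placed: list[tuple[int, int]] = []
    genes: list[GeneModel] = []
    for i in range(n_genes):
        length = int(rng.integers(min_gene_len, max_gene_len + 1))
        for _attempt in range(1_000):
            start = int(rng.integers(0, chrom_length_bp - length))
            end = start + length
            if all(end <= s or start >= e for s, e in placed):
                break
        else:
            raise RuntimeError(
                f"could not place gene {i + 1}/{n_genes} after 1000 tries; "
                "reduce n_genes or gene lengths, or enlarge the chromosome"
            )
        placed.append((start, end))
        strand = "+" if rng.random() < 0.5 else "-"
        body = GenomicInterval(chrom, start, end, strand)
        n_exons = int(rng.integers(0, max_exons + 1))
        exons: tuple[GenomicInterval, ...] = ()
        if n_exons:
            cuts = np.sort(rng.choice(np.arange(start + 1, end), 2 * n_exons, replace=False))
            exons = tuple(
                GenomicInterval(chrom, int(cuts[2 * k]), int(cuts[2 * k + 1]), strand)
                for k in range(n_exons)
            )
        genes.append(GeneModel(f"G{i + 1:04d}", f"gene{i + 1}", body, exons))
    genes.sort(key=lambda g: g.body.start)
    return genes, genome


def pick_targets(
    genes: Sequence[GeneModel],
    n_transactivated: int,
    n_repressed: int,
    seed: int = 0,
) -> dict[str, str]:
    """Designate planted target genes with their regulation labels."""
    if n_transactivated + n_repressed > len(genes):
        raise ValueError("more targets requested than genes available")
    rng = substream(seed, "targets")
    ids = sorted(g.gene_id for g in genes)
    chosen = rng.choice(len(ids), size=n_transactivated + n_repressed, replace=False)
    labels = {}
    for j, idx in enumerate(sorted(int(c) for c in chosen)):
        labels[ids[idx]] = "transactivated" if j < n_transactivated else "repressed"
    return labels


# ---------------------------------------------------------------------------
# peaks


def _background_segments(
    genes: Sequence[GeneModel], chrom_length: int, margin: int
) -> list[tuple[int, int]]:
    """Intervals of the chromosome ≥ ``margin`` bp from every TSS."""
    forbidden = sorted(
        (max(0, tss_of(g) - margin), min(chrom_length, tss_of(g) + margin + 1))
        for g in genes
    )
    segments, pos = [], 0
    for s, e in forbidden:
        if s > pos:
            segments.append((pos, s))
        pos = max(pos, e)
    if pos < chrom_length:
        segments.append((pos, chrom_length))
    return segments


def generate_peaks(
    genes: Sequence[GeneModel],
    truth_targets: Mapping[str, str],
    chrom_length_bp: int,
    planting_halfwidth: int = 2_000,
    n_background: int = 200,
    peak_width_range: tuple[int, int] = (200, 600),
    embed_motif: bool = False,
    genome: SequenceRecord | None = None,
    seed: int = 0,
) -> tuple[list[Peak], dict[int, str | None], SequenceRecord | None]:
    """Plant one peak per target near its TSS plus intergenic background.

    Each target receives exactly one peak whose summit is uniform within
    ±planting_halfwidth of the TSS; background summits are uniform over the
    chromosome excluding ``TSS_EXCLUSION_BP`` around every TSS.  With
    ``embed_motif`` the core motif string is written into the genome at each
    planted summit and the edited genome is returned.
    """
    by_id = {g.gene_id: g for g in genes}
    missing = set(truth_targets) - set(by_id)
    if missing:
        raise ValueError(f"truth targets not among genes: {sorted(missing)}")
    rng = substream(seed, "peaks")
    wmin, wmax = peak_width_range
    if not (0 < wmin <= wmax):
        raise ValueError("invalid peak_width_range")
    chrom = genes[0].body.chrom if genes else (genome.id if genome else "chr1")

    peaks: list[Peak] = []
    peak_to_gene: dict[int, str | None] = {}
    genome_chars = list(genome.seq) if (embed_motif and genome is not None) else None

    def add_peak(summit: int, gene_id: str | None) -> None:
        width = int(rng.integers(wmin, wmax + 1))
        start = max(0, summit - width // 2)
        end = min(chrom_length_bp, start + width)
        if summit >= end:
            start, end = summit, summit + 1
        peak_to_gene[len(peaks)] = gene_id
        peaks.append(Peak(GenomicInterval(chrom, start, end, "."), summit - start, None))
        if genome_chars is not None and summit + len(CORE_MOTIF) <= len(genome_chars):
            genome_chars[summit : summit + len(CORE_MOTIF)] = CORE_MOTIF

    for gid in sorted(truth_targets):
        tss = tss_of(by_id[gid])
        lo = max(0, tss - planting_halfwidth)
        hi = min(chrom_length_bp - 1, tss + planting_halfwidth)
        add_peak(int(rng.integers(lo, hi + 1)), gid)

    if n_background:
        segments = [
            (s, e)
            for s, e in _background_segments(genes, chrom_length_bp, TSS_EXCLUSION_BP)
            if e - s > 1
        ]
        if not segments:
            raise RuntimeError("no intergenic space left for background peaks")
        lengths = np.array([e - s for s, e in segments], dtype=float)
        probs = lengths / lengths.sum()
        for _ in range(n_background):
            k = int(rng.choice(len(segments), p=probs))
            s, e = segments[k]
            add_peak(int(rng.integers(s, e)), None)

    edited = (
        SequenceRecord(genome.id, "".join(genome_chars)) if genome_chars is not None else genome
    )
    return peaks, peak_to_gene, edited


# ---------------------------------------------------------------------------
# differential expression


def _target_sign(regulation: str, design: PerturbationDesign) -> float:
    # transactivated target: TF drives it up, so knockdown lowers it
    down = (regulation == "transactivated") == (design is PerturbationDesign.knockdown)
    return -1.0 if down else 1.0


def generate_de_table(
    genes: Sequence[GeneModel],
    truth_targets: Mapping[str, str],
    design: PerturbationDesign = PerturbationDesign.knockdown,
    effect_lfc: float = 1.0,
    effect_sd: float = 0.1,
    null_sd: float = 0.2,
    sig_padj_range: tuple[float, float] = (1e-6, 0.01),
    null_padj_range: tuple[float, float] = (0.05, 1.0),
    seed: int = 0,
) -> list[DEGRecord]:
    """Perturbation DE table: concordant effects for targets, noise elsewhere.

    Targets get log2fc = s·(effect_lfc + N(0, effect_sd)) with the sign s
    implied by the regulation label and the design, and a significant padj;
    every other gene gets N(0, null_sd) fold change and a non-significant
    padj.  Zero-noise settings make truth recovery exact.
    """
    design = PerturbationDesign(design)
    rng = substream(seed, "de")
    records = []
    for g in sorted(genes, key=lambda g: g.gene_id):
        if g.gene_id in truth_targets:
            s = _target_sign(truth_targets[g.gene_id], design)
            lfc = s * (effect_lfc + (rng.normal(0.0, effect_sd) if effect_sd else 0.0))
            padj = float(rng.uniform(*sig_padj_range))
        else:
            lfc = float(rng.normal(0.0, null_sd)) if null_sd else 0.0
            padj = float(rng.uniform(*null_padj_range))
        records.append(DEGRecord(g.gene_id, float(lfc), padj))
    return records


def generate_deg_count_fixture(
    n_up: int = 1004,
    n_down: int = 355,
    n_null: int = 12_000,
    criteria_lfc: float = 0.585,
    criteria_padj: float = 0.05,
    seed: int = 0,
) -> list[DEGRecord]:
    """A DE table planting exact up/down counts (defaults echo a knockdown
    screen with 1004 up- and 355 downregulated genes).

    Up genes draw log2fc strictly above the fold cutoff, down genes strictly
    below its negation, null genes inside the unselected region, so the
    selection counts are exact by construction.
    """
    rng = substream(seed, "deg_fixture")
    records = []
    i = 0
    for _ in range(n_up):
        i += 1
        records.append(
            DEGRecord(
                f"F{i:06d}",
                float(rng.uniform(criteria_lfc + 0.05, 4.0)),
                float(rng.uniform(1e-8, criteria_padj * 0.5)),
            )
        )
    for _ in range(n_down):
        i += 1
        records.append(
            DEGRecord(
                f"F{i:06d}",
                float(-rng.uniform(criteria_lfc + 0.05, 4.0)),
                float(rng.uniform(1e-8, criteria_padj * 0.5)),
            )
        )
    for _ in range(n_null):
        i += 1
        records.append(
            DEGRecord(
                f"F{i:06d}",
                float(rng.uniform(-criteria_lfc * 0.9, criteria_lfc * 0.9)),
                float(rng.uniform(criteria_padj, 1.0)),
            )
        )
    return records


# ---------------------------------------------------------------------------
# dose–response


def generate_dose_response(
    m: float,
    dm: float,
    doses: Sequence[float],
    logit_noise_sd: float = 0.0,
    seed: int = 0,
) -> DoseResponseCurve:
    """Median-effect dose–response with optional logit-scale Gaussian noise."""
    if m <= 0 or dm <= 0:
        raise ValueError("m and dm must be positive")
    doses = np.asarray(doses, dtype=float)
    if np.any(doses <= 0):
        raise ValueError("doses must be positive")
    rng = substream(seed, "dose_response")
    ratio = (doses / dm) ** m
    fa = ratio / (1.0 + ratio)
    if logit_noise_sd:
        logit = np.log(fa / (1.0 - fa)) + rng.normal(0.0, logit_noise_sd, size=len(fa))
        fa = 1.0 / (1.0 + np.exp(-logit))
    fa = np.clip(fa, 1e-6, 1.0 - 1e-6)
    return DoseResponseCurve(doses.tolist(), fa.tolist())


def generate_additive_combos(
    fit1: MedianEffectFit,
    fit2: MedianEffectFit,
    fa_values: Sequence[float],
    mixing: float = 0.5,
) -> list[ComboMeasurement]:
    """Loewe-additive combination points (CI = 1 by construction).

    At each effect level fa the pair (λ·Dx1(fa), (1−λ)·Dx2(fa)) sits exactly
    on the additivity isobole of the two fitted agents.
    """
    if not (0.0 < mixing < 1.0):
        raise ValueError("mixing must lie strictly inside (0, 1)")
    return [
        ComboMeasurement(
            mixing * dose_for_effect(fit1, fa),
            (1.0 - mixing) * dose_for_effect(fit2, fa),
            fa,
        )
        for fa in fa_values
    ]


# ---------------------------------------------------------------------------
# whole-dataset simulation


def simulate_dataset(
    outdir: str | Path,
    seed: int = 0,
    n_genes: int = 100,
    n_transactivated: int = 5,
    n_repressed: int = 3,
    n_background_peaks: int = 200,
    chrom_length_bp: int = 10_000_000,
    planting_halfwidth: int = 2_000,
    design: PerturbationDesign = PerturbationDesign.knockdown,
    effect_lfc: float = 1.0,
    effect_sd: float = 0.1,
    null_sd: float = 0.2,
    embed_motif: bool = True,
    drug_params: tuple[tuple[float, float], tuple[float, float]] = ((2.0, 10.0), (1.5, 0.5)),
    doses_per_drug: int = 6,
    write_genome: bool = True,
) -> SimulationTruth:
    """Generate and write a complete synthetic study to ``outdir``.

    Emits genes.gff3, genome.fa, peaks.bed, de_table.tsv, per-drug
    dose–response TSVs, a Loewe-additive combination TSV, and truth.json.
    Every text output carries the seed in a header comment.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    design = PerturbationDesign(design)

    genes, genome = generate_genome(
        n_genes, chrom_length_bp=chrom_length_bp, seed=seed
    )
    targets = pick_targets(genes, n_transactivated, n_repressed, seed=seed)
    peaks, peak_to_gene, genome_out = generate_peaks(
        genes,
        targets,
        chrom_length_bp=chrom_length_bp,
        planting_halfwidth=planting_halfwidth,
        n_background=n_background_peaks,
        embed_motif=embed_motif,
        genome=genome,
        seed=seed,
    )
    de_table = generate_de_table(
        genes,
        targets,
        design=design,
        effect_lfc=effect_lfc,
        effect_sd=effect_sd,
        null_sd=null_sd,
        seed=seed,
    )

    tag = f"seed={seed}"
    write_gene_models(genes, outdir / "genes.gff3", "gff3", header_comment=tag)
    write_peaks(peaks, outdir / "peaks.bed", header_comment=tag)
    write_deg_table(de_table, outdir / "de_table.tsv", header_comment=tag)
    if write_genome and genome_out is not None:
        write_fasta([genome_out], outdir / "genome.fa")

    (m1, dm1), (m2, dm2) = drug_params
    doses1 = [dm1 * 2.0 ** (k - doses_per_drug // 2) for k in range(doses_per_drug)]
    doses2 = [dm2 * 2.0 ** (k - doses_per_drug // 2) for k in range(doses_per_drug)]
    curve1 = generate_dose_response(m1, dm1, doses1, logit_noise_sd=0.0, seed=seed)
    curve2 = generate_dose_response(m2, dm2, doses2, logit_noise_sd=0.0, seed=seed + 1)
    for name, curve in (("drug1", curve1), ("drug2", curve2)):
        with open(outdir / f"{name}_dose_response.tsv", "w") as fh:
            fh.write(f"# {tag}\ndose\tfa\n")
            for d, f in zip(curve.doses, curve.fa):
                fh.write(f"{d:.10g}\t{f:.10g}\n")
    combos = generate_additive_combos(
        MedianEffectFit(m1, dm1, 1.0),
        MedianEffectFit(m2, dm2, 1.0),
        fa_values=[0.2, 0.35, 0.5, 0.65, 0.8],
    )
    with open(outdir / "combination.tsv", "w") as fh:
        fh.write(f"# {tag}\nd1\td2\tfa\n")
        for c in combos:
            fh.write(f"{c.d1:.10g}\t{c.d2:.10g}\t{c.fa:.10g}\n")

    truth = SimulationTruth(
        targets=targets,
        peak_to_gene=peak_to_gene,
        params={
            "n_genes": n_genes,
            "n_background_peaks": n_background_peaks,
            "chrom_length_bp": chrom_length_bp,
            "planting_halfwidth": planting_halfwidth,
            "design": design.value,
            "effect_lfc": effect_lfc,
            "effect_sd": effect_sd,
            "null_sd": null_sd,
            "embed_motif": embed_motif,
            "drug_params": [[m1, dm1], [m2, dm2]],
        },
        seed=seed,
    )
    truth.to_json(outdir / "truth.json")
    return truth
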