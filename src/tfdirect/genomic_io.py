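"""Core genomic data types and readers/writers.

All coordinates are held internally as 0-based half-open intervals on the
forward strand.  GFF3 (1-based, fully closed) is converted at the boundary;
BED passes through unchanged.  Readers validate every record against the
type invariants and reject rather than repair: a malformed or impossible
record raises :class:`ParseError` naming the offending line.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

STRANDS = ("+", "-", ".")
DNA_ALPHABET = frozenset("ACGTN")


class ParseError(ValueError):
    """A file record violated the expected dialect or a type invariant."""


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval [start, end) with optional strand."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass(frozen=True)
class GeneModel:
    """A gene body with strand and (optionally) its exon structure.

    The transcription start site is derived from body and strand alone:
    ``body.start`` on the + strand, ``body.end - 1`` on the − strand.
    """

    gene_id: str
    name: str
    body: GenomicInterval
    exons: tuple[GenomicInterval, ...] = ()

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")
        if self.body.strand not in ("+", "-"):
            raise ValueError(
                f"gene {self.gene_id}: strand must be + or -, got {self.body.strand!r}"
            )
        object.__setattr__(self, "exons", tuple(self.exons))
        prev_end = None
        for ex in self.exons:
            if ex.chrom != self.body.chrom:
                raise ValueError(f"gene {self.gene_id}: exon on wrong chromosome")
            if ex.start < self.body.start or ex.end > self.body.end:
                raise ValueError(f"gene {self.gene_id}: exon outside gene body")
            if prev_end is not None and ex.start < prev_end:
                raise ValueError(f"gene {self.gene_id}: exons overlap or are unsorted")
            prev_end = ex.end


@dataclass(frozen=True)
class Peak:
    """A ChIP-seq interval, optionally carrying a summit and a score."""

    interval: GenomicInterval
    summit_offset: int | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if self.summit_offset is not None and not (
            0 <= self.summit_offset < len(self.interval)
        ):
            raise ValueError(
                f"summit_offset {self.summit_offset} outside peak of length "
                f"{len(self.interval)}"
            )
        if self.score is not None and self.score < 0:
            raise ValueError("score must be non-negative")

    @property
    def summit(self) -> int | None:
        """Absolute summit position, when a summit was recorded."""
        if self.summit_offset is None:
            return None
        return self.interval.start + self.summit_offset

    @property
    def midpoint(self) -> int:
        """Interval midpoint (floor for even lengths)."""
        return (self.interval.start + self.interval.end - 1) // 2


@dataclass(frozen=True)
class DEGRecord:
    """One gene's differential-expression result under TF perturbation."""

    gene_id: str
    log2fc: float
    padj: float

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")
        if not (0.0 <= self.padj <= 1.0):
            raise ValueError(f"padj must lie in [0, 1], got {self.padj}")


@dataclass(frozen=True)
class SequenceRecord:
    """A named DNA sequence over {A, C, G, T, N}; uppercased on ingestion."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        object.__setattr__(self, "seq", self.seq.upper())
        if not self.seq:
            raise ValueError(f"sequence {self.id}: empty sequence")
        bad = set(self.seq) - DNA_ALPHABET
        if bad:
            raise ValueError(f"sequence {self.id}: illegal symbols {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.seq)


# ---------------------------------------------------------------------------
# gene models


def _parse_gff3_attributes(text: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for chunk in text.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        key, _, val = chunk.partition("=")
        out[key.strip()] = val.strip()
    return out


def _read_gene_models_gff3(lines: Iterable[str]) -> list[GeneModel]:
    genes: dict[str, dict] = {}
    order: list[str] = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise ParseError(f"line {lineno}: expected 9 GFF3 columns, got {len(fields)}")
        chrom, _source, ftype, start, end, _score, strand, _phase, attrs = fields
        if ftype not in ("gene", "exon"):
            continue
        try:
            start_i, end_i = int(start), int(end)
        except ValueError as exc:
            raise ParseError(f"line {lineno}: non-integer coordinate") from exc
        if strand not in ("+", "-"):
            raise ParseError(f"line {lineno}: strandless {ftype} rejected")
        # GFF3 1-based closed -> 0-based half-open
        iv_start, iv_end = start_i - 1, end_i
        if not (0 <= iv_start < iv_end):
            raise ParseError(f"line {lineno}: invalid coordinates {start}..{end}")
        attr = _parse_gff3_attributes(attrs)
        if ftype == "gene":
            gid = attr.get("ID")
            if not gid:
                raise ParseError(f"line {lineno}: gene without ID attribute")
            if gid in genes:
                raise ParseError(f"line {lineno}: duplicate gene ID {gid!r}")
            genes[gid] = {
                "name": attr.get("Name", gid),
                "body": GenomicInterval(chrom, iv_start, iv_end, strand),
                "exons": [],
            }
            order.append(gid)
        else:  # exon
            parent = attr.get("Parent")
            if not parent or parent not in genes:
                raise ParseError(f"line {lineno}: exon with unknown Parent {parent!r}")
            genes[parent]["exons"].append(GenomicInterval(chrom, iv_start, iv_end, strand))
    out = []
    for gid in order:
        g = genes[gid]
        exons = tuple(sorted(g["exons"], key=lambda iv: iv.start))
        try:
            out.append(GeneModel(gid, g["name"], g["body"], exons))
        except ValueError as exc:
            raise ParseError(str(exc)) from exc
    return out


def _read_gene_models_bed12(lines: Iterable[str]) -> list[GeneModel]:
    out = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 12:
            raise ParseError(f"line {lineno}: expected 12 BED columns, got {len(fields)}")
        chrom, start, end, name, _score, strand = fields[:6]
        block_count, block_sizes, block_starts = fields[9], fields[10], fields[11]
        if strand not in ("+", "-"):
            raise ParseError(f"line {lineno}: strandless gene rejected")
        try:
            start_i, end_i = int(start), int(end)
            n_blocks = int(block_count)
            sizes = [int(x) for x in block_sizes.rstrip(",").split(",")]
            offsets = [int(x) for x in block_starts.rstrip(",").split(",")]
        except ValueError as exc:
            raise ParseError(f"line {lineno}: non-integer field") from exc
        if len(sizes) != n_blocks or len(offsets) != n_blocks:
            raise ParseError(f"line {lineno}: blockCount disagrees with block lists")
        try:
            body = GenomicInterval(chrom, start_i, end_i, strand)
            exons = tuple(
                GenomicInterval(chrom, start_i + off, start_i + off + size, strand)
                for off, size in zip(offsets, sizes)
            )
            out.append(GeneModel(name, name, body, exons))
        except ValueError as exc:
            raise ParseError(f"line {lineno}: {exc}") from exc
    return out


def read_gene_models(path: str | Path, format: str = "gff3") -> list[GeneModel]:
    """Read gene models from GFF3 (``gene``/``exon`` features) or BED12.

    Coordinates are normalised to the internal 0-based half-open convention.
    Strandless genes are rejected.
    """
    if format not in ("gff3", "bed12"):
        raise ValueError(f"unknown gene-model format {format!r}")
    with open(path) as fh:
        if format == "gff3":
            return _read_gene_models_gff3(fh)
        return _read_gene_models_bed12(fh)


def write_gene_models(
    genes: Sequence[GeneModel], path: str | Path, format: str = "gff3",
    header_comment: str | None = None,
) -> None:
    """Write gene models in GFF3 or BED12, inverting the reader's conversion."""
    if format not in ("gff3", "bed12"):
        raise ValueError(f"unknown gene-model format {format!r}")
    with open(path, "w") as fh:
        if format == "gff3":
            fh.write("##gff-version 3\n")
            if header_comment:
                fh.write(f"# {header_comment}\n")
            for g in genes:
                b = g.body
                fh.write(
                    f"{b.chrom}\ttfdirect\tgene\t{b.start + 1}\t{b.end}\t.\t"
                    f"{b.strand}\t.\tID={g.gene_id};Name={g.name}\n"
                )
                for i, ex in enumerate(g.exons, start=1):
                    fh.write(
                        f"{ex.chrom}\ttfdirect\texon\t{ex.start + 1}\t{ex.end}\t.\t"
                        f"{ex.strand}\t.\tID={g.gene_id}.exon{i};Parent={g.gene_id}\n"
                    )
        else:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            for g in genes:
                b = g.body
                exons = g.exons if g.exons else (b,)
                sizes = ",".join(str(len(e)) for e in exons) + ","
                offsets = ",".join(str(e.start - b.start) for e in exons) + ","
                fh.write(
                    f"{b.chrom}\t{b.start}\t{b.end}\t{g.gene_id}\t0\t{b.strand}\t"
                    f"{b.start}\t{b.end}\t0\t{len(exons)}\t{sizes}\t{offsets}\n"
                )


# ---------------------------------------------------------------------------
# peaks


def read_peaks(
    path: str | Path,
    summit_col: int | None = None,
    summit_kind: str = "absolute",
) -> list[Peak]:
    """Read peaks from BED3+ in input order.

    summit_col is a 1-based column index; ``summit_kind`` says whether that
    column holds an absolute genomic position or an offset from peak start
    (the narrowPeak convention).
    """
    if summit_kind not in ("absolute", "offset"):
        raise ValueError(f"summit_kind must be absolute or offset, got {summit_kind!r}")
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"line {lineno}: expected >= 3 BED columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"line {lineno}: non-integer coordinate") from exc
            score = None
            if len(fields) >= 5 and fields[4] not in (".", ""):
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise ParseError(f"line {lineno}: non-numeric score") from exc
            strand = "."
            if len(fields) >= 6 and fields[5] in ("+", "-"):
                strand = fields[5]
            summit_offset = None
            if summit_col is not None:
                if len(fields) < summit_col:
                    raise ParseError(f"line {lineno}: missing summit column {summit_col}")
                raw_summit = fields[summit_col - 1]
                if raw_summit not in (".", ""):
                    try:
                        sv = int(raw_summit)
                    except ValueError as exc:
                        raise ParseError(f"line {lineno}: non-integer summit") from exc
                    summit_offset = sv - start if summit_kind == "absolute" else sv
            try:
                peaks.append(
                    Peak(GenomicInterval(fields[0], start, end, strand), summit_offset, score)
                )
            except ValueError as exc:
                raise ParseError(f"line {lineno}: {exc}") from exc
    return peaks


def write_peaks(
    peaks: Sequence[Peak], path: str | Path, header_comment: str | None = None
) -> None:
    """Write peaks as BED6 plus an absolute summit column (column 7)."""
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        for i, p in enumerate(peaks):
            iv = p.interval
            score = "." if p.score is None else f"{p.score:g}"
            summit = "." if p.summit is None else str(p.summit)
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\tpeak_{i + 1}\t{score}\t"
                f"{iv.strand}\t{summit}\n"
            )


# ---------------------------------------------------------------------------
# differential-expression tables


def read_deg_table(
    path: str | Path,
    gene_col: str = "gene_id",
    lfc_col: str = "log2fc",
    padj_col: str = "padj",
) -> list[DEGRecord]:
    """Read a TSV differential-expression table; duplicated gene ids error."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={0: str})
    for col in (gene_col, lfc_col, padj_col):
        if col not in df.columns:
            raise ParseError(f"missing column {col!r}; found {list(df.columns)}")
    dup = df[gene_col][df[gene_col].duplicated()]
    if len(dup):
        raise ParseError(f"duplicate gene_id rows: {sorted(set(dup))}")
    out: list[DEGRecord] = []
    for idx, row in enumerate(df.itertuples(index=False)):
        rec = row._asdict()
        try:
            out.append(
                DEGRecord(str(rec[gene_col]), float(rec[lfc_col]), float(rec[padj_col]))
            )
        except (TypeError, ValueError) as exc:
            raise ParseError(f"row {idx}: {exc}") from exc
    return out


def write_deg_table(
    records: Sequence[DEGRecord], path: str | Path, header_comment: str | None = None
) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("gene_id\tlog2fc\tpadj\n")
        for r in records:
            fh.write(f"{r.gene_id}\t{r.log2fc:.10g}\t{r.padj:.10g}\n")


# ---------------------------------------------------------------------------
# sequences


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    return [SequenceRecord(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(records: Sequence[SequenceRecord], path: str | Path) -> None:
    bio = [_BioSeqRecord(Seq(r.seq), id=r.id, description="") for r in records]
    SeqIO.write(bio, str(path), "fasta")


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())
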