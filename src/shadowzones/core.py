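"""Genomic interval arithmetic, coordinate conventions, and minimal format IO.

All internal coordinates are 0-based half-open (BED convention). Human-readable
region strings ("chr16:33,148,000-33,328,000") and GFF3/VCF coordinates are
1-based and are converted on read, so a printed closed range of N bp becomes an
internal interval of length N. Everything downstream of this module assumes the
half-open convention; nothing else ever converts coordinates.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pysam

__all__ = [
    "GenomicInterval",
    "GeneModel",
    "VariantRecord",
    "parse_region_string",
    "merge_intervals",
    "total_length",
    "intersect_intervals",
    "intersect_length",
    "subtract_intervals",
    "read_bed",
    "write_bed",
    "read_gff3_genes",
    "read_vcf_minimal",
    "write_vcf_minimal",
]


class FormatError(ValueError):
    """A file did not conform to the expected text format."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic range [start, end) on a named contig."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def __str__(self) -> str:  # 1-based closed, the human-readable convention
        return f"{self.chrom}:{self.start + 1}-{self.end}"


@dataclass
class GeneModel:
    """A gene's coding structure: merged, sorted coding exons on one contig."""

    gene_id: str
    symbol: str
    strand: str
    coding_exons: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        chroms = {iv.chrom for iv in self.coding_exons}
        if len(chroms) > 1:
            raise ValueError(f"gene {self.gene_id} spans contigs {sorted(chroms)}")
        # overlapping/adjacent CDS records collapse so a base counts once per gene
        self.coding_exons = merge_intervals(self.coding_exons)

    @property
    def chrom(self) -> str | None:
        return self.coding_exons[0].chrom if self.coding_exons else None

    @property
    def total_coding_bases(self) -> int:
        return total_length(self.coding_exons)


_SNV_RE = re.compile(r"^[ACGTN]$", re.IGNORECASE)
_ALLELE_RE = re.compile(r"^[ACGTN]+$", re.IGNORECASE)


@dataclass(frozen=True, order=True)
class VariantRecord:
    """A small variant in VCF convention: 1-based pos, explicit ref/alt strings."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if not self.ref or not self.alt:
            raise ValueError("ref and alt must be non-empty")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")

    @property
    def var_class(self) -> str:
        """SNV iff both alleles are single bases, otherwise INDEL."""
        return "SNV" if len(self.ref) == 1 and len(self.alt) == 1 else "INDEL"

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref.upper(), self.alt.upper())


# --------------------------------------------------------------------------
# region strings

_REGION_RE = re.compile(
    r"^\s*([^:\s]+):([0-9][0-9,]*)\s*[-–—]\s*([0-9][0-9,]*)\s*$"
)


def parse_region_string(text: str) -> GenomicInterval:
    """Parse a human-readable ``chrom:start-end`` region string.

    Printed coordinates are interpreted as 1-based fully closed (UCSC style),
    so ``chr1:100-100`` is a single base and ``chr16:33,148,000-33,328,000``
    spans 180,001 bp. Thousands separators and en/em dashes are accepted.
    """
    m = _REGION_RE.match(text)
    if m is None:
        raise FormatError(f"malformed region string: {text!r}")
    chrom = m.group(1)
    start1 = int(m.group(2).replace(",", ""))
    end1 = int(m.group(3).replace(",", ""))
    if end1 < start1:
        raise FormatError(f"region end precedes start in {text!r}")
    if start1 < 1:
        raise FormatError(f"1-based coordinate must be >= 1 in {text!r}")
    return GenomicInterval(chrom, start1 - 1, end1)


def region_span_kb(region: GenomicInterval) -> int:
    """Length of a region to the nearest kb, rounding half up."""
    return int((region.length + 500) // 1000)


# --------------------------------------------------------------------------
# interval set algebra (inputs treated as bags; outputs sorted, disjoint,
# non-adjacent — the canonical merged form every set-level op expects)


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Merge into sorted, pairwise disjoint, non-adjacent intervals.

    Touching intervals (end == next start) merge: under the half-open
    convention they have no gap between them.
    """
    by_pos = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    out: list[GenomicInterval] = []
    for iv in by_pos:
        if out and out[-1].chrom == iv.chrom and iv.start <= out[-1].end:
            if iv.end > out[-1].end:
                out[-1] = GenomicInterval(iv.chrom, out[-1].start, iv.end)
        else:
            out.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return out


def total_length(intervals: Iterable[GenomicInterval]) -> int:
    """Total bases covered by the union of the intervals."""
    return sum(iv.length for iv in merge_intervals(intervals))


def _by_chrom(merged: Sequence[GenomicInterval]) -> dict[str, list[GenomicInterval]]:
    d: dict[str, list[GenomicInterval]] = {}
    for iv in merged:
        d.setdefault(iv.chrom, []).append(iv)
    return d


def intersect_intervals(
    a: Iterable[GenomicInterval], b: Iterable[GenomicInterval]
) -> list[GenomicInterval]:
    """Per-base intersection of two interval sets, returned merged."""
    am, bm = _by_chrom(merge_intervals(a)), _by_chrom(merge_intervals(b))
    out: list[GenomicInterval] = []
    for chrom in sorted(set(am) & set(bm)):
        xs, ys = am[chrom], bm[chrom]
        i = j = 0
        while i < len(xs) and j < len(ys):
            lo = max(xs[i].start, ys[j].start)
            hi = min(xs[i].end, ys[j].end)
            if lo < hi:
                out.append(GenomicInterval(chrom, lo, hi))
            if xs[i].end <= ys[j].end:
                i += 1
            else:
                j += 1
    return out


def intersect_length(
    a: Iterable[GenomicInterval], b: Iterable[GenomicInterval]
) -> int:
    """Total overlapping bases between the unions of two interval sets."""
    return total_length(intersect_intervals(a, b))


def subtract_intervals(
    a: Iterable[GenomicInterval], b: Iterable[GenomicInterval]
) -> list[GenomicInterval]:
    """Per-base set difference union(a) \\ union(b), returned merged."""
    am, bm = merge_intervals(a), _by_chrom(merge_intervals(b))
    out: list[GenomicInterval] = []
    for iv in am:
        cursor = iv.start
        for cut in bm.get(iv.chrom, []):
            if cut.end <= cursor:
                continue
            if cut.start >= iv.end:
                break
            if cut.start > cursor:
                out.append(GenomicInterval(iv.chrom, cursor, cut.start))
            cursor = max(cursor, cut.end)
            if cursor >= iv.end:
                break
        if cursor < iv.end:
            out.append(GenomicInterval(iv.chrom, cursor, iv.end))
    return out


# --------------------------------------------------------------------------
# BED3


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3 (0-based half-open). Name columns beyond 3 are ignored."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            try:
                out.append(GenomicInterval(fields[0], int(fields[1]), int(fields[2])))
            except (IndexError, ValueError) as exc:
                raise FormatError(f"{path}:{lineno}: bad BED line ({exc})") from exc
    return out


def read_bed_named(path: str | Path) -> list[tuple[GenomicInterval, str]]:
    """Read BED4 (interval, name); name defaults to the region string."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            try:
                iv = GenomicInterval(fields[0], int(fields[1]), int(fields[2]))
            except (IndexError, ValueError) as exc:
                raise FormatError(f"{path}:{lineno}: bad BED line ({exc})") from exc
            name = fields[3] if len(fields) > 3 else str(iv)
            out.append((iv, name))
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


# --------------------------------------------------------------------------
# GFF3 gene subset (gene/mRNA/CDS); parsed with gffutils


def read_gff3_genes(path: str | Path) -> list[GeneModel]:
    """Read gene models from GFF3, converting CDS to 0-based half-open exons.

    CDS features are grouped under their gene (directly or through mRNA
    parents); overlapping CDS records of one gene are merged on load.
    """
    import gffutils

    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            merge_strategy="create_unique",
            keep_order=True,
        )
    except Exception as exc:  # sqlite/gffutils wrap parse failures variously
        raise FormatError(f"{path}: unparseable GFF3 ({exc})") from exc

    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by="start"):
        exons = [
            GenomicInterval(cds.seqid, cds.start - 1, cds.end)
            for cds in db.children(gene, featuretype="CDS", order_by="start")
        ]
        symbol = gene.attributes.get("Name", [gene.id])[0]
        genes.append(
            GeneModel(
                gene_id=gene.id, symbol=symbol, strand=gene.strand, coding_exons=exons
            )
        )
    return genes


# --------------------------------------------------------------------------
# minimal VCF 4.2 (CHROM POS ID REF ALT); multi-allelic rows split on read


def read_vcf_minimal(path: str | Path) -> list[VariantRecord]:
    """Read small variants from VCF 4.2, one record per alt allele."""
    out: list[VariantRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            for alt in rec.alts or ():
                if alt is None or not _ALLELE_RE.match(alt):
                    continue  # symbolic / breakend alts are out of scope
                out.append(VariantRecord(rec.chrom, rec.pos, rec.ref, alt))
    return out


def write_vcf_minimal(records: Iterable[VariantRecord], path: str | Path) -> None:
    records = list(records)
    contigs = sorted({r.chrom for r in records})
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=shadowzones\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for r in sorted(records, key=lambda r: (r.chrom, r.pos, r.ref, r.alt)):
            fh.write(f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t.\t.\t.\n")
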