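"""MAPQ-agnostic force calling in dead zones, with paralog-ambiguity flags,
and stop-loss consequence annotation.

Standard pipelines discard MAPQ-0 reads, so a variant inside a gene that has
a near-identical pseudogene is invisible to them. Force calling admits every
mapped read into the pileup regardless of mapping quality and emits
substitution calls that clear simple count/fraction thresholds. Each call
carries the fraction of its alt support that comes from confidently mapped
reads; when essentially all support is MAPQ 0 the call is flagged ambiguous —
the evidence cannot distinguish a variant on the gene from one on its
paralog, which is exactly how pseudogene variants masquerade as apparent
heterozygous calls at the parent locus.

Alignments are modeled as gapless matches (substitutions only): sufficient
for the dead-zone SNV mechanism; indel force calling is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio.Seq import Seq

from .core import FormatError, GenomicInterval, VariantRecord

__all__ = [
    "AlignedRead",
    "ForceCallParams",
    "ForceCall",
    "StopLossAnnotation",
    "pileup_force_call",
    "annotate_stop_loss",
    "format_stop_loss",
    "read_reads_tsv",
    "write_reads_tsv",
    "write_sam",
    "read_sam",
]

_BASES = "ACGT"
STOP_CODONS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class AlignedRead:
    """A gapless aligned read: contiguous match starting at ``pos`` (0-based)."""

    read_id: str
    chrom: str
    pos: int
    seq: str
    mapq: int

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError("seq must be non-empty")
        if self.mapq < 0:
            raise ValueError("mapq must be >= 0")
        if self.pos < 0:
            raise ValueError("pos must be >= 0")

    @property
    def end(self) -> int:
        return self.pos + len(self.seq)


@dataclass(frozen=True)
class ForceCallParams:
    """Evidence thresholds for emitting and flagging a force call.

    min_alt_reads / min_alt_fraction: minimum alt-supporting read count and
    pileup fraction to emit a call at all.
    mapq_confident: MAPQ at or above which a read counts as confidently
    mapped.
    confident_support_min: a call is flagged ambiguous when the confident
    fraction of its alt support is below this.
    """

    min_alt_reads: int = 3
    min_alt_fraction: float = 0.2
    mapq_confident: int = 20
    confident_support_min: float = 0.5


@dataclass(frozen=True)
class ForceCall:
    """A force-called substitution plus its mapping-ambiguity evidence."""

    variant: VariantRecord
    n_alt: int
    n_total: int
    n_alt_highmapq: int
    ambiguous: bool

    @property
    def alt_fraction(self) -> float:
        return self.n_alt / self.n_total


def pileup_force_call(
    reads: Iterable[AlignedRead],
    reference: str,
    region: GenomicInterval,
    params: ForceCallParams | None = None,
) -> list[ForceCall]:
    """Force-call substitutions in ``region`` from ALL mapped reads.

    ``reference`` is the full contig sequence for ``region.chrom``. At every
    base, all covering reads are counted, MAPQ 0 included; each non-reference
    base with count >= min_alt_reads and pileup fraction >= min_alt_fraction
    becomes a call. A call is flagged ambiguous when fewer than
    ``confident_support_min`` of its alt reads have MAPQ >=
    ``mapq_confident``.
    """
    p = params or ForceCallParams()
    if len(reference) < region.end:
        raise ValueError(
            f"reference ({len(reference)} bp) does not cover region {region}"
        )
    ref = reference.upper()
    width = region.length
    base_idx = {b: i for i, b in enumerate(_BASES)}
    counts = np.zeros((4, width), dtype=np.int64)
    hq_counts = np.zeros((4, width), dtype=np.int64)
    for r in reads:
        if r.chrom != region.chrom or r.end <= region.start or r.pos >= region.end:
            continue
        lo = max(r.pos, region.start)
        hi = min(r.end, region.end)
        for gpos in range(lo, hi):
            b = r.seq[gpos - r.pos].upper()
            i = base_idx.get(b)
            if i is None:
                continue
            counts[i, gpos - region.start] += 1
            if r.mapq >= p.mapq_confident:
                hq_counts[i, gpos - region.start] += 1

    calls: list[ForceCall] = []
    depth = counts.sum(axis=0)
    for col in np.flatnonzero(depth > 0):
        gpos = region.start + int(col)
        ref_base = ref[gpos]
        n_total = int(depth[col])
        for i, alt_base in enumerate(_BASES):
            if alt_base == ref_base:
                continue
            n_alt = int(counts[i, col])
            if n_alt < p.min_alt_reads or n_alt / n_total < p.min_alt_fraction:
                continue
            n_hq = int(hq_counts[i, col])
            calls.append(
                ForceCall(
                    variant=VariantRecord(region.chrom, gpos + 1, ref_base, alt_base),
                    n_alt=n_alt,
                    n_total=n_total,
                    n_alt_highmapq=n_hq,
                    ambiguous=(n_hq / n_alt) < p.confident_support_min,
                )
            )
    return calls


def write_forcecalls_vcf(calls: Sequence[ForceCall], path: str | Path) -> None:
    """Write force calls as VCF 4.2 with INFO fields NALT, NTOT, NHQ, AMBIG."""
    contigs = sorted({c.variant.chrom for c in calls})
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n##source=shadowzones-forcecall\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##INFO=<ID=NALT,Number=1,Type=Integer,Description="Alt read count">\n')
        fh.write('##INFO=<ID=NTOT,Number=1,Type=Integer,Description="Total read count">\n')
        fh.write('##INFO=<ID=NHQ,Number=1,Type=Integer,Description="Alt reads with confident MAPQ">\n')
        fh.write('##INFO=<ID=AMBIG,Number=0,Type=Flag,Description="Paralog-ambiguous support">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for fc in sorted(calls, key=lambda c: (c.variant.chrom, c.variant.pos)):
            v = fc.variant
            info = f"NALT={fc.n_alt};NTOT={fc.n_total};NHQ={fc.n_alt_highmapq}"
            if fc.ambiguous:
                info += ";AMBIG"
            fh.write(f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\t.\t{info}\n")


# --------------------------------------------------------------------------
# stop-loss annotation


@dataclass(frozen=True)
class StopLossAnnotation:
    """Consequence of a substitution in the reference stop codon.

    stop_codon_index: 1-based codon number of the reference stop.
    new_aa: one-letter amino acid replacing the stop ('*' if still a stop).
    ext_codons: codons added before the next in-frame stop; None when no
        downstream stop exists within the provided sequence (no-stop flag).
    synonymous: the mutated codon is still a stop codon.
    """

    stop_codon_index: int
    new_aa: str
    ext_codons: int | None
    synonymous: bool = False

    @property
    def hgvs_p(self) -> str:
        return format_stop_loss(self)


def annotate_stop_loss(
    seq: str, cds_end: int, sub_pos: int, ref_base: str, alt_base: str
) -> StopLossAnnotation:
    """Annotate a substitution within a CDS's stop codon.

    ``seq`` is the in-frame coding strand covering the CDS and downstream
    sequence; ``cds_end`` is the 0-based index one past the stop codon (so
    the stop codon is ``seq[cds_end-3:cds_end]`` and must be a multiple of 3
    from the CDS start at index 0). ``sub_pos`` indexes into ``seq``.

    If the mutated codon is still a stop the change is a synonymous stop.
    Otherwise translation reads through: downstream codons are scanned in
    frame and ``ext_codons`` is the 1-based index of the first new stop
    codon, or None when the sequence ends without one.
    """
    if cds_end % 3 != 0 or cds_end < 3 or cds_end > len(seq):
        raise ValueError(f"cds_end {cds_end} is not a codon boundary within seq")
    stop_start = cds_end - 3
    stop_codon = seq[stop_start:cds_end].upper()
    if stop_codon not in STOP_CODONS:
        raise ValueError(f"codon at CDS end is {stop_codon}, not a stop codon")
    if not (stop_start <= sub_pos < cds_end):
        raise ValueError(
            f"substitution at {sub_pos} lies outside the stop codon "
            f"[{stop_start}, {cds_end})"
        )
    if seq[sub_pos].upper() != ref_base.upper():
        raise ValueError(
            f"ref base {ref_base} does not match sequence base {seq[sub_pos]} at {sub_pos}"
        )
    mutated = list(stop_codon)
    mutated[sub_pos - stop_start] = alt_base.upper()
    new_codon = "".join(mutated)
    stop_codon_index = cds_end // 3

    if new_codon in STOP_CODONS:
        return StopLossAnnotation(stop_codon_index, "*", None, synonymous=True)

    new_aa = str(Seq(new_codon).translate())
    ext = None
    i = 1
    for off in range(cds_end, len(seq) - 2, 3):
        if seq[off : off + 3].upper() in STOP_CODONS:
            ext = i
            break
        i += 1
    return StopLossAnnotation(stop_codon_index, new_aa, ext)


def format_stop_loss(annotation: StopLossAnnotation) -> str:
    """HGVS-protein style string for a stop-loss annotation.

    Extension variants format as ``p.X{stop}{aa}ext{n}``; a readthrough with
    no downstream stop uses ``ext*``; a synonymous stop formats as
    ``p.X{stop}=``.
    """
    n = annotation.stop_codon_index
    if annotation.synonymous:
        return f"p.X{n}="
    ext = "*" if annotation.ext_codons is None else str(annotation.ext_codons)
    return f"p.X{n}{annotation.new_aa}ext{ext}"


# --------------------------------------------------------------------------
# read IO: TSV dialect and SAM via pysam


def write_reads_tsv(reads: Iterable[AlignedRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tchrom\tpos0\tseq\tmapq\n")
        for r in reads:
            fh.write(f"{r.read_id}\t{r.chrom}\t{r.pos}\t{r.seq}\t{r.mapq}\n")


def read_reads_tsv(path: str | Path) -> list[AlignedRead]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "read_id\t")):
                continue
            fields = line.split("\t")
            try:
                out.append(
                    AlignedRead(fields[0], fields[1], int(fields[2]), fields[3], int(fields[4]))
                )
            except (IndexError, ValueError) as exc:
                raise FormatError(f"{path}:{lineno}: bad read line ({exc})") from exc
    return out


def write_sam(
    reads: Sequence[AlignedRead], path: str | Path, contig_lengths: dict[str, int]
) -> None:
    """Write gapless reads as SAM (full-length match CIGAR)."""
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": c, "LN": n} for c, n in sorted(contig_lengths.items())],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        tid = {c: i for i, (c, _) in enumerate(sorted(contig_lengths.items()))}
        for r in reads:
            a = pysam.AlignedSegment()
            a.query_name = r.read_id
            a.query_sequence = r.seq
            a.reference_id = tid[r.chrom]
            a.reference_start = r.pos
            a.mapping_quality = r.mapq
            a.cigartuples = [(0, len(r.seq))]
            a.flag = 0
            out.write(a)


def read_sam(path: str | Path) -> list[AlignedRead]:
    """Read gapless mapped reads back from SAM/BAM."""
    import pysam

    out = []
    with pysam.AlignmentFile(str(path), check_sq=False) as af:
        for seg in af:
            if seg.is_unmapped or seg.query_sequence is None:
                continue
            out.append(
                AlignedRead(
                    seg.query_name,
                    seg.reference_name,
                    seg.reference_start,
                    seg.query_sequence,
                    seg.mapping_quality,
                )
            )
    return out
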