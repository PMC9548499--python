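"""Cohort-based NGS dead-zone calling from MAPQ-filtered depth profiles.

A short-read "dead zone" is a region where reads cannot be placed with
confident mapping quality, so depth of MAPQ-filtered coverage collapses across
essentially every genome in a cohort. This module computes per-sample depth
restricted to reads at or above a MAPQ cutoff, calls the bases that fail a
minimum-depth test in at least a given fraction of samples, merges them into
zones, and quantifies how much of those zones a second technology (e.g.
long-read sequencing) can cover.

Depth semantics: a read contributes to every base of its aligned reference
span (deletions covered, insertions ignored, soft-clips excluded).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .core import (
    GenomicInterval,
    intersect_length,
    merge_intervals,
    subtract_intervals,
    total_length,
    write_bed,
    FormatError,
)

__all__ = [
    "DepthProfile",
    "DeadZoneParams",
    "DeadZoneSet",
    "depth_profile_from_alignments",
    "depth_profile_from_sam",
    "call_dead_zones",
    "deadzone_coverage_fraction",
    "uncallable_residual",
    "read_depth_tsv",
    "write_depth_tsv",
]


@dataclass
class DepthProfile:
    """Per-base MAPQ-filtered read depth for one sample on one contig."""

    sample_id: str
    chrom: str
    depth: np.ndarray  # int array, length == contig length
    mapq_min: int

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=np.int64)
        if self.depth.ndim != 1:
            raise ValueError("depth must be a 1-D array")
        if (self.depth < 0).any():
            raise ValueError("depth values must be >= 0")


@dataclass(frozen=True)
class DeadZoneParams:
    """Thresholds defining a dead base and a reportable dead zone.

    mapq_min: reads below this MAPQ do not count toward depth.
    min_depth: a base is failing in a sample when its depth is below this.
    min_sample_fraction: fraction of the cohort that must fail at a base.
    min_length: called zones shorter than this are dropped.
    merge_gap: zones separated by at most this many bases are bridged
        (0 keeps the call exactly invertible against the per-base rule).
    """

    mapq_min: int = 20
    min_depth: int = 5
    min_sample_fraction: float = 0.9
    min_length: int = 50
    merge_gap: int = 0

    def __post_init__(self) -> None:
        if self.mapq_min < 0:
            raise ValueError("mapq_min must be >= 0")
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")
        if not (0 < self.min_sample_fraction <= 1):
            raise ValueError("min_sample_fraction must be in (0, 1]")
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")
        if self.merge_gap < 0:
            raise ValueError("merge_gap must be >= 0")


@dataclass
class DeadZoneSet:
    """Called dead zones plus the parameters and cohort size that produced them."""

    zones: list[GenomicInterval]
    params: DeadZoneParams
    n_samples: int

    def __post_init__(self) -> None:
        self.zones = merge_intervals(self.zones)

    @property
    def total_bases(self) -> int:
        return total_length(self.zones)

    def write(self, bed_path: str | Path) -> None:
        """Write zones as BED3 plus a JSON sidecar with params and cohort size."""
        write_bed(self.zones, bed_path)
        sidecar = Path(str(bed_path) + ".json")
        sidecar.write_text(
            json.dumps(
                {"params": asdict(self.params), "n_samples": self.n_samples},
                indent=2,
            )
            + "\n"
        )


def depth_profile_from_alignments(
    reads: Iterable,
    contig: str,
    contig_length: int,
    mapq_min: int,
    sample_id: str = "sample",
) -> DepthProfile:
    """Per-base depth of reads with MAPQ >= mapq_min over one contig.

    Accepts either :class:`shadowzones.forcecall.AlignedRead` objects or
    pysam aligned segments; each read covers its aligned reference span.
    """
    delta = np.zeros(contig_length + 1, dtype=np.int64)
    for read in reads:
        if hasattr(read, "reference_start"):  # pysam AlignedSegment
            if read.is_unmapped or read.reference_name != contig:
                continue
            mapq, start, end = read.mapping_quality, read.reference_start, read.reference_end
        else:
            if read.chrom != contig:
                continue
            mapq, start, end = read.mapq, read.pos, read.pos + len(read.seq)
        if mapq < mapq_min or end is None:
            continue
        lo, hi = max(0, start), min(contig_length, end)
        if lo < hi:
            delta[lo] += 1
            delta[hi] -= 1
    return DepthProfile(sample_id, contig, np.cumsum(delta[:-1]), mapq_min)


def depth_profile_from_sam(
    path: str | Path,
    contig: str,
    contig_length: int,
    mapq_min: int,
    sample_id: str | None = None,
) -> DepthProfile:
    """Compute a depth profile for one contig directly from a SAM/BAM file."""
    import pysam

    with pysam.AlignmentFile(str(path), check_sq=False) as af:
        reads = [r for r in af if not r.is_unmapped and r.reference_name == contig]
    return depth_profile_from_alignments(
        reads, contig, contig_length, mapq_min, sample_id or Path(path).stem
    )


def dead_base_mask(
    profiles: Sequence[DepthProfile], params: DeadZoneParams
) -> np.ndarray:
    """Boolean per-base mask of dead bases for one contig's cohort profiles."""
    lengths = {len(p.depth) for p in profiles}
    if len(lengths) != 1:
        raise ValueError(f"inconsistent contig lengths across samples: {sorted(lengths)}")
    stack = np.stack([p.depth for p in profiles])
    n_fail = (stack < params.min_depth).sum(axis=0)
    return n_fail / len(profiles) >= params.min_sample_fraction


def _mask_to_intervals(chrom: str, mask: np.ndarray) -> list[GenomicInterval]:
    edges = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    return [
        GenomicInterval(chrom, int(lo), int(hi))
        for lo, hi in zip(edges[::2], edges[1::2])
    ]


def call_dead_zones(
    profiles: Sequence[DepthProfile], params: DeadZoneParams | None = None
) -> DeadZoneSet:
    """Call cohort dead zones from per-sample depth profiles.

    A base is dead when the fraction of samples with depth below
    ``params.min_depth`` reaches ``params.min_sample_fraction``. Dead bases
    are merged into intervals (optionally bridging gaps up to
    ``params.merge_gap``) and intervals shorter than ``params.min_length``
    are dropped.
    """
    params = params or DeadZoneParams()
    if not profiles:
        raise ValueError("at least one depth profile is required")
    by_chrom: dict[str, list[DepthProfile]] = {}
    for p in profiles:
        by_chrom.setdefault(p.chrom, []).append(p)
    n_per_chrom = {c: len(ps) for c, ps in by_chrom.items()}
    if len(set(n_per_chrom.values())) > 1:
        raise ValueError(f"unequal cohort size across contigs: {n_per_chrom}")

    zones: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        mask = dead_base_mask(by_chrom[chrom], params)
        raw = _mask_to_intervals(chrom, mask)
        if params.merge_gap > 0:
            padded = [
                GenomicInterval(z.chrom, z.start, z.end + params.merge_gap)
                for z in raw
            ]
            contig_len = len(by_chrom[chrom][0].depth)
            raw = [
                GenomicInterval(z.chrom, z.start, min(z.end, contig_len))
                for z in merge_intervals(padded)
            ]
        zones.extend(z for z in raw if z.length >= params.min_length)
    return DeadZoneSet(zones, params, n_samples=len(next(iter(by_chrom.values()))))


def deadzone_coverage_fraction(
    zones: DeadZoneSet | Sequence[GenomicInterval],
    callable_regions: Sequence[GenomicInterval],
) -> float:
    """Fraction of total dead-zone length covered by the callable regions.

    Empty dead zones return 1.0 by convention (there is nothing left
    uncovered).
    """
    zs = zones.zones if isinstance(zones, DeadZoneSet) else list(zones)
    denom = total_length(zs)
    if denom == 0:
        return 1.0
    return intersect_length(zs, callable_regions) / denom


def uncallable_residual(
    zones: DeadZoneSet | Sequence[GenomicInterval],
    callable_regions: Sequence[GenomicInterval],
) -> list[GenomicInterval]:
    """Dead-zone bases not covered by the callable regions (merged)."""
    zs = zones.zones if isinstance(zones, DeadZoneSet) else list(zones)
    return subtract_intervals(zs, callable_regions)


# --------------------------------------------------------------------------
# depth TSV / bedGraph IO


def write_depth_tsv(profile: DepthProfile, path: str | Path) -> None:
    """Write a 3-column depth TSV: chrom, 0-based position, depth."""
    with open(path, "w") as fh:
        fh.write(f"#sample={profile.sample_id}\tmapq_min={profile.mapq_min}\n")
        for pos, d in enumerate(profile.depth):
            fh.write(f"{profile.chrom}\t{pos}\t{int(d)}\n")


def read_depth_tsv(
    path: str | Path,
    contig_length: int | None = None,
    mapq_min: int = 0,
    sample_id: str | None = None,
) -> DepthProfile:
    """Read a depth profile from a 3-column TSV or 4-column bedGraph.

    TSV rows are (chrom, pos0, depth); bedGraph rows (chrom, start, end,
    depth) are expanded per base. Positions absent from the file get depth 0.
    """
    chrom = None
    rows: list[tuple[int, int, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                if line.startswith("#sample="):
                    meta = dict(kv.split("=", 1) for kv in line[1:].split("\t"))
                    sample_id = sample_id or meta.get("sample")
                    mapq_min = int(meta.get("mapq_min", mapq_min))
                continue
            fields = line.split("\t")
            try:
                if len(fields) == 3:
                    start, end, d = int(fields[1]), int(fields[1]) + 1, int(fields[2])
                else:
                    start, end, d = int(fields[1]), int(fields[2]), int(float(fields[3]))
            except (IndexError, ValueError) as exc:
                raise FormatError(f"{path}:{lineno}: bad depth line ({exc})") from exc
            if chrom is None:
                chrom = fields[0]
            elif fields[0] != chrom:
                raise FormatError(f"{path}:{lineno}: multiple contigs in one profile")
            rows.append((start, end, d))
    if chrom is None:
        raise FormatError(f"{path}: empty depth file")
    length = contig_length if contig_length is not None else max(e for _, e, _ in rows)
    depth = np.zeros(length, dtype=np.int64)
    for start, end, d in rows:
        depth[start:min(end, length)] = d
    return DepthProfile(sample_id or Path(path).stem, chrom, depth, mapq_min)
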