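"""Small-variant concordance between two call sets (e.g. short vs long reads).

Variants are normalized (allele trimming, optional reference left-alignment)
and matched exactly on (chrom, pos, ref, alt); genotype agreement is not
required. Counts are stratified into SNV and INDEL classes and reported both
against the union of the two sets and against set A alone, since "fraction of
A's calls replicated in B" and "fraction of the union shared" answer different
questions and published concordance figures do not always say which they use.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from .core import GenomicInterval, VariantRecord, merge_intervals

__all__ = [
    "ClassConcordance",
    "ConcordanceSummary",
    "normalize_variant",
    "compare_variant_sets",
    "stratify_by_regions",
]


@dataclass(frozen=True)
class ClassConcordance:
    """Shared/exclusive accounting for one variant class."""

    n_shared: int
    n_a_only: int
    n_b_only: int

    @property
    def n_union(self) -> int:
        return self.n_shared + self.n_a_only + self.n_b_only

    @property
    def shared_frac_union(self) -> float:
        return self.n_shared / self.n_union if self.n_union else math.nan

    @property
    def a_only_frac_union(self) -> float:
        return self.n_a_only / self.n_union if self.n_union else math.nan

    @property
    def b_only_frac_union(self) -> float:
        return self.n_b_only / self.n_union if self.n_union else math.nan

    @property
    def shared_frac_of_a(self) -> float:
        n_a = self.n_shared + self.n_a_only
        return self.n_shared / n_a if n_a else math.nan


@dataclass(frozen=True)
class ConcordanceSummary:
    snv: ClassConcordance
    indel: ClassConcordance

    def by_class(self) -> dict[str, ClassConcordance]:
        return {"SNV": self.snv, "INDEL": self.indel}

    def to_dict(self) -> dict:
        out = {}
        for cls, c in self.by_class().items():
            out[cls] = {
                "n_shared": c.n_shared,
                "n_a_only": c.n_a_only,
                "n_b_only": c.n_b_only,
                "shared_frac_union": c.shared_frac_union,
                "a_only_frac_union": c.a_only_frac_union,
                "b_only_frac_union": c.b_only_frac_union,
                "shared_frac_of_a": c.shared_frac_of_a,
            }
        return out


def normalize_variant(
    v: VariantRecord, reference_window: tuple[str, int] | None = None
) -> VariantRecord:
    """Canonical (parsimonious, left-aligned) representation of a variant.

    Shared suffix then prefix bases are trimmed, always keeping at least one
    base per allele. With ``reference_window`` — a tuple of (sequence,
    1-based start position of that sequence) — indels are additionally
    left-aligned by iterated shifting, the standard vt-style normalization.
    Idempotent: normalizing twice gives the same record.
    """
    chrom, pos, ref, alt = v.chrom, v.pos, v.ref.upper(), v.alt.upper()

    seq = offset = None
    if reference_window is not None:
        seq, win_start = reference_window
        seq = seq.upper()
        offset = win_start  # 1-based genomic position of seq[0]
        lo, hi = pos - offset, pos - offset + len(ref)
        if lo < 0 or hi > len(seq) or seq[lo:hi] != ref:
            raise ValueError(
                f"ref allele {ref!r} at {chrom}:{pos} disagrees with reference window"
            )

    def left_base(p: int) -> str | None:
        if seq is None:
            return None
        i = p - offset - 1
        return seq[i] if 0 <= i < len(seq) else None

    while True:
        # trim shared suffix; when one allele empties, extend left from reference
        if len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
            ref, alt = ref[:-1], alt[:-1]
            continue
        if ref[-1] == alt[-1] and (len(ref) == 1 or len(alt) == 1):
            base = left_base(pos)
            if base is None:
                break
            ref, alt, pos = base + ref[:-1], base + alt[:-1], pos - 1
            continue
        break

    # trim shared prefix
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt, pos = ref[1:], alt[1:], pos + 1

    return VariantRecord(chrom, pos, ref, alt)


def _dedup_keys(variants: Iterable[VariantRecord]) -> dict[tuple, str]:
    return {v.key: v.var_class for v in variants}


def compare_variant_sets(
    a: Iterable[VariantRecord], b: Iterable[VariantRecord]
) -> ConcordanceSummary:
    """Shared/exclusive counts per variant class between two normalized sets.

    Match key is exact (chrom, pos, ref, alt); duplicates within a set are
    collapsed. Swapping the arguments swaps the a_only/b_only roles.
    """
    ka, kb = _dedup_keys(a), _dedup_keys(b)
    classes = {}
    for cls in ("SNV", "INDEL"):
        shared = sum(1 for k in ka.keys() & kb.keys() if ka[k] == cls)
        a_only = sum(1 for k in ka.keys() - kb.keys() if ka[k] == cls)
        b_only = sum(1 for k in kb.keys() - ka.keys() if kb[k] == cls)
        classes[cls] = ClassConcordance(shared, a_only, b_only)
    return ConcordanceSummary(snv=classes["SNV"], indel=classes["INDEL"])


def stratify_by_regions(
    variants: Sequence[VariantRecord], regions: Sequence[GenomicInterval]
) -> float | None:
    """Fraction of variants whose position falls inside the given regions.

    A variant is inside when its 1-based position, converted to 0-based,
    lies within a region. Returns None (undefined) for an empty variant list
    rather than 0.
    """
    if not variants:
        return None
    merged = merge_intervals(regions)
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in merged:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    import bisect

    starts = {c: [iv.start for iv in ivs] for c, ivs in by_chrom.items()}
    n_inside = 0
    for v in variants:
        ivs = by_chrom.get(v.chrom)
        if not ivs:
            continue
        p0 = v.pos - 1
        i = bisect.bisect_right(starts[v.chrom], p0) - 1
        if i >= 0 and ivs[i].start <= p0 < ivs[i].end:
            n_inside += 1
    return n_inside / len(variants)
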