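"""Haplotype-phased CpG methylation fractions and imprinting classification.

Single-molecule long reads report a per-read methylation probability at each
CpG and can be phased into the two parental haplotypes. At a normally
imprinted locus, one haplotype is close to fully methylated and the other
close to fully unmethylated (monoallelic). Both haplotypes hypermethylated at
a maternally imprinted locus is the signature of maternal uniparental disomy
or an imprinting defect (e.g. the Prader-Willi region on chr15); both
hypomethylated is the reciprocal defect.

The module computes, per CpG site and haplotype, the fraction of reads called
methylated, then classifies a locus from the per-haplotype means.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .core import FormatError, GenomicInterval

__all__ = [
    "CpGCall",
    "HaplotypeMethylationProfile",
    "ImprintingStatus",
    "ImprintingClassification",
    "MethylationParams",
    "site_haplotype_fractions",
    "classify_locus",
    "screen_imprinted_loci",
    "read_methylation_tsv",
    "write_methylation_tsv",
]

UNASSIGNED = 0  # haplotype code for reads phasing could not place


@dataclass(frozen=True)
class CpGCall:
    """One read's methylation call at one CpG site."""

    read_id: str
    chrom: str
    site: int  # 0-based CpG position
    meth_prob: float
    haplotype: int  # 1, 2, or 0 = unassigned

    def __post_init__(self) -> None:
        if not (0.0 <= self.meth_prob <= 1.0):
            raise ValueError(f"meth_prob {self.meth_prob} outside [0, 1]")
        if self.haplotype not in (0, 1, 2):
            raise ValueError(f"haplotype must be 0, 1 or 2, got {self.haplotype}")


@dataclass
class SiteFractions:
    n_meth: dict[int, int]  # haplotype -> methylated read count
    n_total: dict[int, int]

    def frac(self, hap: int) -> float:
        return self.n_meth[hap] / self.n_total[hap]


@dataclass
class HaplotypeMethylationProfile:
    """Per-site, per-haplotype methylated-read fractions over a region."""

    chrom: str
    sites: dict[int, SiteFractions] = field(default_factory=dict)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def mean_frac(self, hap: int) -> float:
        """Unweighted mean methylated fraction across sites for one haplotype."""
        if not self.sites:
            return float("nan")
        return sum(self.sites[s].frac(hap) for s in self.sites) / len(self.sites)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (self.chrom, s, sf.frac(1), sf.frac(2), sf.n_total[1], sf.n_total[2])
            for s, sf in sorted(self.sites.items())
        ]
        return pd.DataFrame(
            rows, columns=["chrom", "site0", "frac_h1", "frac_h2", "n_h1", "n_h2"]
        )


class ImprintingStatus(str, Enum):
    MONOALLELIC = "monoallelic"
    BIALLELIC_HYPER = "biallelic_hyper"
    BIALLELIC_HYPO = "biallelic_hypo"
    INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class MethylationParams:
    """Binarization and classification thresholds.

    prob_threshold: a read counts methylated when meth_prob >= this.
    min_reads_per_site: sites with fewer phased reads than this on either
        haplotype are excluded as uninformative.
    min_sites: loci with fewer informative sites are classified indeterminate.
    hyper_threshold / hypo_threshold: per-haplotype mean fraction bounds for
        calling a haplotype methylated / unmethylated.
    """

    prob_threshold: float = 0.5
    min_reads_per_site: int = 5
    min_sites: int = 5
    hyper_threshold: float = 0.75
    hypo_threshold: float = 0.25

    def __post_init__(self) -> None:
        if not (0 <= self.hypo_threshold < self.hyper_threshold <= 1):
            raise ValueError("require 0 <= hypo_threshold < hyper_threshold <= 1")


@dataclass(frozen=True)
class ImprintingClassification:
    locus: GenomicInterval
    name: str
    status: ImprintingStatus
    mean_frac_h1: float
    mean_frac_h2: float
    n_informative_sites: int


def site_haplotype_fractions(
    calls: Iterable[CpGCall],
    region: GenomicInterval,
    prob_threshold: float = 0.5,
    min_reads_per_site: int = 5,
) -> HaplotypeMethylationProfile:
    """Per-site per-haplotype methylated fractions within a region.

    Unassigned-haplotype reads are dropped (the analysis is defined on phased
    reads only). A read counts as methylated when its probability reaches
    ``prob_threshold``; sites with fewer than ``min_reads_per_site`` reads on
    either haplotype are excluded.
    """
    acc: dict[int, SiteFractions] = {}
    for c in calls:
        if c.haplotype == UNASSIGNED or c.chrom != region.chrom:
            continue
        if not (region.start <= c.site < region.end):
            continue
        sf = acc.setdefault(
            c.site, SiteFractions(n_meth={1: 0, 2: 0}, n_total={1: 0, 2: 0})
        )
        sf.n_total[c.haplotype] += 1
        if c.meth_prob >= prob_threshold:
            sf.n_meth[c.haplotype] += 1
    kept = {
        s: sf
        for s, sf in acc.items()
        if sf.n_total[1] >= min_reads_per_site and sf.n_total[2] >= min_reads_per_site
    }
    return HaplotypeMethylationProfile(chrom=region.chrom, sites=kept)


def classify_locus(
    profile: HaplotypeMethylationProfile,
    locus: GenomicInterval,
    name: str = "",
    params: MethylationParams | None = None,
) -> ImprintingClassification:
    """Classify a locus from per-haplotype mean methylation fractions.

    biallelic_hyper: both means at or above the hyper threshold (the UPD /
    imprinting-defect pattern); biallelic_hypo: both at or below the hypo
    threshold; monoallelic: one hyper, one hypo (the normal imprinted
    pattern); anything else, or too few informative sites, is indeterminate.
    """
    p = params or MethylationParams()
    m1, m2 = profile.mean_frac(1), profile.mean_frac(2)
    if profile.n_sites < p.min_sites:
        status = ImprintingStatus.INDETERMINATE
    elif m1 >= p.hyper_threshold and m2 >= p.hyper_threshold:
        status = ImprintingStatus.BIALLELIC_HYPER
    elif m1 <= p.hypo_threshold and m2 <= p.hypo_threshold:
        status = ImprintingStatus.BIALLELIC_HYPO
    elif (m1 >= p.hyper_threshold and m2 <= p.hypo_threshold) or (
        m2 >= p.hyper_threshold and m1 <= p.hypo_threshold
    ):
        status = ImprintingStatus.MONOALLELIC
    else:
        status = ImprintingStatus.INDETERMINATE
    return ImprintingClassification(
        locus=locus,
        name=name,
        status=status,
        mean_frac_h1=m1,
        mean_frac_h2=m2,
        n_informative_sites=profile.n_sites,
    )


def screen_imprinted_loci(
    calls: Sequence[CpGCall],
    loci: Sequence[tuple[GenomicInterval, str]],
    params: MethylationParams | None = None,
) -> list[ImprintingClassification]:
    """Classify each named locus (e.g. MAGEL2, NDN, SNRPN exons) in turn."""
    p = params or MethylationParams()
    out = []
    for region, name in loci:
        profile = site_haplotype_fractions(
            calls, region, p.prob_threshold, p.min_reads_per_site
        )
        out.append(classify_locus(profile, region, name, p))
    return out


# --------------------------------------------------------------------------
# TSV dialect: a flattened equivalent of haplotagged methylation-tagged BAM


_COLUMNS = ["read_id", "chrom", "site0", "meth_prob", "haplotype"]


def write_methylation_tsv(calls: Iterable[CpGCall], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_COLUMNS) + "\n")
        for c in calls:
            fh.write(
                f"{c.read_id}\t{c.chrom}\t{c.site}\t{c.meth_prob:.4f}\t{c.haplotype}\n"
            )


def read_methylation_tsv(path: str | Path) -> list[CpGCall]:
    """Read per-read CpG calls: columns read_id, chrom, site0, meth_prob, haplotype."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("read_id\t"):
                continue
            fields = line.split("\t")
            try:
                out.append(
                    CpGCall(
                        read_id=fields[0],
                        chrom=fields[1],
                        site=int(fields[2]),
                        meth_prob=float(fields[3]),
                        haplotype=int(fields[4]),
                    )
                )
            except (IndexError, ValueError) as exc:
                raise FormatError(f"{path}:{lineno}: bad methylation line ({exc})") from exc
    return out
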