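"""Synthetic data with known ground truth for every pipeline stage.

Real clinical genomes behind these analyses cannot be shared, so this module
builds small, fully deterministic stand-ins: a contig carrying a gene and a
near-identical pseudogene copy (the mechanism that hides IKBKG-like genes
from short reads), idealized short- and long-read sets over it, cohort depth
profiles, variant-set pairs with planted concordance counts, haplotagged CpG
methylation calls with planted imprinting status, and a gene/HPO fixture with
a planted phenotype ranking. Every generator is a pure function of its
parameters and seed.

The mapper is idealized: a short read gets MAPQ 0 exactly when its span lies
inside one of the two homologous copies and contains none of the engineered
positions that distinguish them; otherwise MAPQ 60. MAPQ-0 reads are placed
on either copy with equal probability, which is what creates the apparent
heterozygous pileup at the parent locus when a variant sits on the
pseudogene. Planted sample variants deliberately do not count as
distinguishing positions: an aligner cannot tell a sample variant from a
paralog difference, so a one-mismatch read still maps equally well to both
copies.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .core import (
    GeneModel,
    GenomicInterval,
    VariantRecord,
    merge_intervals,
    write_bed,
    write_vcf_minimal,
)
from .deadzones import DepthProfile, depth_profile_from_alignments
from .forcecall import AlignedRead, write_sam
from .methylation import CpGCall, ImprintingStatus, write_methylation_tsv
from .phenotypes import HpoAnnotation

__all__ = [
    "SyntheticTruth",
    "generate_genome_with_pseudogene",
    "simulate_short_reads",
    "simulate_long_reads",
    "cohort_depth_profiles",
    "generate_variant_pair",
    "generate_methylation_calls",
    "generate_hpo_fixture",
    "write_fasta",
    "write_gff3",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_NONSTOP_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in {"TAA", "TAG", "TGA"}
]


@dataclass
class SyntheticTruth:
    """Ground truth for a gene+pseudogene contig.

    All coordinates are 0-based half-open on ``contig``. ``diff_positions``
    are offsets within a copy (0 .. copy length) where the pseudogene differs
    from the gene; the same offsets apply to both copies.
    """

    seed: int
    contig: str
    reference: str
    gene_region: GenomicInterval
    pseudogene_region: GenomicInterval
    identity: float
    diff_positions: list[int]
    gene_model: GeneModel
    cds_end_offset: int  # offset of one-past-stop-codon within the copy
    planted_variants: list[tuple[VariantRecord, str]] = field(default_factory=list)

    @property
    def copy_length(self) -> int:
        return self.gene_region.length

    @property
    def contig_length(self) -> int:
        return len(self.reference)

    def realized_identity(self) -> float:
        return 1.0 - len(self.diff_positions) / self.copy_length

    def expected_dead_zone(self, read_length: int) -> list[GenomicInterval]:
        """Bases coverable only by MAPQ-0 reads, given the idealized mapper.

        A base inside a copy is rescuable when some read window of the given
        length covers both it and a distinguishing position (an engineered
        diff, or any base outside the copy). Within a maximal identical run
        flanked by distinguishing positions at a-1 and b, the dead bases are
        exactly [a + read_length - 1, b - read_length + 1).
        """
        out: list[GenomicInterval] = []
        for region in (self.gene_region, self.pseudogene_region):
            bounds = (
                [region.start - 1]
                + [region.start + d for d in sorted(self.diff_positions)]
                + [region.end]
            )
            for left, right in zip(bounds, bounds[1:]):
                a, b = left + 1, right  # identical run [a, b)
                lo, hi = a + read_length - 1, b - read_length + 1
                if lo < hi:
                    out.append(GenomicInterval(self.contig, lo, hi))
        return merge_intervals(out)

    def plant_variant(self, origin: str, offset: int, alt_base: str) -> VariantRecord:
        """Plant a homozygous substitution at a copy offset on one locus.

        ``origin`` is "gene" or "pseudogene"; the variant's coordinates are
        reported on the locus it physically occupies. The reference base is
        the origin locus's own sequence (which for the pseudogene already
        includes its engineered differences).
        """
        region = self.gene_region if origin == "gene" else self.pseudogene_region
        pos0 = region.start + offset
        ref_base = self.locus_base(origin, offset)
        if ref_base == alt_base:
            raise ValueError("alt base equals the locus base")
        v = VariantRecord(self.contig, pos0 + 1, ref_base, alt_base)
        self.planted_variants.append((v, origin))
        return v

    def locus_base(self, origin: str, offset: int) -> str:
        region = self.gene_region if origin == "gene" else self.pseudogene_region
        return self.reference[region.start + offset]

    def sample_haplotype(self, carry_variants: bool) -> str:
        """Contig sequence with (or without) the planted variants applied."""
        if not carry_variants or not self.planted_variants:
            return self.reference
        seq = list(self.reference)
        for v, _origin in self.planted_variants:
            assert len(v.ref) == 1 and len(v.alt) == 1
            seq[v.pos - 1] = v.alt
        return "".join(seq)

    def to_json(self) -> dict:
        return {
            "seed": self.seed,
            "contig": self.contig,
            "contig_length": self.contig_length,
            "gene_region": [self.gene_region.start, self.gene_region.end],
            "pseudogene_region": [
                self.pseudogene_region.start,
                self.pseudogene_region.end,
            ],
            "identity_requested": self.identity,
            "identity_realized": self.realized_identity(),
            "n_diff_positions": len(self.diff_positions),
            "diff_positions": self.diff_positions,
            "cds_end_offset": self.cds_end_offset,
            "planted_variants": [
                {"chrom": v.chrom, "pos": v.pos, "ref": v.ref, "alt": v.alt,
                 "origin": origin}
                for v, origin in self.planted_variants
            ],
        }


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode()


def generate_genome_with_pseudogene(
    seed: int,
    gene_length: int = 3000,
    identity: float = 0.99,
    flank: int = 1000,
    identical_core_fraction: float = 0.4,
    contig: str = "chrS",
) -> SyntheticTruth:
    """Build a contig with a gene and a near-identical pseudogene copy.

    The gene copy spans ``gene_length`` bases: an in-frame CDS ending in a
    stop codon followed by a short untranslated tail. The pseudogene is an
    exact copy except at ``round((1 - identity) * gene_length)`` engineered
    positions, so realized identity matches the request exactly. One
    contiguous fraction of the copy (``identical_core_fraction``, centered)
    carries no differences — mimicking the clustered divergence of real
    pseudogenes — and the differences are spread evenly over the remainder.

    Layout: [flank][gene copy][flank][pseudogene copy][flank].
    """
    if not (0.9 <= identity < 1.0):
        raise ValueError("identity must be in [0.9, 1.0); 1.0 would make reads unassignable")
    if gene_length < 300 or gene_length % 3:
        raise ValueError("gene_length must be >= 300 and a multiple of 3")
    if not (0 <= identical_core_fraction < 1):
        raise ValueError("identical_core_fraction must be in [0, 1)")
    n_diff = round((1.0 - identity) * gene_length)
    core_len = int(identical_core_fraction * gene_length)
    if n_diff < 1 or gene_length - core_len < n_diff:
        raise ValueError("infeasible identity / core fraction combination")

    rng = np.random.default_rng(seed)

    # gene copy: CDS of non-stop codons ending in TAG, then untranslated tail
    utr_len = min(150, gene_length - 300)
    cds_len = gene_length - utr_len
    cds_len -= cds_len % 3
    utr_len = gene_length - cds_len
    codons = rng.choice(_NONSTOP_CODONS, size=cds_len // 3 - 1)
    cds = "".join(codons) + "TAG"
    utr = _random_seq(rng, utr_len)
    gene_seq = cds + utr

    # engineered differences: evenly spaced outside the centered identical core
    core_start = (gene_length - core_len) // 2
    core_end = core_start + core_len
    eligible = np.array(
        [i for i in range(gene_length) if not (core_start <= i < core_end)]
    )
    offset = rng.uniform(0, 1)
    picks = np.floor((np.arange(n_diff) + offset) * len(eligible) / n_diff).astype(int)
    diff_positions = sorted(int(eligible[p]) for p in np.unique(picks))
    while len(diff_positions) < n_diff:  # de-dup fallback, keeps count exact
        extra = [i for i in eligible if i not in set(diff_positions)]
        diff_positions = sorted(diff_positions + extra[: n_diff - len(diff_positions)])

    pseudo = list(gene_seq)
    for d in diff_positions:
        orig = pseudo[d]
        choices = [b for b in "ACGT" if b != orig]
        pseudo[d] = choices[int(rng.integers(0, 3))]
    pseudo_seq = "".join(pseudo)

    left = _random_seq(rng, flank)
    mid = _random_seq(rng, flank)
    right = _random_seq(rng, flank)
    reference = left + gene_seq + mid + pseudo_seq + right

    gene_region = GenomicInterval(contig, flank, flank + gene_length)
    pseudo_region = GenomicInterval(
        contig, flank + gene_length + flank, flank + gene_length + flank + gene_length
    )
    gene_model = GeneModel(
        gene_id="GENE1",
        symbol="GENE1",
        strand="+",
        coding_exons=[
            GenomicInterval(contig, gene_region.start, gene_region.start + cds_len)
        ],
    )
    return SyntheticTruth(
        seed=seed,
        contig=contig,
        reference=reference,
        gene_region=gene_region,
        pseudogene_region=pseudo_region,
        identity=identity,
        diff_positions=diff_positions,
        gene_model=gene_model,
        cds_end_offset=cds_len,
    )


def _read_mapq(truth: SyntheticTruth, start: int, end: int) -> int:
    """Idealized mapper: MAPQ 0 iff the span is inside a copy and diff-free."""
    for region in (truth.gene_region, truth.pseudogene_region):
        if start >= region.start and end <= region.end:
            lo, hi = start - region.start, end - region.start
            if any(lo <= d < hi for d in truth.diff_positions):
                return 60
            return 0
    return 60


def simulate_short_reads(
    truth: SyntheticTruth,
    read_length: int = 100,
    depth: float = 30.0,
    seed: int = 0,
    carry_variants: bool = False,
    error_rate: float = 0.0,
    sample_id: str = "S",
) -> list[AlignedRead]:
    """Idealized short reads tiling the whole contig.

    Reads originating inside a copy with no distinguishing position in their
    span get MAPQ 0 and are placed on either copy with equal probability;
    all other reads get MAPQ 60 at their true origin. Optional uniform
    substitution errors at ``error_rate`` per base.
    """
    if read_length >= truth.copy_length:
        raise ValueError("read_length must be shorter than the homologous segment")
    rng = np.random.default_rng(seed)
    hap = truth.sample_haplotype(carry_variants)
    L = truth.contig_length
    n_reads = int(round(depth * L / read_length))
    starts = rng.integers(0, L - read_length + 1, size=n_reads)
    copy_offset = truth.pseudogene_region.start - truth.gene_region.start

    reads: list[AlignedRead] = []
    for i, s in enumerate(sorted(int(x) for x in starts)):
        e = s + read_length
        seq = hap[s:e]
        mapq = _read_mapq(truth, s, e)
        pos = s
        if mapq == 0 and rng.random() < 0.5:
            # equally good placement on the homologous copy
            if s >= truth.pseudogene_region.start:
                pos = s - copy_offset
            else:
                pos = s + copy_offset
        if error_rate > 0:
            arr = list(seq)
            for j in np.flatnonzero(rng.random(read_length) < error_rate):
                arr[j] = "ACGT"[(("ACGT".index(arr[j])) + int(rng.integers(1, 4))) % 4]
            seq = "".join(arr)
        reads.append(AlignedRead(f"{sample_id}_r{i}", truth.contig, pos, seq, mapq))
    return reads


def simulate_long_reads(
    truth: SyntheticTruth,
    read_length: int | None = None,
    depth: float = 12.0,
    seed: int = 0,
    carry_variants: bool = False,
    sample_id: str = "L",
) -> list[AlignedRead]:
    """Idealized long reads: every read spans a diagnostic flank, MAPQ 60."""
    if read_length is None:
        read_length = truth.copy_length + max(1000, truth.copy_length // 2)
    if read_length <= truth.copy_length + 2:
        raise ValueError("read_length must exceed the homologous segment by > 2 bp")
    rng = np.random.default_rng(seed)
    hap = truth.sample_haplotype(carry_variants)
    L = truth.contig_length
    read_length = min(read_length, L)
    n_reads = max(1, int(round(depth * L / read_length)))
    starts = rng.integers(0, L - read_length + 1, size=n_reads)
    # deterministic anchors so the span union always covers the contig
    anchors = np.linspace(0, L - read_length, max(2, int(np.ceil(L / read_length)) + 1))
    starts = np.concatenate([starts, anchors.astype(int)])
    return [
        AlignedRead(
            f"{sample_id}_r{i}",
            truth.contig,
            int(s),
            hap[int(s) : int(s) + read_length],
            60,
        )
        for i, s in enumerate(sorted(int(x) for x in starts))
    ]


def cohort_depth_profiles(
    truth: SyntheticTruth,
    n_samples: int,
    read_length: int = 100,
    depth: float = 30.0,
    mapq_min: int = 20,
    seed: int = 0,
) -> list[DepthProfile]:
    """MAPQ-filtered depth profiles for a cohort of variant-free samples."""
    rng = np.random.default_rng(seed)
    profiles = []
    for k in range(n_samples):
        reads = simulate_short_reads(
            truth,
            read_length=read_length,
            depth=depth,
            seed=int(rng.integers(0, 2**31 - 1)),
            sample_id=f"P{k}",
        )
        profiles.append(
            depth_profile_from_alignments(
                reads, truth.contig, truth.contig_length, mapq_min, sample_id=f"P{k}"
            )
        )
    return profiles


# --------------------------------------------------------------------------
# variant-set pairs with planted concordance


def generate_variant_pair(
    n_shared: int,
    n_a_only: int,
    n_b_only: int,
    indel_fraction: float = 0.0,
    seed: int = 0,
    contig: str = "chrV",
) -> tuple[list[VariantRecord], list[VariantRecord], dict]:
    """Two call sets with exactly the planted shared/exclusive counts.

    Positions are drawn without collision on a virtual contig, so the match
    keys are distinct by construction. Per category, ``round(indel_fraction
    * n)`` records are indels (single-base insertions/deletions) and the rest
    SNVs; the per-class planted counts are returned as truth.
    """
    total = n_shared + n_a_only + n_b_only
    rng = np.random.default_rng(seed)
    span = max(10 * total + 1000, 10_000)
    positions = rng.choice(span, size=total, replace=False) + 1

    def make(pos: int, indel: bool) -> VariantRecord:
        ref = "ACGT"[int(rng.integers(0, 4))]
        if not indel:
            alt = "ACGT"[("ACGT".index(ref) + int(rng.integers(1, 4))) % 4]
            return VariantRecord(contig, int(pos), ref, alt)
        other = "ACGT"[int(rng.integers(0, 4))]
        if rng.random() < 0.5:
            return VariantRecord(contig, int(pos), ref, ref + other)  # insertion
        return VariantRecord(contig, int(pos), ref + other, ref)  # deletion

    truth = {"SNV": {"n_shared": 0, "n_a_only": 0, "n_b_only": 0},
             "INDEL": {"n_shared": 0, "n_a_only": 0, "n_b_only": 0}}
    a: list[VariantRecord] = []
    b: list[VariantRecord] = []
    cursor = 0
    for category, n in (("n_shared", n_shared), ("n_a_only", n_a_only),
                        ("n_b_only", n_b_only)):
        n_indel = round(indel_fraction * n)
        for j in range(n):
            v = make(positions[cursor], indel=j < n_indel)
            cursor += 1
            truth[v.var_class][category] += 1
            if category in ("n_shared", "n_a_only"):
                a.append(v)
            if category in ("n_shared", "n_b_only"):
                b.append(v)
    return a, b, truth


# --------------------------------------------------------------------------
# methylation calls with planted imprinting status

_PATTERN_PROBS = {
    "normal_imprinted": (lambda eps: (1 - eps, eps)),
    "upd_hyper": (lambda eps: (1 - eps, 1 - eps)),
    "upd_hypo": (lambda eps: (eps, eps)),
}

PATTERN_STATUS = {
    "normal_imprinted": ImprintingStatus.MONOALLELIC,
    "upd_hyper": ImprintingStatus.BIALLELIC_HYPER,
    "upd_hypo": ImprintingStatus.BIALLELIC_HYPO,
}


def generate_methylation_calls(
    pattern: str,
    n_sites: int = 20,
    reads_per_hap: int = 15,
    noise_eps: float = 0.05,
    seed: int = 0,
    chrom: str = "chr15",
    region_start: int = 0,
    site_spacing: int = 25,
) -> tuple[list[CpGCall], ImprintingStatus, GenomicInterval]:
    """Haplotagged per-read CpG calls under a planted imprinting pattern.

    Per read and site, the methylation state is Bernoulli with per-haplotype
    success probability 1-eps or eps according to the pattern (``noise_eps``
    is the per-read flip noise); the reported probability is drawn well above
    or below the 0.5 binarization threshold accordingly.
    """
    if pattern not in _PATTERN_PROBS:
        raise ValueError(f"unknown pattern {pattern!r}; choose from {sorted(_PATTERN_PROBS)}")
    if not (0 <= noise_eps < 0.5):
        raise ValueError("noise_eps must be in [0, 0.5)")
    p1, p2 = _PATTERN_PROBS[pattern](noise_eps)
    rng = np.random.default_rng(seed)
    calls: list[CpGCall] = []
    for i in range(n_sites):
        site = region_start + i * site_spacing
        for hap, p in ((1, p1), (2, p2)):
            for r in range(reads_per_hap):
                meth = rng.random() < p
                prob = rng.uniform(0.75, 1.0) if meth else rng.uniform(0.0, 0.25)
                calls.append(
                    CpGCall(
                        read_id=f"h{hap}_r{r}",
                        chrom=chrom,
                        site=site,
                        meth_prob=float(prob),
                        haplotype=hap,
                    )
                )
    region = GenomicInterval(
        chrom, region_start, region_start + max(1, (n_sites - 1) * site_spacing + 1)
    )
    return calls, PATTERN_STATUS[pattern], region


# --------------------------------------------------------------------------
# HPO fixture with planted per-gene loads and implied ranking


def generate_hpo_fixture(
    n_genes: int,
    n_terms: int,
    max_terms_per_gene: int = 3,
    seed: int = 0,
    contig: str = "chrH",
) -> tuple[list[GeneModel], list[HpoAnnotation], list[GenomicInterval], dict, list[str]]:
    """Genes, annotations and dead zones realizing planted per-gene loads.

    Returns (gene models, annotations, dead-zone intervals, planted load per
    gene, truth term ranking). The dead zones are carved from each gene's
    single coding exon so the planted load is realized exactly; the truth
    ranking orders terms by summed planted load, ties broken by term id.
    """
    if n_terms < 2:
        raise ValueError("n_terms must be >= 2")
    rng = np.random.default_rng(seed)
    genes: list[GeneModel] = []
    zones: list[GenomicInterval] = []
    loads: dict[str, int] = {}
    cursor = 100
    for i in range(n_genes):
        exon_len = int(rng.integers(300, 1500))
        exon = GenomicInterval(contig, cursor, cursor + exon_len)
        gid = f"G{i:03d}"
        genes.append(GeneModel(gid, gid, "+", [exon]))
        load = int(rng.integers(0, exon_len + 1))
        loads[gid] = load
        if load > 0:
            zones.append(GenomicInterval(contig, exon.start, exon.start + load))
        cursor += exon_len + int(rng.integers(200, 500))

    terms = [f"HP:{7000000 + t}" for t in range(n_terms)]
    anns = {t: HpoAnnotation(t, f"Phenotype {t[-4:]}", set()) for t in terms}
    for i, g in enumerate(genes):
        k = int(rng.integers(1, max_terms_per_gene + 1))
        chosen = set(rng.choice(n_terms, size=min(k, n_terms), replace=False).tolist())
        chosen.add(i % n_terms)  # every term keeps at least one gene when possible
        for t in chosen:
            anns[terms[t]].gene_ids.add(g.gene_id)

    annotations = [anns[t] for t in terms if anns[t].gene_ids]
    totals = {
        a.term_id: sum(loads.get(g, 0) for g in a.gene_ids) for a in annotations
    }
    truth_ranking = [t for t, _ in sorted(totals.items(), key=lambda kv: (-kv[1], kv[0]))]
    return genes, annotations, merge_intervals(zones), loads, truth_ranking


# --------------------------------------------------------------------------
# file writers for scenario export


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name in sequences:
            fh.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_gff3(genes: Sequence[GeneModel], path: str | Path) -> None:
    """Write gene models as GFF3 gene/mRNA/CDS features (1-based closed)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            if not g.coding_exons:
                continue
            chrom = g.chrom
            lo = min(iv.start for iv in g.coding_exons) + 1
            hi = max(iv.end for iv in g.coding_exons)
            fh.write(
                f"{chrom}\tshadowzones\tgene\t{lo}\t{hi}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id};Name={g.symbol}\n"
            )
            fh.write(
                f"{chrom}\tshadowzones\tmRNA\t{lo}\t{hi}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}.t1;Parent={g.gene_id}\n"
            )
            for j, iv in enumerate(g.coding_exons):
                fh.write(
                    f"{chrom}\tshadowzones\tCDS\t{iv.start + 1}\t{iv.end}\t.\t"
                    f"{g.strand}\t0\tID={g.gene_id}.cds{j};Parent={g.gene_id}.t1\n"
                )


def export_pseudogene_scenario(
    seed: int,
    outdir: str | Path,
    n_samples: int = 10,
    read_length: int = 100,
    depth: float = 30.0,
) -> SyntheticTruth:
    """Write the full gene+pseudogene scenario: FASTA, GFF3, SAM, truth files."""
    from .deadzones import write_depth_tsv

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth = generate_genome_with_pseudogene(seed)
    # plant a variant in the identical core of the pseudogene
    core_mid = truth.copy_length // 2
    alt = "A" if truth.locus_base("pseudogene", core_mid) != "A" else "G"
    truth.plant_variant("pseudogene", core_mid, alt)

    write_fasta({truth.contig: truth.reference}, outdir / "reference.fasta")
    write_gff3([truth.gene_model], outdir / "genes.gff3")
    write_bed(truth.expected_dead_zone(read_length), outdir / "true_deadzone.bed")
    write_vcf_minimal(
        [v for v, _ in truth.planted_variants], outdir / "planted_variants.vcf"
    )
    rng = np.random.default_rng(seed)
    contig_lengths = {truth.contig: truth.contig_length}
    for k in range(n_samples):
        reads = simulate_short_reads(
            truth,
            read_length=read_length,
            depth=depth,
            seed=int(rng.integers(0, 2**31 - 1)),
            sample_id=f"P{k}",
        )
        prof = depth_profile_from_alignments(
            reads, truth.contig, truth.contig_length, mapq_min=20, sample_id=f"P{k}"
        )
        write_depth_tsv(prof, outdir / f"depth_P{k}.tsv")
    proband = simulate_short_reads(
        truth,
        read_length=read_length,
        depth=depth,
        seed=int(rng.integers(0, 2**31 - 1)),
        carry_variants=True,
        sample_id="PROBAND",
    )
    write_sam(proband, outdir / "proband_srs.sam", contig_lengths)
    lrs = simulate_long_reads(
        truth, seed=int(rng.integers(0, 2**31 - 1)), carry_variants=True
    )
    write_sam(lrs, outdir / "proband_lrs.sam", contig_lengths)
    (outdir / "truth.json").write_text(json.dumps(truth.to_json(), indent=2) + "\n")
    return truth


def export_concordance_scenario(
    seed: int,
    outdir: str | Path,
    n_shared: int = 9960,
    n_a_only: int = 20,
    n_b_only: int = 20,
    indel_fraction: float = 0.0,
) -> dict:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    a, b, truth = generate_variant_pair(
        n_shared, n_a_only, n_b_only, indel_fraction, seed
    )
    write_vcf_minimal(a, outdir / "set_a.vcf")
    write_vcf_minimal(b, outdir / "set_b.vcf")
    (outdir / "truth.json").write_text(json.dumps(truth, indent=2) + "\n")
    return truth


def export_methylation_scenario(seed: int, outdir: str | Path) -> dict:
    """Three named loci: two normal imprinted, one UPD-like hypermethylated."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    loci = [("MAGEL2", "normal_imprinted"), ("NDN", "normal_imprinted"),
            ("SNRPN", "upd_hyper")]
    calls: list[CpGCall] = []
    truth: dict[str, str] = {}
    bed_rows = []
    start = 1000
    for name, pattern in loci:
        c, status, region = generate_methylation_calls(
            pattern, seed=int(rng.integers(0, 2**31 - 1)), region_start=start
        )
        calls.extend(c)
        truth[name] = status.value
        bed_rows.append((region, name))
        start = region.end + 500
    write_methylation_tsv(calls, outdir / "calls.tsv")
    with open(outdir / "loci.bed", "w") as fh:
        for region, name in bed_rows:
            fh.write(f"{region.chrom}\t{region.start}\t{region.end}\t{name}\n")
    (outdir / "truth.json").write_text(json.dumps(truth, indent=2) + "\n")
    return truth


def export_hpo_scenario(
    seed: int, outdir: str | Path, n_genes: int = 30, n_terms: int = 8
) -> list[str]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genes, annotations, zones, loads, ranking = generate_hpo_fixture(
        n_genes, n_terms, seed=seed
    )
    write_gff3(genes, outdir / "genes.gff3")
    write_bed(zones, outdir / "zones.bed")
    with open(outdir / "gene_to_phenotype.tsv", "w") as fh:
        for ann in annotations:
            for g in sorted(ann.gene_ids):
                fh.write(f"{g}\t{ann.term_id}\t{ann.term_name}\n")
    (outdir / "truth.json").write_text(
        json.dumps({"loads": loads, "ranking": ranking}, indent=2) + "\n"
    )
    return ranking
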