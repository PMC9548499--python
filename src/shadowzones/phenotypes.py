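"""Phenotype prioritization by coding dead-zone burden.

Genes whose coding exons fall inside short-read dead zones cannot be assayed
by short-read sequencing; aggregating their hidden coding bases over the
Human Phenotype Ontology (HPO) terms they are annotated to ranks phenotypes
by how much of their genic territory only long reads can reach. A handful of
very large genes (TTN-sized) can dominate every term they touch, so the
module also proposes dominant genes for explicit, auditable exclusion rather
than silently dropping them.

A gene's dead bases count once per term it is annotated to; terms are not
mutually exclusive, so totals are comparable across terms but do not sum to a
genome-wide quantity. No ontology propagation to ancestor terms is performed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .core import GeneModel, GenomicInterval, intersect_length, total_length
from .deadzones import DeadZoneSet

__all__ = [
    "GeneDeadZoneLoad",
    "HpoAnnotation",
    "PhenotypeRankRow",
    "coding_dead_bases_per_gene",
    "rank_phenotypes",
    "flag_dominant_genes",
    "read_gene_to_phenotype",
    "ranking_to_frame",
]


@dataclass(frozen=True)
class GeneDeadZoneLoad:
    """Coding bases of one gene that lie inside dead zones."""

    gene_id: str
    dead_coding_bases: int
    total_coding_bases: int

    def __post_init__(self) -> None:
        if not (0 <= self.dead_coding_bases <= self.total_coding_bases):
            raise ValueError(
                f"{self.gene_id}: dead bases {self.dead_coding_bases} outside "
                f"[0, {self.total_coding_bases}]"
            )


@dataclass
class HpoAnnotation:
    """One HPO term and the disease genes annotated to it."""

    term_id: str
    term_name: str
    gene_ids: set[str] = field(default_factory=set)


@dataclass(frozen=True)
class PhenotypeRankRow:
    term_id: str
    term_name: str
    n_genes: int
    total_dead_bases: int
    rank: int


def _zones_list(zones: DeadZoneSet | Sequence[GenomicInterval]) -> list[GenomicInterval]:
    return zones.zones if isinstance(zones, DeadZoneSet) else list(zones)


def coding_dead_bases_per_gene(
    zones: DeadZoneSet | Sequence[GenomicInterval], genes: Iterable[GeneModel]
) -> list[GeneDeadZoneLoad]:
    """Per-gene coding bases inside dead zones; one row per gene, zeros kept."""
    zs = _zones_list(zones)
    return [
        GeneDeadZoneLoad(
            gene_id=g.gene_id,
            dead_coding_bases=intersect_length(zs, g.coding_exons),
            total_coding_bases=total_length(g.coding_exons),
        )
        for g in genes
    ]


def _term_totals(
    loads: Sequence[GeneDeadZoneLoad],
    annotations: Sequence[HpoAnnotation],
    excluded_genes: set[str],
) -> dict[str, tuple[int, int]]:
    by_gene = {l.gene_id: l.dead_coding_bases for l in loads}
    totals: dict[str, tuple[int, int]] = {}
    for ann in annotations:
        members = ann.gene_ids - excluded_genes
        loads_present = [by_gene.get(g, 0) for g in members]
        totals[ann.term_id] = (
            sum(loads_present),
            sum(1 for x in loads_present if x > 0),
        )
    return totals


def rank_phenotypes(
    loads: Sequence[GeneDeadZoneLoad],
    annotations: Sequence[HpoAnnotation],
    excluded_genes: set[str] | None = None,
) -> list[PhenotypeRankRow]:
    """Rank HPO terms by total coding dead-zone bases of their genes.

    Genes in ``excluded_genes`` contribute nothing; genes absent from
    ``loads`` contribute zero. Ties break lexicographically by term id so the
    ranking is deterministic; ranks are 1..n with no repeats.
    """
    excluded = excluded_genes or set()
    names = {a.term_id: a.term_name for a in annotations}
    totals = _term_totals(loads, annotations, excluded)
    ordered = sorted(totals.items(), key=lambda kv: (-kv[1][0], kv[0]))
    return [
        PhenotypeRankRow(
            term_id=tid,
            term_name=names[tid],
            n_genes=n_genes,
            total_dead_bases=tot,
            rank=i,
        )
        for i, (tid, (tot, n_genes)) in enumerate(ordered, 1)
    ]


def flag_dominant_genes(
    loads: Sequence[GeneDeadZoneLoad],
    annotations: Sequence[HpoAnnotation],
    dominance_fraction: float = 0.5,
) -> set[str]:
    """Genes contributing at least ``dominance_fraction`` of some term's total.

    This is stage one of a deliberately two-stage process: it proposes
    candidates, and the caller passes an explicit exclusion list to
    :func:`rank_phenotypes` — mirroring how large genes are removed by
    inspection rather than automatically.
    """
    if not (0 < dominance_fraction <= 1):
        raise ValueError("dominance_fraction must be in (0, 1]")
    by_gene = {l.gene_id: l.dead_coding_bases for l in loads}
    flagged: set[str] = set()
    for ann in annotations:
        term_total = sum(by_gene.get(g, 0) for g in ann.gene_ids)
        if term_total <= 0:
            continue
        for g in ann.gene_ids:
            if by_gene.get(g, 0) / term_total >= dominance_fraction:
                flagged.add(g)
    return flagged


def read_gene_to_phenotype(path: str | Path) -> list[HpoAnnotation]:
    """Read a two/three-column gene-to-phenotype TSV.

    Columns: gene symbol, HPO term id, optional term name — the layout of
    standard genes-to-phenotype exports. Rows aggregate into one annotation
    per term.
    """
    anns: dict[str, HpoAnnotation] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected >= 2 tab-separated columns")
            gene, term_id = fields[0], fields[1]
            term_name = fields[2] if len(fields) > 2 else term_id
            ann = anns.setdefault(term_id, HpoAnnotation(term_id, term_name, set()))
            ann.gene_ids.add(gene)
            if len(fields) > 2 and ann.term_name == ann.term_id:
                ann.term_name = term_name
    return [anns[t] for t in sorted(anns)]


def ranking_to_frame(rows: Sequence[PhenotypeRankRow]) -> pd.DataFrame:
    """Ranking as a DataFrame, column order matching the TSV output."""
    return pd.DataFrame(
        [
            (r.term_id, r.term_name, r.n_genes, r.total_dead_bases, r.rank)
            for r in rows
        ],
        columns=["term_id", "term_name", "n_genes", "total_dead_bases", "rank"],
    )
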