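"""Shared fixtures and brute-force per-base oracles.

The oracles deliberately use dumb per-base boolean masks on small contigs:
they are independent of the interval-sweep implementations they check.
"""

from __future__ import annotations

import numpy as np
import pytest

from shadowzones.core import GenomicInterval


CONTIG = "chrT"
CONTIG_LEN = 10_000


def bitmap(intervals, length=CONTIG_LEN) -> np.ndarray:
    """Per-base boolean mask of a single-contig interval set."""
    mask = np.zeros(length, dtype=bool)
    for iv in intervals:
        mask[iv.start : iv.end] = True
    return mask


def mask_to_intervals(mask: np.ndarray, chrom=CONTIG) -> list[GenomicInterval]:
    out = []
    start = None
    for i, v in enumerate(mask):
        if v and start is None:
            start = i
        elif not v and start is not None:
            out.append(GenomicInterval(chrom, start, i))
            start = None
    if start is not None:
        out.append(GenomicInterval(chrom, start, len(mask)))
    return out


def random_intervals(rng: np.random.Generator, n_max=50, length=CONTIG_LEN):
    n = int(rng.integers(0, n_max + 1))
    out = []
    for _ in range(n):
        start = int(rng.integers(0, length - 1))
        end = int(rng.integers(start + 1, min(length, start + 500) + 1))
        out.append(GenomicInterval(CONTIG, start, end))
    return out


@pytest.fixture(scope="session")
def pseudogene_truth():
    from shadowzones.simulate import generate_genome_with_pseudogene

    return generate_genome_with_pseudogene(seed=11)
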