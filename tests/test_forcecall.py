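"""Force calling with ambiguity flags, and stop-loss consequence annotation."""

import numpy as np
import pytest

from shadowzones.core import GenomicInterval
from shadowzones.forcecall import (
    AlignedRead,
    ForceCallParams,
    StopLossAnnotation,
    annotate_stop_loss,
    format_stop_loss,
    pileup_force_call,
    read_reads_tsv,
    read_sam,
    write_reads_tsv,
    write_sam,
)
from shadowzones.simulate import (
    generate_genome_with_pseudogene,
    simulate_long_reads,
    simulate_short_reads,
)


def plant_core_variant(truth, origin):
    mid = truth.copy_length // 2
    alt = "A" if truth.locus_base(origin, mid) != "A" else "G"
    return truth.plant_variant(origin, mid, alt)


class TestPileup:
    def test_reference_reads_give_no_calls(self):
        ref = "ACGT" * 50
        reads = [AlignedRead(f"r{i}", "c", 10 * i, ref[10 * i : 10 * i + 60], 60)
                 for i in range(10)]
        assert pileup_force_call(reads, ref, GenomicInterval("c", 0, 200)) == []

    def test_homozygous_high_mapq_variant_unambiguous(self):
        ref = "A" * 100
        alt_seq = "A" * 50 + "T" + "A" * 9
        reads = [AlignedRead(f"r{i}", "c", 0, alt_seq + "A" * 40, 60) for i in range(8)]
        calls = pileup_force_call(reads, ref, GenomicInterval("c", 0, 100))
        assert len(calls) == 1
        c = calls[0]
        assert (c.variant.pos, c.variant.ref, c.variant.alt) == (51, "A", "T")
        assert c.alt_fraction == 1.0 and not c.ambiguous
        assert c.n_alt_highmapq == c.n_alt == 8

    def test_region_outside_reference_rejected(self):
        with pytest.raises(ValueError, match="cover"):
            pileup_force_call([], "ACGT", GenomicInterval("c", 0, 10))

    def test_thresholds_suppress_weak_calls(self):
        ref = "A" * 20
        reads = [AlignedRead("alt1", "c", 0, "A" * 5 + "T" + "A" * 14, 60)] + [
            AlignedRead(f"ref{i}", "c", 0, ref, 60) for i in range(20)
        ]
        # 1 alt read < min_alt_reads, and 1/21 < min_alt_fraction
        assert pileup_force_call(reads, ref, GenomicInterval("c", 0, 20)) == []

    def test_pseudogene_variant_appears_heterozygous_and_ambiguous(self):
        """The false-positive mechanism: a pseudogene variant force-called at
        the gene locus looks like a ~50% het with only MAPQ-0 support."""
        truth = generate_genome_with_pseudogene(seed=21)
        v = plant_core_variant(truth, "pseudogene")
        reads = simulate_short_reads(truth, depth=60, seed=3, carry_variants=True)
        calls = pileup_force_call(reads, truth.reference, truth.gene_region)
        gene_pos = truth.gene_region.start + (v.pos - 1 - truth.pseudogene_region.start) + 1
        match = [c for c in calls if c.variant.pos == gene_pos and c.variant.alt == v.alt]
        assert len(match) == 1
        c = match[0]
        assert c.ambiguous and c.n_alt_highmapq == 0
        sigma = 0.5 / np.sqrt(c.n_total)
        assert abs(c.alt_fraction - 0.5) <= 3 * sigma

    def test_gene_variant_equally_ambiguous_under_short_reads(self):
        """A true positive on the gene produces the identical ambiguous signal —
        short-read evidence cannot distinguish the two without orthogonal data."""
        truth = generate_genome_with_pseudogene(seed=22)
        v = plant_core_variant(truth, "gene")
        reads = simulate_short_reads(truth, depth=60, seed=4, carry_variants=True)
        calls = pileup_force_call(reads, truth.reference, truth.gene_region)
        match = [c for c in calls if c.variant.pos == v.pos and c.variant.alt == v.alt]
        assert len(match) == 1
        c = match[0]
        assert c.ambiguous and c.n_alt_highmapq == 0
        sigma = 0.5 / np.sqrt(c.n_total)
        assert abs(c.alt_fraction - 0.5) <= 3 * sigma

    def test_long_reads_recover_gene_variant_unambiguously(self):
        truth = generate_genome_with_pseudogene(seed=23)
        v = plant_core_variant(truth, "gene")
        reads = simulate_long_reads(truth, depth=15, seed=5, carry_variants=True)
        calls = pileup_force_call(reads, truth.reference, truth.gene_region)
        match = [c for c in calls if c.variant.pos == v.pos and c.variant.alt == v.alt]
        assert len(match) == 1
        c = match[0]
        assert not c.ambiguous
        assert c.alt_fraction == 1.0

    @pytest.mark.parametrize("seed", range(50))
    def test_force_calls_superset_of_confident_only_calls(self, seed):
        """Admitting all reads never loses a call made from confident reads only."""
        rng = np.random.default_rng(seed)
        truth = generate_genome_with_pseudogene(
            seed=seed, gene_length=600, flank=200, identical_core_fraction=0.3
        )
        origin = "gene" if rng.random() < 0.5 else "pseudogene"
        offset = int(rng.integers(10, truth.copy_length - 10))
        base = truth.locus_base(origin, offset)
        truth.plant_variant(origin, offset, "ACGT"[("ACGT".index(base) + 1) % 4])
        reads = simulate_short_reads(
            truth, read_length=80, depth=25, seed=seed + 1, carry_variants=True
        )
        params = ForceCallParams()
        all_calls = pileup_force_call(reads, truth.reference, truth.gene_region, params)
        hq_reads = [r for r in reads if r.mapq >= params.mapq_confident]
        hq_calls = pileup_force_call(reads=hq_reads, reference=truth.reference,
                                     region=truth.gene_region, params=params)
        all_keys = {c.variant.key for c in all_calls}
        assert {c.variant.key for c in hq_calls} <= all_keys


class TestStopLoss:
    def test_tag_third_base_to_tyrosine(self):
        # TAG with third-base G>C -> TAC, tyrosine readthrough
        seq = "ATG" + "GCT" * 5 + "TAG" + "CCC" * 4 + "TAA" + "GGG"
        cds_end = 3 + 15 + 3
        ann = annotate_stop_loss(seq, cds_end, cds_end - 1, "G", "C")
        assert ann.new_aa == "Y"
        assert ann.ext_codons == 5  # CCC x4 then TAA
        assert ann.stop_codon_index == 7
        assert format_stop_loss(ann) == "p.X7Yext5"

    def test_synonymous_stop(self):
        seq = "ATG" + "TAA" + "CCCCCC"
        ann = annotate_stop_loss(seq, 6, 4, "A", "G")  # TAA -> TGA, still stop
        assert ann.synonymous and ann.new_aa == "*"
        assert ann.ext_codons is None
        assert format_stop_loss(ann) == "p.X2="

    def test_no_downstream_stop_flagged(self):
        seq = "ATG" + "TAG" + "CCC" * 3
        ann = annotate_stop_loss(seq, 6, 5, "G", "C")  # TAG -> TAC = Y
        assert ann.ext_codons is None and not ann.synonymous
        assert format_stop_loss(ann) == "p.X2Yext*"

    def test_substitution_outside_stop_codon_rejected(self):
        seq = "ATG" + "TAG" + "CCC"
        with pytest.raises(ValueError, match="outside the stop codon"):
            annotate_stop_loss(seq, 6, 1, "T", "A")

    def test_ref_base_mismatch_rejected(self):
        seq = "ATG" + "TAG" + "CCC"
        with pytest.raises(ValueError, match="does not match"):
            annotate_stop_loss(seq, 6, 5, "A", "C")

    def test_formatting_examples(self):
        assert format_stop_loss(StopLossAnnotation(420, "Y", 27)) == "p.X420Yext27"
        assert format_stop_loss(StopLossAnnotation(10, "W", 1)) == "p.X10Wext1"
        assert format_stop_loss(StopLossAnnotation(9, "L", None)) == "p.X9Lext*"

    @pytest.mark.parametrize("seed", range(8))
    def test_extension_agrees_with_full_translation_oracle(self, seed):
        """ext_codons equals the oracle's position of the first downstream stop,
        found by translating the entire readthrough frame with biopython."""
        from Bio.Seq import Seq

        rng = np.random.default_rng(seed)
        nonstop = [c for c in
                   ("".join(t) for t in __import__("itertools").product("ACGT", repeat=3))
                   if c not in {"TAA", "TAG", "TGA"}]
        for _ in range(25):
            n_codons = int(rng.integers(2, 30))
            cds = "".join(rng.choice(nonstop, size=n_codons - 1)) + str(
                rng.choice(["TAA", "TAG", "TGA"])
            )
            tail = "".join(rng.choice(["".join(t) for t in
                                       __import__("itertools").product("ACGT", repeat=3)],
                                      size=int(rng.integers(0, 40))))
            seq = cds + tail
            cds_end = len(cds)
            stop = seq[cds_end - 3 : cds_end]
            k = int(rng.integers(0, 3))
            ref = stop[k]
            alt = "ACGT"[("ACGT".index(ref) + int(rng.integers(1, 4))) % 4]
            ann = annotate_stop_loss(seq, cds_end, cds_end - 3 + k, ref, alt)
            mutated = stop[:k] + alt + stop[k + 1 :]
            if mutated in {"TAA", "TAG", "TGA"}:
                assert ann.synonymous
                continue
            # oracle: translate the full readthrough frame and find the first stop
            frame = mutated + tail
            frame = frame[: len(frame) - len(frame) % 3]
            prot = str(Seq(frame).translate())
            star = prot.find("*")
            expected = None if star == -1 else star  # codons after the lost stop
            assert ann.new_aa == prot[0]
            assert ann.ext_codons == expected


def test_reads_tsv_and_sam_round_trip(tmp_path):
    reads = [
        AlignedRead("r1", "chrS", 0, "ACGTACGT", 60),
        AlignedRead("r2", "chrS", 5, "TTTT", 0),
    ]
    tsv = tmp_path / "reads.tsv"
    write_reads_tsv(reads, tsv)
    assert read_reads_tsv(tsv) == reads
    sam = tmp_path / "reads.sam"
    write_sam(reads, sam, {"chrS": 100})
    assert read_sam(sam) == reads
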