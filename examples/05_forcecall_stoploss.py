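"""Force-call a dead-zone variant and annotate a stop-loss substitution.

Plants a variant on the PSEUDOGENE, then force-calls the GENE locus from all
mapped short reads (MAPQ 0 included): the pseudogene variant appears as an
apparent heterozygote at the gene with every supporting read ambiguously
mapped — the classic paralog false positive. Also annotates a stop-codon
substitution that extends translation into the downstream frame.
"""

from shadowzones import annotate_stop_loss, pileup_force_call
from shadowzones.simulate import generate_genome_with_pseudogene, simulate_short_reads

truth = generate_genome_with_pseudogene(seed=21)
mid = truth.copy_length // 2
base = truth.locus_base("pseudogene", mid)
variant = truth.plant_variant("pseudogene", mid, "A" if base != "A" else "G")
print(f"planted on pseudogene: {variant.chrom}:{variant.pos} {variant.ref}>{variant.alt}")

reads = simulate_short_reads(truth, depth=120, seed=22, carry_variants=True)
calls = pileup_force_call(reads, truth.reference, truth.gene_region)
gene_pos = truth.gene_region.start + mid + 1
for c in calls:
    if c.variant.pos == gene_pos:
        print(f"force call at GENE locus {c.variant.chrom}:{c.variant.pos} "
              f"{c.variant.ref}>{c.variant.alt}: alt fraction "
              f"{c.alt_fraction:.2f} ({c.n_alt}/{c.n_total} reads), "
              f"confident-MAPQ alt support {c.n_alt_highmapq}, "
              f"ambiguous={c.ambiguous}")
# alt fraction ~0.5 with zero confidently mapped support: indistinguishable
# from a real heterozygote without orthogonal confirmation.

seq = ("ATG" + "GCT" * 418 + "TAG"  # 420-codon CDS ending in TAG
       + "CCA" * 26 + "TGA" + "GGGCCC")  # readthrough frame stops 27 codons in
ann = annotate_stop_loss(seq, cds_end=1260, sub_pos=1259, ref_base="G", alt_base="C")
print(f"\nstop-loss annotation: {ann.hgvs_p} "
      f"(stop codon {ann.stop_codon_index} becomes {ann.new_aa}; translation "
      f"extends {ann.ext_codons} codons to the next in-frame stop)")
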