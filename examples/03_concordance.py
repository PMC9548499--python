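"""Compare two small-variant call sets (e.g. short-read vs long-read calls).

Builds a pair of call sets with planted overlap — 9,960 shared SNVs and 20
exclusive to each side — and prints the per-class concordance under both
denominator conventions.
"""

from shadowzones import compare_variant_sets, normalize_variant, VariantRecord
from shadowzones.simulate import generate_variant_pair

a, b, _ = generate_variant_pair(n_shared=9960, n_a_only=20, n_b_only=20, seed=1)
summary = compare_variant_sets(a, b)
snv = summary.snv
print(f"SNVs: {snv.n_shared} shared, {snv.n_a_only} A-only, {snv.n_b_only} B-only")
print(f"  shared / union : {snv.shared_frac_union:.1%}")
print(f"  shared / |A|   : {snv.shared_frac_of_a:.1%}")

# indels must be normalized before matching: the same deletion written two
# ways matches only after left-alignment against the reference
ref_window = ("GTTTTTACGTAC", 1)  # sequence starting at 1-based position 1
v1 = normalize_variant(VariantRecord("chr1", 5, "TT", "T"), ref_window)
v2 = normalize_variant(VariantRecord("chr1", 2, "TT", "T"), ref_window)
print(f"\nleft-aligned homopolymer deletion: {v1.pos} {v1.ref}>{v1.alt} "
      f"(same event from either placement: {v1 == v2})")
# shared/union is the headline concordance; shared/|A| answers "how many of
# technology A's calls did technology B replicate".
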