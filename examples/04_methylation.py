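"""Classify imprinted loci from haplotype-phased CpG methylation calls.

Simulates three named loci: two with the normal imprinted pattern (one
haplotype methylated, the other not) and one with biallelic hypermethylation
— the signature of maternal uniparental disomy at the Prader-Willi region.
"""

from shadowzones import screen_imprinted_loci
from shadowzones.simulate import generate_methylation_calls

calls, loci = [], []
start = 0
for seed, (name, pattern) in enumerate((("MAGEL2-like", "normal_imprinted"),
                                        ("NDN-like", "normal_imprinted"),
                                        ("SNRPN-like", "upd_hyper"))):
    c, _, region = generate_methylation_calls(pattern, seed=seed,
                                              region_start=start)
    calls.extend(c)
    loci.append((region, name))
    start = region.end + 500

for r in screen_imprinted_loci(calls, loci):
    print(f"{r.name:12s} {r.status.value:16s} "
          f"h1 {r.mean_frac_h1:.2f}  h2 {r.mean_frac_h2:.2f}  "
          f"({r.n_informative_sites} informative sites)")
# h1/h2 are the mean fractions of phased reads methylated per haplotype.
# monoallelic (~1.0 / ~0.0) is the normal imprinted state; both near 1.0
# (biallelic_hyper) at a maternally imprinted locus indicates a methylation
# defect such as uniparental disomy.
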