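"""Rank phenotypes (HPO terms) by how many coding bases of their genes are
hidden in short-read dead zones.

Generates a fixture with planted per-gene dead-coding loads, aggregates them
per HPO term, flags a dominant gene, and prints the ranking with and without
it — the same two-stage flow used to keep TTN-sized genes from dominating
every term they touch.
"""

from shadowzones import coding_dead_bases_per_gene, flag_dominant_genes, rank_phenotypes
from shadowzones.phenotypes import ranking_to_frame
from shadowzones.simulate import generate_hpo_fixture

genes, annotations, zones, loads_truth, truth_ranking = generate_hpo_fixture(
    n_genes=25, n_terms=6, seed=3
)
loads = coding_dead_bases_per_gene(zones, genes)

rows = rank_phenotypes(loads, annotations)
print("ranking (all genes):")
print(ranking_to_frame(rows).to_string(index=False))
print(f"matches generator truth: {[r.term_id for r in rows] == truth_ranking}")

dominant = flag_dominant_genes(loads, annotations, dominance_fraction=0.3)
print(f"\ngenes contributing >=30% of some term's total: {sorted(dominant)}")
rows2 = rank_phenotypes(loads, annotations, excluded_genes=dominant)
print("ranking after excluding them:")
print(ranking_to_frame(rows2).to_string(index=False))
# total_dead_bases is the summed coding length (bp) each term's genes hide in
# dead zones; terms at the top are the phenotypes long reads help most.
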