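# Methods

This note documents the models behind each module, the defaults and why they
were chosen, what the synthetic generators do and do not emulate, and the
numerical conventions. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Coordinates

All internal coordinates are 0-based half-open (BED convention); GFF3, VCF
and human-readable `chrom:start-end` strings are converted on read. Printed
region strings are interpreted as 1-based fully closed (UCSC style), so a
printed range `chr16:33,148,000-33,328,000` spans 180,001 bp; kb reporting
rounds half up, giving 180 kb under either the closed or half-open reading —
published coordinate strings rarely state their convention, so we pick one,
document it, and note that the headline kb figure is insensitive to the
choice. Interval set operations (merge, intersect, subtract) are exact
per-base operations; touching intervals merge because half-open ranges with
`end == next.start` have no gap. All of them are validated against
brute-force boolean-mask oracles on ≤10 kb contigs in the test suite.

## Dead-zone calling

Per sample, depth at a base counts reads with MAPQ ≥ `mapq_min` whose
aligned span covers the base (deletions covered, insertions ignored,
soft-clips excluded — conventional depth semantics). A base is **dead** when

    #{samples with depth < min_depth} / n_samples ≥ min_sample_fraction

and dead bases merge into zones, dropping zones shorter than `min_length`.
Defaults: `mapq_min 20, min_depth 5, min_sample_fraction 0.9, min_length 50`.
These are deliberately conservative, fully configurable values — clinical
dead-zone catalogs in the literature do not print transferable thresholds,
and the right numbers depend on platform and cohort depth — and every
`DeadZoneSet` records the parameters and cohort size it was called with.
No gap-bridging is applied by default (`merge_gap 0`) so the call is exactly
invertible against the per-base definition. Per-sample mean-coverage
normalization is **not** applied; cohorts are assumed depth-comparable.
This is a documented limitation: with heterogeneous cohorts a shallow sample
inflates the failing fraction everywhere.

The calling rule is monotone by construction — dead bases grow with
`min_depth`, shrink with `min_sample_fraction`, and never shrink as
`mapq_min` rises (raising the cutoff can only lower depth) — and the tests
assert all three per base on random cohorts.

Coverage accounting: `deadzone_coverage_fraction` is intersect length over
total zone length (1.0 for empty zones, by convention: nothing is left
uncovered); `uncallable_residual` is the merged set difference, and
`length(residual) = (1 − fraction) × total` holds to 1 bp of rounding.

## Phenotype ranking

Per gene, `dead_coding_bases = |zones ∩ coding exons|` with overlapping CDS
records merged so a base counts once per gene. Per HPO term,
`total_dead_bases` sums member genes' loads; a gene's bases count once per
term it is annotated to (terms are not mutually exclusive, so totals compare
across terms but do not sum to a genome-wide quantity). No propagation to
ontology ancestors is performed — aggregation is over the direct
gene-to-phenotype annotations only. Genes with no annotation simply
contribute to no term. Ranking sorts by total descending with lexicographic
term-id tie-break for determinism.

Dominant-gene handling is deliberately two-stage: `flag_dominant_genes`
*proposes* genes contributing ≥ `dominance_fraction` (default 0.5) of some
positive term total, and `rank_phenotypes` takes an explicit exclusion list.
Very large genes (TTN, NEB, the SMN1/2 pair) dominate every term they touch
by length alone; keeping the removal explicit and auditable mirrors how it
is done in practice (by inspection) instead of hiding a heuristic inside the
ranking.

## Variant concordance

Normalization trims shared suffix then prefix bases (always keeping one base
per allele) and, when a reference window is supplied, left-aligns indels by
the standard iterated-shift rule; the result is idempotent and is tested
against an exhaustive enumeration of equivalent placements. Matching is
exact on (chrom, pos, ref, alt) after splitting multi-allelic rows; genotype
agreement is not required (no genotype-level accounting is defined here).
Both `shared/|A∪B|` and `shared/|A|` are reported: published concordance
percentages do not always state their denominator, and the two conventions
differ exactly when exclusive calls exist. The union convention is the
package's headline number and the one the tests pin. Fractions of an empty
class are NaN rather than 0 — absence of indels is not perfect indel
concordance. `stratify_by_regions` returns None for an empty variant list
(0/0 is undefined, not zero).

## Methylation and imprinting

A read counts methylated at a CpG when its reported methylation probability
is ≥ `prob_threshold` (default 0.5). Unassigned-haplotype reads are dropped,
not redistributed: the analysis is defined on phased reads. Sites need
`min_reads_per_site` (default 5) on *both* haplotypes to be informative; a
locus needs `min_sites` (default 5) informative sites. Per-haplotype locus
means are unweighted across sites — robustness to coverage spikes at single
CpGs beats read-count weighting here. Classification: both means ≥
`hyper_threshold` (0.75) → biallelic hypermethylation (the
uniparental-disomy / imprinting-defect signature); both ≤ `hypo_threshold`
(0.25) → biallelic hypomethylation; one above and one below → monoallelic
(normal imprinted state); anything else indeterminate. The thresholds are
explicit numeric stand-ins for what is often a visual call in practice; at
HiFi-typical depth (≥10–15 phased reads per site per haplotype) they leave
wide margins, and the suite shows ≥99% recovery of planted status over
1,000 replicates at 20 sites × 15 reads/haplotype with 5% per-read flip
noise.

## Force calling and stop-loss annotation

Force calling admits every mapped read into the pileup, MAPQ 0 included,
and emits a substitution call at each base where a non-reference base has
count ≥ `min_alt_reads` (3) and pileup fraction ≥ `min_alt_fraction` (0.2).
Each call carries its alt support with MAPQ ≥ `mapq_confident` (20); when
that confident fraction is below `confident_support_min` (0.5) the call is
flagged **ambiguous**. The flag marks mapping ambiguity only — the suite
demonstrates that a variant planted on the pseudogene and a variant planted
on the gene produce byte-identical ambiguous apparent-het signatures at the
gene locus, which is precisely why such calls need orthogonal confirmation.
This caller is a transparent pileup-counting stand-in for production force
callers built on haplotype models; it is not one. Alignments are modeled as
gapless matches: sufficient for the dead-zone SNV mechanism, and indel force
calling is explicitly out of scope.

Stop-loss annotation mutates the reference stop codon, translates it by the
standard genetic code (stop codons TAA/TAG/TGA only), and scans downstream
codons in frame for the first new stop; `ext_codons` is its 1-based index.
Formatting follows the HGVS-protein extension style `p.X{N}{aa}ext{M}`, with
`ext*` when no downstream stop exists in the provided sequence and `p.X{N}=`
for a stop-to-stop (synonymous) change. The scan is verified against a
full-frame translation oracle on 200 random sequences.

## Synthetic data: what it emulates, and what it does not

Generators are pure functions of (parameters, seed); identical seeds give
byte-identical outputs.

**Gene + pseudogene contig.** Defaults: 3,000 bp copies at 99% identity with
1,000 bp unique flanks — the ">99% homology" regime in which pseudogenes
shadow their parent genes. The number of engineered differences is exact
(`round((1−identity)·length)`), so realized identity matches the request.
One contiguous 40% core of the copy carries no differences, with the
differences spread evenly over the remainder: real pseudogene divergence is
clustered, and a long identical stretch is what actually produces a dead
zone (with differences spaced evenly at 1 per 100 bp, every 100 bp read
would overlap one and nothing would be dead). The mapper is idealized: a
read gets MAPQ 0 exactly when its span lies inside a copy and contains no
engineered difference, and such reads are placed on either copy with equal
probability. Planted sample variants deliberately do not count as
distinguishing positions — an aligner cannot tell a sample variant from a
paralog difference. This idealization makes dead-zone truth exact and
computable (`expected_dead_zone(read_length)`), at the cost of realism: no
base-quality structure, no partial-identity MAPQ gradations, no indel
divergence. Passing tests therefore demonstrate the *logic* of dead-zone
calling and paralog ambiguity, not performance under a real aligner's
behavior. Short reads default to 100 bp at 30× (typical clinical WGS
scale); long reads default to copy length + 1,000 bp so every read spans a
diagnostic flank, at 12×, with deterministic anchor reads guaranteeing span
coverage of the contig even at low requested depth.

**Cohorts.** Default 8–10 samples in tests (a real cohort of hundreds is
desk-scaled down; the calling rule is per-base and sample-count enters only
through the failing fraction, so small cohorts exercise the same logic).

**Variant pairs.** Planted shared/exclusive counts at collision-free
positions; per class the counts are exact by construction, so recovery tests
are exact. The headline constructions (9,960/20/20 SNVs → 99.6% of the
union shared; 9,690/155/155 indels → 96.9%) mirror the concordance regime
of matched short-/long-read call sets on the same genomes.

**Methylation.** Per-read states are Bernoulli draws at 1−ε or ε per
haplotype (ε = 0.05 default, the per-read flip noise); reported
probabilities are drawn uniformly in [0.75, 1] or [0, 0.25]. Sites are
independent — no spatial correlation along the locus, no partially
methylated boundary CpGs.

**HPO fixture.** Planted per-gene loads are realized exactly by carving the
dead zone from each gene's single coding exon; the truth ranking is an
independent direct summation over the planted loads.

## Problem sizes

The test suite and acceptance script run at desk scale by design: 9 kb
contigs, 8-sample cohorts, 10,000-variant call sets, 20-site loci, 300–1,000
replicates for recovery rates. Cohort-scale quantities that require hundreds
of protected human genomes (genome-wide dead-zone catalogs, per-genome extra
variant counts) are out of scope and not reported.

## Known limitations

- No per-sample coverage normalization or GC correction in dead-zone calling.
- Sex chromosomes are not treated specially (ploidy-aware thresholds would
  be needed for chrX/chrY cohorts of mixed sex).
- The force caller handles substitutions only and models no base qualities.
- HPO aggregation does not use the ontology graph; terms are independent
  labels here.
- The idealized mapper makes dead zones binary; real MAPQ distributions
  produce graded boundaries that the boundary-slack tests only approximate.
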