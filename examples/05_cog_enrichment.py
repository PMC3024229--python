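"""Test whether duplicated genes are enriched in particular COG categories.

Tallies COG functional classes for the duplicated genes and for the whole
genome, then runs a chi-square goodness-of-fit test of the duplicated-gene
distribution against the genome-wide proportions (the null hypothesis is that
duplications sample functions uniformly from the genome).
"""

from dupcensus import SimConfig, all_vs_all, build_families, call_duplicate_pairs, simulate_cohort
from dupcensus.cog_stats import bin_divergence, chisq_gof, find_cog_clusters, tally_cogs

cohort = simulate_cohort(SimConfig(n_families=40, master_seed=2))
hits = all_vs_all(cohort.focal)
families, _ = build_families(hits)
pairs = call_duplicate_pairs(families, cohort.focal)
dup_genes = [g for p in pairs for g in (p.gene_a, p.gene_b)]

genome = tally_cogs(cohort.focal.genes, "general")
dups = tally_cogs(dup_genes, "general")
gof = chisq_gof(dups, {c: n / genome.total for c, n in genome.counts.items()})

print(f"general COG tallies (duplicated genes): {dups.counts}")
print(f"chi-square = {gof.chi2:.3f}, df = {gof.df}, p = {gof.p:.3f}")
print("(p < 0.05 would reject 'duplications mirror the genome distribution')")

bins = bin_divergence(pairs)
print("divergence histogram:", {k: v for k, v in bins.items() if v})
clusters = find_cog_clusters(dup_genes, window=100_000, min_count=3)
print(f"same-COG positional clusters (100 kb windows, >=3 genes): {len(clusters)}")
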