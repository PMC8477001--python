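"""Snowball clustering and genomic annotation of poly(A) sites.

Read 3' ends scatter around true cleavage positions; the snowball rule
repeatedly seeds a cluster at the highest-count position and absorbs
everything within +/-24 nt.  Clusters are then categorized (TTS, 3'UTR,
exon, intron, intergenic) and matched to a known-site database.
"""

from apa3t import (
    SimConfig,
    annotate_clusters,
    cluster_read_ends,
    filter_read_ends,
    generate_genome,
    generate_reads,
    summarize_pas_per_gene,
)

config = SimConfig(n_genes=60, reads_per_gene=120.0, n_priming_traps=6, seed=5)
genome, genes, known_db, truth = generate_genome(config)
reads = generate_reads(genome, genes, truth, config)
all_reads = [r for sample in reads.values() for r in sample]

kept, removed = filter_read_ends(all_reads, genome)
clusters = annotate_clusters(
    cluster_read_ends(kept, window=24, min_cluster_reads=5), genes, known_db
)

n_true = sum(len(g.pas_positions) for g in truth.genes.values())
print(f"{len(all_reads)} reads -> {sum(removed.values())} filtered as "
      f"internal priming -> {len(clusters)} clusters ({n_true} true sites)")
by_cat = {}
for c in clusters:
    by_cat[c.category] = by_cat.get(c.category, 0) + 1
print("cluster categories:", dict(sorted(by_cat.items())))
print(f"known sites matched: {sum(c.known for c in clusters)} "
      f"(database holds {len(known_db)})")

per_gene, hist = summarize_pas_per_gene(clusters)
print("genes by detected PAS count:", hist)
print("\nWith low jitter and spaced true sites, cluster representatives")
print("recover the planted poly(A) sites nearly one-to-one.")
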