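"""Generate a synthetic two-condition 3'-end sequencing study.

Builds a small genome with non-overlapping genes, 1-4 true poly(A) sites
per gene, planted 3'UTR shortening/lengthening shifts and internal-priming
traps, then samples per-replicate reads.  All files land in sim_demo/,
together with a ready-to-run pipeline config.
"""

from apa3t import SimConfig, simulate

config = SimConfig(
    n_genes=100,
    reads_per_gene=150.0,
    frac_shifted_genes=0.2,        # 20% of genes change site usage
    frac_shortened_among_shifted=0.85,
    n_priming_traps=10,
    seed=42,
)
out = simulate(config, "sim_demo")

print(f"genome:        {out.genome_fa}")
print(f"gene models:   {out.genes_bed} + {out.genes_tsv}")
print(f"known PAS db:  {out.known_pas_bed}")
print(f"ground truth:  {out.truth_tsv}")
for sample, path in out.read_files.items():
    print(f"reads {sample:<13}{path}")
print()
print("Each reads/*.bed line is one read's strand-aware 3'-end position;")
print("truth.tsv records every gene's true sites, usage fractions and")
print("shift class, so downstream calls can be scored exactly.")
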