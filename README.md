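# apa3t — alternative polyadenylation from 3′-end sequencing reads

Most human genes carry several poly(A) sites (PAS) in their last exon, so
the same gene can produce mRNA isoforms with short or long 3′UTRs.
Because 3′UTRs harbor miRNA and RBP binding sites, a global shift toward
proximal PAS usage — 3′UTR *shortening*, a hallmark of proliferating and
cancer cells and of cleavage-factor (CFIm/CPSF6) depletion — changes how
strongly genes are post-transcriptionally repressed.

`apa3t` is a Python library (plus a thin CLI) that turns mapped 3′-end
sequencing reads — protocols in which each read's 3′ end marks a cleavage
site — into per-gene 3′UTR shortening/lengthening calls between two
conditions. It is aimed at computational biologists who have per-sample
alignments (SAM/BAM) or read 3′-end BED files, gene models, and optionally
a known-PAS database, and who want a tested, deterministic pipeline with a
fully ground-truthed simulator for validation.

## Method

For each read the strand-aware 3′-most aligned base is a candidate
cleavage position. The pipeline then applies:

1. **Internal-priming filter.** Oligo(dT) priming on genomic A stretches
   creates false pile-ups. A read end is discarded iff the 20-nt genomic
   window strictly downstream (transcript orientation) contains **more
   than 12 A's** or a run of **≥ 8 consecutive A's**.
2. **Snowball clustering.** Per (chromosome, strand), the position with
   the highest remaining read count seeds a cluster (ties → leftmost),
   absorbs all positions within ±24 nt, and the process repeats; clusters
   with < 5 reads are dropped. The result is order-independent and
   partitions the kept reads.
3. **Annotation.** Each cluster is categorized with precedence
   TTS > 3′UTR > exon > intron > intergenic (TTS = within 100 nt of an
   annotated transcription terminal site) and matched against a known-PAS
   database within ±24 nt.
4. **Per-gene testing.** For every gene with ≥ 2 UTR-type clusters,
   ordered proximal→distal by distance *dᵢ* from the stop codon:
   - **CULI** (3′UTR length index):
     `CULI = Σᵢ uᵢᵗ·dᵢ/d_max − Σᵢ uᵢᶜ·dᵢ/d_max`, where `uᵢᵗ`, `uᵢᶜ` are the
     treated/control usage fractions of PAS *i*. CULI ∈ [−1, 1]; negative
     = shortened in the treated condition, positive = lengthened.
   - **Cochran–Armitage linear trend test** on the 2 × k condition-by-PAS
     count table with rank scores 1…k; for tables with ≤ 200 reads the
     p-value is the exact conditional tail of the score statistic
     (dynamic-programming enumeration over all tables with the observed
     margins), otherwise the asymptotic normal reference.
   - **Benjamini–Hochberg FDR** across genes; a gene is called
     *shortened* iff q < 0.05 and CULI < 0, *lengthened* iff q < 0.05 and
     CULI > 0.
   - Optionally, the **dPAS/pPAS ratio** (most-distal over most-proximal
     isoform reads, +0.5 continuity correction on zeros) and its
     treated/control fold change.

The package also ships a synthetic-data generator that emulates the
statistical structure of such libraries — Poisson per-gene depths,
multinomial PAS choice, Gaussian positional jitter, planted usage shifts
and planted A-rich internal-priming traps — with a complete ground-truth
table, so every stage can be scored exactly.

## Worked example

`examples/04_call_apa_shifts.py` runs the default synthetic study
(300 genes, 20% with planted shifts moving proximal usage 0.3 → 0.8, 85%
of shifts shortened, ~200 reads/gene, 2 replicates per condition) end to
end and prints:

```
genes tested: 224
altered 3'UTRs (q < 0.05): 63
  shortened: 53  lengthened: 10  (84.1% shortened)
sensitivity for planted shifts: 1.000
empirical FDR: 0.048

strongest shift: g0214 (CULI +0.362, q 1.97e-58, lengthened)
distal/proximal isoform ratio control 0.22 vs knockdown 3.04 (fold change 14.07)
```

224 of 300 genes have ≥ 2 detected UTR-type PAS and are testable; all 60
planted shifts are recovered at q < 0.05 with 3 false positives (empirical
FDR 0.048), and the shortened fraction among calls (84.1%) matches the
planted 85%. The other scripts in `examples/` demonstrate the simulator,
the internal-priming filter, and clustering/annotation individually;
`examples/05_cli_pipeline.sh` shows the same flow through the CLI:

```bash
apa3t simulate --seed 1 -o sim/        # synthetic study + config.json
apa3t run -c sim/config.json           # filter -> cluster -> test
apa3t report sim/run                   # summary tables
```

Each run writes `clusters.bed`, `clusters.tsv`, `results.tsv` (gene_id,
n_pas, culi, trend_stat, p, q, call), `summary.json` with per-stage read
accounting, and `run.log`. Reruns with the same config are byte-identical
(the log's wall-clock timings aside).

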