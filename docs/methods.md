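# Methods

## Scope and data model

`apa3t` analyses 3′-end sequencing libraries in which each read's 3′-most
aligned base marks a candidate cleavage/polyadenylation position. The
pipeline compares exactly two conditions (each with one or more replicate
libraries) and reports, per gene, whether poly(A)-site usage shifted
toward proximal sites (3′UTR shortening) or distal sites (lengthening).
Read mapping is out of scope: inputs are alignments (SAM/BAM; primary,
mapped records only — secondary and supplementary alignments are skipped
and counted) or pre-extracted 3′-end BED files. Duplicate reads are not
collapsed; all counts are read counts.

All internal coordinates are 0-based, half-open, on the forward reference
strand; conversions happen only at format boundaries. For a minus-strand
gene the transcription terminal site (TTS) is the interval start and the
3′UTR precedes the stop codon in reference coordinates.

## Internal-priming filter

Oligo(dT)-primed protocols produce artifactual pile-ups where the primer
anneals to genomic A stretches instead of a poly(A) tail. A read end at
position *p* is removed when the 20-nt window strictly downstream of *p*
in transcript orientation (plus strand: *p*+1…*p*+20 read as-is; minus
strand: the 20 reference bases 5′ of *p*, reverse-complemented) contains
more than 12 'A' characters or a run of at least 8 consecutive 'A's.
Matching is case-insensitive; 'N' never counts as an A; at a chromosome
edge only the available bases are examined. "Downstream" is read as
strictly after the mapped position — the mapped base itself is not part
of the window. Window length and both thresholds are configurable
(`--ip-window`, `--ip-max-a`, `--ip-run-a`).

## Snowball clustering

Cleavage is heterogeneous over a few nucleotides, so read ends are grouped
per (chromosome, strand) by a greedy seed-and-accrete rule: the position
with the highest remaining read count becomes a cluster seed (ties broken
to the leftmost coordinate), absorbs every position within ± `window` nt
(default 24), and the procedure repeats on the remainder. Clusters are
therefore disjoint position sets that partition the kept reads, and the
outcome depends only on aggregate counts and coordinates, never on input
order. Clusters with fewer than `min_cluster_reads` total reads (default
5; 0 disables) are discarded but still tracked in the run accounting so
that reads in = reads filtered + reads in kept clusters + reads in
discarded clusters holds exactly. The cluster representative is the seed,
i.e. the modal read end.

The greedy highest-count formulation is this package's own concrete
definition of seed-and-accrete ("snowball") clustering; the window is a
free parameter, and the default of 24 nt reflects typical cleavage-site
micro-heterogeneity.

## Annotation

Each cluster's representative position is assigned one exclusive category
with precedence **TTS > 3′UTR > exon > intron > intergenic**, matching
only same-strand gene models: TTS means within `tts_window` nt (default
100) of an annotated TTS; 3′UTR means inside the annotated 3′UTR
interval. Because a TTS neighbourhood usually lies inside a 3′UTR, the
exclusive categories are supplemented by non-exclusive overlap flags
(`hits_tts`, `hits_utr3`) so reports can show both a partition and the
overlapping percentages. A cluster is "known" when a same-strand database
site lies within `match_tolerance` nt (default 24).

## Per-gene testing

Genes with ≥ 2 UTR-type (TTS or 3′UTR) clusters are testable. Clusters
are ordered by strand-aware distance from the stop codon,
*d* = rep − stop (plus) or stop − rep (minus); clusters at non-positive
distance or on the antisense strand are dropped with a warning.
Replicates are summed into one row per condition for testing; the
replicate-level vectors are retained on the profile for per-replicate
designs.

**CULI.** For a condition with usage fractions *uᵢ* over sites at
distances *dᵢ* (normalised by *d*ₘₐₓ, the gene's most distal site), the
usage-weighted normalised 3′UTR length is L = Σᵢ uᵢ·dᵢ/d_max, and
CULI = L(treated) − L(control). The index is dimensionless, bounded by
|CULI| ≤ 1 − d_min/d_max ≤ 1, exactly antisymmetric under swapping the
condition labels, zero for identical usage, and signed so that negative
values mean proximal-ward shifts (shortening) in the treated condition.
This usage-weighted-length difference is this package's concrete
definition of a 3′UTR length index; its sign convention is the one
standard in the APA literature. It is undefined (gene skipped, logged)
when either condition has zero reads.

**Linear trend test.** The 2 × k condition-by-ordered-site table is
tested with the Cochran–Armitage statistic using rank scores 1…k:
T = Σⱼ sⱼ·n₂ⱼ, standardised by its conditional (both-margins-fixed) mean
and variance with the N−1 finite-population factor. All-zero site columns
are dropped and scores re-ranked; a table collapsing to one informative
column, or with an empty condition row, is untestable (NaN, gene
excluded). For tables with total count ≤ 200 the two-sided p-value is
exact: a dynamic program over columns enumerates the conditional null
distribution of T across all tables with the observed margins (each
weighted by ∏ⱼ C(cⱼ, xⱼ)), and the p-value is the total probability of
tables at least as far from E[T] as observed. Tail membership uses an
absolute slack of 1e−8; distinct |T − E| values for a table with total N
are multiples of 1/N ≥ 1/200 apart, so the slack only serves to make
exact ties robust to floating-point rounding. For 2 × 2 tables this
reduces to the two-sided central hypergeometric tail. Above 200 the
standard-normal reference is used; the two branches agree closely at the
boundary (monitored by test).

**FDR and calls.** P-values are adjusted across genes with the
Benjamini–Hochberg step-up procedure (via
`statsmodels.stats.multitest.multipletests`). A gene is called
*shortened* iff q < α and CULI < 0, *lengthened* iff q < α and CULI > 0,
otherwise *unchanged*; α defaults to 0.05.

**dPAS/pPAS ratio.** Per condition, reads at the most distal site over
reads at the most proximal site; when either count is zero, 0.5 is added
to both terms (so 0 proximal / 10 distal gives 10.5/0.5 = 21). The fold
change is the treated ratio over the control ratio.

## Synthetic-data generator

The generator emulates the statistical structure of a two-condition
3′-end study and is itself first-class, tested code. Defaults define the
reference study: 300 genes, 2 replicates per condition, ~200 reads per
gene per library (Poisson), 1–4 true poly(A) sites per gene with
probabilities (0.25, 0.45, 0.20, 0.10) — so ~30% of genes carry three or
more sites — 20% of genes shifted, 85% of shifts shortened, proximal
usage moving 0.3 → 0.8, 40% of true sites present in the known-site
database, rounded-Gaussian positional jitter with sd 3 nt, 30 genes with
an internal-priming trap at which 5% of that gene's reads terminate.

Construction guarantees worth knowing:

* **Background sequence can never trigger the priming filter.** Bases are
  drawn so that no 20-nt window accumulates more than 12 A's (or T's, for
  the minus strand) and no A/T run reaches 8. The only filter-positive
  windows are the planted traps (a 15-base sense-strand A run), so the
  filter's behaviour on simulated data is exactly attributable.
* **True sites never merge.** Minimum spacing between a gene's sites
  (default 100 nt) must exceed the clustering window, and gene bodies are
  separated by ≥ 300 nt intergenic gaps on an auto-sized genome (a
  user-capped genome length raises a sizing error if genes cannot be
  placed without overlap).
* **Traps sit away from true sites.** Each trap is centred in the gene's
  widest inter-site gap, at least 34 nt upstream / 30 nt downstream of
  the flanking sites, so jittered true reads (|jitter| ≤ ~4 sd) cannot
  enter a trap's detection zone and artifact reads cannot join a true
  cluster. Artifact read ends are placed exactly at the trap position.
* **Shifts only on multi-site genes**; a request for more shifted genes
  than multi-site genes raises an error. For k sites the usage vector
  gives the proximal site its configured fraction and splits the rest
  evenly; a "shortened" gene uses (baseline → shifted) proximal usage
  from control to treated, a "lengthened" gene the mirror image. The
  ground-truth writer validates that usage sums to one and that each
  shift class is consistent with its usage change.
* **Jitter is applied along the transcript axis** (sign flipped on the
  minus strand) and rounded; positions are clipped to chromosome bounds.
* **Determinism**: one integer seed drives separate generator streams for
  genome construction and read sampling; identical seeds give
  byte-identical output files (sorted writers, fixed float formats).

What the generator does **not** emulate: sequencing errors, mappability,
expression-level differences between conditions (only usage shifts),
overlapping genes, multi-exon 3′UTRs, or jitter distributions with heavy
tails. Passing the end-to-end recovery tests therefore demonstrates the
pipeline's correctness under its own model assumptions — clean site
spacing and modest jitter — not performance on real libraries, where
closely spaced sites, antisense transcription and expression confounding
add difficulty.

## Numerical and design choices

* Trend-test exact/asymptotic crossover at 200 total reads: the DP is
  exact but O(k·N·T) per gene; 200 keeps the exact branch instantaneous
  while covering the regime where the normal approximation is weakest.
* BH rather than any other FDR procedure: the standard step-up adjustment
  for independent-ish gene-level tests.
* The pipeline clusters all samples pooled (per-sample counts retained on
  each cluster) so both conditions see the same site definitions.
* Null calibration of the trend test (acceptance suite and
  `scripts/acceptance.py`) simulates 1,000 null genes, each with one
  shared usage vector applied to both condition rows of 200 reads;
  usage vectors alternate two- and three-site genes with proximal usage
  uniform in [0.2, 0.8]. Observed type-I error at nominal 0.05 must fall
  in [0.037, 0.063].
* Problem sizes in the test and acceptance runs (tens to hundreds of
  genes, ~10⁵ reads) are desk-scale choices that finish in seconds while
  leaving every statistical check well-powered.
* Reruns with an identical configuration are byte-identical for all
  result artifacts; `run.log` records wall-clock stage timings and is
  excluded from that contract.

## Known limitations

* The category precedence makes TTS and 3′UTR mutually exclusive even
  though a TTS-proximal cluster is also in the 3′UTR; use the overlap
  flags when comparing against overlapping-percentage conventions.
* With more than two conditions the design must be decomposed into
  pairwise runs; the config validator enforces exactly two.
* `min_cluster_reads` interacts with depth: at very low coverage real
  distal sites fall below the threshold and genes silently become
  untestable (they are logged and counted in the summary).
* The exact trend p-value conditions on both margins; with very uneven
  replicate depths the summed-row conditioning is a simplification of a
  replicate-aware model.
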