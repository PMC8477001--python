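"""Poly(A)-site discovery from read 3'-end positions.

Three stages, mirroring how 3'-end sequencing data is usually cleaned up:

1.  **Internal-priming filter.**  Oligo(dT) priming on genomic A-rich
    stretches produces read pile-ups that look like cleavage sites but are
    artifacts.  A read 3' end is flagged when the 20-nt genomic window
    strictly downstream of it (in transcript orientation) contains more
    than 12 'A's in total or a run of at least 8 consecutive 'A's.

2.  **Snowball clustering.**  Surviving 3'-end positions on the same
    chromosome and strand are grouped by a greedy seed-and-accrete rule:
    the position with the highest remaining read count seeds a cluster
    (ties broken to the leftmost coordinate), absorbs every position within
    a fixed window on either side, and the process repeats on what is
    left.  Clusters below a minimum read count are discarded.

3.  **Annotation.**  Each cluster's representative position is assigned a
    genomic category with precedence TTS > 3'UTR > exon > intron >
    intergenic, and matched against a database of known poly(A) sites.
"""

from __future__ import annotations

import bisect
import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import GeneModel, Genome, ReadEnd, revcomp

logger = logging.getLogger(__name__)

IP_WINDOW = 20       # nt scanned downstream of the mapped 3' end
IP_MAX_A = 12        # more than this many A's in the window flags the read
IP_RUN_A = 8         # a run this long (or longer) flags the read
CLUSTER_WINDOW = 24  # nt absorbed on either side of a cluster seed
MIN_CLUSTER_READS = 5
TTS_WINDOW = 100     # nt around an annotated TTS that still counts as TTS
MATCH_TOLERANCE = 24  # nt tolerance when matching the known-PAS database

CATEGORIES = ("TTS", "UTR3", "exon", "intron", "intergenic")


@dataclass
class PASCluster:
    """A clustered poly(A) site.

    ``rep_pos`` is the seed position (the modal read 3' end); ``span`` is the
    half-open interval covering all member positions.  ``counts`` maps
    sample id to the number of member reads from that sample.
    """

    chrom: str
    strand: str
    rep_pos: int
    span: tuple[int, int]
    counts: dict[str, int]
    category: str | None = None
    known: bool | None = None
    gene_id: str | None = None
    hits_tts: bool = False   # within tts_window of some TTS (non-exclusive)
    hits_utr3: bool = False  # inside some annotated 3'UTR (non-exclusive)

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def is_internal_priming(
    genome: Genome,
    chrom: str,
    strand: str,
    pos: int,
    *,
    window: int = IP_WINDOW,
    max_a: int = IP_MAX_A,
    run_a: int = IP_RUN_A,
) -> bool:
    """Apply the A-rich downstream-window rule to one read 3' end.

    The window is the ``window`` bases strictly downstream of ``pos`` in
    transcript orientation: on the plus strand positions pos+1..pos+window
    read as-is, on the minus strand the ``window`` reference bases 5' of
    ``pos``, reverse-complemented.  At a chromosome edge only the available
    bases are examined.  'N' never counts as an A.
    """
    n = genome.length(chrom)
    if strand == "+":
        seq = genome.fetch(chrom, min(pos + 1, n), min(pos + 1 + window, n))
    else:
        seq = revcomp(genome.fetch(chrom, max(pos - window, 0), max(pos, 0)))
    seq = seq.upper()
    return seq.count("A") > max_a or "A" * run_a in seq


def filter_read_ends(
    reads: Iterable[ReadEnd],
    genome: Genome,
    *,
    window: int = IP_WINDOW,
    max_a: int = IP_MAX_A,
    run_a: int = IP_RUN_A,
) -> tuple[list[ReadEnd], dict[str, int]]:
    """Remove internal-priming reads; report removed counts per sample."""
    kept: list[ReadEnd] = []
    removed: dict[str, int] = defaultdict(int)
    # distinct (chrom, strand, pos) triples are few relative to reads
    cache: dict[tuple[str, str, int], bool] = {}
    for r in reads:
        key = (r.chrom, r.strand, r.pos)
        hit = cache.get(key)
        if hit is None:
            hit = is_internal_priming(
                genome, r.chrom, r.strand, r.pos,
                window=window, max_a=max_a, run_a=run_a,
            )
            cache[key] = hit
        if hit:
            removed[r.sample_id] += 1
        else:
            kept.append(r)
    return kept, dict(removed)


def cluster_read_ends(
    reads: Iterable[ReadEnd],
    *,
    window: int = CLUSTER_WINDOW,
    min_cluster_reads: int = MIN_CLUSTER_READS,
) -> list[PASCluster]:
    """Greedy snowball clustering of read 3'-end positions.

    Operates per (chrom, strand); the result is independent of input order
    because seeds are chosen from aggregate counts (highest count, then
    leftmost coordinate) and clusters are disjoint position sets.  Clusters
    with fewer than ``min_cluster_reads`` total reads are dropped.
    """
    if window <= 0:
        raise ValueError(f"cluster window must be positive, got {window}")
    by_group: dict[tuple[str, str], dict[int, Counter]] = defaultdict(
        lambda: defaultdict(Counter)
    )
    for r in reads:
        by_group[(r.chrom, r.strand)][r.pos][r.sample_id] += 1

    clusters: list[PASCluster] = []
    for (chrom, strand), pos_counts in by_group.items():
        positions = np.array(sorted(pos_counts), dtype=np.int64)
        totals = np.array(
            [sum(pos_counts[p].values()) for p in positions], dtype=np.int64
        )
        remaining = totals.copy()
        while remaining.any():
            seed_idx = int(np.argmax(remaining))  # argmax → leftmost on ties
            seed = int(positions[seed_idx])
            lo = int(np.searchsorted(positions, seed - window, side="left"))
            hi = int(np.searchsorted(positions, seed + window, side="right"))
            member_idx = [i for i in range(lo, hi) if remaining[i] > 0]
            counts: Counter = Counter()
            for i in member_idx:
                counts.update(pos_counts[int(positions[i])])
            span = (int(positions[member_idx[0]]),
                    int(positions[member_idx[-1]]) + 1)
            remaining[member_idx] = 0
            clusters.append(
                PASCluster(chrom, strand, seed, span, dict(sorted(counts.items())))
            )
    clusters = [c for c in clusters if c.total >= min_cluster_reads]
    clusters.sort(key=lambda c: (c.chrom, c.span[0], c.strand))
    return clusters


def annotate_clusters(
    clusters: Sequence[PASCluster],
    gene_models: Sequence[GeneModel],
    known_pas: Sequence[tuple[str, int, str]] = (),
    *,
    tts_window: int = TTS_WINDOW,
    match_tolerance: int = MATCH_TOLERANCE,
) -> list[PASCluster]:
    """Assign genomic category, owning gene and known/novel status.

    Category precedence is TTS > UTR3 > exon > intron > intergenic so the
    exclusive categories partition the clusters; the non-exclusive
    ``hits_tts``/``hits_utr3`` flags record overlap with *any* same-strand
    TTS neighbourhood or 3'UTR regardless of precedence.  All matching is
    same-strand.
    """
    genes_by_group: dict[tuple[str, str], list[GeneModel]] = defaultdict(list)
    for g in gene_models:
        genes_by_group[(g.chrom, g.strand)].append(g)
    known_by_group: dict[tuple[str, str], list[int]] = defaultdict(list)
    for chrom, pos, strand in known_pas:
        known_by_group[(chrom, strand)].append(pos)
    for v in known_by_group.values():
        v.sort()

    out: list[PASCluster] = []
    for c in clusters:
        genes = genes_by_group.get((c.chrom, c.strand), [])
        category, gene_id = "intergenic", None
        hits_tts = hits_utr3 = False
        tts_gene = utr_gene = exon_gene = intron_gene = None
        tts_dist = None
        for g in genes:
            d = abs(c.rep_pos - g.tts_pos)
            if d <= tts_window:
                hits_tts = True
                if tts_dist is None or d < tts_dist:
                    tts_gene, tts_dist = g, d
            if g.utr3_interval[0] <= c.rep_pos < g.utr3_interval[1]:
                hits_utr3 = True
                if utr_gene is None:
                    utr_gene = g
            if exon_gene is None and any(
                a <= c.rep_pos < b for a, b in g.exons
            ):
                exon_gene = g
            if intron_gene is None and g.start <= c.rep_pos < g.end:
                intron_gene = g
        if tts_gene is not None:
            category, gene_id = "TTS", tts_gene.gene_id
        elif utr_gene is not None:
            category, gene_id = "UTR3", utr_gene.gene_id
        elif exon_gene is not None:
            category, gene_id = "exon", exon_gene.gene_id
        elif intron_gene is not None:
            category, gene_id = "intron", intron_gene.gene_id

        sites = known_by_group.get((c.chrom, c.strand), [])
        i = bisect.bisect_left(sites, c.rep_pos - match_tolerance)
        known = i < len(sites) and sites[i] <= c.rep_pos + match_tolerance

        out.append(
            replace(
                c,
                category=category,
                gene_id=gene_id,
                known=known,
                hits_tts=hits_tts,
                hits_utr3=hits_utr3,
            )
        )
    return out


def summarize_pas_per_gene(
    clusters: Sequence[PASCluster],
) -> tuple[pd.Series, dict[str, int]]:
    """Per-gene count of UTR-type (TTS or 3'UTR) clusters plus a histogram.

    Genes whose only clusters are exonic/intronic do not appear.  The
    histogram bins gene-level counts into 1, 2, 3 and "4+".
    """
    counts: Counter = Counter(
        c.gene_id
        for c in clusters
        if c.category in ("TTS", "UTR3") and c.gene_id is not None
    )
    per_gene = pd.Series(counts, dtype=int).sort_index()
    per_gene.index.name = "gene_id"
    per_gene.name = "n_pas"
    hist = {"1": 0, "2": 0, "3": 0, "4+": 0}
    for n in per_gene:
        hist["4+" if n >= 4 else str(n)] += 1
    return per_gene, hist


def clusters_to_frame(clusters: Sequence[PASCluster]) -> pd.DataFrame:
    """Flatten clusters into a table (one per-sample count column each)."""
    samples = sorted({s for c in clusters for s in c.counts})
    rows = []
    for c in clusters:
        row = {
            "chrom": c.chrom,
            "strand": c.strand,
            "rep_pos": c.rep_pos,
            "span_start": c.span[0],
            "span_end": c.span[1],
            "category": c.category,
            "known": c.known,
            "gene_id": c.gene_id if c.gene_id is not None else ".",
            "hits_tts": c.hits_tts,
            "hits_utr3": c.hits_utr3,
            "total": c.total,
        }
        for s in samples:
            row[f"count_{s}"] = c.counts.get(s, 0)
        rows.append(row)
    cols = [
        "chrom", "strand", "rep_pos", "span_start", "span_end", "category",
        "known", "gene_id", "hits_tts", "hits_utr3", "total",
    ] + [f"count_{s}" for s in samples]
    return pd.DataFrame(rows, columns=cols)
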