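"""Synthetic 3'-end sequencing study generator with ground truth.

Emulates the statistical structure of a two-condition 3'-end library
comparison (control vs. a cleavage-factor knockdown) at desk scale:

*   a small genome whose background sequence is constructed so that no
    20-nt window contains more than 12 A's (or T's, for the minus strand)
    or an 8-base homopolymer run — i.e. no *accidental* internal-priming
    signal exists;
*   non-overlapping single-exon genes on both strands, each with a CDS,
    an annotated 3'UTR and a transcription terminal site (TTS) that
    coincides with the gene's most distal true poly(A) site;
*   1-4 true poly(A) sites per gene (about 30% of genes get three or
    more), spaced far enough apart that distinct sites can never merge
    during downstream clustering;
*   a known-PAS database containing a stated fraction of the true sites;
*   deliberate internal-priming traps: A-rich stretches (a 15-base A run
    on the gene's sense strand) planted inside some 3'UTRs away from any
    true site, at which a stated fraction of that gene's reads terminate;
*   per-sample reads whose 3' ends sit at a true site plus rounded
    Gaussian jitter, with per-gene totals Poisson distributed and site
    choice multinomial in the condition's true usage fractions.

Planted APA shifts move usage between the proximal and the remaining
sites: a "shortened" gene uses the proximal site at the baseline fraction
in the control condition and at the elevated fraction in the knockdown;
a "lengthened" gene is the mirror image.  Expression *levels* do not
differ between conditions — only site usage does.

Everything is driven by one integer seed; the same seed yields
byte-identical output files.
"""

from __future__ import annotations

import json
import logging
from collections import deque
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .io import (
    GeneModel,
    Genome,
    ReadEnd,
    write_gene_models,
    write_pas_bed,
    write_read_ends_bed,
    write_read_ends_sam,
)

logger = logging.getLogger(__name__)

# geometry margins (nt, transcript coordinates)
_MIN_PROXIMAL_DIST = 60   # closest a proximal PAS may sit to the stop codon
_TRAP_RUN = 15            # length of the planted A run
_TRAP_UP_CLEAR = 34       # required gap, trap artifact position to upstream PAS
_TRAP_DOWN_CLEAR = 30     # required gap to the downstream PAS


class SimError(ValueError):
    """Raised when a configuration cannot be realised."""


@dataclass
class SimConfig:
    """Study conditions for the synthetic 3'-end experiment.

    ``pas_count_probs`` gives P(1), P(2), P(3), P(4) true poly(A) sites per
    gene.  Usage knobs are proximal-site fractions: an unshifted multi-site
    gene uses its proximal site at ``proximal_usage_baseline`` in both
    conditions; a shifted gene swaps between the baseline and
    ``proximal_usage_shifted`` (direction per its shift class).
    """

    n_genes: int = 300
    pas_count_probs: tuple[float, float, float, float] = (0.25, 0.45, 0.20, 0.10)
    utr_length_range: tuple[int, int] = (400, 1600)
    pas_spacing_min: int = 100
    frac_shifted_genes: float = 0.20
    frac_shortened_among_shifted: float = 0.85
    proximal_usage_baseline: float = 0.30
    proximal_usage_shifted: float = 0.80
    reads_per_gene: float = 200.0
    jitter_sd: float = 3.0
    n_priming_traps: int = 30
    internal_priming_rate: float = 0.05
    frac_known_pas: float = 0.40
    replicates_per_condition: int = 2
    seed: int = 0
    cds_length_range: tuple[int, int] = (200, 600)
    intergenic_gap: int = 300
    n_chroms: int = 2
    genome_length: int | None = None  # per-chromosome cap; None = auto-size
    conditions: tuple[str, str] = ("control", "knockdown")
    read_format: str = "bed"  # "bed" or "sam"

    def validate(self, cluster_window: int = 24) -> None:
        fracs = {
            "frac_shifted_genes": self.frac_shifted_genes,
            "frac_shortened_among_shifted": self.frac_shortened_among_shifted,
            "proximal_usage_baseline": self.proximal_usage_baseline,
            "proximal_usage_shifted": self.proximal_usage_shifted,
            "internal_priming_rate": self.internal_priming_rate,
            "frac_known_pas": self.frac_known_pas,
        }
        for name, v in fracs.items():
            if not 0.0 <= v <= 1.0:
                raise SimError(f"{name} must be in [0, 1], got {v}")
        if len(self.pas_count_probs) != 4 or min(self.pas_count_probs) < 0:
            raise SimError("pas_count_probs must be 4 non-negative weights")
        if abs(sum(self.pas_count_probs) - 1.0) > 1e-9:
            raise SimError("pas_count_probs must sum to 1")
        if self.pas_spacing_min <= cluster_window:
            raise SimError(
                f"pas_spacing_min ({self.pas_spacing_min}) must exceed the "
                f"clustering window ({cluster_window}) so distinct sites "
                "never merge"
            )
        if self.pas_spacing_min < _TRAP_UP_CLEAR + _TRAP_DOWN_CLEAR:
            raise SimError("pas_spacing_min too small to host priming traps")
        if self.n_genes < 1 or self.replicates_per_condition < 1:
            raise SimError("need at least one gene and one replicate")
        if self.n_priming_traps > self.n_genes:
            raise SimError("more priming traps than genes")
        if self.jitter_sd < 0 or self.reads_per_gene <= 0:
            raise SimError("jitter_sd must be >=0 and reads_per_gene > 0")
        max_k = max(k for k, p in zip((1, 2, 3, 4), self.pas_count_probs) if p > 0)
        needed = _MIN_PROXIMAL_DIST + max_k * self.pas_spacing_min
        if self.utr_length_range[1] < needed:
            raise SimError(
                f"utr_length_range upper bound must be >= {needed} nt to fit "
                f"{max_k} spaced poly(A) sites"
            )
        if self.read_format not in ("bed", "sam"):
            raise SimError(f"read_format must be 'bed' or 'sam'")
        if len(set(self.conditions)) != 2:
            raise SimError("exactly two distinct condition names required")


@dataclass
class GeneTruth:
    gene_id: str
    chrom: str
    strand: str
    pas_positions: tuple[int, ...]  # reference coords, proximal -> distal
    distances: tuple[int, ...]      # nt from stop codon, increasing
    usage: dict[str, tuple[float, ...]]  # condition -> usage fractions
    shift_class: str                # shortened | lengthened | unchanged
    trap_pos: int | None            # artifact read 3'-end position, if trapped


@dataclass
class GroundTruth:
    genes: dict[str, GeneTruth]
    conditions: tuple[str, str]
    known_pas: list[tuple[str, int, str]]
    artifact_counts: dict[str, int] = field(default_factory=dict)

    def validate(self) -> None:
        ctrl, treat = self.conditions
        for gt in self.genes.values():
            for cond, u in gt.usage.items():
                if abs(sum(u) - 1.0) > 1e-9:
                    raise SimError(f"{gt.gene_id}/{cond}: usage does not sum to 1")
            if len(gt.pas_positions) >= 2:
                delta = gt.usage[treat][0] - gt.usage[ctrl][0]
                expect = {"shortened": delta > 0, "lengthened": delta < 0,
                          "unchanged": delta == 0}[gt.shift_class]
                if not expect:
                    raise SimError(
                        f"{gt.gene_id}: class {gt.shift_class} inconsistent "
                        f"with proximal usage change {delta:+.3f}"
                    )

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(
                "gene_id\tchrom\tstrand\tshift_class\tpas_positions\t"
                "distances\tusage_%s\tusage_%s\ttrap_pos\n" % self.conditions
            )
            for gid in sorted(self.genes):
                gt = self.genes[gid]
                fh.write(
                    "\t".join(
                        [
                            gt.gene_id,
                            gt.chrom,
                            gt.strand,
                            gt.shift_class,
                            ",".join(map(str, gt.pas_positions)),
                            ",".join(map(str, gt.distances)),
                            ",".join(f"{u:.6g}" for u in gt.usage[self.conditions[0]]),
                            ",".join(f"{u:.6g}" for u in gt.usage[self.conditions[1]]),
                            str(gt.trap_pos) if gt.trap_pos is not None else ".",
                        ]
                    )
                    + "\n"
                )


def sample_names(config: SimConfig) -> dict[str, str]:
    """Deterministic sample -> condition map, e.g. control_1, knockdown_2."""
    return {
        f"{cond}_{i + 1}": cond
        for cond in config.conditions
        for i in range(config.replicates_per_condition)
    }


# ---------------------------------------------------------------------------
# genome + gene models + truth
# ---------------------------------------------------------------------------

def _constrained_sequence(rng: np.random.Generator, length: int) -> list[str]:
    """Random sequence in which no 20-nt window holds >12 A's (or T's) and
    no A/T run reaches 8 — so the internal-priming rule can never fire on
    background sequence, on either strand."""
    out: list[str] = []
    win: deque = deque()
    win_a = win_t = run_a = run_t = 0
    rand = rng.random(length)
    for i in range(length):
        choices = "ACGT"
        if win_a >= 12 or run_a >= 7:
            choices = choices.replace("A", "")
        if win_t >= 12 or run_t >= 7:
            choices = choices.replace("T", "")
        b = choices[int(rand[i] * len(choices))]
        out.append(b)
        run_a = run_a + 1 if b == "A" else 0
        run_t = run_t + 1 if b == "T" else 0
        win.append(b)
        win_a += b == "A"
        win_t += b == "T"
        if len(win) > 19:
            old = win.popleft()
            win_a -= old == "A"
            win_t -= old == "T"
    return out


def _spaced_values(
    rng: np.random.Generator, low: int, high: int, k: int, gap: int
) -> list[int]:
    """k sorted integers in [low, high] with pairwise differences >= gap."""
    span = high - low - (k - 1) * gap
    if span < 0:
        raise SimError(f"cannot place {k} values {gap} nt apart in [{low},{high}]")
    u = np.sort(rng.integers(0, span + 1, size=k))
    return [int(low + u[i] + i * gap) for i in range(k)]


def _usage_vector(k: int, proximal: float) -> tuple[float, ...]:
    if k == 1:
        return (1.0,)
    rest = (1.0 - proximal) / (k - 1)
    return (proximal,) + (rest,) * (k - 1)


def generate_genome(
    config: SimConfig,
) -> tuple[Genome, list[GeneModel], list[tuple[str, int, str]], GroundTruth]:
    """Build genome sequence, gene models, known-PAS database and truth.

    Gene placement, poly(A)-site geometry, shift-class assignment, the
    known-site subset and trap placement are all decided here; only read
    sampling is left to :func:`generate_reads`.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 0])
    ctrl, treat = config.conditions

    # per-gene geometry
    ks = rng.choice([1, 2, 3, 4], size=config.n_genes, p=config.pas_count_probs)
    strands = rng.choice(["+", "-"], size=config.n_genes)
    cds_lens = rng.integers(
        config.cds_length_range[0], config.cds_length_range[1] + 1,
        size=config.n_genes,
    )

    # shift classes: only multi-site genes can shift
    multi = [i for i in range(config.n_genes) if ks[i] >= 2]
    n_shift = round(config.frac_shifted_genes * config.n_genes)
    if n_shift > len(multi):
        raise SimError(
            f"{n_shift} shifted genes requested but only {len(multi)} genes "
            "have >=2 poly(A) sites"
        )
    shifted = rng.choice(multi, size=n_shift, replace=False)
    n_short = round(config.frac_shortened_among_shifted * n_shift)
    classes = {int(i): "unchanged" for i in range(config.n_genes)}
    for j, i in enumerate(shifted):
        classes[int(i)] = "shortened" if j < n_short else "lengthened"

    # trapped genes
    trap_genes = set(
        int(i) for i in rng.choice(config.n_genes, size=config.n_priming_traps,
                                   replace=False)
    ) if config.n_priming_traps else set()

    gap = config.intergenic_gap
    cursors = [gap] * config.n_chroms
    chrom_names = [f"chr{c + 1}" for c in range(config.n_chroms)]
    genes: list[GeneModel] = []
    truth_genes: dict[str, GeneTruth] = {}
    traps: list[tuple[int, str, int, int]] = []  # (chrom idx, strand, run start, run end)
    all_pas: list[tuple[str, int, str]] = []

    for i in range(config.n_genes):
        k = int(ks[i])
        strand = str(strands[i])
        cds_len = int(cds_lens[i])
        utr_lo = max(
            config.utr_length_range[0],
            _MIN_PROXIMAL_DIST + k * config.pas_spacing_min,
        )
        utr_len = int(rng.integers(utr_lo, config.utr_length_range[1] + 1))
        gene_id = f"g{i:04d}"
        ci = i % config.n_chroms
        chrom = chrom_names[ci]
        gstart = cursors[ci]
        glen = cds_len + utr_len
        cursors[ci] = gstart + glen + gap

        if strand == "+":
            stop = gstart + cds_len
            gend = stop + utr_len
            d_max = utr_len - 1
            tts = gend - 1
            utr3 = (stop, gend)
        else:
            stop = gstart + utr_len
            gend = stop + cds_len
            d_max = utr_len
            tts = gstart
            utr3 = (gstart, stop)

        if k == 1:
            distances = [d_max]
        else:
            inner = _spaced_values(
                rng, _MIN_PROXIMAL_DIST, d_max - config.pas_spacing_min,
                k - 1, config.pas_spacing_min,
            )
            distances = inner + [d_max]
        sign = 1 if strand == "+" else -1
        pas_positions = tuple(stop + sign * d for d in distances)

        trap_pos = None
        if i in trap_genes:
            gaps = list(zip([0] + distances[:-1], distances))
            lo, hi = max(gaps, key=lambda g: g[1] - g[0])
            d_t = (lo + hi) // 2
            if d_t - lo < _TRAP_UP_CLEAR or hi - d_t < _TRAP_DOWN_CLEAR:
                raise SimError(f"{gene_id}: no room for a priming trap")
            trap_pos = stop + sign * d_t
            if strand == "+":
                traps.append((ci, "+", trap_pos + 1, trap_pos + 1 + _TRAP_RUN))
            else:
                traps.append((ci, "-", trap_pos - _TRAP_RUN, trap_pos))

        cls = classes[i]
        p_base = config.proximal_usage_baseline
        p_shift = config.proximal_usage_shifted
        if k == 1:
            usage = {ctrl: (1.0,), treat: (1.0,)}
        elif cls == "shortened":
            usage = {ctrl: _usage_vector(k, p_base), treat: _usage_vector(k, p_shift)}
        elif cls == "lengthened":
            usage = {ctrl: _usage_vector(k, p_shift), treat: _usage_vector(k, p_base)}
        else:
            usage = {ctrl: _usage_vector(k, p_base), treat: _usage_vector(k, p_base)}

        genes.append(
            GeneModel(
                gene_id=gene_id,
                chrom=chrom,
                strand=strand,
                exons=((gstart, gend),),
                stop_codon_pos=stop,
                utr3_interval=utr3,
                tts_pos=tts,
            )
        )
        truth_genes[gene_id] = GeneTruth(
            gene_id, chrom, strand, pas_positions, tuple(distances),
            usage, cls, trap_pos,
        )
        all_pas.extend((chrom, p, strand) for p in pas_positions)

    # chromosome sequences
    lengths = [c for c in cursors]
    if config.genome_length is not None:
        if max(lengths) > config.genome_length:
            raise SimError(
                f"genome_length {config.genome_length} too short to place "
                f"{config.n_genes} genes without overlap "
                f"(need {max(lengths)} nt per chromosome)"
            )
        lengths = [config.genome_length] * config.n_chroms
    seqs = {
        name: _constrained_sequence(rng, n)
        for name, n in zip(chrom_names, lengths)
    }
    for ci, strand, a, b in traps:
        base = "A" if strand == "+" else "T"
        seq = seqs[chrom_names[ci]]
        seq[a:b] = [base] * (b - a)
    genome = Genome({name: "".join(seq) for name, seq in seqs.items()})

    # known-PAS database: a stated fraction of the true sites
    n_known = round(config.frac_known_pas * len(all_pas))
    known_idx = rng.choice(len(all_pas), size=n_known, replace=False)
    known = sorted(all_pas[int(j)] for j in known_idx)

    truth = GroundTruth(truth_genes, (ctrl, treat), known)
    truth.validate()
    return genome, genes, known, truth


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------

def generate_reads(
    genome: Genome,
    gene_models: list[GeneModel],
    truth: GroundTruth,
    config: SimConfig,
) -> dict[str, list[ReadEnd]]:
    """Sample per-library read 3' ends from the ground truth.

    Per gene and sample the read total is Poisson(``reads_per_gene``); for
    trapped genes a Binomial(``internal_priming_rate``) share terminates
    exactly at the trap position (internal-priming artifacts), the rest are
    multinomial over true sites with the condition's usage fractions plus
    rounded Gaussian jitter applied along the transcript axis.  Fills
    ``truth.artifact_counts`` per sample.
    """
    rng = np.random.default_rng([config.seed, 1])
    out: dict[str, list[ReadEnd]] = {}
    for sample, cond in sample_names(config).items():
        reads: list[ReadEnd] = []
        n_art_total = 0
        for gene_id in sorted(truth.genes):
            gt = truth.genes[gene_id]
            chrom_len = genome.length(gt.chrom)
            sign = 1 if gt.strand == "+" else -1
            n = int(rng.poisson(config.reads_per_gene))
            n_art = (
                int(rng.binomial(n, config.internal_priming_rate))
                if gt.trap_pos is not None and n
                else 0
            )
            counts = rng.multinomial(n - n_art, gt.usage[cond])
            for pas, cnt in zip(gt.pas_positions, counts):
                if cnt == 0:
                    continue
                if config.jitter_sd > 0:
                    jit = np.rint(
                        rng.normal(0.0, config.jitter_sd, size=int(cnt))
                    ).astype(np.int64)
                else:
                    jit = np.zeros(int(cnt), dtype=np.int64)
                pos = np.clip(pas + sign * jit, 0, chrom_len - 1)
                reads.extend(
                    ReadEnd(gt.chrom, gt.strand, int(p), sample) for p in pos
                )
            if n_art:
                reads.extend(
                    [ReadEnd(gt.chrom, gt.strand, gt.trap_pos, sample)] * n_art
                )
                n_art_total += n_art
        truth.artifact_counts[sample] = n_art_total
        out[sample] = reads
    return out


# ---------------------------------------------------------------------------
# one-call dataset writer
# ---------------------------------------------------------------------------

@dataclass
class SimOutput:
    genome_fa: Path
    genes_bed: Path
    genes_tsv: Path
    known_pas_bed: Path
    read_files: dict[str, Path]
    sample_condition: dict[str, str]
    truth_tsv: Path
    sim_json: Path


def simulate(config: SimConfig, out_dir: str | Path) -> SimOutput:
    """Generate a full synthetic study on disk; returns the file manifest."""
    out_dir = Path(out_dir)
    (out_dir / "reads").mkdir(parents=True, exist_ok=True)
    genome, genes, known, truth = generate_genome(config)
    reads = generate_reads(genome, genes, truth, config)

    genome_fa = out_dir / "genome.fa"
    genome.write(genome_fa)
    genes_bed = out_dir / "genes.bed12"
    genes_tsv = out_dir / "genes.tsv"
    write_gene_models(genes, genes_bed, genes_tsv)
    known_bed = out_dir / "known_pas.bed"
    write_pas_bed(known, known_bed)
    truth_tsv = out_dir / "truth.tsv"
    truth.write(truth_tsv)

    ext = "sam" if config.read_format == "sam" else "bed"
    read_files: dict[str, Path] = {}
    for sample in sorted(reads):
        path = out_dir / "reads" / f"{sample}.{ext}"
        if ext == "sam":
            write_read_ends_sam(reads[sample], genome, path)
        else:
            write_read_ends_bed(reads[sample], path)
        read_files[sample] = path

    sim_json = out_dir / "sim.json"
    with open(sim_json, "w") as fh:
        json.dump(
            {
                "config": asdict(config),
                "artifact_counts": truth.artifact_counts,
                "sample_condition": sample_names(config),
                "n_true_pas": sum(
                    len(g.pas_positions) for g in truth.genes.values()
                ),
                "n_known_pas": len(known),
            },
            fh,
            indent=2,
            sort_keys=True,
        )
        fh.write("\n")
    return SimOutput(
        genome_fa=genome_fa,
        genes_bed=genes_bed,
        genes_tsv=genes_tsv,
        known_pas_bed=known_bed,
        read_files=read_files,
        sample_condition=sample_names(config),
        truth_tsv=truth_tsv,
        sim_json=sim_json,
    )
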