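"""Readers and writers for the external formats the pipeline touches.

One coordinate convention rules everywhere inside the package: 0-based,
half-open intervals on the forward reference strand, as in BED and BAM.
Conversion to/from other conventions happens only at format boundaries.

Gene models arrive as BED12 (thickStart/thickEnd delimit the CDS, so the
3'UTR is derivable) plus a sidecar TSV carrying explicit stop-codon and
transcription-terminal-site (TTS) coordinates.  Read 3' ends arrive either
as SAM/BAM alignments (reduced here to their strand-aware 3'-most aligned
reference base) or as a BED6 file with one 1-nt interval per read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, NamedTuple

import pandas as pd
import pysam
from pyfaidx import Fasta

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

RESULT_COLUMNS = ["gene_id", "n_pas", "culi", "trend_stat", "p", "q", "call"]


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


class BoundsError(ValueError):
    """Raised when a genomic interval falls outside its chromosome."""


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class ReadEnd(NamedTuple):
    """A mapped read reduced to its strand-aware 3'-end reference position."""

    chrom: str
    strand: str
    pos: int
    sample_id: str


@dataclass(frozen=True)
class GeneModel:
    """A gene's structure as the pipeline needs it.

    ``stop_codon_pos`` and ``tts_pos`` are single 0-based coordinates;
    ``utr3_interval`` is half-open and lies between them in transcription
    order (for minus-strand genes it therefore *precedes* the stop codon in
    reference coordinates).
    """

    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    stop_codon_pos: int
    utr3_interval: tuple[int, int]
    tts_pos: int

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r} for {self.gene_id}")
        for (a, b), (c, d) in zip(self.exons, self.exons[1:]):
            if not (a < b <= c < d):
                raise ValueError(f"exons of {self.gene_id} unsorted or overlapping")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]


class Genome:
    """In-memory genome with bounds-checked, case-preserving access."""

    def __init__(self, seqs: dict[str, str]):
        self._seqs = dict(seqs)

    @classmethod
    def from_fasta(cls, path: str | Path) -> "Genome":
        try:
            fa = Fasta(str(path), as_raw=True, rebuild=True)
        except Exception as exc:  # pyfaidx raises several flavours
            raise FormatError(f"cannot parse FASTA {path}: {exc}") from exc
        seqs = {name: str(fa[name][:]) for name in fa.keys()}
        fa.close()
        return cls(seqs)

    def chroms(self) -> list[str]:
        return list(self._seqs)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs

    def length(self, chrom: str) -> int:
        if chrom not in self._seqs:
            raise KeyError(f"unknown chromosome {chrom!r}")
        return len(self._seqs[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        n = self.length(chrom)
        if not (0 <= start <= end <= n):
            raise BoundsError(
                f"interval [{start}, {end}) outside {chrom} (length {n})"
            )
        return self._seqs[chrom][start:end]

    def write(self, path: str | Path, width: int = 60) -> None:
        with open(path, "w") as fh:
            for name, seq in self._seqs.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# gene models: BED12 + sidecar TSV
# ---------------------------------------------------------------------------

def write_gene_models(
    genes: Iterable[GeneModel], bed_path: str | Path, sidecar_path: str | Path
) -> None:
    """Write BED12 (CDS as the thick region) plus the sidecar coordinate TSV."""
    genes = sorted(genes, key=lambda g: (g.chrom, g.start, g.gene_id))
    with open(bed_path, "w") as bed:
        for g in genes:
            if g.strand == "+":
                thick_start, thick_end = g.start, g.utr3_interval[0]
            else:
                thick_start, thick_end = g.utr3_interval[1], g.end
            sizes = ",".join(str(b - a) for a, b in g.exons) + ","
            starts = ",".join(str(a - g.start) for a, b in g.exons) + ","
            bed.write(
                "\t".join(
                    map(
                        str,
                        [
                            g.chrom,
                            g.start,
                            g.end,
                            g.gene_id,
                            0,
                            g.strand,
                            thick_start,
                            thick_end,
                            0,
                            len(g.exons),
                            sizes,
                            starts,
                        ],
                    )
                )
                + "\n"
            )
    side = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "stop_codon_pos": [g.stop_codon_pos for g in genes],
            "tts_pos": [g.tts_pos for g in genes],
        }
    )
    side.to_csv(sidecar_path, sep="\t", index=False)


def read_gene_models(
    bed_path: str | Path, sidecar_path: str | Path
) -> list[GeneModel]:
    """Parse BED12 gene models; stop-codon/TTS coordinates come from the sidecar.

    The 3'UTR is derived from the thick (CDS) boundary: plus strand
    [thickEnd, chromEnd), minus strand [chromStart, thickStart).  The TTS is
    the transcription-order last base: chromEnd-1 on plus, chromStart on minus.
    """
    side = pd.read_csv(sidecar_path, sep="\t", dtype={"gene_id": str})
    sidecar = {r.gene_id: r for r in side.itertuples()}
    genes: list[GeneModel] = []
    with open(bed_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise FormatError(f"{bed_path}:{lineno}: expected 12 BED fields")
            chrom, start, end, name, _score, strand = fields[:6]
            start, end = int(start), int(end)
            thick_start, thick_end = int(fields[6]), int(fields[7])
            n_blocks = int(fields[9])
            sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
            offsets = [int(x) for x in fields[11].rstrip(",").split(",")]
            if len(sizes) != n_blocks or len(offsets) != n_blocks:
                raise FormatError(f"{bed_path}:{lineno}: block count mismatch")
            exons = tuple(
                (start + o, start + o + s) for o, s in zip(offsets, sizes)
            )
            if name not in sidecar:
                raise FormatError(
                    f"gene {name!r} present in {bed_path} but missing from "
                    f"sidecar {sidecar_path}"
                )
            if strand == "+":
                utr3 = (thick_end, end)
                tts = end - 1
            else:
                utr3 = (start, thick_start)
                tts = start
            genes.append(
                GeneModel(
                    gene_id=name,
                    chrom=chrom,
                    strand=strand,
                    exons=exons,
                    stop_codon_pos=int(sidecar[name].stop_codon_pos),
                    utr3_interval=utr3,
                    tts_pos=tts,
                )
            )
    return genes


# ---------------------------------------------------------------------------
# read 3' ends: SAM/BAM or BED6
# ---------------------------------------------------------------------------

def read_read_ends(
    path: str | Path, sample_id: str
) -> tuple[list[ReadEnd], int]:
    """Load read 3'-end positions for one sample.

    Returns ``(reads, n_skipped)`` where skipped counts unmapped, secondary
    and supplementary records (SAM/BAM only).  The 3' end of a plus-strand
    alignment is its last aligned reference base; of a minus-strand
    alignment its first aligned reference base.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in {".sam", ".bam"}:
        return _read_ends_from_alignments(path, sample_id)
    if suffix == ".bed":
        return _read_ends_from_bed(path, sample_id), 0
    raise FormatError(f"unknown read-file extension {suffix!r} for {path}")


def _read_ends_from_alignments(path: Path, sample_id: str):
    mode = "rb" if path.suffix.lower() == ".bam" else "r"
    reads: list[ReadEnd] = []
    skipped = 0
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as af:
        for rec in af.fetch(until_eof=True):
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                skipped += 1
                continue
            if rec.is_reverse:
                strand, pos = "-", rec.reference_start
            else:
                strand, pos = "+", rec.reference_end - 1
            reads.append(ReadEnd(rec.reference_name, strand, pos, sample_id))
    if skipped:
        logger.info("%s: skipped %d non-primary/unmapped records", path, skipped)
    return reads, skipped


def _read_ends_from_bed(path: Path, sample_id: str) -> list[ReadEnd]:
    reads: list[ReadEnd] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise FormatError(f"{path}:{lineno}: expected BED6")
            chrom, start, _end, _name, _score, strand = fields[:6]
            reads.append(ReadEnd(chrom, strand, int(start), sample_id))
    return reads


def write_read_ends_bed(reads: Iterable[ReadEnd], path: str | Path) -> None:
    """One BED6 line per read (1-nt interval at the 3'-end position), sorted."""
    rows = sorted(reads, key=lambda r: (r.chrom, r.pos, r.strand))
    with open(path, "w") as fh:
        for i, r in enumerate(rows):
            fh.write(f"{r.chrom}\t{r.pos}\t{r.pos + 1}\tread_{i}\t0\t{r.strand}\n")


def write_read_ends_sam(
    reads: Iterable[ReadEnd], genome: Genome, path: str | Path
) -> None:
    """Minimal coordinate-sorted SAM: one 1M alignment per read 3' end."""
    chroms = genome.chroms()
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": genome.length(c)} for c in chroms],
    }
    order = {c: i for i, c in enumerate(chroms)}
    rows = sorted(reads, key=lambda r: (order[r.chrom], r.pos, r.strand))
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for i, r in enumerate(rows):
            a = pysam.AlignedSegment(out.header)
            a.query_name = f"read_{i}"
            a.flag = 16 if r.strand == "-" else 0
            a.reference_id = order[r.chrom]
            a.reference_start = r.pos
            a.mapping_quality = 60
            a.cigarstring = "1M"
            a.query_sequence = "N"
            out.write(a)


# ---------------------------------------------------------------------------
# poly(A)-site BED and results tables
# ---------------------------------------------------------------------------

def read_pas_bed(path: str | Path) -> list[tuple[str, int, str]]:
    """Known poly(A)-site database: BED6 of single positions."""
    sites: list[tuple[str, int, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise FormatError(f"{path}:{lineno}: expected BED6")
            sites.append((fields[0], int(fields[1]), fields[5]))
    return sites


def write_pas_bed(sites, path: str | Path) -> None:
    """Write poly(A) sites/clusters as sorted BED6.

    Accepts either ``(chrom, pos, strand)`` triples (score 0) or objects with
    ``chrom``, ``rep_pos``, ``strand`` and a ``total`` read count, which is
    placed in the score field.
    """
    rows = []
    for s in sites:
        if isinstance(s, tuple):
            chrom, pos, strand = s
            score = 0
            name = "pas"
        else:
            chrom, pos, strand = s.chrom, s.rep_pos, s.strand
            score = s.total
            name = "cluster"
        rows.append((chrom, pos, strand, name, score))
    rows.sort(key=lambda r: (r[0], r[1], r[2]))
    with open(path, "w") as fh:
        for i, (chrom, pos, strand, name, score) in enumerate(rows):
            fh.write(f"{chrom}\t{pos}\t{pos + 1}\t{name}_{i}\t{score}\t{strand}\n")


def write_results(results, path: str | Path) -> None:
    """Write the per-gene APA results TSV, sorted by gene_id.

    ``results`` is a DataFrame with the columns gene_id, n_pas, culi,
    trend_stat, p, q, call.  Numeric fields are written with 6 significant
    digits.
    """
    df = pd.DataFrame(results, columns=RESULT_COLUMNS)
    df = df.sort_values("gene_id").reset_index(drop=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_results(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "call": str})
    missing = set(RESULT_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing result columns {sorted(missing)}")
    return df
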