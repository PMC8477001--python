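"""End-to-end orchestration: filter -> cluster -> annotate -> test -> report.

A run is driven by a :class:`RunConfig` (JSON-serialisable; every threshold
explicit) and produces, in its output directory:

``clusters.bed``      poly(A)-site clusters as BED6 (score = read count)
``clusters.tsv``      the full annotated cluster table
``results.tsv``       per-gene CULI / trend-test / FDR / call table
``summary.json``      per-stage read accounting plus every parameter used
``run.log``           console log replica with stage timings

All result artifacts are deterministic (sorted rows, fixed float format):
rerunning with the same config and inputs reproduces them byte for byte.
The log file carries wall-clock timings and is the one artifact excluded
from that guarantee.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import discovery, stats
from .io import (
    Genome,
    read_gene_models,
    read_pas_bed,
    read_read_ends,
    write_pas_bed,
    write_results,
)

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Raised for user-facing configuration problems."""


@dataclass
class RunConfig:
    genome: str
    genes_bed: str
    genes_tsv: str
    sample_reads: dict[str, str]        # sample id -> read file path
    sample_condition: dict[str, str]    # sample id -> condition name
    control: str
    treated: str
    out_dir: str
    known_pas: str | None = None
    ip_window: int = discovery.IP_WINDOW
    ip_max_a: int = discovery.IP_MAX_A
    ip_run_a: int = discovery.IP_RUN_A
    cluster_window: int = discovery.CLUSTER_WINDOW
    min_cluster_reads: int = discovery.MIN_CLUSTER_READS
    tts_window: int = discovery.TTS_WINDOW
    match_tolerance: int = discovery.MATCH_TOLERANCE
    alpha: float = stats.ALPHA
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        conds = set(self.sample_condition.values())
        if conds != {self.control, self.treated}:
            raise ConfigError(
                f"sample map names conditions {sorted(conds)}; expected "
                f"exactly {{{self.control!r}, {self.treated!r}}}"
            )
        if set(self.sample_reads) != set(self.sample_condition):
            raise ConfigError("sample_reads and sample_condition disagree")
        paths = [self.genome, self.genes_bed, self.genes_tsv]
        if self.known_pas:
            paths.append(self.known_pas)
        paths.extend(self.sample_reads.values())
        missing = [p for p in paths if not Path(p).exists()]
        if missing:
            raise ConfigError(f"missing input files: {missing}")
        if self.cluster_window <= 0:
            raise ConfigError("cluster_window must be positive")

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = json.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        extra = set(data) - known
        if extra:
            raise ConfigError(f"unknown config keys: {sorted(extra)}")
        return cls(**data)


def _setup_run_logger(out_dir: Path, level: str) -> logging.Handler:
    handler = logging.FileHandler(out_dir / "run.log", mode="w")
    handler.setFormatter(
        logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s")
    )
    root = logging.getLogger("apa3t")
    root.setLevel(getattr(logging, level.upper(), logging.INFO))
    root.addHandler(handler)
    return handler


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages; returns the output directory.

    Raises with the failing stage's name on error.  The summary JSON
    asserts read conservation: input reads = internal-priming filtered +
    reads in kept clusters + reads in discarded (sub-threshold) clusters.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    handler = _setup_run_logger(out_dir, config.log_level)
    t0 = time.perf_counter()
    stage = "load"
    timings: dict[str, float] = {}
    try:
        logger.info("parameters: %s", dataclasses.asdict(config))
        genome = Genome.from_fasta(config.genome)
        gene_models = read_gene_models(config.genes_bed, config.genes_tsv)
        known = read_pas_bed(config.known_pas) if config.known_pas else []
        reads = []
        reads_in: dict[str, int] = {}
        for sample in sorted(config.sample_reads):
            sample_reads, skipped = read_read_ends(
                config.sample_reads[sample], sample
            )
            reads.extend(sample_reads)
            reads_in[sample] = len(sample_reads)
            if skipped:
                logger.info("%s: %d non-primary/unmapped skipped", sample, skipped)
        timings[stage] = time.perf_counter() - t0
        logger.info("loaded %d reads from %d samples", len(reads), len(reads_in))

        stage = "filter_internal_priming"
        t = time.perf_counter()
        kept, removed = discovery.filter_read_ends(
            reads, genome,
            window=config.ip_window, max_a=config.ip_max_a,
            run_a=config.ip_run_a,
        )
        timings[stage] = time.perf_counter() - t
        logger.info(
            "internal-priming filter removed %d / %d reads",
            sum(removed.values()), len(reads),
        )

        stage = "cluster"
        t = time.perf_counter()
        all_clusters = discovery.cluster_read_ends(
            kept, window=config.cluster_window, min_cluster_reads=0
        )
        clusters = [
            c for c in all_clusters if c.total >= config.min_cluster_reads
        ]
        discarded_reads = sum(
            c.total for c in all_clusters if c.total < config.min_cluster_reads
        )
        timings[stage] = time.perf_counter() - t
        logger.info(
            "%d clusters kept (>=%d reads), %d reads in discarded clusters",
            len(clusters), config.min_cluster_reads, discarded_reads,
        )

        stage = "annotate"
        t = time.perf_counter()
        clusters = discovery.annotate_clusters(
            clusters, gene_models, known,
            tts_window=config.tts_window,
            match_tolerance=config.match_tolerance,
        )
        per_gene, hist = discovery.summarize_pas_per_gene(clusters)
        timings[stage] = time.perf_counter() - t

        stage = "test"
        t = time.perf_counter()
        profiles = stats.build_profiles(
            clusters, gene_models, config.sample_condition,
            config.control, config.treated,
        )
        results, test_summary = stats.call_apa_shifts(profiles, alpha=config.alpha)
        timings[stage] = time.perf_counter() - t

        stage = "write"
        write_pas_bed(clusters, out_dir / "clusters.bed")
        cl_df = discovery.clusters_to_frame(clusters)
        cl_df.to_csv(out_dir / "clusters.tsv", sep="\t", index=False)
        write_results(results, out_dir / "results.tsv")

        n_clustered = sum(c.total for c in clusters)
        conservation_ok = (
            len(reads)
            == sum(removed.values()) + n_clustered + discarded_reads
        )
        if not conservation_ok:
            raise RuntimeError("read conservation violated across stages")
        cats = {
            cat: int(sum(1 for c in clusters if c.category == cat))
            for cat in discovery.CATEGORIES
        }
        summary = {
            "parameters": dataclasses.asdict(config),
            "reads": {
                "input_per_sample": reads_in,
                "input_total": len(reads),
                "internal_priming_removed_per_sample": dict(sorted(removed.items())),
                "internal_priming_removed_total": sum(removed.values()),
                "in_kept_clusters": n_clustered,
                "in_discarded_clusters": discarded_reads,
                "conservation_ok": conservation_ok,
            },
            "clusters": {
                "n_kept": len(clusters),
                "n_discarded_small": len(all_clusters) - len(clusters),
                "category_counts": cats,
                "n_known": int(sum(1 for c in clusters if c.known)),
                "n_hits_tts": int(sum(1 for c in clusters if c.hits_tts)),
                "n_hits_utr3": int(sum(1 for c in clusters if c.hits_utr3)),
            },
            "genes": {
                "n_with_utr_pas": int(len(per_gene)),
                "pas_per_gene_hist": hist,
                **test_summary,
            },
            "timings_s": {k: round(v, 3) for k, v in timings.items()},
        }
        with open(out_dir / "summary.json", "w") as fh:
            # timings change run to run; keep them out of the deterministic file
            det = {k: v for k, v in summary.items() if k != "timings_s"}
            json.dump(det, fh, indent=2, sort_keys=True)
            fh.write("\n")
        logger.info("run complete: %s", out_dir)
        return out_dir
    except Exception:
        logger.exception("pipeline failed at stage %r", stage)
        raise
    finally:
        logging.getLogger("apa3t").removeHandler(handler)
        handler.close()


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------

def make_report(out_dir: str | Path) -> dict[str, pd.DataFrame]:
    """Summarise a completed run into four TSV tables plus scatter data.

    Tables: exclusive genomic-category percentages (with the non-exclusive
    TTS/3'UTR overlap percentages appended), genes-per-PAS histogram,
    known/novel split, and the shift-call summary.  Also writes
    ``report_culi_scatter.tsv`` (CULI vs. -log10 q per gene).
    """
    out_dir = Path(out_dir)
    for name in ("clusters.tsv", "results.tsv"):
        if not (out_dir / name).exists():
            raise FileNotFoundError(f"missing pipeline artifact: {out_dir / name}")
    clusters = pd.read_csv(out_dir / "clusters.tsv", sep="\t")
    results = pd.read_csv(out_dir / "results.tsv", sep="\t")

    n = len(clusters)
    rows = []
    for cat in discovery.CATEGORIES:
        k = int((clusters["category"] == cat).sum()) if n else 0
        rows.append({"category": cat, "n": k, "pct": 100.0 * k / n if n else 0.0})
    for label, col in (("TTS_overlap", "hits_tts"), ("UTR3_overlap", "hits_utr3")):
        k = int(clusters[col].sum()) if n else 0
        rows.append({"category": label, "n": k, "pct": 100.0 * k / n if n else 0.0})
    categories = pd.DataFrame(rows, columns=["category", "n", "pct"])

    if n:
        utr = clusters[clusters["category"].isin(["TTS", "UTR3"])]
        per_gene = utr.groupby("gene_id").size()
        hist = {"1": 0, "2": 0, "3": 0, "4+": 0}
        for v in per_gene:
            hist["4+" if v >= 4 else str(v)] += 1
    else:
        hist = {"1": 0, "2": 0, "3": 0, "4+": 0}
    total_genes = sum(hist.values())
    genes_per_pas = pd.DataFrame(
        {
            "n_pas": list(hist),
            "n_genes": list(hist.values()),
            "pct": [
                100.0 * v / total_genes if total_genes else 0.0
                for v in hist.values()
            ],
        }
    )

    n_known = int(clusters["known"].sum()) if n else 0
    known_novel = pd.DataFrame(
        {
            "status": ["known", "novel"],
            "n": [n_known, n - n_known],
            "pct": [
                100.0 * n_known / n if n else 0.0,
                100.0 * (n - n_known) / n if n else 0.0,
            ],
        }
    )

    n_tested = len(results)
    n_short = int((results["call"] == "shortened").sum()) if n_tested else 0
    n_long = int((results["call"] == "lengthened").sum()) if n_tested else 0
    n_altered = n_short + n_long
    shift = pd.DataFrame(
        {
            "metric": [
                "n_genes_tested", "n_altered", "n_shortened", "n_lengthened",
                "pct_shortened_among_altered",
            ],
            "value": [
                n_tested, n_altered, n_short, n_long,
                100.0 * n_short / n_altered if n_altered else 0.0,
            ],
        }
    )

    import numpy as np

    scatter = results[["gene_id", "culi", "q", "call"]].copy()
    if n_tested:
        scatter["neglog10_q"] = -np.log10(scatter["q"].clip(lower=1e-300))
    else:
        scatter["neglog10_q"] = pd.Series(dtype=float)

    tables = {
        "report_categories": categories,
        "report_genes_per_pas": genes_per_pas,
        "report_known_novel": known_novel,
        "report_shift_summary": shift,
        "report_culi_scatter": scatter,
    }
    for name, df in tables.items():
        df.to_csv(out_dir / f"{name}.tsv", sep="\t", index=False,
                  float_format="%.6g")
    return tables
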