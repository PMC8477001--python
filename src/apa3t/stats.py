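"""Per-gene APA-shift inference between two conditions.

For every gene with at least two UTR-type poly(A)-site clusters the
pipeline builds an ordered usage profile (clusters sorted proximal to
distal by distance from the stop codon) and computes:

*   **CULI**, a 3'UTR length index: the difference, treated minus control,
    of the usage-weighted normalized 3'UTR length
    ``L = sum_i u_i * d_i / d_max`` where ``u_i`` is the condition's usage
    fraction of site *i* and ``d_i`` its distance from the stop codon.
    CULI is bounded in [-1, 1], antisymmetric under swapping the
    conditions, positive when the treated condition favours distal sites
    (3'UTR lengthening) and negative for shortening.

*   A **Cochran–Armitage linear trend test** on the 2 x k condition-by-site
    count table with rank scores 1..k.  For small tables (total count at or
    below ``EXACT_MAX_TOTAL``) the p-value comes from the exact conditional
    null distribution of the score statistic given both margins, computed
    by dynamic programming over all tables with those margins; otherwise
    the asymptotic standard-normal reference is used, two-sided.

*   Benjamini–Hochberg FDR adjustment across genes and a
    shortened/lengthened/unchanged call: q < alpha with CULI < 0 is
    "shortened", q < alpha with CULI > 0 is "lengthened".
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .discovery import PASCluster
from .io import GeneModel, RESULT_COLUMNS

logger = logging.getLogger(__name__)

ALPHA = 0.05
EXACT_MAX_TOTAL = 200
# tolerance when deciding membership in the two-sided tail of the discrete
# exact null; distinct |T - E| values for tables with total N differ by
# at least 1/N, far above this
_TAIL_TOL = 1e-8


@dataclass
class GeneAPAProfile:
    """Ordered per-gene poly(A)-site usage across two conditions.

    ``counts`` has shape (2, k): row 0 control, row 1 treated, columns the
    sites ordered proximal to distal (strictly increasing ``distances`` from
    the stop codon, in nt).  ``replicate_counts`` retains the per-sample
    vectors the rows were summed from.
    """

    gene_id: str
    chrom: str
    strand: str
    rep_positions: tuple[int, ...]
    distances: tuple[int, ...]
    conditions: tuple[str, str]  # (control, treated)
    counts: np.ndarray
    replicate_counts: dict[str, np.ndarray]

    @property
    def n_pas(self) -> int:
        return len(self.distances)


def build_profiles(
    clusters: Sequence[PASCluster],
    gene_models: Sequence[GeneModel],
    sample_condition: Mapping[str, str],
    control: str,
    treated: str,
) -> list[GeneAPAProfile]:
    """Assemble testable per-gene profiles from annotated clusters.

    Only UTR-type clusters (category TTS or UTR3) participate.  Distances
    are strand-aware: rep_pos - stop_codon on plus, stop_codon - rep_pos on
    minus.  Clusters on the wrong strand for their gene are dropped with a
    warning; genes with fewer than two sites are skipped.
    """
    conds = set(sample_condition.values())
    if conds != {control, treated}:
        raise ValueError(
            f"sample map names conditions {sorted(conds)}, "
            f"expected {{{control!r}, {treated!r}}}"
        )
    genes = {g.gene_id: g for g in gene_models}
    by_gene: dict[str, list[PASCluster]] = {}
    for c in clusters:
        if c.category in ("TTS", "UTR3") and c.gene_id is not None:
            by_gene.setdefault(c.gene_id, []).append(c)

    profiles: list[GeneAPAProfile] = []
    for gene_id in sorted(by_gene):
        g = genes[gene_id]
        members = []
        for c in by_gene[gene_id]:
            if c.strand != g.strand:
                logger.warning(
                    "gene %s: dropping antisense cluster at %s:%d",
                    gene_id, c.chrom, c.rep_pos,
                )
                continue
            d = (c.rep_pos - g.stop_codon_pos) if g.strand == "+" else (
                g.stop_codon_pos - c.rep_pos
            )
            if d <= 0:
                logger.warning(
                    "gene %s: dropping cluster at nonpositive distance %d",
                    gene_id, d,
                )
                continue
            members.append((d, c))
        members.sort(key=lambda t: t[0])
        if len(members) < 2:
            logger.debug("gene %s: <2 UTR-type sites, not testable", gene_id)
            continue
        distances = tuple(d for d, _ in members)
        rep_positions = tuple(c.rep_pos for _, c in members)
        samples = sorted({s for _, c in members for s in c.counts})
        rep_counts = {
            s: np.array([c.counts.get(s, 0) for _, c in members], dtype=np.int64)
            for s in samples
        }
        counts = np.zeros((2, len(members)), dtype=np.int64)
        for s, vec in rep_counts.items():
            row = 0 if sample_condition[s] == control else 1
            counts[row] += vec
        profiles.append(
            GeneAPAProfile(
                gene_id=gene_id,
                chrom=g.chrom,
                strand=g.strand,
                rep_positions=rep_positions,
                distances=distances,
                conditions=(control, treated),
                counts=counts,
                replicate_counts=rep_counts,
            )
        )
    return profiles


def compute_culi(profile: GeneAPAProfile) -> float:
    """Usage-weighted normalized 3'UTR length, treated minus control."""
    totals = profile.counts.sum(axis=1)
    if (totals == 0).any():
        raise ValueError(
            f"gene {profile.gene_id}: zero reads in one condition, "
            "CULI undefined"
        )
    w = np.asarray(profile.distances, dtype=float)
    w /= w.max()
    usage = profile.counts / totals[:, None]
    return float(usage[1] @ w - usage[0] @ w)


def _trend_z(table: np.ndarray, scores: np.ndarray) -> float:
    """Cochran–Armitage standardized trend statistic for a 2 x k table.

    Positive when the *second* row (treated) is weighted toward higher
    scores (more distal sites).  Uses the conditional (both margins fixed)
    variance with the N-1 finite-population factor.
    """
    n = table.sum()
    r = table.sum(axis=1).astype(float)
    c = table.sum(axis=0).astype(float)
    t_obs = float(scores @ table[1])
    e = r[1] * float(scores @ c) / n
    var = (
        r[0] * r[1] / (n * n * (n - 1.0))
        * (n * float((scores ** 2) @ c) - float(scores @ c) ** 2)
    )
    if var <= 0:
        return 0.0
    return (t_obs - e) / math.sqrt(var)


def _exact_trend_pvalue(table: np.ndarray, scores: np.ndarray) -> float:
    """Exact conditional two-sided p for the score statistic T = s . row2.

    Enumerates (via DP over columns) the null distribution of T across all
    2 x k tables with the observed margins, each weighted by its
    multivariate-hypergeometric probability, and sums the probability of
    tables at least as far from E[T] as the observed one.
    """
    c = table.sum(axis=0)
    r1 = int(table[1].sum())
    t_obs = int(scores @ table[1])
    t_max = int(scores @ c)
    # dp[m, t] = sum over allocations x (row-2 counts so far) with
    # sum x = m and s.x = t of prod binom(c_j, x_j)
    dp = np.zeros((r1 + 1, t_max + 1))
    dp[0, 0] = 1.0
    for cj, sj in zip(c.tolist(), scores.astype(int).tolist()):
        new = np.zeros_like(dp)
        binom = [math.comb(cj, x) for x in range(min(cj, r1) + 1)]
        for x, w in enumerate(binom):
            if x == 0:
                new += dp * w
            else:
                new[x:, x * sj:] += dp[:-x, : dp.shape[1] - x * sj] * w
        dp = new
    weights = dp[r1]
    total = weights.sum()
    probs = weights / total
    ts = np.arange(t_max + 1, dtype=float)
    e = float(ts @ probs)
    d_obs = abs(t_obs - e)
    return float(probs[np.abs(ts - e) >= d_obs - _TAIL_TOL].sum())


def trend_test_table(
    table: np.ndarray, *, exact_max_total: int = EXACT_MAX_TOTAL
) -> tuple[float, float]:
    """Linear trend test on a 2 x k count table with rank scores.

    All-zero columns are dropped (scores re-ranked).  Returns
    ``(trend_stat, p)``; the statistic is the standardized Cochran–Armitage
    z in both branches.  Returns ``(nan, nan)`` when fewer than two
    informative columns remain or a row is empty.
    """
    table = np.asarray(table, dtype=np.int64)
    if table.ndim != 2 or table.shape[0] != 2:
        raise ValueError(f"expected a 2 x k table, got shape {table.shape}")
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    table = table[:, table.sum(axis=0) > 0]
    if table.shape[1] < 2 or (table.sum(axis=1) == 0).any():
        return float("nan"), float("nan")
    scores = np.arange(1, table.shape[1] + 1, dtype=float)
    z = _trend_z(table, scores)
    n = int(table.sum())
    if n <= exact_max_total:
        p = _exact_trend_pvalue(table, scores)
    else:
        p = 2.0 * sps.norm.sf(abs(z))
    return z, min(p, 1.0)


def trend_test(
    profile: GeneAPAProfile, *, exact_max_total: int = EXACT_MAX_TOTAL
) -> tuple[float, float]:
    return trend_test_table(profile.counts, exact_max_total=exact_max_total)


def bh_fdr(pvalues: Iterable[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def distal_proximal_ratio(profile: GeneAPAProfile) -> dict[str, float]:
    """Per-condition distal/proximal isoform ratio and its fold change.

    Ratio = reads at the most distal site / reads at the most proximal
    site; when either count is zero both get a +0.5 continuity correction.
    The fold change is treated ratio over control ratio.
    """
    out: dict[str, float] = {}
    for row, cond in zip(profile.counts, profile.conditions):
        prox, dist = float(row[0]), float(row[-1])
        if prox == 0 or dist == 0:
            prox, dist = prox + 0.5, dist + 0.5
        out[cond] = dist / prox
    control, treated = profile.conditions
    out["fold_change"] = out[treated] / out[control]
    return out


def call_apa_shifts(
    profiles: Sequence[GeneAPAProfile],
    *,
    alpha: float = ALPHA,
    exact_max_total: int = EXACT_MAX_TOTAL,
) -> tuple[pd.DataFrame, dict]:
    """Run CULI + trend test + BH-FDR over all profiles and call shifts.

    Genes with an empty condition row or a degenerate table are excluded
    (logged).  Returns the results table (columns gene_id, n_pas, culi,
    trend_stat, p, q, call) and a summary dict.
    """
    rows = []
    for prof in profiles:
        if (prof.counts.sum(axis=1) == 0).any():
            logger.info("gene %s skipped: empty condition row", prof.gene_id)
            continue
        z, p = trend_test(prof, exact_max_total=exact_max_total)
        if math.isnan(p):
            logger.info("gene %s skipped: degenerate count table", prof.gene_id)
            continue
        rows.append((prof.gene_id, prof.n_pas, compute_culi(prof), z, p))
    df = pd.DataFrame(rows, columns=["gene_id", "n_pas", "culi", "trend_stat", "p"])
    df["q"] = bh_fdr(df["p"]) if len(df) else np.array([], dtype=float)
    df["call"] = classify_calls(df["q"], df["culi"], alpha=alpha)
    df = df[RESULT_COLUMNS]
    n_altered = int((df["q"] < alpha).sum())
    n_short = int(((df["q"] < alpha) & (df["culi"] < 0)).sum())
    summary = {
        "n_genes_tested": int(len(df)),
        "n_altered": n_altered,
        "n_shortened": n_short,
        "n_lengthened": n_altered - n_short,
        "frac_shortened": (n_short / n_altered) if n_altered else float("nan"),
        "alpha": alpha,
    }
    return df, summary


def classify_calls(
    q: Iterable[float], culi: Iterable[float], *, alpha: float = ALPHA
) -> list[str]:
    """shortened iff q < alpha and CULI < 0; lengthened iff q < alpha and
    CULI > 0; unchanged otherwise."""
    calls = []
    for qi, ci in zip(q, culi):
        if qi < alpha and ci < 0:
            calls.append("shortened")
        elif qi < alpha and ci > 0:
            calls.append("lengthened")
        else:
            calls.append("unchanged")
    return calls
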