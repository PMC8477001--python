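import math

import numpy as np
import pytest

from apa3t.discovery import PASCluster
from apa3t.io import GeneModel
from apa3t.stats import (
    GeneAPAProfile,
    bh_fdr,
    build_profiles,
    classify_calls,
    compute_culi,
    distal_proximal_ratio,
    call_apa_shifts,
    trend_test_table,
)


def make_profile(counts, distances, conditions=("control", "knockdown")):
    counts = np.asarray(counts, dtype=np.int64)
    return GeneAPAProfile(
        gene_id="g", chrom="chr1", strand="+",
        rep_positions=tuple(1000 + d for d in distances),
        distances=tuple(distances),
        conditions=conditions,
        counts=counts,
        replicate_counts={},
    )


def exact_2x2_oracle(table):
    """Two-sided exact trend p for a 2x2 table by brute-force enumeration of
    every table with the observed margins, weighted hypergeometrically."""
    table = np.asarray(table)
    c0, c1 = table.sum(axis=0)
    r1 = table[1].sum()
    lo, hi = max(0, r1 - c1), min(r1, c0)
    ts, ws = [], []
    for x0 in range(lo, hi + 1):
        x1 = r1 - x0
        ws.append(math.comb(int(c0), int(x0)) * math.comb(int(c1), int(x1)))
        ts.append(x0 + 2 * x1)
    total = sum(ws)
    probs = [w / total for w in ws]
    e = sum(t * p for t, p in zip(ts, probs))
    t_obs = table[1, 0] + 2 * table[1, 1]
    d = abs(t_obs - e)
    return sum(p for t, p in zip(ts, probs) if abs(t - e) >= d - 1e-8)


class TestBuildProfiles:
    GENES = [
        GeneModel("gp", "chr1", "+", ((0, 2000),), 1000, (1000, 2000), 1999),
        GeneModel("gm", "chr1", "-", ((500, 2500),), 2000, (500, 2000), 500),
    ]

    @staticmethod
    def _cluster(gene_id, pos, strand, counts):
        return PASCluster(
            "chr1", strand, pos, (pos, pos + 1), counts,
            category="UTR3", known=False, gene_id=gene_id,
        )

    def test_plus_strand_ordering_and_distances(self):
        clusters = [
            self._cluster("gp", 1800, "+", {"a": 3, "b": 4}),
            self._cluster("gp", 1200, "+", {"a": 5, "b": 1}),
        ]
        (p,) = build_profiles(
            clusters, self.GENES, {"a": "control", "b": "knockdown"},
            "control", "knockdown",
        )
        assert p.rep_positions == (1200, 1800)
        assert p.distances == (200, 800)
        np.testing.assert_array_equal(p.counts, [[5, 3], [1, 4]])

    def test_minus_strand_mirror(self):
        clusters = [
            self._cluster("gm", 1900, "-", {"a": 1, "b": 1}),
            self._cluster("gm", 1100, "-", {"a": 1, "b": 1}),
        ]
        (p,) = build_profiles(
            clusters, self.GENES, {"a": "control", "b": "knockdown"},
            "control", "knockdown",
        )
        assert p.rep_positions == (1900, 1100)  # proximal first
        assert p.distances == (100, 900)

    def test_single_cluster_gene_excluded(self):
        clusters = [self._cluster("gp", 1500, "+", {"a": 5, "b": 5})]
        assert build_profiles(
            clusters, self.GENES, {"a": "control", "b": "knockdown"},
            "control", "knockdown",
        ) == []

    def test_antisense_cluster_dropped(self):
        clusters = [
            self._cluster("gp", 1200, "+", {"a": 5, "b": 5}),
            self._cluster("gp", 1800, "+", {"a": 5, "b": 5}),
            self._cluster("gp", 1500, "-", {"a": 9, "b": 9}),
        ]
        (p,) = build_profiles(
            clusters, self.GENES, {"a": "control", "b": "knockdown"},
            "control", "knockdown",
        )
        assert p.n_pas == 2

    def test_bad_condition_map_rejected(self):
        with pytest.raises(ValueError):
            build_profiles([], self.GENES, {"a": "x", "b": "y", "c": "z"},
                           "control", "knockdown")

    def test_replicates_summed_into_condition_rows(self):
        clusters = [
            self._cluster("gp", 1200, "+", {"c1": 2, "c2": 3, "k1": 7}),
            self._cluster("gp", 1800, "+", {"c1": 4, "c2": 1, "k1": 0}),
        ]
        (p,) = build_profiles(
            clusters, self.GENES,
            {"c1": "control", "c2": "control", "k1": "knockdown"},
            "control", "knockdown",
        )
        np.testing.assert_array_equal(p.counts, [[5, 5], [7, 0]])
        np.testing.assert_array_equal(p.replicate_counts["c2"], [3, 1])


class TestCULI:
    def test_identical_usage_gives_zero(self):
        p = make_profile([[40, 60], [20, 30]], [200, 800])
        assert compute_culi(p) == pytest.approx(0.0, abs=1e-12)

    def test_full_proximal_to_distal_shift(self):
        p = make_profile([[100, 0], [0, 100]], [200, 800])
        assert compute_culi(p) == pytest.approx(1 - 200 / 800)

    def test_hand_worked_example(self):
        p = make_profile([[80, 20], [30, 70]], [200, 800])
        # (0.3*0.25 + 0.7*1) - (0.8*0.25 + 0.2*1) = 0.375
        assert compute_culi(p) == pytest.approx(0.375, abs=1e-12)

    def test_antisymmetry_under_condition_swap(self, rng):
        for _ in range(50):
            k = int(rng.integers(2, 5))
            counts = rng.integers(0, 100, size=(2, k))
            counts[:, 0] += 1  # keep both rows non-empty
            d = np.sort(rng.choice(np.arange(50, 2000), size=k, replace=False))
            p = make_profile(counts, list(d))
            q = make_profile(counts[::-1], list(d))
            assert compute_culi(p) == pytest.approx(-compute_culi(q), abs=1e-12)

    def test_bound_by_distance_ratio(self, rng):
        for _ in range(50):
            k = int(rng.integers(2, 6))
            counts = rng.integers(1, 50, size=(2, k))
            d = np.sort(rng.choice(np.arange(10, 3000), size=k, replace=False))
            p = make_profile(counts, list(d))
            assert abs(compute_culi(p)) <= 1 - d[0] / d[-1] + 1e-12

    def test_zero_condition_total_rejected(self):
        p = make_profile([[0, 0], [10, 10]], [100, 500])
        with pytest.raises(ValueError):
            compute_culi(p)


class TestTrendTest:
    def test_flat_table_has_no_trend(self):
        z, p = trend_test_table([[10, 10], [10, 10]])
        assert z == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_perfect_separation_matches_enumeration(self):
        table = np.array([[20, 0], [0, 20]])
        _, p = trend_test_table(table)
        assert p == pytest.approx(exact_2x2_oracle(table), abs=1e-12)

    def test_random_2x2_tables_match_enumeration(self, rng):
        for _ in range(200):
            table = rng.integers(0, 30, size=(2, 2))
            if (table.sum(axis=1) == 0).any() or (table.sum(axis=0) == 0).any():
                continue
            _, p = trend_test_table(table)
            assert p == pytest.approx(exact_2x2_oracle(table), abs=1e-12)

    def test_zero_column_dropped_with_reranking(self):
        with_gap = np.array([[5, 0, 10], [10, 0, 5]])
        collapsed = np.array([[5, 10], [10, 5]])
        assert trend_test_table(with_gap) == trend_test_table(collapsed)

    def test_collapse_to_single_column_untestable(self):
        z, p = trend_test_table([[5, 0], [9, 0]])
        assert math.isnan(z) and math.isnan(p)

    def test_empty_row_untestable(self):
        z, p = trend_test_table([[0, 0], [5, 5]])
        assert math.isnan(p)

    def test_asymptotic_close_to_exact_on_moderate_tables(self, rng):
        # the two branches must agree reasonably as totals grow
        diffs = []
        for _ in range(40):
            table = rng.integers(10, 50, size=(2, 3))
            _, p_exact = trend_test_table(table, exact_max_total=10**9)
            _, p_asym = trend_test_table(table, exact_max_total=0)
            diffs.append(abs(p_exact - p_asym))
        assert np.median(diffs) < 0.02

    def test_2xk_exact_matches_full_enumeration(self, rng):
        # brute-force enumeration over all 2x3 tables with fixed margins
        def enumerate_2x3(table):
            c = table.sum(axis=0)
            r1 = table[1].sum()
            ts, ws = [], []
            for x0 in range(min(r1, c[0]) + 1):
                for x1 in range(min(r1 - x0, c[1]) + 1):
                    x2 = r1 - x0 - x1
                    if x2 < 0 or x2 > c[2]:
                        continue
                    w = (
                        math.comb(int(c[0]), x0)
                        * math.comb(int(c[1]), x1)
                        * math.comb(int(c[2]), x2)
                    )
                    ws.append(w)
                    ts.append(x0 + 2 * x1 + 3 * x2)
            total = sum(ws)
            probs = [w / total for w in ws]
            e = sum(t * p for t, p in zip(ts, probs))
            t_obs = int(table[1] @ np.array([1, 2, 3]))
            d = abs(t_obs - e)
            return sum(p for t, p in zip(ts, probs) if abs(t - e) >= d - 1e-8)

        for _ in range(25):
            table = rng.integers(1, 12, size=(2, 3))
            _, p = trend_test_table(table)
            assert p == pytest.approx(enumerate_2x3(table), abs=1e-12)


class TestFDRAndCalls:
    def test_single_pvalue_is_identity(self):
        assert bh_fdr([0.03]) == pytest.approx([0.03])

    def test_step_up_formula(self):
        np.testing.assert_allclose(
            bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03]
        )

    def test_all_ones_stay_one(self):
        np.testing.assert_allclose(bh_fdr([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])

    def test_monotone_order_preserving(self, rng):
        p = rng.random(50)
        q = bh_fdr(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()
        assert (q >= p - 1e-12).all() and (q <= 1.0).all()

    def test_call_rules(self):
        calls = classify_calls(
            q=[0.01, 0.2, 0.01, 0.2], culi=[-0.4, -0.9, 0.3, 0.0], alpha=0.05
        )
        assert calls == ["shortened", "unchanged", "lengthened", "unchanged"]


class TestDistalProximalRatio:
    def test_simple_ratio(self):
        p = make_profile([[50, 100], [50, 100]], [200, 800])
        r = distal_proximal_ratio(p)
        assert r["control"] == pytest.approx(2.0)
        assert r["fold_change"] == pytest.approx(1.0)

    def test_continuity_correction(self):
        p = make_profile([[10, 10], [0, 10]], [200, 800])
        r = distal_proximal_ratio(p)
        assert r["knockdown"] == pytest.approx(10.5 / 0.5)

    def test_three_site_profile_uses_extremes(self):
        p = make_profile([[10, 99, 20], [10, 99, 20]], [100, 400, 900])
        assert distal_proximal_ratio(p)["control"] == pytest.approx(2.0)


class TestCallApaShifts:
    def test_results_schema_and_summary(self):
        profiles = [
            make_profile([[80, 20], [30, 70]], [200, 800]),   # strong shift
            make_profile([[50, 50], [50, 50]], [200, 800]),   # null
        ]
        profiles[0].gene_id = "shifted"
        profiles[1].gene_id = "flat"
        df, summary = call_apa_shifts(profiles)
        assert list(df.columns) == [
            "gene_id", "n_pas", "culi", "trend_stat", "p", "q", "call"
        ]
        row = df.set_index("gene_id")
        assert row.loc["shifted", "call"] == "lengthened"
        assert row.loc["flat", "call"] == "unchanged"
        assert summary["n_genes_tested"] == 2
        assert summary["n_altered"] == 1

    def test_degenerate_profiles_skipped(self):
        profiles = [
            make_profile([[0, 0], [10, 10]], [100, 300]),
            make_profile([[5, 0], [9, 0]], [100, 300]),
        ]
        df, summary = call_apa_shifts(profiles)
        assert len(df) == 0 and summary["n_genes_tested"] == 0
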