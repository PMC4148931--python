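"""Normalization identities, fold-change rules, clusters and correlation."""

import math

import numpy as np
import pytest

from hypoxamir import quantify
from hypoxamir.errors import UndefinedLibraryError
from hypoxamir.quantify import (
    call_differential,
    cluster_coregulation,
    compute_fold_change,
    derive_clusters,
    normalize_rpkm,
    normalize_tpm,
    pearson_correlation,
)

# library totals after adapter removal and 16-35 length filtering, and the
# miR-210-3p read counts, as printed for the U87MG normoxia/hypoxia libraries
NORMOXIC_TOTAL = 7_297_894
HYPOXIC_TOTAL = 5_256_222
MIR210_NORMOXIC = 396
MIR210_HYPOXIC = 7252


class TestTPM:
    def test_zero_count(self):
        assert normalize_tpm(0, 1000) == 0.0

    def test_printed_mir210_normoxic_tpm(self):
        # 396 / 7,297,894 * 1e6, hand arithmetic
        assert normalize_tpm(MIR210_NORMOXIC, NORMOXIC_TOTAL) == pytest.approx(
            54.26, abs=0.01
        )

    def test_full_library_normalizes_to_a_million(self):
        assert normalize_tpm(12345, 12345) == pytest.approx(1e6)

    def test_zero_total_rejected(self):
        with pytest.raises(UndefinedLibraryError):
            normalize_tpm(0, 0)

    def test_sum_over_library_is_a_million(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            counts = rng.integers(1, 500, size=50)
            total = int(counts.sum())
            tpms = [normalize_tpm(int(c), total) for c in counts]
            assert math.fsum(tpms) == pytest.approx(1e6)


class TestRPKM:
    def test_zero(self):
        assert normalize_rpkm(0.0, 22) == 0.0

    def test_division(self):
        assert normalize_rpkm(54.26, 22) == pytest.approx(2.466, abs=0.001)

    def test_algebraic_identity(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            tpm = float(rng.uniform(0, 1e5))
            length = int(rng.integers(16, 28))
            assert normalize_rpkm(tpm, length) * length == pytest.approx(
                tpm, rel=1e-12
            )

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            normalize_rpkm(1.0, 0)


class TestFoldChange:
    def test_mir210_reproduces_25_fold(self):
        fc = compute_fold_change(
            MIR210_HYPOXIC, HYPOXIC_TOTAL, MIR210_NORMOXIC, NORMOXIC_TOTAL
        )
        assert round(fc) == 25
        assert fc == pytest.approx(25.4, abs=0.05)

    def test_equal_tpm_gives_unity(self):
        assert compute_fold_change(100, 10_000, 50, 5_000) == pytest.approx(1.0)

    def test_pseudocount_only_applied_to_zero_counts(self):
        assert compute_fold_change(0, 10**6, 100, 10**6) == pytest.approx(
            1 / 101
        )
        # both nonzero: no pseudocount
        assert compute_fold_change(200, 10**6, 100, 10**6) == pytest.approx(2.0)

    def test_condition_swap_inverts(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            ch, cn = int(rng.integers(0, 100)), int(rng.integers(0, 100))
            fc = compute_fold_change(ch, 10_000, cn, 20_000)
            rev = compute_fold_change(cn, 20_000, ch, 10_000)
            assert fc * rev == pytest.approx(1.0)


class TestDifferentialCalls:
    def _records(self, fcs):
        counts_h = {f"m{i}": int(round(fc * 1000)) for i, fc in enumerate(fcs)}
        counts_n = {f"m{i}": 1000 for i in range(len(fcs))}
        return call_differential(counts_h, 10**6, counts_n, 10**6)

    def test_strict_threshold_boundary(self):
        recs = {r.mirna: r for r in self._records([1.6, 1.5, 0.5])}
        assert recs["m0"].direction == "up"
        assert recs["m1"].direction == "unchanged"  # equality is not DE
        assert recs["m2"].direction == "down"

    def test_sorted_by_absolute_log_fold(self):
        recs = self._records([1.2, 8.0, 0.1, 2.0])
        folds = [abs(math.log(r.fold_change)) for r in recs]
        assert folds == sorted(folds, reverse=True)

    def test_direction_flips_under_condition_swap(self):
        counts_h = {"a": 300, "b": 50}
        counts_n = {"a": 100, "b": 100}
        fwd = {r.mirna: r for r in
               call_differential(counts_h, 10**4, counts_n, 10**4)}
        rev = {r.mirna: r for r in
               call_differential(counts_n, 10**4, counts_h, 10**4)}
        flip = {"up": "down", "down": "up", "unchanged": "unchanged"}
        for m in fwd:
            assert rev[m].direction == flip[fwd[m].direction]


class TestClusters:
    def test_co_up_cluster(self):
        de = call_differential(
            {"a": 400, "b": 300}, 10**4, {"a": 100, "b": 100}, 10**4
        )
        (summary,) = cluster_coregulation(de, {"c1": ["a", "b"]})
        assert summary.n_up == 2 and summary.co_regulated

    def test_discordant_cluster_not_coregulated(self):
        de = call_differential(
            {"a": 400, "b": 25}, 10**4, {"a": 100, "b": 100}, 10**4
        )
        (summary,) = cluster_coregulation(de, {"c1": ["a", "b"]})
        assert summary.n_up == 1 and summary.n_down == 1
        assert not summary.co_regulated

    def test_missing_member_warned_and_skipped(self):
        de = call_differential({"a": 100}, 10**4, {"a": 100}, 10**4)
        with pytest.warns(UserWarning):
            (summary,) = cluster_coregulation(de, {"c1": ["a", "ghost"]})
        assert summary.members == ["a"]

    def test_random_assignment_matches_recount_oracle(self):
        rng = np.random.default_rng(8)
        names = [f"m{i}" for i in range(30)]
        counts_h = {n: int(rng.integers(10, 1000)) for n in names}
        counts_n = {n: int(rng.integers(10, 1000)) for n in names}
        de = call_differential(counts_h, 10**5, counts_n, 10**5)
        clusters = {
            f"c{j}": list(rng.choice(names, size=4, replace=False))
            for j in range(5)
        }
        by_name = {r.mirna: r.direction for r in de}
        for summary in cluster_coregulation(de, clusters):
            dirs = [by_name[m] for m in clusters[summary.cluster]]
            assert summary.n_up == dirs.count("up")
            assert summary.n_down == dirs.count("down")

    def test_derived_clusters_match_declared_toy_clusters(self, small_ref):
        derived = derive_clusters(small_ref.precursors)
        derived_sets = {frozenset(v) for v in derived.values()}
        declared_sets = {frozenset(v) for v in small_ref.clusters.values()}
        assert declared_sets <= derived_sets


class TestPearson:
    def test_perfect_linearity(self):
        x = np.arange(10.0)
        assert pearson_correlation(x, 2 * x + 1) == pytest.approx(1.0)
        assert pearson_correlation(x, -x) == pytest.approx(-1.0)

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        xc, yc = x - x.mean(), y - y.mean()
        manual = float(
            (xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum())
        )
        assert pearson_correlation(x, y) == pytest.approx(manual, rel=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_correlation([1, 1, 1], [1, 2, 3])
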