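import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from reosig.io import ExpressionMatrix, LabelTable
from reosig.reo import (
    PairStats,
    bh_adjust,
    compute_fd,
    de_statistics,
    fisher_exact_p,
    pair_reo_counts,
    remove_redundant_pairs,
    screen_de_genes,
    select_candidate_pairs,
)
from reosig.simulate import SimulationConfig, apply_monotone_distortion, simulate_dataset

from conftest import make_two_class_matrix


def bh_stepup_oracle(p):
    """Brute-force Benjamini-Hochberg step-up: q_(i) = min_{j>=i} p_(j) * m / j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        q[idx] = running
    return q


def fisher_tail_oracle(a, b, c, d):
    """Upper hypergeometric tail P(X >= a) by direct enumeration."""
    N, K, n = a + b + c + d, a + c, a + b
    total = math.comb(N, n)
    return sum(
        math.comb(K, x) * math.comb(N - K, n - x)
        for x in range(a, min(K, n) + 1)
        if n - x <= N - K
    ) / total


class TestBhAdjust:
    @pytest.mark.parametrize(
        "p,expected",
        [
            ([0.05], [0.05]),
            ([0.01, 0.04, 0.03, 0.02], [0.04, 0.04, 0.04, 0.04]),
            ([0.0, 0.0, 0.0], [0.0, 0.0, 0.0]),
        ],
    )
    def test_hand_computed_adjustments(self, p, expected):
        np.testing.assert_allclose(bh_adjust(p), expected, atol=1e-12)

    def test_rejects_values_outside_unit_interval(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @given(
        st.lists(st.floats(min_value=0, max_value=1, allow_nan=False), min_size=1, max_size=40)
    )
    @settings(derandomize=True, max_examples=100)
    def test_matches_stepup_oracle(self, p):
        np.testing.assert_allclose(bh_adjust(p), bh_stepup_oracle(p), atol=1e-12)


class TestDeScreen:
    def test_constant_gene_gets_q_one_and_is_not_retained(self, tiny_labels):
        data = pd.DataFrame(
            {"s1": [1.0, 9.0], "s2": [1.0, 8.0], "s3": [1.0, 2.0], "s4": [1.0, 1.0]},
            index=["flat", "var"],
        )
        matrix = ExpressionMatrix(data)
        stats = de_statistics(matrix, tiny_labels)
        assert stats.loc["flat", "p"] == 1.0
        retained = screen_de_genes(matrix, tiny_labels, fdr_cutoff=0.5)
        assert "flat" not in [r.gene_id for r in retained]

    def test_class_with_fewer_than_two_samples_is_an_error(self, tiny_matrix):
        labels = LabelTable({"s1": "MSI", "s2": "MSS", "s3": "MSS", "s4": "MSS"})
        with pytest.raises(ValueError, match=">=2 samples"):
            de_statistics(tiny_matrix, labels)

    def test_recovers_strongly_shifted_genes(self):
        # 50 genes shifted by 3 SD between classes among 500 nulls, n=30/30
        rng = np.random.default_rng(2024)
        matrix, labels = make_two_class_matrix(
            rng, n_genes=550, n_shifted=50, shift=3.0, n_per_class=30
        )
        retained = {r.gene_id for r in screen_de_genes(matrix, labels, 0.01)}
        shifted = {f"g{i}" for i in range(50)}
        assert len(retained & shifted) >= 45

    def test_max_genes_caps_by_p_value(self):
        rng = np.random.default_rng(5)
        matrix, labels = make_two_class_matrix(
            rng, n_genes=100, n_shifted=20, shift=3.0, n_per_class=20
        )
        capped = screen_de_genes(matrix, labels, 0.01, max_genes=5)
        assert len(capped) == 5


class TestPairCounts:
    def test_perfect_separation(self, tiny_matrix, tiny_labels):
        counts = pair_reo_counts(tiny_matrix, tiny_labels, "g1", "g2")
        np.testing.assert_array_equal(counts, [[2, 0], [0, 2]])

    def test_tie_counts_as_non_pattern(self, tiny_labels):
        data = pd.DataFrame(
            {"s1": [2.0, 2.0], "s2": [3.0, 1.0], "s3": [1.0, 3.0], "s4": [1.0, 3.0]},
            index=["g1", "g2"],
        )
        counts = pair_reo_counts(ExpressionMatrix(data), tiny_labels, "g1", "g2")
        np.testing.assert_array_equal(counts, [[1, 1], [0, 2]])

    def test_direct_count_on_larger_classes(self):
        rng = np.random.default_rng(0)
        n = 10
        g1 = np.concatenate([np.r_[np.ones(9) * 5, 1.0], np.r_[5.0, np.ones(9)]])
        g2 = np.full(2 * n, 3.0)
        samples = [f"x{i}" for i in range(2 * n)]
        matrix = ExpressionMatrix(
            pd.DataFrame([g1, g2], index=["g1", "g2"], columns=samples)
        )
        labels = LabelTable(
            {s: ("MSI" if i < n else "MSS") for i, s in enumerate(samples)}
        )
        counts = pair_reo_counts(matrix, labels, "g1", "g2")
        np.testing.assert_array_equal(counts, [[9, 1], [1, 9]])

    def test_missing_gene_is_named(self, tiny_matrix, tiny_labels):
        with pytest.raises(KeyError, match="nope"):
            pair_reo_counts(tiny_matrix, tiny_labels, "g1", "nope")


class TestFisherAndFd:
    def test_strong_enrichment_matches_enumeration(self):
        p = fisher_exact_p([[9, 1], [1, 9]])
        assert p == pytest.approx(fisher_tail_oracle(9, 1, 1, 9), abs=1e-12)
        assert p == pytest.approx(101 / math.comb(20, 10), abs=1e-12)

    def test_no_enrichment_is_large(self):
        assert fisher_exact_p([[5, 5], [5, 5]]) > 0.5

    def test_anti_pattern_gives_p_one(self):
        assert fisher_exact_p([[0, 10], [10, 0]]) == pytest.approx(1.0)

    def test_rejects_invalid_counts(self):
        with pytest.raises(ValueError):
            fisher_exact_p([[1, -2], [3, 4]])
        with pytest.raises(ValueError):
            fisher_exact_p([[0.5, 1], [1, 1]])

    def test_matches_enumeration_on_all_small_tables(self):
        for n1 in range(1, 9):
            for n2 in range(1, 9):
                for a in range(n1 + 1):
                    for c in range(n2 + 1):
                        table = [[a, n1 - a], [c, n2 - c]]
                        assert fisher_exact_p(table) == pytest.approx(
                            fisher_tail_oracle(a, n1 - a, c, n2 - c), abs=1e-10
                        )

    @pytest.mark.parametrize(
        "table,expected",
        [
            ([[9, 1], [1, 9]], 0.8),
            ([[5, 5], [5, 5]], 0.0),
            ([[10, 0], [0, 10]], 1.0),
        ],
    )
    def test_fd_is_frequency_difference(self, table, expected):
        assert compute_fd(table) == pytest.approx(expected)

    def test_fd_requires_non_empty_classes(self):
        with pytest.raises(ValueError):
            compute_fd([[0, 0], [3, 4]])


class TestSelectCandidatePairs:
    def test_planted_pairs_are_all_recovered(self):
        config = SimulationConfig(
            n_planted_pairs=20, n_genes=60, p_pattern_msi=0.95,
            p_pattern_mss=0.05, seed=11,
        )
        matrix, labels, planted = simulate_dataset(config)
        genes = sorted(matrix.gene_ids)
        pairs = select_candidate_pairs(matrix, labels, genes, fdr_cutoff=0.01)
        found = {ps.genes for ps in pairs}
        assert set(planted) <= found

    def test_pure_noise_yields_almost_no_pairs(self):
        rng = np.random.default_rng(99)
        matrix, labels = make_two_class_matrix(
            rng, n_genes=100, n_shifted=0, shift=0.0, n_per_class=60
        )
        pairs = select_candidate_pairs(
            matrix, labels, matrix.gene_ids, fdr_cutoff=0.01
        )
        assert len(pairs) <= 5

    def test_orientation_makes_fd_non_negative(self, planted_dataset):
        matrix, labels, _, _ = planted_dataset
        genes = [g for g in matrix.gene_ids if g.startswith("P")]
        pairs = select_candidate_pairs(matrix, labels, genes, fdr_cutoff=0.5)
        assert pairs and all(ps.fd >= 0 for ps in pairs)

    def test_invariant_under_monotone_per_sample_transform(self, planted_dataset):
        matrix, labels, _, _ = planted_dataset
        genes = sorted(matrix.gene_ids)[:40]
        before = select_candidate_pairs(matrix, labels, genes, 0.01)
        distorted = apply_monotone_distortion(matrix, seed=123)
        after = select_candidate_pairs(distorted, labels, genes, 0.01)
        assert [ps.genes for ps in before] == [ps.genes for ps in after]
        assert [ps.fd for ps in before] == [ps.fd for ps in after]

    def test_duplicate_genes_rejected(self, tiny_matrix, tiny_labels):
        with pytest.raises(ValueError, match="duplicates"):
            select_candidate_pairs(tiny_matrix, tiny_labels, ["g1", "g1"], 0.01)


def _ps(g1, g2, n1_pattern, fisher_p=0.001, n=10):
    return PairStats(
        gene1=g1, gene2=g2, n1_pattern=n1_pattern, n1_total=n,
        n2_pattern=0, n2_total=n, fisher_p=fisher_p,
    )


class TestRemoveRedundantPairs:
    def test_greedy_chain(self):
        # fds 0.9, 0.85, 0.8: (B,C) loses B to (A,B), freeing (C,D) to be kept
        pairs = [
            _ps("A", "B", 18, n=20),
            _ps("B", "C", 17, n=20),
            _ps("C", "D", 16, n=20),
        ]
        kept = remove_redundant_pairs(pairs)
        assert [ps.genes for ps in kept] == [("A", "B"), ("C", "D")]

    def test_disjoint_pairs_all_kept_sorted_by_fd(self):
        pairs = [_ps("C", "D", 7), _ps("A", "B", 9), _ps("E", "F", 8)]
        kept = remove_redundant_pairs(pairs)
        assert [ps.genes for ps in kept] == [("A", "B"), ("E", "F"), ("C", "D")]

    def test_lexicographic_tie_break(self):
        kept = remove_redundant_pairs([_ps("A", "C", 9), _ps("A", "B", 9)])
        assert [ps.genes for ps in kept] == [("A", "B")]

    @given(st.integers(0, 2**31 - 1))
    @settings(derandomize=True, max_examples=30)
    def test_genes_unique_and_order_independent(self, seed):
        rng = np.random.default_rng(seed)
        genes = [f"G{i}" for i in range(12)]
        pairs = []
        for _ in range(rng.integers(1, 20)):
            g1, g2 = rng.choice(12, size=2, replace=False)
            pairs.append(
                _ps(genes[g1], genes[g2], int(rng.integers(1, 11)),
                    fisher_p=float(rng.random()))
            )
        kept = remove_redundant_pairs(pairs)
        used = [g for ps in kept for g in ps.genes]
        assert len(used) == len(set(used))
        shuffled = list(pairs)
        rng.shuffle(shuffled)
        assert remove_redundant_pairs(shuffled) == kept
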