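"""PCC, mutual ranks, edge selection, network statistics and ROC."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import random_expression
from coexnet import synthio
from coexnet.network import (
    CoexpressionNetwork,
    calibrate_min_abs_pcc,
    compute_mutual_ranks,
    compute_pcc_pairs,
    degree_distribution,
    evaluate_cutoffs_roc,
    network_statistics,
    pearson_correlation,
    select_edges,
)


def naive_pcc(x, y):
    """The plain product-moment formula, written independently."""
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = math.sqrt(sum((a - mx) ** 2 for a in x) * sum((b - my) ** 2 for b in y))
    return num / den


def naive_ranked_pairs(matrix, min_abs_pcc):
    """Double-loop oracle for pair selection and signed mutual ranks."""
    genes = matrix.gene_ids
    values = {g: matrix.df.loc[g].to_numpy() for g in genes}
    pcc = {}
    for a, b in itertools.combinations(genes, 2):
        r = naive_pcc(values[a], values[b])
        if abs(r) >= min_abs_pcc:
            pcc[(a, b)] = r

    def rank(source, partner, r):
        partners = []
        for (x, y), v in pcc.items():
            if source in (x, y):
                other = y if x == source else x
                if (v >= 0) == (r >= 0):
                    partners.append((other, v))
        partners.sort(key=lambda t: (-t[1] if r >= 0 else t[1], t[0]))
        return [p for p, _ in partners].index(partner) + 1

    rows = []
    for (a, b), r in sorted(pcc.items()):
        ra, rb = rank(a, b, r), rank(b, a, r)
        rows.append((a, b, r, ra, rb, math.sqrt(ra * rb)))
    return rows


class TestPearson:
    @pytest.mark.parametrize(
        "x, y, expected",
        [
            ((1, 2, 3), (2, 4, 6), 1.0),
            ((1, 2, 3), (6, 4, 2), -1.0),
            ((1, 2, 3, 4), (1, 3, 2, 4), 0.8),
        ],
    )
    def test_hand_examples(self, x, y, expected):
        assert pearson_correlation(x, y) == pytest.approx(expected)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pearson_correlation([1, 1, 1], [1, 2, 3])

    @given(st.lists(st.floats(0.01, 1e4), min_size=3, max_size=20))
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_self_correlation_is_one(self, xs):
        if len(set(xs)) > 1:
            assert pearson_correlation(xs, xs) == pytest.approx(1.0)


class TestPairTable:
    def test_zero_cutoff_counts_all_pairs(self, tiny_matrix):
        pairs = compute_pcc_pairs(tiny_matrix, 0.0)
        assert len(pairs) == 4 * 3 // 2

    def test_cutoff_one_keeps_only_duplicated_profile(self, tiny_matrix):
        pairs = compute_pcc_pairs(tiny_matrix, 1.0)
        assert list(zip(pairs.gene_a, pairs.gene_b)) == [("g1", "g2")]

    def test_constant_genes_dropped_and_counted(self, tiny_matrix):
        df = tiny_matrix.df.copy()
        df.loc["flat"] = 2.0
        from coexnet.exprfilter import ExpressionMatrix

        pairs = compute_pcc_pairs(ExpressionMatrix(df), 0.0)
        assert pairs.attrs["n_constant_dropped"] == 1
        assert "flat" not in set(pairs.gene_a) | set(pairs.gene_b)

    def test_matches_double_loop_oracle(self):
        matrix = random_expression(50, 8, seed=3)
        got = compute_mutual_ranks(compute_pcc_pairs(matrix, 0.6))
        expected = naive_ranked_pairs(matrix, 0.6)
        assert len(got) == len(expected)
        for row, (a, b, r, ra, rb, mr) in zip(got.itertuples(), expected):
            assert (row.gene_a, row.gene_b) == (a, b)
            assert row.pcc == pytest.approx(r, abs=1e-12)
            assert (row.rank_ab, row.rank_ba) == (ra, rb)
            assert row.mr == pytest.approx(mr)

    def test_gene_order_permutation_invariant(self):
        matrix = random_expression(30, 6, seed=9)
        shuffled = matrix.df.sample(frac=1.0, random_state=1)
        from coexnet.exprfilter import ExpressionMatrix

        a = compute_mutual_ranks(compute_pcc_pairs(matrix, 0.5))
        b = compute_mutual_ranks(compute_pcc_pairs(ExpressionMatrix(shuffled), 0.5))
        pd.testing.assert_frame_equal(
            a.reset_index(drop=True), b.reset_index(drop=True), check_exact=False
        )


class TestMutualRank:
    @pytest.mark.parametrize(
        "ra, rb, mr", [(1, 4, 2.0), (3, 3, 3.0), (3, 10, math.sqrt(30))]
    )
    def test_geometric_mean(self, ra, rb, mr):
        assert math.sqrt(ra * rb) == pytest.approx(mr)
        # and the invariant min <= mr <= max
        assert min(ra, rb) <= mr <= max(ra, rb)

    def test_mr_column_satisfies_formula(self):
        matrix = random_expression(25, 7, seed=4)
        ranked = compute_mutual_ranks(compute_pcc_pairs(matrix, 0.3))
        np.testing.assert_allclose(
            ranked.mr, np.sqrt(ranked.rank_ab * ranked.rank_ba)
        )
        assert (ranked.loc[ranked.pcc < 0, "sign"] == "negative").all()


def _ranked_row(ra, rb, pcc=0.9):
    return pd.DataFrame(
        {
            "gene_a": ["a"], "gene_b": ["b"], "pcc": [pcc],
            "rank_ab": [ra], "rank_ba": [rb],
            "mr": [math.sqrt(ra * rb)], "sign": ["positive"],
        }
    )


class TestSelectEdges:
    @pytest.mark.parametrize(
        "ra, rb, union_kept, intersection_kept",
        [
            (2, 40, True, True),  # rank passes; mr = 8.94 passes
            (10, 10, True, False),  # mr = 10 <= 30 but no rank <= 3
            (50, 50, False, False),  # mr = 50
        ],
    )
    def test_rule_semantics(self, ra, rb, union_kept, intersection_kept):
        ranked = _ranked_row(ra, rb)
        assert (select_edges(ranked, rule="union").n_edges == 1) is union_kept
        assert (
            select_edges(ranked, rule="intersection").n_edges == 1
        ) is intersection_kept

    def test_monotone_in_cutoffs(self):
        matrix = random_expression(40, 6, seed=12)
        ranked = compute_mutual_ranks(compute_pcc_pairs(matrix, 0.4))
        loose = select_edges(ranked, rank_cutoff=5, mr_cutoff=40)
        tight = select_edges(ranked, rank_cutoff=3, mr_cutoff=30)
        tight_pairs = set(zip(tight.edges.gene_a, tight.edges.gene_b))
        loose_pairs = set(zip(loose.edges.gene_a, loose.edges.gene_b))
        assert tight_pairs <= loose_pairs

    def test_bad_cutoffs(self):
        with pytest.raises(ValueError):
            select_edges(_ranked_row(1, 1), rank_cutoff=0)


class TestStatistics:
    def test_printed_table_convention(self):
        # 2E/N for E=630,081, N=31,847 rounds to the published 39.6
        from coexnet.network import _round_half_up

        assert _round_half_up(2 * 630081 / 31847, 1) == 39.6

    def test_small_networks(self):
        edges = pd.DataFrame(
            {"gene_a": [f"a{i}" for i in range(10)],
             "gene_b": [f"b{i}" for i in range(10)],
             "pcc": [1.0] * 10, "rank_ab": [1] * 10, "rank_ba": [1] * 10,
             "mr": [1.0] * 10, "sign": ["positive"] * 10}
        )
        net = CoexpressionNetwork(edges=edges)
        stats = network_statistics(net, genome_size=40)
        assert stats["n_edges"] == 10 and stats["n_nodes"] == 20
        assert stats["mean_edges_per_gene"] == 1.0
        assert stats["coverage_percent"] == 50.0

    def test_self_edges_rejected(self):
        edges = pd.DataFrame({"gene_a": ["a"], "gene_b": ["a"]})
        with pytest.raises(ValueError, match="self-edges"):
            CoexpressionNetwork(edges=edges)


class TestDegreeDistribution:
    @staticmethod
    def _net(pairs):
        edges = pd.DataFrame(pairs, columns=["gene_a", "gene_b"])
        return CoexpressionNetwork(edges=edges)

    def test_triangle(self):
        table, _ = degree_distribution(self._net([("a", "b"), ("b", "c"), ("a", "c")]))
        assert table.to_dict("records") == [{"degree": 2, "gene_count": 3}]

    def test_star(self):
        table, _ = degree_distribution(
            self._net([("hub", f"leaf{i}") for i in range(5)])
        )
        assert dict(zip(table.degree, table.gene_count)) == {1: 5, 5: 1}

    def test_histogram_mass_conserved(self, planted_dataset):
        matrix, _, _ = planted_dataset
        ranked = compute_mutual_ranks(compute_pcc_pairs(matrix, 0.8))
        net = select_edges(ranked)
        table, slope = degree_distribution(net)
        assert int(table.gene_count.sum()) == net.n_nodes


class TestRoc:
    def test_perfect_separation(self):
        ranked = pd.concat(
            [_ranked_row(1, 1).assign(gene_a=f"p{i}", gene_b=f"q{i}") for i in range(5)]
            + [_ranked_row(40, 40, 0.7).assign(gene_a=f"x{i}", gene_b=f"y{i}") for i in range(5)],
            ignore_index=True,
        )
        pos = {(f"p{i}", f"q{i}") for i in range(5)}
        neg = {(f"x{i}", f"y{i}") for i in range(5)}
        _, auc = evaluate_cutoffs_roc(ranked, pos, neg)
        assert auc == pytest.approx(1.0)

    def test_all_tied_is_chance(self):
        ranked = pd.concat(
            [_ranked_row(2, 2).assign(gene_a=f"p{i}", gene_b=f"q{i}") for i in range(4)],
            ignore_index=True,
        )
        pos = {("p0", "q0"), ("p1", "q1")}
        neg = {("p2", "q2"), ("p3", "q3")}
        _, auc = evaluate_cutoffs_roc(ranked, pos, neg)
        assert auc == pytest.approx(0.5)

    def test_random_labels_near_half(self):
        rng = np.random.default_rng(5)
        matrix = random_expression(60, 8, seed=5)
        ranked = compute_mutual_ranks(compute_pcc_pairs(matrix, 0.0))
        pairs = list(zip(ranked.gene_a, ranked.gene_b))
        chosen = rng.permutation(len(pairs))[:1000]
        labels = rng.integers(0, 2, size=len(chosen))
        pos = {pairs[i] for i, l in zip(chosen, labels) if l}
        neg = {pairs[i] for i, l in zip(chosen, labels) if not l}
        _, auc = evaluate_cutoffs_roc(ranked, pos, neg)
        assert auc == pytest.approx(0.5, abs=0.05)

    def test_planted_blocks_separate_well(self, planted_dataset):
        matrix, _, truth = planted_dataset
        ranked = compute_mutual_ranks(compute_pcc_pairs(matrix, 0.6))
        rng = np.random.default_rng(0)
        pos = set()
        for block in truth.planted_blocks.values():
            pos.update(itertools.combinations(sorted(block), 2))
        block_of = {g: b for b, gs in truth.planted_blocks.items() for g in gs}
        genes = matrix.gene_ids
        neg = set()
        while len(neg) < 2000:
            a, b = rng.choice(genes, 2, replace=False)
            if a != b and block_of.get(a) != block_of.get(b):
                neg.add(tuple(sorted((a, b))))
        _, auc = evaluate_cutoffs_roc(ranked, pos, neg)
        assert auc > 0.9


class TestCalibration:
    def test_null_cutoff_controls_chance_pairs(self):
        matrix = random_expression(150, 12, seed=21)
        cutoff = calibrate_min_abs_pcc(matrix, quantile=99.5, seed=1)
        pairs = compute_pcc_pairs(matrix, cutoff)
        n_total = 150 * 149 / 2
        # on pure noise, roughly the top half-percent of pairs survive
        assert len(pairs) / n_total < 0.02
        assert 0.5 < cutoff < 0.95
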