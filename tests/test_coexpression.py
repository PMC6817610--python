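"""PCC, mutual rank, QC and network construction against hand values and oracles."""

import numpy as np
import pandas as pd
import pytest

from omicsforge import coexpression as cx
from omicsforge.io import ExpressionMatrix

from conftest import mutual_rank_bruteforce, random_correlation_matrix


def _matrix(rows: dict[str, list[float]]) -> ExpressionMatrix:
    return ExpressionMatrix(pd.DataFrame(rows).T.astype(float))


class TestPCC:
    @pytest.mark.parametrize(
        "y, expected",
        [([2, 4, 6, 8], 1.0), ([4, 3, 2, 1], -1.0), ([1, 3, 2, 4], 0.8)],
    )
    def test_hand_examples(self, y, expected):
        m = _matrix({"x": [1, 2, 3, 4], "y": y, "z": [5, 1, 4, 2]})
        corr = cx.compute_pcc(m, transform="none")
        assert corr.values[0, 1] == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_genes_dropped_and_listed(self):
        m = _matrix({"flat": [2, 2, 2, 2], "x": [1, 2, 3, 4], "y": [2, 1, 2, 4]})
        corr = cx.compute_pcc(m, transform="none")
        assert corr.dropped_zero_variance == ["flat"]
        assert corr.gene_ids == ["x", "y"]

    def test_too_few_samples_rejected(self):
        m = _matrix({"x": [1, 2], "y": [2, 1]})
        with pytest.raises(ValueError, match="samples"):
            cx.compute_pcc(m)

    def test_all_zero_variance_rejected(self):
        m = _matrix({"a": [1, 1, 1], "b": [2, 2, 2]})
        with pytest.raises(ValueError, match="variance"):
            cx.compute_pcc(m, transform="none")

    def test_symmetry_and_bounds_on_random_data(self):
        rng = np.random.default_rng(0)
        m = ExpressionMatrix(pd.DataFrame(
            rng.gamma(2.0, 10.0, size=(30, 12)),
            index=[f"g{i}" for i in range(30)],
            columns=[f"s{j}" for j in range(12)],
        ))
        corr = cx.compute_pcc(m)
        np.testing.assert_array_equal(corr.values, corr.values.T)
        assert np.abs(corr.values).max() <= 1.0


class TestQC:
    def test_identical_samples_never_flagged(self):
        # every sample sees the same expression vector -> pairwise corr 1
        m = _matrix({"a": [1, 1, 1], "b": [5, 5, 5], "c": [3, 3, 3]})
        res = cx.qc_filter_samples(m, min_mean_corr=0.99, transform="none")
        assert res.flagged == []
        assert res.kept == m.sample_ids

    def test_noise_sample_flagged(self):
        rng = np.random.default_rng(42)
        base = rng.gamma(2.0, 10.0, size=50)
        good = np.column_stack([base * f + rng.normal(0, 0.5, 50) for f in (1.0, 1.1, 0.9)])
        noise = rng.permutation(base)[:, None]
        data = np.clip(np.column_stack([good, noise]), 0, None)
        m = ExpressionMatrix(pd.DataFrame(
            data, index=[f"g{i}" for i in range(50)], columns=["s1", "s2", "s3", "odd"]
        ))
        res = cx.qc_filter_samples(m, min_mean_corr=0.5)
        assert res.flagged == ["odd"]

    def test_vacuous_threshold_flags_nothing(self):
        rng = np.random.default_rng(1)
        m = ExpressionMatrix(pd.DataFrame(
            rng.random((10, 5)), index=[f"g{i}" for i in range(10)],
            columns=[f"s{j}" for j in range(5)],
        ))
        assert cx.qc_filter_samples(m, min_mean_corr=-1).flagged == []

    def test_too_few_samples_rejected(self):
        m = _matrix({"a": [1, 2], "b": [2, 1]})
        with pytest.raises(ValueError):
            cx.qc_filter_samples(m)


class TestMutualRank:
    def test_mutual_top_partners_have_mr_one(self):
        # gA and gB are each other's best partner by construction
        m = _matrix({
            "gA": [1, 2, 3, 4, 5], "gB": [1.1, 2, 3, 4, 4.9],
            "gC": [5, 1, 4, 2, 3], "gD": [2, 5, 1, 4, 2],
        })
        corr = cx.compute_pcc(m, transform="none")
        for mode in ("geometric_mean", "product"):
            mr = cx.compute_mutual_rank(corr, mode=mode)
            assert mr.values[0, 1] == pytest.approx(1.0)

    @pytest.mark.parametrize("mode", ["geometric_mean", "product"])
    @pytest.mark.parametrize("tail", ["positive", "negative"])
    def test_matches_bruteforce_on_random_matrices(self, mode, tail):
        rng = np.random.default_rng(7)
        for _ in range(5):
            n = int(rng.integers(5, 20))
            genes = [f"g{i:02d}" for i in range(n)]
            c = random_correlation_matrix(rng, n)
            corr = cx.CorrelationMatrix(genes, c)
            mr = cx.compute_mutual_rank(corr, tail=tail, mode=mode)
            oracle = mutual_rank_bruteforce(genes, c, mode=mode, tail=tail)
            np.testing.assert_allclose(mr.values, oracle, atol=1e-9)

    def test_symmetric_and_at_least_one(self):
        rng = np.random.default_rng(3)
        c = random_correlation_matrix(rng, 15)
        mr = cx.compute_mutual_rank(cx.CorrelationMatrix([f"g{i}" for i in range(15)], c))
        np.testing.assert_allclose(mr.values, mr.values.T)
        off = mr.values[~np.eye(15, dtype=bool)]
        assert off.min() >= 1.0

    def test_small_matrix_rejected(self):
        corr = cx.CorrelationMatrix(["a", "b"], np.eye(2))
        with pytest.raises(ValueError):
            cx.compute_mutual_rank(corr)


class TestBuildNetwork:
    def _random_inputs(self, seed, n=12):
        rng = np.random.default_rng(seed)
        genes = [f"g{i:02d}" for i in range(n)]
        corr = cx.CorrelationMatrix(genes, random_correlation_matrix(rng, n))
        mr_pos = cx.compute_mutual_rank(corr, tail="positive")
        mr_neg = cx.compute_mutual_rank(corr, tail="negative")
        return genes, corr, mr_pos, mr_neg

    def test_edges_match_exhaustive_pairwise_filter(self):
        genes, corr, mr_pos, mr_neg = self._random_inputs(11)
        net = cx.build_network(corr, mr_pos, mr_neg,
                               pcc_min_pos=0.3, pcc_max_neg=-0.3, mr_max=6)
        expected = set()
        for i in range(len(genes)):
            for j in range(i + 1, len(genes)):
                if corr.values[i, j] >= 0.3 and mr_pos.values[i, j] <= 6:
                    expected.add((genes[i], genes[j], "positive"))
                elif corr.values[i, j] <= -0.3 and mr_neg.values[i, j] <= 6:
                    expected.add((genes[i], genes[j], "negative"))
        got = {(a, b, attrs["sign"]) for a, b, attrs in net.edges()}
        assert got == expected

    def test_thresholds_below_everything_give_empty_network(self):
        genes, corr, mr_pos, _ = self._random_inputs(5)
        net = cx.build_network(corr, mr_pos, pcc_min_pos=1.1, mr_max=0.5)
        assert net.n_edges == 0
        assert net.nodes == sorted(genes)  # isolated nodes retained

    def test_published_presets(self):
        assert cx.PRESETS["global"] == {
            "pcc_min_pos": 0.8, "pcc_max_neg": -0.3, "mr_max": 55.0}
        assert cx.PRESETS["conditional"]["mr_max"] == 50.0

    def test_stricter_thresholds_never_add_edges(self):
        _, corr, mr_pos, mr_neg = self._random_inputs(23)
        loose = cx.build_network(corr, mr_pos, mr_neg, pcc_min_pos=0.2, mr_max=8)
        for pcc_min, mr_max in [(0.4, 8), (0.2, 4), (0.6, 2)]:
            tight = cx.build_network(corr, mr_pos, mr_neg,
                                     pcc_min_pos=pcc_min, mr_max=mr_max)
            assert tight.edge_set("positive") <= loose.edge_set("positive")

    def test_invariant_under_gene_permutation(self):
        rng = np.random.default_rng(9)
        data = rng.gamma(2.0, 10.0, size=(10, 30))
        genes = [f"g{i}" for i in range(10)]
        cols = [f"s{j}" for j in range(30)]

        def edges(order):
            m = ExpressionMatrix(pd.DataFrame(data[order], index=[genes[i] for i in order], columns=cols))
            corr = cx.compute_pcc(m)
            net = cx.build_network(corr, cx.compute_mutual_rank(corr),
                                   pcc_min_pos=0.2, mr_max=5)
            return net.edge_set()

        identity = list(range(10))
        shuffled = list(rng.permutation(10))
        assert edges(identity) == edges(shuffled)

    def test_mismatched_gene_ids_rejected(self):
        _, corr, mr_pos, _ = self._random_inputs(2)
        other = cx.MutualRankMatrix(["x"] * 0 + [f"h{i}" for i in range(12)], mr_pos.values)
        with pytest.raises(ValueError, match="gene ids"):
            cx.build_network(corr, other)


class TestCompareNetworks:
    def _net(self, edges):
        import networkx as nx
        g = nx.Graph()
        for a, b in edges:
            g.add_edge(a, b, pcc=0.9, mr=1.0, sign="positive")
        return cx.CoexpressionNetwork(graph=g)

    def test_identical_networks_jaccard_one(self):
        n = self._net([("a", "b"), ("b", "c")])
        assert cx.compare_networks(n, n).jaccard == 1.0

    def test_disjoint_edge_sets_jaccard_zero(self):
        a = self._net([("a", "b")])
        b = self._net([("c", "d")])
        assert cx.compare_networks(a, b).jaccard == 0.0

    def test_partial_overlap(self):
        a = self._net([("a", "b"), ("b", "c")])
        b = self._net([("a", "b"), ("c", "d")])
        res = cx.compare_networks(a, b)
        assert res.jaccard == pytest.approx(1 / 3)
        assert res.shared_edges == {("a", "b")}

    def test_neighbor_overlap_table(self):
        a = self._net([("a", "b"), ("a", "c")])
        b = self._net([("a", "b")])
        tab = cx.compare_networks(a, b).neighbor_overlap
        assert tab.loc["a", "shared"] == 1
        assert tab.loc["a", "jaccard"] == pytest.approx(0.5)


def test_edge_list_round_trip(tmp_path):
    rng = np.random.default_rng(4)
    genes = [f"g{i:02d}" for i in range(8)]
    corr = cx.CorrelationMatrix(genes, random_correlation_matrix(rng, 8))
    net = cx.build_network(corr, cx.compute_mutual_rank(corr), pcc_min_pos=0.1, mr_max=5)
    path = tmp_path / "edges.tsv"
    cx.write_edge_list(net, path)
    back = cx.read_edge_list(path)
    assert back.edge_set() == net.edge_set()
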