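"""Co-expression network: correlations, soft threshold, edge filtering."""
import numpy as np
import pandas as pd
import pytest

from cernet.coexpr import (adjacency, build_lncrna_pcg_network,
                           correlation_matrix, extract_subnetwork,
                           network_to_frame, pick_soft_power, scale_free_r2)
from cernet.synthdata import CohortConfig, generate_cohort

from helpers import pearson_with_p


class TestCorrelationMatrix:
    def test_diagonal_and_anticorrelation(self):
        expr = pd.DataFrame({"s1": [1, 3], "s2": [2, 2], "s3": [3, 1]},
                            index=["x", "y"], dtype=float)
        corr = correlation_matrix(expr)
        assert corr.loc["x", "x"] == 1.0
        assert corr.loc["x", "y"] == pytest.approx(-1.0)

    def test_matches_pairwise_oracle(self):
        rng = np.random.default_rng(2)
        expr = pd.DataFrame(rng.normal(size=(20, 10)))
        corr = correlation_matrix(expr)
        for i in range(20):
            for j in range(i + 1, 20):
                r, _ = pearson_with_p(expr.iloc[i], expr.iloc[j])
                assert corr.iloc[i, j] == pytest.approx(r, abs=1e-12)

    def test_zero_variance_dropped_with_warning(self):
        expr = pd.DataFrame({"s1": [1, 5], "s2": [2, 5], "s3": [3, 5]},
                            index=["ok", "flat"], dtype=float)
        with pytest.warns(UserWarning, match="zero-variance"):
            corr = correlation_matrix(expr)
        assert list(corr.index) == ["ok"]

    def test_needs_three_samples(self):
        expr = pd.DataFrame({"s1": [1.0], "s2": [2.0]})
        with pytest.raises(ValueError):
            correlation_matrix(expr)


class TestAdjacency:
    def test_perfect_correlation_gives_one(self):
        corr = pd.DataFrame([[1.0, -1.0], [-1.0, 1.0]], index=list("ab"),
                            columns=list("ab"))
        adj = adjacency(corr, 6)
        assert adj.loc["a", "b"] == 1.0
        assert adj.loc["a", "a"] == 0.0  # diagonal zeroed

    def test_power_six_arithmetic(self):
        corr = pd.DataFrame([[1.0, 0.8], [0.8, 1.0]], index=list("ab"),
                            columns=list("ab"))
        assert adjacency(corr, 6).loc["a", "b"] == pytest.approx(0.262144)

    def test_monotone_nonincreasing_in_power(self):
        rng = np.random.default_rng(3)
        r = rng.uniform(-0.99, 0.99, (5, 5))
        corr = pd.DataFrame((r + r.T) / 2)
        np.fill_diagonal(corr.values, 1.0)
        prev = adjacency(corr, 1)
        for power in range(2, 8):
            cur = adjacency(corr, power)
            assert (cur.to_numpy() <= prev.to_numpy() + 1e-15).all()
            prev = cur

    def test_power_below_one_rejected(self):
        with pytest.raises(ValueError):
            adjacency(pd.DataFrame([[1.0]]), 0.5)


class TestPickSoftPower:
    def _oracle_pick(self, corr, r2_min=0.8):
        for beta in range(1, 21):
            if self._oracle_r2(adjacency(corr, beta)) >= r2_min:
                return beta
        return 6

    @staticmethod
    def _oracle_r2(adj, n_bins=10):
        # independent re-computation: bin degrees, regress log-log, square r
        k = np.asarray(adj).sum(axis=0)
        k = k[k > 0]
        if k.size < 3 or np.ptp(k) == 0:
            return 0.0
        edges = np.linspace(k.min(), k.max(), n_bins + 1)
        idx = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
        pts = [(np.log10(k[idx == b].mean()), np.log10((idx == b).sum() / k.size))
               for b in range(n_bins) if (idx == b).any()]
        if len(pts) < 3:
            return 0.0
        x, y = map(np.array, zip(*pts))
        if np.ptp(x) == 0:
            return 0.0
        return float(np.corrcoef(x, y)[0, 1] ** 2)

    def test_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(5):
            x = rng.normal(size=(40, 12))
            blocks = rng.integers(0, 3, 40)
            x += rng.normal(size=(3, 12))[blocks] * 1.5
            corr = correlation_matrix(pd.DataFrame(x))
            import warnings
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                assert pick_soft_power(corr) == self._oracle_pick(corr)

    def test_smallest_qualifying_power_wins(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=(40, 12))
        corr = correlation_matrix(pd.DataFrame(x))
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            beta = pick_soft_power(corr)
        for smaller in range(1, beta):
            assert scale_free_r2(adjacency(corr, smaller)) < 0.8

    def test_fallback_is_six_with_warning(self):
        # two features cannot produce a meaningful degree distribution
        corr = pd.DataFrame([[1.0, 0.5], [0.5, 1.0]], index=list("ab"),
                            columns=list("ab"))
        with pytest.warns(UserWarning, match="falling back"):
            assert pick_soft_power(corr) == 6


class TestNetworkConstruction:
    @staticmethod
    def _toy():
        ids = ["L1", "L2", "G1", "G2", "G3"]
        biotypes = pd.Series(["lncRNA", "lncRNA", "mRNA", "mRNA", "mRNA"],
                             index=ids)
        adj = pd.DataFrame(0.0, index=ids, columns=ids)
        vals = {("L1", "G1"): 0.5, ("L1", "G2"): 0.01, ("L2", "G3"): 0.03,
                ("L1", "L2"): 0.2, ("G1", "G2"): 0.9, ("G2", "G3"): 0.015}
        for (u, v), a in vals.items():
            adj.loc[u, v] = adj.loc[v, u] = a
        return adj, biotypes

    def test_toy_matches_brute_force_filter(self):
        adj, biotypes = self._toy()
        net = build_lncrna_pcg_network(adj, biotypes, threshold=0.02)
        expected = set()
        for u in adj.index:
            for v in adj.columns:
                if u < v and adj.loc[u, v] > 0.02 and \
                        "lncRNA" in (biotypes[u], biotypes[v]):
                    expected.add((u, v))
        assert {tuple(sorted(e)) for e in net.edges} == expected

    def test_pcg_pcg_pair_excluded_even_when_strong(self):
        adj, biotypes = self._toy()
        net = build_lncrna_pcg_network(adj, biotypes, threshold=0.02)
        assert not net.has_edge("G1", "G2")  # adjacency 0.9 but no lncRNA

    def test_all_below_threshold_gives_empty_edge_set(self):
        adj, biotypes = self._toy()
        net = build_lncrna_pcg_network(adj, biotypes, threshold=1.0)
        assert net.number_of_edges() == 0

    def test_edge_count_conserved(self):
        adj, biotypes = self._toy()
        net = build_lncrna_pcg_network(adj, biotypes, threshold=0.02)
        a = adj.to_numpy()
        iu, ju = np.triu_indices(len(adj), 1)
        is_lnc = (biotypes.loc[adj.index] == "lncRNA").to_numpy()
        n_pass = int(((a[iu, ju] > 0.02) & (is_lnc[iu] | is_lnc[ju])).sum())
        assert net.number_of_edges() == n_pass

    def test_threshold_is_strict(self):
        ids = ["L1", "G1"]
        adj = pd.DataFrame([[0.0, 0.02], [0.02, 0.0]], index=ids, columns=ids)
        biotypes = pd.Series(["lncRNA", "mRNA"], index=ids)
        net = build_lncrna_pcg_network(adj, biotypes, threshold=0.02)
        assert net.number_of_edges() == 0  # "higher than", not ">="

    def test_unknown_biotype_errors_with_name(self):
        ids = ["L1", "X9"]
        adj = pd.DataFrame(0.0, index=ids, columns=ids)
        biotypes = pd.Series(["lncRNA", "rRNA"], index=ids)
        with pytest.raises(ValueError, match="X9"):
            build_lncrna_pcg_network(adj, biotypes)

    def test_mirnas_excluded(self):
        ids = ["L1", "M1"]
        adj = pd.DataFrame([[0.0, 0.9], [0.9, 0.0]], index=ids, columns=ids)
        biotypes = pd.Series(["lncRNA", "miRNA"], index=ids)
        net = build_lncrna_pcg_network(adj, biotypes)
        assert "M1" not in net.nodes


class TestExtractSubnetwork:
    def test_full_node_set_is_identity(self):
        adj, biotypes = TestNetworkConstruction._toy()
        net = build_lncrna_pcg_network(adj, biotypes)
        sub = extract_subnetwork(net, set(net.nodes))
        assert set(sub.edges) == set(net.edges)

    def test_star_hub_keeps_everything(self):
        import networkx as nx
        star = nx.star_graph(["hub", "a", "b", "c"])
        sub = extract_subnetwork(star, {"hub"})
        assert sub.number_of_edges() == 3

    def test_random_toy_matches_brute_force(self):
        import networkx as nx
        rng = np.random.default_rng(12)
        g = nx.gnp_random_graph(15, 0.3, seed=4)
        node_set = set(rng.choice(15, 5, replace=False).tolist())
        sub = extract_subnetwork(g, node_set)
        expected = {(u, v) for u, v in g.edges
                    if u in node_set or v in node_set}
        assert {tuple(sorted(e)) for e in sub.edges} == \
               {tuple(sorted(e)) for e in expected}
        assert set(sub.nodes) == {n for e in expected for n in e}

    def test_disjoint_node_set_warns_and_empties(self):
        import networkx as nx
        g = nx.path_graph(3)
        with pytest.warns(UserWarning, match="disjoint"):
            sub = extract_subnetwork(g, {"absent"})
        assert sub.number_of_nodes() == 0

    def test_input_unmodified(self):
        import networkx as nx
        g = nx.path_graph(5)
        before = set(g.edges)
        extract_subnetwork(g, {0})
        assert set(g.edges) == before


class TestBlockStructure:
    def test_within_block_above_between_block_below(self):
        """Planted co-expression blocks separate across the adjacency
        threshold: within-block pairs land above 0.02, between-block pairs
        below (aggregated over 20 seeds at power 6)."""
        within_above = within_total = between_below = between_total = 0
        for seed in range(20):
            c = generate_cohort(CohortConfig(
                n_mrna=24, n_lncrna=12, n_mirna=5, n_stable_mirna=1,
                n_per_group=30, n_circuits=0, de_fraction=0.0,
                n_blocks=3, block_sd=1.2, dispersion=0.05, seed=seed))
            x = np.log2(c.rna.values + 1.0)
            adj = adjacency(correlation_matrix(x), 6)
            blk = c.blocks.loc[adj.index].to_numpy()
            a = adj.to_numpy()
            iu, ju = np.triu_indices(len(adj), 1)
            same = blk[iu] == blk[ju]
            within_above += int((a[iu, ju][same] > 0.02).sum())
            within_total += int(same.sum())
            between_below += int((a[iu, ju][~same] < 0.02).sum())
            between_total += int((~same).sum())
        assert within_above / within_total >= 0.9
        assert between_below / between_total >= 0.95


def test_network_frame_round_trips_edges():
    adj, biotypes = TestNetworkConstruction._toy()
    corr = adj.copy()
    net = build_lncrna_pcg_network(adj, biotypes, corr=corr)
    frame = network_to_frame(net)
    assert len(frame) == net.number_of_edges()
    assert set(frame.columns) == {"u", "v", "weight", "sign",
                                  "biotype_u", "biotype_v"}
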