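"""Bridge centralities and the bootstrap difference test."""

from itertools import permutations

import numpy as np
import pytest

import gestnet as gn


def net(edges, labels):
    """Dense weight matrix from an edge dict {(a, b): w}."""
    m = np.zeros((len(labels), len(labels)))
    idx = {lab: i for i, lab in enumerate(labels)}
    for (a, b), w in edges.items():
        m[idx[a], idx[b]] = m[idx[b], idx[a]] = w
    return m


class TestBridgeExpectedInfluence:
    def test_within_only_is_zero(self):
        labels = ("a", "b", "c")
        m = net({("a", "b"): 0.5}, labels)
        part = {"a": 0, "b": 0, "c": 1}
        assert gn.bridge_expected_influence(m, labels, part, "a") == 0.0

    def test_signed_sum(self):
        labels = ("a", "b", "c", "d")
        m = net({("a", "b"): 0.3, ("a", "c"): -0.1, ("a", "d"): 0.7}, labels)
        part = {"a": 0, "b": 1, "c": 1, "d": 0}
        assert gn.bridge_expected_influence(m, labels, part, "a") == \
            pytest.approx(0.2)

    def test_handshake_identity(self, rng):
        labels = tuple(f"n{i}" for i in range(7))
        m = np.zeros((7, 7))
        for i in range(7):
            for j in range(i + 1, 7):
                if rng.random() < 0.6:
                    m[i, j] = m[j, i] = rng.uniform(-0.5, 0.5)
        part = {lab: i % 3 for i, lab in enumerate(labels)}
        total_bei = sum(gn.bridge_expected_influence(m, labels, part, lab)
                        for lab in labels)
        comm = np.array([part[lab] for lab in labels])
        cross = comm[:, None] != comm[None, :]
        assert total_bei == pytest.approx((m * cross).sum())


class TestBridgeCloseness:
    def test_single_out_neighbor(self):
        labels = ("a", "b")
        m = net({("a", "b"): 0.5}, labels)
        part = {"a": 0, "b": 1}
        # distance = 1/0.5 = 2, mean = 2, BCL = 0.5
        assert gn.bridge_closeness(m, labels, part, "a") == pytest.approx(0.5)

    def test_disconnected_gives_zero(self):
        labels = ("a", "b", "c")
        m = net({("a", "b"): 0.5}, labels)
        part = {"a": 0, "b": 0, "c": 1}
        assert gn.bridge_closeness(m, labels, part, "a") == 0.0

    def test_doubling_weights_doubles_bcl(self, rng):
        labels = tuple(f"n{i}" for i in range(6))
        m = np.zeros((6, 6))
        for i in range(6):
            for j in range(i + 1, 6):
                m[i, j] = m[j, i] = rng.uniform(0.1, 0.6)
        part = {lab: i % 2 for i, lab in enumerate(labels)}
        for lab in labels:
            a = gn.bridge_closeness(m, labels, part, lab)
            b = gn.bridge_closeness(2 * m, labels, part, lab)
            assert b == pytest.approx(2 * a)


def brute_force_bbw(m, labels, part):
    """Exhaustive shortest-path enumeration over all simple paths."""
    n = len(labels)
    idx = {lab: i for i, lab in enumerate(labels)}
    score = {lab: 0.0 for lab in labels}
    for si in range(n):
        for ti in range(si + 1, n):
            s, t = labels[si], labels[ti]
            if part[s] == part[t]:
                continue
            best, paths = np.inf, []
            for k in range(n):
                for mid in permutations([x for x in range(n) if x not in (si, ti)], k):
                    path = [si, *mid, ti]
                    if any(m[path[a], path[a + 1]] == 0 for a in range(len(path) - 1)):
                        continue
                    length = sum(1.0 / abs(m[path[a], path[a + 1]])
                                 for a in range(len(path) - 1))
                    if length < best - 1e-12:
                        best, paths = length, [path]
                    elif abs(length - best) <= 1e-12:
                        paths.append(path)
            for path in paths:
                for v in path[1:-1]:
                    score[labels[v]] += 1.0 / len(paths)
    return score


class TestBridgeBetweenness:
    def test_three_node_path(self):
        labels = ("u", "v", "w")
        m = net({("u", "v"): 0.5, ("v", "w"): 0.5}, labels)
        part = {"u": 0, "v": 0, "w": 1}
        assert gn.bridge_betweenness(m, labels, part, "v") == pytest.approx(1.0)

    def test_leaf_is_zero(self):
        labels = ("u", "v", "w")
        m = net({("u", "v"): 0.5, ("v", "w"): 0.5}, labels)
        part = {"u": 0, "v": 0, "w": 1}
        assert gn.bridge_betweenness(m, labels, part, "u") == 0.0

    def test_tied_geodesics_split_fractionally(self):
        # two equal-length 2-hop routes from s to t
        labels = ("s", "x", "y", "t")
        m = net({("s", "x"): 0.5, ("x", "t"): 0.5,
                 ("s", "y"): 0.5, ("y", "t"): 0.5}, labels)
        part = {"s": 0, "x": 0, "y": 0, "t": 1}
        assert gn.bridge_betweenness(m, labels, part, "x") == pytest.approx(0.5)
        assert gn.bridge_betweenness(m, labels, part, "y") == pytest.approx(0.5)

    @pytest.mark.parametrize("n", [5, 6])
    def test_exhaustive_oracle(self, rng, n):
        for _ in range(4):
            m = np.zeros((n, n))
            for i in range(n):
                for j in range(i + 1, n):
                    if rng.random() < 0.6:
                        m[i, j] = m[j, i] = rng.uniform(0.1, 1.0)
            labels = tuple(f"n{i}" for i in range(n))
            part = {lab: i % 2 for i, lab in enumerate(labels)}
            expected = brute_force_bbw(m, labels, part)
            scores = gn.bridge_scores(m, part, labels)
            for _, row in scores.iterrows():
                assert row.bbw == pytest.approx(expected[row.node], abs=1e-9)


class TestMetricProperties:
    def test_invariant_to_community_relabeling(self, network_1000, partition_1000):
        base = gn.bridge_scores(network_1000, partition_1000.membership)
        relabeled = {k: 10 - v for k, v in partition_1000.membership.items()}
        moved = gn.bridge_scores(network_1000, relabeled)
        assert np.allclose(base[["bei", "bcl", "bbw"]].to_numpy(),
                           moved[["bei", "bcl", "bbw"]].to_numpy())

    def test_hub_carrying_all_cross_edges_dominates(self):
        labels = ("h", "a1", "a2", "b1", "b2")
        m = net({("h", "a1"): 0.4, ("h", "a2"): 0.4,
                 ("h", "b1"): 0.4, ("h", "b2"): 0.4,
                 ("a1", "a2"): 0.3, ("b1", "b2"): 0.3}, labels)
        part = {"h": 0, "a1": 0, "a2": 0, "b1": 1, "b2": 1}
        scores = gn.bridge_scores(m, part, labels).set_index("node")
        for metric in ("bei", "bcl", "bbw"):
            assert scores.loc["h", metric] == scores[metric].max()


class TestDifferenceTest:
    def test_seed_contract(self, subscales_1000, network_1000, partition_1000):
        kw = dict(metric="bei", n_boot=40, seed=6)
        a = gn.bridge_difference_test(subscales_1000, network_1000,
                                      partition_1000.membership, **kw)
        b = gn.bridge_difference_test(subscales_1000, network_1000,
                                      partition_1000.membership, **kw)
        assert np.array_equal(a.diff_lower, b.diff_lower)
        assert np.array_equal(a.significant, b.significant)

    def test_significance_matches_ci_rule(self, subscales_1000, network_1000,
                                          partition_1000):
        res = gn.bridge_difference_test(subscales_1000, network_1000,
                                        partition_1000.membership,
                                        metric="bei", n_boot=60, seed=8)
        off = ~np.eye(len(res.node_labels), dtype=bool)
        expected = (res.diff_lower > 0) | (res.diff_upper < 0)
        assert np.array_equal(res.significant[off], expected[off])

    def test_exchangeable_null_rate(self):
        """Two generating-role-identical nodes: their BEI difference should be
        declared significant at roughly the nominal 5% rate."""
        pcor = np.eye(4)
        # a and b play identical roles bridging to c (communities: {a,b},{c,d})
        pcor[0, 2] = pcor[2, 0] = 0.25
        pcor[1, 2] = pcor[2, 1] = 0.25
        gt = gn.GroundTruthNetwork(node_labels=("a", "b", "c", "d"),
                                   pcor=pcor,
                                   communities={"a": 0, "b": 0, "c": 1, "d": 1})
        part = dict(gt.communities)
        hits = 0
        n_sim = 60
        for s in range(n_sim):
            df = gn.simulate_subscales(gt, 300, seed=1000 + s)
            mask = np.ones((4, 4), dtype=bool)
            np.fill_diagonal(mask, False)
            netw = gn.EstimatedNetwork(
                node_labels=gt.node_labels,
                weights=np.zeros((4, 4)), included=mask,
                ci_lower=np.zeros((4, 4)), ci_upper=np.zeros((4, 4)),
                n=300, n_boot=0, alpha=0.05)
            res = gn.bridge_difference_test(df, netw, part, metric="bei",
                                            n_boot=150, seed=s)
            i, j = 0, 1
            if res.significant[i, j]:
                hits += 1
        rate = hits / n_sim
        # nominal 0.05; binomial sd ~ 0.028 at 60 sims
        assert rate <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / n_sim)

    def test_unknown_metric_rejected(self, subscales_1000, network_1000,
                                     partition_1000):
        with pytest.raises(ValueError, match="metric"):
            gn.bridge_difference_test(subscales_1000, network_1000,
                                      partition_1000.membership,
                                      metric="degree", n_boot=5, seed=0)
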