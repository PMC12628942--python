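import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from networkx.algorithms.community import modularity as nx_modularity

from drynet import (AbundanceMatrix, fast_greedy_partition, module_eigengenes,
                    module_env_correlation, zi_pi_roles)
from drynet.keystones import Partition, classify_role
from drynet.netbuild import SignedNetwork
from drynet.tables_io import SampleFrame

from conftest import make_signed_network


def set_partitions(items):
    """All set partitions of ``items`` (exhaustive modularity oracle)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for partial in set_partitions(rest):
        for i in range(len(partial)):
            yield partial[:i] + [[first] + partial[i]] + partial[i + 1:]
        yield [[first]] + partial


def exhaustive_best_q(graph):
    """Maximum modularity over every partition, via networkx's (unweighted) Q."""
    return max(nx_modularity(graph, [set(b) for b in partition], weight=None)
               for partition in set_partitions(graph.nodes))


def _signed(graph):
    nx.set_edge_attributes(graph, "positive", "sign")
    return SignedNetwork(graph)


class TestFastGreedy:
    def test_two_triangles_reach_exhaustive_optimum(self):
        graph = nx.Graph([("a", "b"), ("b", "c"), ("a", "c"),
                          ("x", "y"), ("y", "z"), ("x", "z")])
        part = fast_greedy_partition(_signed(graph))
        assert part.Q == pytest.approx(0.5)
        assert exhaustive_best_q(graph) == pytest.approx(0.5)
        assert part.n_modules == 2
        assert {part.membership[n] for n in "abc"} != \
               {part.membership[n] for n in "xyz"}

    def test_complete_graph_is_one_module(self):
        graph = nx.complete_graph(5)
        part = fast_greedy_partition(_signed(graph))
        assert part.Q == pytest.approx(0.0)
        assert part.n_modules == 1
        assert exhaustive_best_q(graph) == pytest.approx(0.0)

    @pytest.mark.parametrize("seed", [1, 2, 3, 4])
    def test_never_exceeds_exhaustive_optimum(self, seed):
        rng = np.random.default_rng(seed)
        while True:
            graph = nx.gnp_random_graph(7, 0.35, seed=int(rng.integers(1e6)))
            if nx.is_connected(graph) and graph.number_of_edges() >= 1:
                break
        part = fast_greedy_partition(_signed(graph))
        assert part.Q <= exhaustive_best_q(graph) + 1e-12

    def test_deterministic_across_runs(self):
        graph = nx.karate_club_graph()
        a = fast_greedy_partition(_signed(graph))
        b = fast_greedy_partition(_signed(graph.copy()))
        assert a.membership == b.membership and a.Q == b.Q

    def test_q_matches_networkx_definition(self):
        # unweighted modularity of the returned membership, independent route
        graph = nx.karate_club_graph()
        part = fast_greedy_partition(_signed(graph))
        comms = {}
        for node, mod in part.membership.items():
            comms.setdefault(mod, set()).add(node)
        assert part.Q == pytest.approx(
            nx_modularity(graph, list(comms.values()), weight=None))

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            fast_greedy_partition(SignedNetwork(nx.Graph()))


TWO_MODULE_GRAPH = [
    # module 1: n0..n5 (dense), module 2: n6..n11 (dense), 3 bridges
    ("n0", "n1"), ("n0", "n2"), ("n1", "n2"), ("n2", "n3"), ("n3", "n4"),
    ("n4", "n5"), ("n3", "n5"), ("n0", "n4"),
    ("n6", "n7"), ("n6", "n8"), ("n7", "n8"), ("n8", "n9"), ("n9", "n10"),
    ("n10", "n11"), ("n9", "n11"), ("n6", "n10"),
    ("n5", "n6"), ("n2", "n9"), ("n4", "n11"),
]
TWO_MODULE_PARTITION = {f"n{i}": (1 if i < 6 else 2) for i in range(12)}


def brute_force_zi_pi(edges, membership):
    """Direct kappa-counting oracle for Zi and Pi."""
    adj = {}
    for u, v in edges:
        adj.setdefault(u, set()).add(v)
        adj.setdefault(v, set()).add(u)
    kappa = {n: {} for n in adj}
    for n in adj:
        for m in adj[n]:
            kappa[n][membership[m]] = kappa[n].get(membership[m], 0) + 1
    out = {}
    for n in adj:
        own = membership[n]
        intra = [kappa[x].get(membership[x], 0) for x in adj
                 if membership[x] == own]
        mean = sum(intra) / len(intra)
        sd = (sum((v - mean) ** 2 for v in intra) / len(intra)) ** 0.5
        zi = (kappa[n].get(own, 0) - mean) / sd if sd > 0 else 0.0
        k = len(adj[n])
        pi = 1.0 - sum((c / k) ** 2 for c in kappa[n].values())
        out[n] = (zi, pi)
    return out


class TestZiPi:
    def test_matches_brute_force_oracle(self):
        net = make_signed_network(TWO_MODULE_GRAPH)
        sizes = {1: 6, 2: 6}
        roles = zi_pi_roles(net, Partition(TWO_MODULE_PARTITION, 0.0, sizes))
        oracle = brute_force_zi_pi(TWO_MODULE_GRAPH, TWO_MODULE_PARTITION)
        for node, (zi, pi) in oracle.items():
            assert roles.table.at[node, "Zi"] == pytest.approx(zi)
            assert roles.table.at[node, "Pi"] == pytest.approx(pi)

    def test_all_links_internal_gives_zero_pi(self):
        net = make_signed_network([("a", "b"), ("b", "c"), ("a", "c")])
        roles = zi_pi_roles(net, Partition({"a": 1, "b": 1, "c": 1}, 0.0, {1: 3}))
        assert (roles.table["Pi"] == 0.0).all()

    def test_even_spread_over_four_modules(self):
        edges = [("hub", x) for x in "abcd"]
        membership = {"hub": 1, "a": 1, "b": 2, "c": 3, "d": 4}
        net = make_signed_network(edges)
        roles = zi_pi_roles(net, Partition(membership, 0.0,
                                           {1: 2, 2: 1, 3: 1, 4: 1}))
        assert roles.table.at["hub", "Pi"] == pytest.approx(0.75)

    def test_link_conservation(self):
        net = make_signed_network(TWO_MODULE_GRAPH)
        roles = zi_pi_roles(net, Partition(TWO_MODULE_PARTITION, 0.0,
                                           {1: 6, 2: 6}))
        for node in net.graph.nodes:
            assert sum(roles.kappa[node].values()) == net.graph.degree[node]

    def test_missing_node_named(self):
        net = make_signed_network([("a", "b")])
        with pytest.raises(KeyError, match="b"):
            zi_pi_roles(net, Partition({"a": 1}, 0.0, {1: 1}))


class TestRoleClassification:
    @pytest.mark.parametrize("zi,pi,expected", [
        (3.0, 0.5, "module hub"),
        (3.0, 0.7, "network hub"),
        (1.0, 0.7, "connector"),
        (1.0, 0.5, "peripheral"),
        (2.5, 0.62, "peripheral"),   # boundary values fall in the low class
        (2.5, 0.63, "connector"),
        (2.51, 0.62, "module hub"),
    ])
    def test_categories(self, zi, pi, expected):
        assert classify_role(zi, pi) == expected

    def test_monotone_in_pi(self):
        # increasing Pi never demotes a connector to peripheral
        for zi in (0.0, 1.0, 2.5):
            labels = [classify_role(zi, pi) for pi in np.linspace(0, 0.99, 50)]
            if "connector" in labels:
                first = labels.index("connector")
                assert all(l == "connector" for l in labels[first:])


class TestEigengenes:
    def _abundance(self, rows, taxa):
        rows = np.asarray(rows, dtype=float)
        return AbundanceMatrix(pd.DataFrame(
            rows, index=taxa, columns=[f"S{j}" for j in range(rows.shape[1])]))

    def test_rank_one_module(self):
        base = np.array([1.0, 3.0, 2.0, 5.0, 4.0, 6.0])
        rows = [base * a + b for a, b in [(1, 0), (2, 1), (0.5, -3),
                                          (3, 2), (1.5, 0)]]
        taxa = [f"T{i}" for i in range(5)]
        X = self._abundance(rows, taxa)
        part = Partition({t: 1 for t in taxa}, 0.0, {1: 5})
        eig = module_eigengenes(X, part, min_size=5)
        assert eig.variance_explained[1] == pytest.approx(1.0)
        e = eig.eigengenes[1].to_numpy()
        z = (base - base.mean()) / base.std(ddof=1)
        assert abs(np.corrcoef(e, z)[0, 1]) == pytest.approx(1.0)
        assert np.corrcoef(e, base)[0, 1] > 0  # sign convention

    def test_small_modules_excluded(self):
        taxa = [f"T{i}" for i in range(9)]
        rng = np.random.default_rng(0)
        X = self._abundance(rng.normal(size=(9, 10)), taxa)
        membership = {t: (1 if i < 5 else 2) for i, t in enumerate(taxa)}
        part = Partition(membership, 0.0, {1: 5, 2: 4})
        eig = module_eigengenes(X, part, min_size=5)
        assert list(eig.eigengenes.columns) == [1]

    def test_member_correlation_sum_nonnegative(self):
        rng = np.random.default_rng(3)
        taxa = [f"T{i}" for i in range(6)]
        X = self._abundance(rng.normal(size=(6, 20)), taxa)
        part = Partition({t: 1 for t in taxa}, 0.0, {1: 6})
        eig = module_eigengenes(X, part, min_size=5)
        e = eig.eigengenes[1].to_numpy()
        total = sum(np.corrcoef(e, X.values.loc[t])[0, 1] for t in taxa)
        assert total >= 0

    def test_missing_member_rejected(self):
        X = self._abundance(np.ones((2, 6)) * np.arange(6), ["T0", "T1"])
        part = Partition({f"T{i}": 1 for i in range(5)}, 0.0, {1: 5})
        with pytest.raises(KeyError):
            module_eigengenes(X, part, min_size=5)


class TestModuleEnvCorrelation:
    def _setup(self):
        rng = np.random.default_rng(1)
        samples = [f"S{j}" for j in range(20)]
        e = rng.normal(size=20)
        eig = pd.DataFrame({1: e / np.linalg.norm(e)}, index=samples)
        from drynet.keystones import EigengeneTable
        table = EigengeneTable(eig, {1: 0.8})
        frame = SampleFrame(pd.DataFrame({
            "group": ["Arid"] * 20, "treatment": ["ambient"] * 20,
            "MAP": eig[1].to_numpy() * 50 + 300,
            "pH": rng.normal(7, 0.5, size=20),
        }, index=samples))
        return table, frame

    def test_identical_column_gives_r_one(self):
        table, frame = self._setup()
        out = module_env_correlation(table, frame, alpha=0.05)
        row = out[(out["module"] == 1) & (out["variable"] == "MAP")].iloc[0]
        assert row["r"] == pytest.approx(1.0)
        assert row["significant"]

    def test_consistent_sample_shuffle_leaves_r_unchanged(self):
        table, frame = self._setup()
        base = module_env_correlation(table, frame)
        rng = np.random.default_rng(0)
        order = list(rng.permutation(table.eigengenes.index))
        from drynet.keystones import EigengeneTable
        shuffled = EigengeneTable(table.eigengenes.loc[order],
                                  table.variance_explained)
        out = module_env_correlation(shuffled, frame)
        merged = base.merge(out, on=["module", "variable"], suffixes=("_a", "_b"))
        assert np.allclose(merged["r_a"], merged["r_b"])

    def test_non_numeric_column_named(self):
        table, frame = self._setup()
        frame.frame["soil_type"] = "clay"
        with pytest.raises(Exception, match="soil_type"):
            module_env_correlation(table, frame)
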