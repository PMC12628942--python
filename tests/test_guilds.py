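import numpy as np
import pandas as pd
import pytest

from drynet import (classify_functional_groups, crossdomain_edge_summary,
                    keystone_env_spearman, parse_fungal_mode,
                    topology_summary)
from drynet.guilds import GuildMap
from drynet.keystones import Partition, zi_pi_roles
from drynet.tables_io import CountTable, SampleFrame, TaxonomyTable

from conftest import make_signed_network


def _taxonomy(rows):
    return TaxonomyTable(pd.DataFrame(rows).set_index("taxon_id"))


class TestClassification:
    def _classify(self, rows, domains):
        tax = _taxonomy(rows)
        return classify_functional_groups(tax, pd.Series(domains))

    def test_rrn_threshold_is_inclusive(self):
        # Pseudomonas 5.2 / Arthrobacter exactly 5.0 -> copiotroph;
        # Micrococcaceae family 4.2 -> oligotroph
        gm = self._classify(
            [{"taxon_id": "B1", "genus": "Arthrobacter"},
             {"taxon_id": "B2", "genus": "Sphingomonas"},
             {"taxon_id": "B3", "genus": "", "family": "Micrococcaceae"}],
            {"B1": "bacteria", "B2": "bacteria", "B3": "bacteria"})
        assert gm.group_of("B1") == "copiotroph"
        assert gm.group_of("B2") == "oligotroph"
        assert gm.group_of("B3") == "oligotroph"  # family-level fallback

    def test_unmatched_bacterium_is_unknown(self):
        gm = self._classify([{"taxon_id": "B1", "genus": "Nosuchgenus"}],
                            {"B1": "bacteria"})
        assert gm.group_of("B1") == "unknown"

    def test_fungal_first_listed_mode(self):
        gm = self._classify(
            [{"taxon_id": "F1", "guild": "Pathotroph-Saprotroph-Symbiotroph"},
             {"taxon_id": "F2", "guild": "Saprotroph-Symbiotroph"},
             {"taxon_id": "F3", "genus": "Glomus"}],  # via genus lookup
            {"F1": "fungi", "F2": "fungi", "F3": "fungi"})
        assert gm.group_of("F1") == "pathotroph"
        assert gm.group_of("F2") == "saprotroph"
        assert gm.group_of("F3") == "symbiotroph"

    def test_protist_genus_lookup(self):
        gm = self._classify(
            [{"taxon_id": "P1", "genus": "Cercomonas"},
             {"taxon_id": "P2", "genus": "Chlorella"},
             {"taxon_id": "P3", "genus": "Absentgenus"}],
            {"P1": "protist", "P2": "protist", "P3": "protist"})
        assert gm.group_of("P1") == "consumer"
        assert gm.group_of("P2") == "phototroph"
        assert gm.group_of("P3") == "unknown"

    def test_nematodes_are_consumers(self):
        gm = self._classify([{"taxon_id": "N1", "genus": "Acrobeles"}],
                            {"N1": "nematode"})
        assert gm.group_of("N1") == "consumer"

    def test_override_takes_precedence(self):
        tax = _taxonomy([{"taxon_id": "F1",
                          "guild": "Pathotroph-Saprotroph"}])
        overrides = pd.DataFrame({"taxon_id": ["F1"], "group": ["saprotroph"]})
        gm = classify_functional_groups(tax, pd.Series({"F1": "fungi"}),
                                        overrides=overrides)
        assert gm.group_of("F1") == "saprotroph"

    def test_map_is_total(self):
        domains = {"B1": "bacteria", "F1": "fungi", "P1": "protist",
                   "N1": "nematode", "X1": "bacteria"}
        gm = self._classify([{"taxon_id": t} for t in domains], domains)
        assert len(gm.table) == len(domains)
        assert gm.table["group"].notna().all()

    @pytest.mark.parametrize("text,expected", [
        ("Pathotroph-Saprotroph-Symbiotroph", "pathotroph"),
        ("Saprotroph", "saprotroph"),
        ("symbiotroph_endophyte", "symbiotroph"),
        ("Unknown guild", "unknown"),
    ])
    def test_mode_parser(self, text, expected):
        assert parse_fungal_mode(text) == expected


def _guild_map(domains, groups=None):
    groups = groups or {t: "unknown" for t in domains}
    return GuildMap(pd.DataFrame({
        "domain": pd.Series(domains), "group": pd.Series(groups),
        "source": "", "rrn": np.nan}))


class TestCrossDomain:
    def test_pair_assignment_and_conservation(self):
        net = make_signed_network([
            ("b1", "b2", "positive"), ("b1", "f1", "negative"),
            ("f1", "p1", "positive"), ("b2", "n1", "positive"),
        ])
        domains = {"b1": "bacteria", "b2": "bacteria", "f1": "fungi",
                   "p1": "protist", "n1": "nematode"}
        for node, dom in domains.items():
            net.graph.nodes[node]["domain"] = dom
        summary = crossdomain_edge_summary(net, _guild_map(domains))
        assert summary.edges.at["BB", "positive"] == 1
        assert summary.edges.at["BF", "negative"] == 1
        assert summary.edges.at["FP", "positive"] == 1
        assert summary.edges.at["BN", "positive"] == 1
        assert summary.total_edges == net.n_edges
        assert summary.edges["percent"].sum() == pytest.approx(100.0)

    def test_single_domain_network(self):
        net = make_signed_network([("b1", "b2"), ("b2", "b3")])
        domains = {n: "bacteria" for n in ("b1", "b2", "b3")}
        for node in net.graph.nodes:
            net.graph.nodes[node]["domain"] = "bacteria"
        summary = crossdomain_edge_summary(net, _guild_map(domains))
        assert summary.edges.at["BB", "percent"] == pytest.approx(100.0)

    def test_counts_match_topology_signs(self):
        net = make_signed_network([("b1", "b2", "positive"),
                                   ("b2", "b3", "negative"),
                                   ("b1", "b3", "negative")])
        for node in net.graph.nodes:
            net.graph.nodes[node]["domain"] = "bacteria"
        topo = topology_summary(net)
        summary = crossdomain_edge_summary(
            net, _guild_map({n: "bacteria" for n in net.graph.nodes}))
        assert summary.edges["positive"].sum() == topo.n_positive
        assert summary.edges["negative"].sum() == topo.n_negative

    def test_missing_domain_rejected(self):
        net = make_signed_network([("a", "b")])
        with pytest.raises(KeyError):
            crossdomain_edge_summary(net, _guild_map({}))


class TestKeystoneSpearman:
    def _inputs(self):
        rng = np.random.default_rng(2)
        samples = [f"S{j}" for j in range(12)]
        taxa = ["b1", "b2", "f1"]
        counts = pd.DataFrame(rng.integers(1, 200, size=(3, 12)),
                              index=taxa, columns=samples)
        table = CountTable(counts, pd.Series(
            {"b1": "bacteria", "b2": "bacteria", "f1": "fungi"}))
        net = make_signed_network([("b1", "b2"), ("b1", "f1"), ("b2", "f1")])
        partition = Partition({"b1": 1, "b2": 1, "f1": 2}, 0.0, {1: 2, 2: 1})
        roles = zi_pi_roles(net, partition)
        # force b1 to be a keystone for the test regardless of topology
        roles.table.loc["b1", "role"] = "connector"
        guilds = _guild_map({"b1": "bacteria", "b2": "bacteria", "f1": "fungi"},
                            {"b1": "oligotroph", "b2": "copiotroph",
                             "f1": "saprotroph"})
        frame = SampleFrame(pd.DataFrame({
            "group": ["Arid"] * 12, "treatment": ["ambient"] * 12,
            "MAP": np.linspace(230, 460, 12)}, index=samples))
        return table, roles, guilds, frame

    def test_monotone_abundance_gives_rho_one(self):
        table, roles, guilds, frame = self._inputs()
        # rising counts over constant companions: relative abundance of b1
        # increases strictly with MAP
        table.counts.loc["b1"] = np.arange(10, 130, 10)
        table.counts.loc["b2"] = 500
        table.counts.loc["f1"] = 300
        out = keystone_env_spearman(table, roles, guilds, frame)
        row = out[(out["unit"] == "taxon:b1") & (out["variable"] == "MAP")].iloc[0]
        assert row["rho"] == pytest.approx(1.0)

    def test_tied_rank_oracle(self):
        # keystone abundances x=(1,2,2,4) vs environment y=(1,3,2,4):
        # average ranks x -> (1, 2.5, 2.5, 4), y -> (1, 3, 2, 4); Pearson on
        # the ranks gives rho = 4.5 / sqrt(4.5 * 5) = 0.9486832980505138
        samples = [f"S{j}" for j in range(4)]
        counts = pd.DataFrame({"S0": [1, 9], "S1": [2, 8], "S2": [2, 8],
                               "S3": [4, 6]}, index=["b1", "b2"])
        table = CountTable(counts, pd.Series({"b1": "bacteria",
                                              "b2": "bacteria"}))
        net = make_signed_network([("b1", "b2")])
        roles = zi_pi_roles(net, Partition({"b1": 1, "b2": 1}, 0.0, {1: 2}))
        roles.table.loc["b1", "role"] = "connector"
        guilds = _guild_map({"b1": "bacteria", "b2": "bacteria"},
                            {"b1": "oligotroph", "b2": "copiotroph"})
        frame = SampleFrame(pd.DataFrame({
            "group": ["Arid"] * 4, "treatment": ["ambient"] * 4,
            "MAP": [1.0, 3.0, 2.0, 4.0]}, index=samples))
        out = keystone_env_spearman(table, roles, guilds, frame)
        row = out[(out["unit"] == "taxon:b1")
                  & (out["variable"] == "MAP")].iloc[0]
        assert row["rho"] == pytest.approx(0.9486832980505138)

    def test_rho_invariant_under_monotone_transform(self):
        table, roles, guilds, frame = self._inputs()
        base = keystone_env_spearman(table, roles, guilds, frame)
        frame.frame["MAP"] = np.exp(frame.frame["MAP"] / 100.0)
        out = keystone_env_spearman(table, roles, guilds, frame)
        merged = base.merge(out, on=["unit", "variable"], suffixes=("_a", "_b"))
        assert np.allclose(merged["rho_a"], merged["rho_b"])

    def test_empty_keystone_set_warns(self, caplog):
        table, roles, guilds, frame = self._inputs()
        roles.table["role"] = "peripheral"
        import logging
        with caplog.at_level(logging.WARNING):
            out = keystone_env_spearman(table, roles, guilds, frame)
        assert out.empty
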