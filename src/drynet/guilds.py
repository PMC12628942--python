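"""Functional-guild annotation and cross-domain edge accounting.

Bacteria are split into copiotrophs (mean rRNA operon copy number >= 5) and
oligotrophs (< 5) from a genus/family copy-number lookup; fungi take the
first-listed trophic mode of their guild string (pathotroph / saprotroph /
symbiotroph); protists are assigned feeding groups (consumer, phototroph,
pathotroph) at the genus level; nematode trophic groups are collapsed into
a single consumer category.  Taxa without a match stay ``unknown``.

The packaged lookup tables under ``data/`` are small constructed stand-ins
(see their docstrings/filenames) so the pipeline runs self-contained; users
with access to the full reference databases can pass richer tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .keystones import RoleTable
from .netbuild import SignedNetwork
from .tables_io import DOMAIN_PREFIX, CountTable, SampleFrame, TaxonomyTable

logger = logging.getLogger(__name__)

COPIOTROPH_RRN_THRESHOLD = 5.0
FUNGAL_MODES = ("pathotroph", "saprotroph", "symbiotroph")
PROTIST_GROUPS = ("consumer", "phototroph", "pathotroph")

#: Allowed functional groups per domain (plus "unknown" everywhere).
DOMAIN_GROUPS = {
    "bacteria": ("oligotroph", "copiotroph"),
    "fungi": FUNGAL_MODES,
    "protist": PROTIST_GROUPS,
    "nematode": ("consumer",),
}

_PAIR_ORDER = ("B", "F", "P", "N")
DOMAIN_PAIRS = ("BB", "BF", "BP", "BN", "FF", "FP", "FN", "PP", "PN", "NN")


@dataclass
class GuildMap:
    """Per-taxon domain, functional group and annotation provenance."""

    table: pd.DataFrame  # index taxon_id; columns domain, group, source, rrn

    def group_of(self, taxon_id: str) -> str:
        return str(self.table.at[taxon_id, "group"])

    def members(self, group: str) -> list[str]:
        return list(self.table.index[self.table["group"] == group])


@dataclass
class CrossDomainSummary:
    """Signed edge counts per unordered domain pair, plus node tallies."""

    edges: pd.DataFrame        # index pair; columns positive, negative, percent
    nodes_by_domain: pd.Series
    nodes_by_group: pd.Series

    @property
    def total_edges(self) -> int:
        return int(self.edges[["positive", "negative"]].to_numpy().sum())


def _load_fixture(name: str) -> pd.DataFrame:
    with resources.files("drynet.data").joinpath(name).open("rb") as fh:
        return pd.read_csv(fh, sep="\t", dtype=str)


def load_rrn_lookup(path: str | Path | None = None) -> pd.DataFrame:
    """Genus/family -> mean rRNA operon copy number (columns rank, name, rrn)."""
    df = (pd.read_csv(path, sep="\t", dtype=str) if path is not None
          else _load_fixture("rrn_copies.synthetic.tsv"))
    df["rrn"] = pd.to_numeric(df["rrn"])
    return df


def load_fungal_guild_lookup(path: str | Path | None = None) -> pd.DataFrame:
    """Fungal genus -> free-text guild/trophic-mode string."""
    if path is not None:
        return pd.read_csv(path, sep="\t", dtype=str)
    return _load_fixture("fungal_guilds.synthetic.tsv")


def load_protist_lookup(path: str | Path | None = None) -> pd.DataFrame:
    """Protist genus -> feeding group (consumer / phototroph / pathotroph)."""
    if path is not None:
        return pd.read_csv(path, sep="\t", dtype=str)
    return _load_fixture("protist_groups.synthetic.tsv")


def parse_fungal_mode(guild_string: str) -> str:
    """First-listed trophic mode of a (possibly multi-mode) guild string."""
    for token in str(guild_string).replace("_", "-").split("-"):
        token = token.strip().lower()
        for mode in FUNGAL_MODES:
            if token.startswith(mode):
                return mode
    return "unknown"


def classify_functional_groups(
    tax: TaxonomyTable,
    domains: pd.Series,
    rrn_lookup: pd.DataFrame | None = None,
    fungal_guild_lookup: pd.DataFrame | None = None,
    protist_lookup: pd.DataFrame | None = None,
    overrides: pd.DataFrame | None = None,
) -> GuildMap:
    """Assign every taxon exactly one functional group.

    ``overrides`` (columns taxon_id, group), when given, take precedence —
    the hook for expert "most ecologically plausible" reassignments, which
    are never inferred automatically.
    """
    rrn_lookup = rrn_lookup if rrn_lookup is not None else load_rrn_lookup()
    fungal_guild_lookup = (fungal_guild_lookup if fungal_guild_lookup is not None
                           else load_fungal_guild_lookup())
    protist_lookup = (protist_lookup if protist_lookup is not None
                      else load_protist_lookup())

    rrn_by_rank = {
        rank: dict(zip(sub["name"], sub["rrn"]))
        for rank, sub in rrn_lookup.groupby("rank")
    }
    fungal_by_genus = dict(zip(fungal_guild_lookup["genus"],
                               fungal_guild_lookup["guild"]))
    protist_by_genus = dict(zip(protist_lookup["genus"], protist_lookup["group"]))
    override_map = ({} if overrides is None
                    else dict(zip(overrides["taxon_id"], overrides["group"])))

    rows = []
    for taxon in domains.index:
        domain = domains[taxon]
        group, source, rrn = "unknown", "", np.nan
        if taxon in override_map:
            group, source = override_map[taxon], "override"
        elif domain == "bacteria":
            # genus first, then one-level family fallback
            for rank in ("genus", "family"):
                name = tax.rank(taxon, rank) if taxon in tax.lineages.index else ""
                if name and name in rrn_by_rank.get(rank, {}):
                    rrn = float(rrn_by_rank[rank][name])
                    group = ("copiotroph" if rrn >= COPIOTROPH_RRN_THRESHOLD
                             else "oligotroph")
                    source = f"rrn:{rank}:{name}"
                    break
        elif domain == "fungi":
            guild = (tax.rank(taxon, "guild")
                     if taxon in tax.lineages.index else "")
            if not guild:
                genus = (tax.rank(taxon, "genus")
                         if taxon in tax.lineages.index else "")
                guild = fungal_by_genus.get(genus, "")
            if guild:
                group = parse_fungal_mode(guild)
                source = f"guild:{guild}"
        elif domain == "protist":
            genus = tax.rank(taxon, "genus") if taxon in tax.lineages.index else ""
            if genus and genus in protist_by_genus:
                group = str(protist_by_genus[genus]).lower()
                source = f"genus:{genus}"
        elif domain == "nematode":
            group, source = "consumer", "domain-rule"
        allowed = set(DOMAIN_GROUPS.get(domain, ())) | {"unknown"}
        if group not in allowed:
            logger.warning("guilds: group %r invalid for domain %s (taxon %s); "
                           "set to unknown", group, domain, taxon)
            group = "unknown"
        rows.append({"taxon_id": taxon, "domain": domain, "group": group,
                     "source": source, "rrn": rrn})
    return GuildMap(pd.DataFrame(rows).set_index("taxon_id"))


def crossdomain_edge_summary(net: SignedNetwork, guilds: GuildMap) -> CrossDomainSummary:
    """Signed edge counts and percentages per unordered domain pair."""
    graph = net.graph
    counts = {pair: {"positive": 0, "negative": 0} for pair in DOMAIN_PAIRS}
    for u, v, sign in graph.edges(data="sign"):
        pair_letters = []
        for node in (u, v):
            domain = graph.nodes[node].get("domain") or (
                guilds.table.at[node, "domain"] if node in guilds.table.index else None
            )
            if domain is None or domain not in DOMAIN_PREFIX:
                raise KeyError(f"node {node!r} has no domain annotation")
            pair_letters.append(DOMAIN_PREFIX[domain])
        pair_letters.sort(key=_PAIR_ORDER.index)
        counts["".join(pair_letters)][sign] += 1
    total = graph.number_of_edges()
    edges = pd.DataFrame(counts).T
    edges.index.name = "pair"
    edges["percent"] = (100.0 * (edges["positive"] + edges["negative"]) / total
                        if total else 0.0)

    node_domains = []
    node_groups = []
    for node in graph.nodes:
        domain = graph.nodes[node].get("domain") or guilds.table.at[node, "domain"]
        node_domains.append(domain)
        node_groups.append(guilds.group_of(node) if node in guilds.table.index
                           else "unknown")
    return CrossDomainSummary(
        edges,
        pd.Series(node_domains).value_counts(),
        pd.Series(node_groups).value_counts(),
    )


def keystone_env_spearman(table: CountTable, roles: RoleTable, guilds: GuildMap,
                          frame: SampleFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Spearman correlation of keystone-group relative abundances vs environment.

    Keystones are the connector / module hub / network hub nodes.  For each
    functional group among them (and each individual keystone taxon), the
    per-sample relative abundance is the group's summed counts over the
    sample total; Spearman rho uses average ranks for ties.  Returns a long
    table (unit, variable, rho, p, q, significant); empty with a warning if
    no keystones exist.
    """
    keystones = [k for k in roles.keystones() if k in table.counts.index]
    if not keystones:
        logger.warning("keystone_env_spearman: no keystone taxa in table")
        return pd.DataFrame(
            columns=["unit", "variable", "rho", "p", "q", "significant"])
    samples = table.sample_ids
    missing = set(samples) - set(frame.frame.index)
    if missing:
        raise KeyError(f"samples missing from metadata: {sorted(missing)[:5]}")
    totals = table.counts.sum(axis=0).to_numpy(dtype=float)
    totals[totals == 0] = 1.0
    env = frame.frame.loc[samples, frame.env_columns()]

    units: dict[str, np.ndarray] = {}
    groups = sorted({guilds.group_of(k) for k in keystones
                     if k in guilds.table.index})
    for group in groups:
        members = [k for k in keystones if k in guilds.table.index
                   and guilds.group_of(k) == group]
        units[f"group:{group}"] = (
            table.counts.loc[members].sum(axis=0).to_numpy(dtype=float) / totals)
    for k in keystones:
        units[f"taxon:{k}"] = table.counts.loc[k].to_numpy(dtype=float) / totals

    rows = []
    for unit, abundance in units.items():
        for var in env.columns:
            x = pd.to_numeric(env[var], errors="raise").to_numpy(dtype=float)
            if np.all(abundance == abundance[0]) or np.all(x == x[0]):
                rho, p = 0.0, 1.0
            else:
                rho, p = stats.spearmanr(abundance, x)
            rows.append({"unit": unit, "variable": var,
                         "rho": float(rho), "p": float(p)})
    out = pd.DataFrame(rows)
    _, q, _, _ = multipletests(out["p"], method="fdr_bh")
    out["q"] = q
    out["significant"] = out["p"] < alpha
    return out
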