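"""Tabular and network input/output.

All on-disk artifacts are tab-delimited UTF-8 text with ``.`` as the decimal
mark, the exchange dialect common to amplicon workflows.  Count tables are
oriented taxa x samples (QIIME-style): taxon identifiers in the first column,
sample identifiers in the header.  Networks are exported both as
Cytoscape-compatible edge/node attribute tables and as GraphML.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

DOMAINS = ("bacteria", "fungi", "protist", "nematode")
DOMAIN_PREFIX = {"bacteria": "B", "fungi": "F", "protist": "P", "nematode": "N"}

CLIMATIC_GROUPS = ("Arid", "Semi-arid Low CV", "Semi-arid High CV")
TREATMENTS = ("ambient", "reduced", "increased")

#: Environmental variables carried by a sample frame.  Names follow the field's
#: reporting conventions: MAP = mean annual precipitation (mm), OYR = one-year
#: rainfall, TMR = three-month rainfall, MAT = mean annual temperature (deg C),
#: CV = interannual rainfall coefficient of variation, AI = aridity index,
#: VR = vegetation richness, SB = standing biomass.
ENV_VARIABLES = (
    "pH", "TotalC", "TotalN", "TotalP", "C:N", "C:P", "N:P",
    "VR", "SB", "MAP", "OYR", "TMR", "MAT", "CV", "AI",
)


class TableFormatError(ValueError):
    """Raised when an on-disk table violates a structural invariant."""


# ---------------------------------------------------------------------------
# Count tables
# ---------------------------------------------------------------------------

@dataclass
class CountTable:
    """Taxa x samples matrix of non-negative integer read counts.

    Parameters
    ----------
    counts
        DataFrame indexed by taxon id with sample ids as columns.
    domain
        Per-taxon domain tag, aligned with ``counts.index``; each entry is one
        of :data:`DOMAINS`.
    """

    counts: pd.DataFrame
    domain: pd.Series

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            dupes = self.counts.index[self.counts.index.duplicated()].unique()
            raise TableFormatError(f"duplicate taxon ids: {list(dupes)}")
        if self.counts.columns.has_duplicates:
            dupes = self.counts.columns[self.counts.columns.duplicated()].unique()
            raise TableFormatError(f"duplicate sample ids: {list(dupes)}")
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.all(np.equal(np.mod(arr, 1), 0)):
                bad = np.argwhere(np.mod(arr, 1) != 0)[0]
                raise TableFormatError(
                    f"non-integer count at taxon {self.counts.index[bad[0]]!r}, "
                    f"sample {self.counts.columns[bad[1]]!r}"
                )
            self.counts = self.counts.astype(np.int64)
            arr = self.counts.to_numpy()
        if (arr < 0).any():
            bad = np.argwhere(arr < 0)[0]
            raise TableFormatError(
                f"negative count at taxon {self.counts.index[bad[0]]!r}, "
                f"sample {self.counts.columns[bad[1]]!r}"
            )
        self.domain = self.domain.reindex(self.counts.index)
        if self.domain.isna().any():
            missing = list(self.domain.index[self.domain.isna()])
            raise TableFormatError(f"taxa without a domain tag: {missing}")
        unknown = set(self.domain.unique()) - set(DOMAINS)
        if unknown:
            raise TableFormatError(
                f"unknown domain tags {sorted(unknown)}; expected one of {DOMAINS}"
            )

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def subset_samples(self, sample_ids: Iterable[str]) -> "CountTable":
        ids = list(sample_ids)
        missing = set(ids) - set(self.counts.columns)
        if missing:
            raise KeyError(f"samples not in table: {sorted(missing)}")
        return CountTable(self.counts[ids].copy(), self.domain.copy())


def read_count_table(path: str | Path, domain: str) -> CountTable:
    """Read a taxa x samples TSV and tag every row with ``domain``."""
    if domain not in DOMAINS:
        raise TableFormatError(f"unknown domain {domain!r}; expected one of {DOMAINS}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    df.index.name = None
    try:
        values = df.apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        raise TableFormatError(f"non-numeric cell in {path}: {exc}") from exc
    arr = values.to_numpy()
    bad = np.argwhere((arr < 0) | (np.mod(arr, 1) != 0))
    if bad.size:
        i, j = bad[0]
        raise TableFormatError(
            f"invalid count {arr[i, j]!r} at taxon {values.index[i]!r}, "
            f"sample {values.columns[j]!r} in {path}"
        )
    domains = pd.Series(domain, index=values.index)
    return CountTable(values.astype(np.int64), domains)


def write_count_table(table: CountTable, path: str | Path) -> None:
    out = table.counts.copy()
    out.index.name = "taxon_id"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Taxonomy
# ---------------------------------------------------------------------------

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")


@dataclass
class TaxonomyTable:
    """Ranked lineages per taxon, with an optional free-text guild string.

    Missing ranks are stored as empty strings, never dropped.
    """

    lineages: pd.DataFrame  # index taxon_id, columns RANKS + 'guild'

    def __post_init__(self) -> None:
        if self.lineages.index.has_duplicates:
            raise TableFormatError("duplicate taxon ids in taxonomy")
        for col in (*RANKS, "guild"):
            if col not in self.lineages.columns:
                self.lineages[col] = ""
        self.lineages = self.lineages[[*RANKS, "guild"]].fillna("").astype(str)

    def rank(self, taxon_id: str, rank: str) -> str:
        return str(self.lineages.at[taxon_id, rank])


def read_taxonomy_table(path: str | Path) -> TaxonomyTable:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    df.index.name = None
    return TaxonomyTable(df)


def write_taxonomy_table(tax: TaxonomyTable, path: str | Path) -> None:
    out = tax.lineages.copy()
    out.index.name = "taxon_id"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Sample metadata
# ---------------------------------------------------------------------------

@dataclass
class SampleFrame:
    """Per-sample metadata: climatic group, rainfall treatment, environment.

    ``group`` and ``treatment`` come from closed vocabularies
    (:data:`CLIMATIC_GROUPS`, :data:`TREATMENTS`); every other column is
    numeric (or NaN for explicitly missing values).
    """

    frame: pd.DataFrame  # index sample_id

    def __post_init__(self) -> None:
        if self.frame.index.has_duplicates:
            raise TableFormatError("duplicate sample ids in metadata")
        if "group" in self.frame.columns:
            bad = set(self.frame["group"].dropna().unique()) - set(CLIMATIC_GROUPS)
            if bad:
                raise TableFormatError(
                    f"unknown climatic group(s) {sorted(bad)}; "
                    f"allowed: {list(CLIMATIC_GROUPS)}"
                )
        if "treatment" in self.frame.columns:
            bad = set(self.frame["treatment"].dropna().unique()) - set(TREATMENTS)
            if bad:
                raise TableFormatError(
                    f"unknown treatment(s) {sorted(bad)}; allowed: {list(TREATMENTS)}"
                )
        for col in self.frame.columns:
            if col in ("group", "treatment"):
                continue
            try:
                self.frame[col] = pd.to_numeric(self.frame[col])
            except (ValueError, TypeError) as exc:
                raise TableFormatError(
                    f"metadata column {col!r} is not numeric: {exc}"
                ) from exc

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    def env_columns(self) -> list[str]:
        return [c for c in self.frame.columns if c not in ("group", "treatment")]

    def samples_in_group(self, group: str) -> list[str]:
        if group not in CLIMATIC_GROUPS:
            raise TableFormatError(
                f"unknown climatic group {group!r}; allowed: {list(CLIMATIC_GROUPS)}"
            )
        mask = self.frame["group"] == group
        return list(self.frame.index[mask])


def read_sample_frame(path: str | Path) -> SampleFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    df.index.name = None
    return SampleFrame(df)


def write_sample_frame(frame: SampleFrame, path: str | Path) -> None:
    out = frame.frame.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Network export / import
# ---------------------------------------------------------------------------

def export_network(net, partition, roles, prefix: str | Path) -> dict[str, Path]:
    """Write edge list, node attribute table, and GraphML for a signed network.

    Parameters
    ----------
    net : SignedNetwork
        The network to export.
    partition : Partition
        Module assignment covering every node.
    roles : RoleTable
        Zi/Pi role table covering every node.
    prefix
        Output path prefix; ``<prefix>.edges.tsv``, ``<prefix>.nodes.tsv`` and
        ``<prefix>.graphml`` are written.

    Returns
    -------
    dict mapping artifact name to written path.
    """
    prefix = Path(prefix)
    graph = net.graph
    role_index = set(roles.table.index)
    for node in graph.nodes:
        if node not in partition.membership:
            raise KeyError(f"partition missing node {node!r}")
        if node not in role_index:
            raise KeyError(f"role table missing node {node!r}")

    edge_rows = []
    for u, v, data in sorted(graph.edges(data=True)):
        edge_rows.append({
            "source": u,
            "target": v,
            "r": data["r"],
            "sign": data["sign"],
            "q": data["q"],
        })
    edges = pd.DataFrame(edge_rows, columns=["source", "target", "r", "sign", "q"])
    edges_path = prefix.with_suffix(".edges.tsv")
    edges.to_csv(edges_path, sep="\t", index=False)

    node_rows = []
    for node in sorted(graph.nodes):
        row = roles.table.loc[node]
        node_rows.append({
            "node": node,
            "domain": graph.nodes[node].get("domain", ""),
            "guild": graph.nodes[node].get("guild", ""),
            "module": partition.membership[node],
            "Zi": row["Zi"],
            "Pi": row["Pi"],
            "role": row["role"],
        })
    nodes = pd.DataFrame(
        node_rows, columns=["node", "domain", "guild", "module", "Zi", "Pi", "role"]
    )
    nodes_path = prefix.with_suffix(".nodes.tsv")
    nodes.to_csv(nodes_path, sep="\t", index=False)

    gml = nx.Graph()
    for row in node_rows:
        gml.add_node(
            row["node"], domain=row["domain"], guild=row["guild"],
            module=int(row["module"]), Zi=float(row["Zi"]), Pi=float(row["Pi"]),
            role=row["role"],
        )
    for row in edge_rows:
        gml.add_edge(
            row["source"], row["target"],
            r=float(row["r"]), sign=row["sign"], q=float(row["q"]),
        )
    graphml_path = prefix.with_suffix(".graphml")
    nx.write_graphml(gml, graphml_path)
    return {"edges": edges_path, "nodes": nodes_path, "graphml": graphml_path}


def read_network_graphml(path: str | Path) -> nx.Graph:
    """Re-import an exported GraphML network (topology + attributes)."""
    return nx.read_graphml(path)
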