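"""Module detection, topological roles, and module-environment correlation.

Modules come from fast-greedy (Clauset-Newman-Moore) modularity maximisation
on the unsigned graph: starting from singleton communities, the pair of
connected communities whose merge maximises the modularity gain is merged
repeatedly, and the partition with the highest modularity along the merge
path is returned.  Ties in the gain are broken by the lexicographically
smallest community-id pair, so the greedy path is deterministic.

Node roles follow the within-module degree z-score (Zi) and participation
coefficient (Pi): peripherals, connectors (Pi > 0.62), module hubs
(Zi > 2.5) and network hubs (both).  Connectors and hubs are the putative
keystone taxa.  Module eigengenes (first left singular vector of the
standardised member profiles) summarise each module in sample space for
correlation with environmental variables.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .netbuild import SignedNetwork
from .preprocess import AbundanceMatrix
from .tables_io import SampleFrame

logger = logging.getLogger(__name__)

ZI_THRESHOLD = 2.5
PI_THRESHOLD = 0.62
ROLES = ("peripheral", "connector", "module hub", "network hub")
KEYSTONE_ROLES = ("connector", "module hub", "network hub")


@dataclass
class Partition:
    """Module assignment with modularity Q and the greedy merge history."""

    membership: dict[str, int]
    Q: float
    module_sizes: dict[int, int]
    merge_history: list[tuple[str, str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not -0.5 - 1e-9 <= self.Q <= 1 + 1e-9:
            raise ValueError(f"modularity {self.Q} outside [-0.5, 1]")

    @property
    def n_modules(self) -> int:
        return len(self.module_sizes)

    def modules_at_least(self, min_size: int) -> list[int]:
        return sorted(m for m, s in self.module_sizes.items() if s >= min_size)

    def members(self, module: int) -> list[str]:
        return sorted(n for n, m in self.membership.items() if m == module)


@dataclass
class RoleTable:
    """Per-node Zi, Pi, role category and per-module link counts kappa_is."""

    table: pd.DataFrame  # index node; columns module, degree, Zi, Pi, role
    kappa: dict[str, dict[int, int]]

    def keystones(self) -> list[str]:
        mask = self.table["role"].isin(KEYSTONE_ROLES)
        return list(self.table.index[mask])


@dataclass
class EigengeneTable:
    """Per-module sample-space eigengene and its variance explained."""

    eigengenes: pd.DataFrame  # samples x modules, unit-norm columns
    variance_explained: dict[int, float]


# ---------------------------------------------------------------------------
# Fast-greedy modularity maximisation
# ---------------------------------------------------------------------------

def modularity(graph_edges_total: int, within: dict, degsum: dict) -> float:
    L = graph_edges_total
    return sum(within[c] / L - (degsum[c] / (2 * L)) ** 2 for c in within)


def fast_greedy_partition(net: SignedNetwork) -> Partition:
    """Clauset-Newman-Moore agglomerative modularity maximisation.

    Q = sum_c [L_c/L - (d_c/2L)^2] with L_c the intra-community edges and
    d_c the community degree sum.  Deterministic: merge gains tie-break on
    the lexicographically smallest community-id pair, where a community is
    identified by its smallest member node.
    """
    graph = net.graph
    if graph.number_of_nodes() == 0:
        raise ValueError("cannot partition an empty graph")
    L = graph.number_of_edges()
    if L == 0:
        raise ValueError("cannot partition a graph without edges")

    nodes = sorted(graph.nodes)
    assign: dict[str, str] = {n: n for n in nodes}            # node -> community rep
    degsum: dict[str, float] = {n: float(graph.degree[n]) for n in nodes}
    within: dict[str, float] = {n: 0.0 for n in nodes}
    between: dict[str, dict[str, float]] = {n: {} for n in nodes}
    for u, v in graph.edges:
        between[u][v] = between[u].get(v, 0.0) + 1.0
        between[v][u] = between[v].get(u, 0.0) + 1.0

    q = modularity(L, within, degsum)
    best_q = q
    best_assign = dict(assign)
    history: list[tuple[str, str, float]] = []

    while len(within) > 1:
        best_gain = None
        best_pair: tuple[str, str] | None = None
        for a, nbrs in between.items():
            for b, e_ab in nbrs.items():
                if a >= b:
                    continue
                # dQ of merging a,b: e_ab/L - d_a d_b / (2 L^2)
                gain = e_ab / L - degsum[a] * degsum[b] / (2.0 * L * L)
                if (best_gain is None or gain > best_gain + 1e-15
                        or (abs(gain - best_gain) <= 1e-15 and (a, b) < best_pair)):
                    best_gain = gain
                    best_pair = (a, b)
        if best_pair is None:  # remaining communities are disconnected
            break
        a, b = best_pair
        keep, gone = (a, b) if a < b else (b, a)
        within[keep] += within[gone] + between[keep].get(gone, 0.0)
        degsum[keep] += degsum[gone]
        del within[gone], degsum[gone]
        for c, e in between[gone].items():
            if c == keep:
                continue
            between[keep][c] = between[keep].get(c, 0.0) + e
            between[c][keep] = between[keep][c]
            del between[c][gone]
        between[keep].pop(gone, None)
        del between[gone]
        for n, rep in assign.items():
            if rep == gone:
                assign[n] = keep
        q += best_gain
        history.append((keep, gone, q))
        if q > best_q + 1e-12:
            best_q = q
            best_assign = dict(assign)

    # relabel communities 1..k by decreasing size (ties: smallest member id)
    groups: dict[str, list[str]] = {}
    for n, rep in best_assign.items():
        groups.setdefault(rep, []).append(n)
    order = sorted(groups, key=lambda r: (-len(groups[r]), r))
    relabel = {rep: i + 1 for i, rep in enumerate(order)}
    membership = {n: relabel[rep] for n, rep in best_assign.items()}
    sizes = {relabel[rep]: len(groups[rep]) for rep in groups}
    return Partition(membership, best_q, sizes, history)


# ---------------------------------------------------------------------------
# Zi / Pi topological roles
# ---------------------------------------------------------------------------

def classify_role(zi: float, pi: float, z_thresh: float = ZI_THRESHOLD,
                  p_thresh: float = PI_THRESHOLD) -> str:
    """Role from (Zi, Pi); boundary values fall in the low class."""
    high_z = zi > z_thresh
    high_p = pi > p_thresh
    if high_z and high_p:
        return "network hub"
    if high_z:
        return "module hub"
    if high_p:
        return "connector"
    return "peripheral"


def zi_pi_roles(net: SignedNetwork, partition: Partition,
                z_thresh: float = ZI_THRESHOLD,
                p_thresh: float = PI_THRESHOLD) -> RoleTable:
    """Within-module degree z-score and participation coefficient per node.

    Zi standardises the node's link count into its own module against that
    module's distribution (Zi = 0 when the module's spread is zero);
    Pi = 1 - sum_s (kappa_is / k_i)^2 measures how evenly links spread over
    modules.
    """
    graph = net.graph
    missing = [n for n in graph.nodes if n not in partition.membership]
    if missing:
        raise KeyError(f"partition missing node(s): {sorted(missing)[:5]}")

    kappa: dict[str, dict[int, int]] = {}
    intra: dict[str, int] = {}
    for node in graph.nodes:
        per_module: dict[int, int] = {}
        for nbr in graph.neighbors(node):
            m = partition.membership[nbr]
            per_module[m] = per_module.get(m, 0) + 1
        kappa[node] = per_module
        intra[node] = per_module.get(partition.membership[node], 0)

    by_module: dict[int, list[str]] = {}
    for node in graph.nodes:
        by_module.setdefault(partition.membership[node], []).append(node)

    rows = []
    for node in sorted(graph.nodes):
        m = partition.membership[node]
        members = by_module[m]
        vals = np.array([intra[n] for n in members], dtype=float)
        sd = vals.std()  # population sd over the module's nodes
        zi = (intra[node] - vals.mean()) / sd if sd > 0 else 0.0
        k = graph.degree[node]
        pi = 1.0 - sum((c / k) ** 2 for c in kappa[node].values()) if k else 0.0
        rows.append({
            "node": node, "module": m, "degree": k,
            "Zi": zi, "Pi": pi, "role": classify_role(zi, pi, z_thresh, p_thresh),
        })
    table = pd.DataFrame(rows).set_index("node")
    return RoleTable(table, kappa)


# ---------------------------------------------------------------------------
# Module eigengenes and environmental correlation
# ---------------------------------------------------------------------------

def module_eigengenes(X: AbundanceMatrix, partition: Partition,
                      min_size: int = 5) -> EigengeneTable:
    """First left singular vector of each module's standardised profiles.

    Members are z-scored across samples; the eigengene is the leading left
    singular vector of the samples x members matrix, sign-oriented so the
    summed member correlation is non-negative.  Modules below ``min_size``
    are omitted, matching the convention of reporting modules with five or
    more nodes.
    """
    values = X.values
    cols: dict[int, np.ndarray] = {}
    varexp: dict[int, float] = {}
    for module in partition.modules_at_least(min_size):
        members = partition.members(module)
        missing = [m for m in members if m not in values.index]
        if missing:
            raise KeyError(f"module {module} members missing from abundance "
                           f"matrix: {missing[:5]}")
        mat = values.loc[members].to_numpy(dtype=float).T  # samples x members
        mu = mat.mean(axis=0)
        sd = mat.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        z = (mat - mu) / sd
        u, s, _ = np.linalg.svd(z, full_matrices=False)
        eig = u[:, 0]
        corr_sum = sum(
            np.corrcoef(eig, z[:, j])[0, 1] for j in range(z.shape[1])
            if z[:, j].std() > 0
        )
        if corr_sum < 0:
            eig = -eig
        cols[module] = eig
        total = float((s ** 2).sum())
        varexp[module] = float(s[0] ** 2 / total) if total > 0 else 0.0
    frame = pd.DataFrame(cols, index=list(values.columns))
    return EigengeneTable(frame, varexp)


def module_env_correlation(eig: EigengeneTable, frame: SampleFrame,
                           alpha: float = 0.05) -> pd.DataFrame:
    """Pearson r of each module eigengene against each environmental variable.

    Returns a long table (module, variable, r, p, q, significant) with BH q
    across all tests; the significance flag uses the raw p at ``alpha``.
    """
    samples = list(eig.eigengenes.index)
    missing = set(samples) - set(frame.frame.index)
    if missing:
        raise KeyError(f"samples missing from metadata: {sorted(missing)[:5]}")
    env = frame.frame.loc[samples, frame.env_columns()]
    rows = []
    for module in eig.eigengenes.columns:
        e = eig.eigengenes[module].to_numpy(dtype=float)
        for var in env.columns:
            try:
                x = pd.to_numeric(env[var], errors="raise").to_numpy(dtype=float)
            except (ValueError, TypeError) as exc:
                raise ValueError(
                    f"environmental column {var!r} is not numeric") from exc
            if np.std(x) == 0 or np.std(e) == 0:
                r, p = 0.0, 1.0
            else:
                r, p = stats.pearsonr(e, x)
            rows.append({"module": module, "variable": var,
                         "r": float(r), "p": float(p)})
    out = pd.DataFrame(rows)
    if len(out):
        _, q, _, _ = multipletests(out["p"], method="fdr_bh")
        out["q"] = q
        out["significant"] = out["p"] < alpha
    return out
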