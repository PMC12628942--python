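"""End-to-end per-climatic-group analysis driven by a single config.

Stages per group: preprocess (rarefy, merge, prevalence-filter, transform)
-> Pearson/SparCC association + BH-FDR -> signed network at the published
cutoffs (|r| >= 0.6, q < 0.001 by default) -> topology metrics and null
ensembles -> fast-greedy modules -> Zi/Pi roles -> module eigengenes and
environment correlations -> guild annotation, cross-domain edge summary and
keystone-environment Spearman correlations.  Every output file is listed in
a manifest carrying the config hash and seed; an identical config and seed
reproduce every numeric output.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import association as assoc_mod
from . import guilds as guilds_mod
from . import keystones as keys_mod
from . import netbuild, preprocess, tables_io
from .preprocess import DEFAULT_DEPTHS
from .synthetic import SynthSpec, generate_dataset

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """All knobs of the per-group analysis.

    Exactly one of ``count_tables`` (paths per domain, with ``taxonomy`` and
    ``metadata``) or ``synthetic`` must be provided.  Defaults are the
    published analysis settings: prevalence > 0.5, |r| >= 0.6, FDR q < 0.001,
    Zi/Pi cutoffs 2.5/0.62, modules reported at >= 5 nodes.
    """

    count_tables: dict[str, str] | None = None
    taxonomy: str | None = None
    metadata: str | None = None
    rrn_lookup: str | None = None
    fungal_guild_lookup: str | None = None
    protist_lookup: str | None = None
    synthetic: SynthSpec | dict | None = None

    depths: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_DEPTHS))
    min_prevalence: float = 0.5
    pseudo: float = 0.01
    method: str = "pearson"
    sparcc_options: dict[str, Any] = field(default_factory=dict)
    r_min: float = 0.6
    q_max: float = 0.001
    null_method: str = "rewire"
    null_reps: int = 100
    zi_threshold: float = 2.5
    pi_threshold: float = 0.62
    min_module_size: int = 5
    alpha_env: float = 0.05
    seed: int = 0
    outdir: str = "drynet_out"

    def __post_init__(self) -> None:
        has_files = self.count_tables is not None
        has_synth = self.synthetic is not None
        if has_files == has_synth:
            raise ConfigError(
                "provide exactly one of count_tables or synthetic")
        if has_files and (self.taxonomy is None or self.metadata is None):
            raise ConfigError("file input needs taxonomy and metadata paths")
        if isinstance(self.synthetic, dict):
            self.synthetic = SynthSpec(**self.synthetic)
        if not 0 <= self.min_prevalence < 1:
            raise ConfigError("min_prevalence must be in [0, 1)")
        if not 0 < self.r_min <= 1:
            raise ConfigError("r_min must be in (0, 1]")
        if not 0 < self.q_max <= 1:
            raise ConfigError("q_max must be in (0, 1]")
        if self.method not in ("pearson", "sparcc"):
            raise ConfigError("method must be 'pearson' or 'sparcc'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def hash(self) -> str:
        def default(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            return str(o)
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True,
                          default=default)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class GroupResult:
    group: str
    network: netbuild.SignedNetwork
    topology: netbuild.TopologySummary | None
    nulls: netbuild.NullSummary | None
    partition: keys_mod.Partition | None
    roles: keys_mod.RoleTable | None
    eigengenes: keys_mod.EigengeneTable | None
    env_correlation: pd.DataFrame | None
    crossdomain: guilds_mod.CrossDomainSummary | None
    keystone_spearman: pd.DataFrame | None


@dataclass
class PipelineResult:
    config: PipelineConfig
    groups: dict[str, GroupResult]
    guilds: guilds_mod.GuildMap
    manifest: dict


def write_association(assoc: assoc_mod.AssociationMatrix, prefix: Path) -> list[Path]:
    paths = []
    for name, mat in (("r", assoc.r), ("p", assoc.p), ("q", assoc.q)):
        if mat is None:
            continue
        path = Path(f"{prefix}.{name}.tsv")
        pd.DataFrame(mat, index=assoc.taxon_ids,
                     columns=assoc.taxon_ids).to_csv(path, sep="\t")
        paths.append(path)
    return paths


def read_association(prefix: Path, method: str = "pearson") -> assoc_mod.AssociationMatrix:
    r = pd.read_csv(f"{prefix}.r.tsv", sep="\t", index_col=0)
    p = pd.read_csv(f"{prefix}.p.tsv", sep="\t", index_col=0)
    qpath = Path(f"{prefix}.q.tsv")
    q = pd.read_csv(qpath, sep="\t", index_col=0).to_numpy() if qpath.exists() else None
    return assoc_mod.AssociationMatrix(
        list(r.index.astype(str)), r.to_numpy(), p.to_numpy(), q, method,
        n_samples=0)


def _load_inputs(config: PipelineConfig, rng: np.random.Generator):
    """Return (merged CountTable, SampleFrame, TaxonomyTable, GuildMap)."""
    if config.synthetic is not None:
        bundle = generate_dataset(config.synthetic)
        # synthetic counts are drawn at an even per-domain depth already
        return bundle.counts, bundle.frame, bundle.taxonomy, bundle.guilds
    tables = []
    for domain in tables_io.DOMAINS:
        path = config.count_tables.get(domain)
        if path is None:
            raise ConfigError(f"count_tables missing domain {domain!r}")
        table = tables_io.read_count_table(path, domain)
        table = preprocess.rarefy(table, config.depths[domain],
                                  seed=int(rng.integers(2**31 - 1)))
        tables.append(table)
    merged = preprocess.merge_domains(tables)
    frame = tables_io.read_sample_frame(config.metadata)
    taxonomy = tables_io.read_taxonomy_table(config.taxonomy)
    # merged ids are domain-prefixed; align taxonomy to them
    lineages = taxonomy.lineages
    new_index = []
    for tid in merged.taxon_ids:
        raw = tid.split("_", 1)[1]
        new_index.append(raw if raw in lineages.index else tid)
    aligned = lineages.reindex(new_index)
    aligned.index = merged.taxon_ids
    taxonomy = tables_io.TaxonomyTable(aligned)
    guilds = guilds_mod.classify_functional_groups(
        taxonomy, merged.domain,
        guilds_mod.load_rrn_lookup(config.rrn_lookup),
        guilds_mod.load_fungal_guild_lookup(config.fungal_guild_lookup),
        guilds_mod.load_protist_lookup(config.protist_lookup),
    )
    return merged, frame, taxonomy, guilds


def analyse_group(counts: tables_io.CountTable, frame: tables_io.SampleFrame,
                  guilds: guilds_mod.GuildMap, group: str,
                  config: PipelineConfig, seed: int) -> GroupResult:
    """Run the full analysis chain for one climatic group."""
    samples = frame.samples_in_group(group)
    sub = counts.subset_samples([s for s in samples if s in counts.sample_ids])
    filtered = preprocess.prevalence_filter(sub, config.min_prevalence)
    if filtered.n_taxa == 0:
        logger.warning("group %s: no taxa pass prevalence filter", group)
        return GroupResult(group, netbuild.SignedNetwork(nx.Graph()),
                           None, None, None, None, None, None, None, None)
    X = preprocess.transform_abundance(filtered, config.pseudo)
    if config.method == "sparcc":
        assoc = assoc_mod.sparcc(filtered, seed=seed, **config.sparcc_options)
    else:
        assoc = assoc_mod.pearson_with_p(X)
    assoc = assoc_mod.bh_fdr(assoc)
    domains = dict(filtered.domain)
    net = netbuild.build_network(assoc, config.r_min, config.q_max, domains)
    if net.is_empty():
        return GroupResult(group, net, None, None, None, None, None, None,
                           None, None)
    partition = keys_mod.fast_greedy_partition(net)
    topology = netbuild.topology_summary(net, modularity=partition.Q)
    nulls = netbuild.null_ensemble(net, config.null_reps, config.null_method,
                                   seed=seed + 1)
    roles = keys_mod.zi_pi_roles(net, partition, config.zi_threshold,
                                 config.pi_threshold)
    eigengenes = keys_mod.module_eigengenes(X, partition, config.min_module_size)
    env_corr = (keys_mod.module_env_correlation(eigengenes, frame,
                                                config.alpha_env)
                if len(eigengenes.eigengenes.columns) else None)
    crossdomain = guilds_mod.crossdomain_edge_summary(net, guilds)
    keystone_sp = guilds_mod.keystone_env_spearman(filtered, roles, guilds,
                                                   frame, config.alpha_env)
    return GroupResult(group, net, topology, nulls, partition, roles,
                       eigengenes, env_corr, crossdomain, keystone_sp)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run every climatic group present in the metadata; write a manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    counts, frame, taxonomy, guilds = _load_inputs(config, rng)

    groups_present = [g for g in tables_io.CLIMATIC_GROUPS
                      if g in set(frame.frame.get("group", pd.Series()))]
    results: dict[str, GroupResult] = {}
    outputs: list[str] = []
    for group in groups_present:
        seed = int(rng.integers(2**31 - 1))
        res = analyse_group(counts, frame, guilds, group, config, seed)
        results[group] = res
        slug = group.lower().replace(" ", "_").replace("-", "_")
        prefix = outdir / f"network_{slug}"
        if res.topology is not None:
            tables_io.export_network(res.network, res.partition, res.roles,
                                     prefix)
            outputs += [f"{prefix}.edges.tsv", f"{prefix}.nodes.tsv",
                        f"{prefix}.graphml"]
            pd.DataFrame([res.topology.as_dict()]).to_csv(
                outdir / f"topology_{slug}.tsv", sep="\t", index=False)
            outputs.append(str(outdir / f"topology_{slug}.tsv"))
            null_df = pd.DataFrame({"metric": list(res.nulls.means),
                                    "mean": list(res.nulls.means.values()),
                                    "sd": list(res.nulls.sds.values())})
            null_df.to_csv(outdir / f"nulls_{slug}.tsv", sep="\t", index=False)
            outputs.append(str(outdir / f"nulls_{slug}.tsv"))
            if res.env_correlation is not None:
                res.env_correlation.to_csv(
                    outdir / f"module_env_{slug}.tsv", sep="\t", index=False)
                outputs.append(str(outdir / f"module_env_{slug}.tsv"))
            if res.keystone_spearman is not None and len(res.keystone_spearman):
                res.keystone_spearman.to_csv(
                    outdir / f"keystone_env_{slug}.tsv", sep="\t", index=False)
                outputs.append(str(outdir / f"keystone_env_{slug}.tsv"))

    manifest = {
        "config_hash": config.hash(),
        "seed": config.seed,
        "null_model_note": (
            "Null ensembles: 'rewire' preserves the degree sequence "
            "(stronger than matching only node and edge counts); 'er' matches "
            "node and edge counts only.  Both readings of the published "
            "randomisation are available via null_method."),
        "groups": {
            g: (r.topology.as_dict() if r.topology else {"empty": True})
            for g, r in results.items()
        },
        "outputs": outputs,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return PipelineResult(config, results, guilds, manifest)
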