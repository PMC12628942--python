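"""Synthetic multitrophic dataset generator with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: four amplicon domains of unequal richness, samples organised into
climatic groups, a modular latent correlation structure with planted
multi-module connector taxa, compositional count sampling at domain-specific
sequencing depths, and environmental variables linearly coupled to chosen
modules.  Every draw flows from a single seeded generator, so an identical
spec and seed reproduce the bundle byte for byte.

Latent model, per sample: each module k has a factor f_k ~ N(0, 1); taxon j
in module k has log-abundance

    lambda_j = mu_j + s_j * beta * f_k + eps_j,   eps_j ~ N(0, sigma_noise^2)

with loading sign s_j negative with probability ``frac_negative``.  Planted
keystone taxa load equally on >= 3 factors (loading beta/sqrt(m) on each, so
their variance matches ordinary members); note that equal loading on m
orthogonal factors caps their correlation with any single-module member at
1/sqrt(m).  Background taxa carry independent noise only.  Counts are drawn
per domain by multinomial sampling of exp(lambda) proportions at that
domain's depth, mirroring separate marker assays rarefied separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .guilds import (GuildMap, classify_functional_groups, load_fungal_guild_lookup,
                     load_protist_lookup, load_rrn_lookup)
from .keystones import Partition
from .preprocess import DEFAULT_DEPTHS
from .tables_io import (CLIMATIC_GROUPS, DOMAIN_PREFIX, DOMAINS, ENV_VARIABLES,
                        TREATMENTS, CountTable, SampleFrame, TaxonomyTable)

#: Truth-partition labels for taxa outside ordinary modules.
KEYSTONE_MODULE = 0
BACKGROUND_MODULE = -1

# realistic base level and scale per environmental variable
_ENV_BASE = {
    "pH": (7.0, 0.5), "TotalC": (1.2, 0.4), "TotalN": (0.10, 0.03),
    "TotalP": (0.03, 0.01), "C:N": (12.0, 2.0), "C:P": (40.0, 8.0),
    "N:P": (3.5, 0.8), "VR": (10.0, 3.0), "SB": (150.0, 50.0),
    "MAP": (340.0, 70.0), "OYR": (300.0, 80.0), "TMR": (60.0, 25.0),
    "MAT": (20.0, 1.5), "CV": (0.4, 0.1), "AI": (0.2, 0.05),
}


class SynthSpecError(ValueError):
    """A synthetic-data spec field violates its invariant."""


@dataclass
class SynthSpec:
    """Parameters of the synthetic multitrophic dataset.

    Defaults mirror the study design this generator emulates: 3 climatic
    groups of 18 samples, four domains with bacteria-dominated richness, and
    the published per-marker sequencing depths.
    """

    n_samples: int = 18
    n_groups: int = 3
    module_sizes: list[int] = dc_field(default_factory=lambda: [15, 12, 10, 8, 6])
    n_background: int = 40
    domain_fractions: dict[str, float] = dc_field(default_factory=lambda: {
        "bacteria": 0.62, "fungi": 0.27, "protist": 0.09, "nematode": 0.02})
    mu: float = 0.0
    mu_spread: float = 1.0
    beta: float = 1.0
    frac_negative: float = 0.3
    sigma_noise: float = 0.3
    n_keystone: int = 3
    depth_by_domain: dict[str, int] = dc_field(
        default_factory=lambda: dict(DEFAULT_DEPTHS))
    #: None -> couple the first up-to-three modules to MAP(+), SB(-), pH(+)
    env_coupling: dict[int, tuple[str, int]] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.env_coupling is None:
            canonical = [("MAP", 1), ("SB", -1), ("pH", 1)]
            self.env_coupling = {
                k: canonical[k]
                for k in range(min(len(canonical), len(self.module_sizes)))}
        self.env_coupling = {int(k): (var, int(sign))
                             for k, (var, sign) in self.env_coupling.items()}

    def validate(self) -> None:
        if self.n_samples < 2:
            raise SynthSpecError("n_samples: need at least 2 samples per group")
        if not 1 <= self.n_groups <= len(CLIMATIC_GROUPS):
            raise SynthSpecError(
                f"n_groups: must be in [1, {len(CLIMATIC_GROUPS)}]")
        if not self.module_sizes or any(s < 2 for s in self.module_sizes):
            raise SynthSpecError("module_sizes: every module needs >= 2 taxa")
        if self.n_background < 0:
            raise SynthSpecError("n_background: must be non-negative")
        if set(self.domain_fractions) != set(DOMAINS):
            raise SynthSpecError(
                f"domain_fractions: must cover exactly {DOMAINS}")
        if abs(sum(self.domain_fractions.values()) - 1.0) > 1e-9:
            raise SynthSpecError("domain_fractions: must sum to 1")
        if any(f < 0 for f in self.domain_fractions.values()):
            raise SynthSpecError("domain_fractions: must be non-negative")
        if not 0 <= self.frac_negative <= 1:
            raise SynthSpecError("frac_negative: must be in [0, 1]")
        if self.sigma_noise < 0:
            raise SynthSpecError("sigma_noise: must be >= 0")
        if self.mu_spread < 0:
            raise SynthSpecError("mu_spread: must be >= 0")
        if self.n_keystone < 0:
            raise SynthSpecError("n_keystone: must be non-negative")
        if (set(self.depth_by_domain) != set(DOMAINS)
                or any(d <= 0 for d in self.depth_by_domain.values())):
            raise SynthSpecError(
                "depth_by_domain: need a positive depth for every domain")
        for k, (var, sign) in self.env_coupling.items():
            if not 0 <= k < len(self.module_sizes):
                raise SynthSpecError(f"env_coupling: module index {k} out of range")
            if var not in ENV_VARIABLES:
                raise SynthSpecError(f"env_coupling: unknown variable {var!r}")
            if sign not in (-1, 1):
                raise SynthSpecError("env_coupling: sign must be +1 or -1")


@dataclass
class SyntheticBundle:
    """A generated dataset plus the ground truth the analysis should recover."""

    counts: CountTable
    frame: SampleFrame
    taxonomy: TaxonomyTable
    guilds: GuildMap
    truth_partition: Partition
    truth_keystones: set[str]
    truth_env_links: dict[int, tuple[str, int]]
    latent: pd.DataFrame  # taxa x samples latent log-abundances


def _assign_domains(n_taxa: int, fractions: dict[str, float],
                    rng: np.random.Generator) -> list[str]:
    """Largest-remainder quota per domain, shuffled across taxa."""
    quotas = {d: fractions[d] * n_taxa for d in DOMAINS}
    base = {d: int(np.floor(q)) for d, q in quotas.items()}
    short = n_taxa - sum(base.values())
    for d in sorted(DOMAINS, key=lambda d: quotas[d] - base[d], reverse=True)[:short]:
        base[d] += 1
    pool = [d for d in DOMAINS for _ in range(base[d])]
    rng.shuffle(pool)
    return pool


def _taxonomy_for(domain: str, rng: np.random.Generator) -> dict[str, str]:
    """Draw a plausible lineage; ~1 in 8 taxa get an unmatched genus."""
    if rng.random() < 0.125:
        return {"kingdom": domain, "genus": f"Unassigned{rng.integers(100)}",
                "guild": ""}
    if domain == "bacteria":
        lut = load_rrn_lookup()
        genera = list(lut.loc[lut["rank"] == "genus", "name"])
        return {"kingdom": "Bacteria", "genus": str(rng.choice(genera)), "guild": ""}
    if domain == "fungi":
        lut = load_fungal_guild_lookup()
        i = int(rng.integers(len(lut)))
        return {"kingdom": "Fungi", "genus": str(lut["genus"].iloc[i]),
                "guild": str(lut["guild"].iloc[i])}
    if domain == "protist":
        lut = load_protist_lookup()
        return {"kingdom": "Eukaryota",
                "genus": str(rng.choice(list(lut["genus"]))), "guild": ""}
    return {"kingdom": "Eukaryota",
            "genus": str(rng.choice(["Acrobeles", "Aphelenchus", "Cephalobus"])),
            "guild": ""}


def generate_dataset(spec: SynthSpec) -> SyntheticBundle:
    """Generate a seeded multitrophic dataset with planted structure."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    n_modules = len(spec.module_sizes)
    n_module_taxa = int(sum(spec.module_sizes))
    n_taxa = n_module_taxa + spec.n_keystone + spec.n_background
    n_total_samples = spec.n_samples * spec.n_groups

    # --- taxa: truth module labels and domain assignment -------------------
    truth_module = (
        [k + 1 for k, size in enumerate(spec.module_sizes) for _ in range(size)]
        + [KEYSTONE_MODULE] * spec.n_keystone
        + [BACKGROUND_MODULE] * spec.n_background
    )
    domains_list = _assign_domains(n_taxa, spec.domain_fractions, rng)
    taxon_ids = [f"{DOMAIN_PREFIX[d]}_ASV{i:04d}"
                 for i, d in enumerate(domains_list)]
    domain = pd.Series(domains_list, index=taxon_ids)

    # --- latent log-abundances ---------------------------------------------
    factors = rng.standard_normal((n_total_samples, n_modules))
    mu_j = spec.mu + spec.mu_spread * rng.standard_normal(n_taxa)
    signs = np.where(rng.random(n_taxa) < spec.frac_negative, -1.0, 1.0)
    m_key = min(3, n_modules)
    keystone_factors = [tuple(sorted(rng.choice(n_modules, size=m_key,
                                                replace=False)))
                        for _ in range(spec.n_keystone)]
    lam = np.tile(mu_j[:, None], (1, n_total_samples))
    key_idx = 0
    for j in range(n_taxa):
        label = truth_module[j]
        if label >= 1:
            lam[j] += signs[j] * spec.beta * factors[:, label - 1]
        elif label == KEYSTONE_MODULE:
            ks = keystone_factors[key_idx]
            key_idx += 1
            lam[j] += (signs[j] * spec.beta / np.sqrt(m_key)
                       * factors[:, list(ks)].sum(axis=1))
    lam += spec.sigma_noise * rng.standard_normal((n_taxa, n_total_samples))

    # --- compositional counts per domain -----------------------------------
    sample_ids = [f"S{i + 1:03d}" for i in range(n_total_samples)]
    counts = np.zeros((n_taxa, n_total_samples), dtype=np.int64)
    for d in DOMAINS:
        rows = np.flatnonzero(domain.to_numpy() == d)
        if rows.size == 0:
            continue
        depth = spec.depth_by_domain[d]
        for s in range(n_total_samples):
            logp = lam[rows, s]
            p = np.exp(logp - logp.max())
            p /= p.sum()
            counts[rows, s] = rng.multinomial(depth, p)
    count_table = CountTable(
        pd.DataFrame(counts, index=taxon_ids, columns=sample_ids), domain)

    # --- sample metadata -----------------------------------------------------
    groups = [CLIMATIC_GROUPS[g] for g in range(spec.n_groups)
              for _ in range(spec.n_samples)]
    treatments = [TREATMENTS[i % len(TREATMENTS)] for i in range(n_total_samples)]
    env = {}
    coupled_vars = {var: (k, sign) for k, (var, sign) in spec.env_coupling.items()}
    for var in ENV_VARIABLES:
        base, scale = _ENV_BASE[var]
        noise = rng.standard_normal(n_total_samples)
        if var in coupled_vars:
            k, sign = coupled_vars[var]
            env[var] = base + scale * (sign * factors[:, k] + noise) / np.sqrt(2)
        else:
            env[var] = base + scale * noise
    frame = SampleFrame(pd.DataFrame(
        {"group": groups, "treatment": treatments, **env}, index=sample_ids))

    # --- taxonomy and guilds -------------------------------------------------
    lineages = pd.DataFrame(
        [_taxonomy_for(d, rng) for d in domains_list], index=taxon_ids)
    taxonomy = TaxonomyTable(lineages)
    guilds = classify_functional_groups(taxonomy, domain)

    membership = dict(zip(taxon_ids, truth_module))
    sizes: dict[int, int] = {}
    for m in truth_module:
        sizes[m] = sizes.get(m, 0) + 1
    truth_partition = Partition(membership, 0.0, sizes)
    truth_keystones = {t for t, m in membership.items() if m == KEYSTONE_MODULE}
    truth_env_links = {k + 1: (var, sign)
                       for k, (var, sign) in spec.env_coupling.items()}
    latent = pd.DataFrame(lam, index=taxon_ids, columns=sample_ids)
    return SyntheticBundle(count_table, frame, taxonomy, guilds,
                           truth_partition, truth_keystones, truth_env_links,
                           latent)
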