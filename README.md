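# drynet

Multitrophic soil co-occurrence network analysis for dryland amplicon
surveys.

Soil food webs in arid and semi-arid ecosystems couple bacteria, fungi,
protists and nematodes across trophic levels.  A standard way to study how
rainfall regimes reshape these couplings is to build per-condition
co-occurrence networks from amplicon ASV tables: taxa are nodes, and edges
are statistically robust pairwise abundance correlations.  `drynet`
implements that analysis as a tested, reusable library and CLI:

- **Preprocessing** — seeded rarefaction to per-marker depths, merging the
  four domain tables, strict >50% prevalence filtering per climatic group,
  and log10 abundance transform.
- **Association** — all-pairs Pearson r with exact t-distribution p-values
  and Benjamini–Hochberg FDR; SparCC (Dirichlet-resampled log-ratio
  variances with sparsity-driven basis-variance estimation) as the
  compositionally aware alternative.
- **Threshold diagnostics** — the random-matrix-theory scan: the
  nearest-neighbour spacing distribution of the thresholded matrix's
  unfolded eigenvalues transitions from GOE (Wigner) to Poisson statistics
  as the threshold clears noise.
- **Networks** — signed edges at |r| ≥ 0.6, q < 0.001 (configurable);
  topology metrics avgK = 2E/N, avgCC, mean path distance GD,
  positive:negative ratio; degree-preserving rewiring and Erdős–Rényi null
  ensembles.
- **Modules & keystones** — deterministic fast-greedy (Clauset–Newman–
  Moore) modularity maximisation; Zi–Pi topological roles with the 2.5/0.62
  cutoffs (peripherals, connectors, module hubs, network hubs); module
  eigengenes (first singular vector of member profiles) correlated against
  environmental variables.
- **Guilds** — oligotroph/copiotroph bacteria by rrn copy number (≥ 5 →
  copiotroph), fungal trophic modes by first-listed guild, protist feeding
  groups by genus, nematodes as consumers; cross-domain edge accounting
  (BB, BF, …) and Spearman correlations of keystone-group abundances
  against environment.
- **Synthetic data** — a seeded generator that plants modules, multi-module
  keystone taxa and module–environment couplings in compositional counts,
  so the whole chain is testable without sequencing data.

## Worked example

Run the full pipeline on a synthetic three-condition dataset:

```bash
cat > config.yaml <<'YAML'
synthetic:
  seed: 4
null_reps: 20
outdir: demo_out
YAML
drynet run-all --config config.yaml --seed 4
```

This prints the per-condition topology summaries, e.g. for the first
condition:

```json
"Arid": {
  "nodes": 58,
  "edges": 153,
  "positive": 123,
  "negative": 30,
  "pos_neg_ratio": 4.1,
  "avgK": 5.276,
  "avgCC": 0.634,
  "GD": 1.485,
  "modularity": 0.688
}
```

Read it as: 58 taxa kept at least one robust association; of the 153 edges,
123 are positive co-variation and 30 negative (ratio 4.1); the average node
has 5.3 partners (avgK = 2·153/58); high clustering (avgCC 0.63) and a
short mean path (GD 1.49) reflect the planted dense modules; and the
fast-greedy partition reaches modularity Q = 0.688, far above the
Erdős–Rényi null mean (~0.15 at this size), confirming modular structure.
`demo_out/` then contains, per condition, the Cytoscape-ready edge/node
attribute tables, GraphML, topology and null-model summaries, Zi–Pi role
tables, and module–environment correlation tables, listed in
`manifest.json` together with the config hash and seed — identical config
and seed reproduce every number.

Library use mirrors the CLI:

```python
from drynet import (SynthSpec, generate_dataset, prevalence_filter,
                    transform_abundance, pearson_with_p, bh_fdr,
                    build_network, fast_greedy_partition, zi_pi_roles)

bundle = generate_dataset(SynthSpec(seed=4))
counts = prevalence_filter(bundle.counts.subset_samples(
    bundle.frame.samples_in_group("Arid")))
assoc = bh_fdr(pearson_with_p(transform_abundance(counts)))
net = build_network(assoc, r_min=0.6, q_max=0.001, domains=dict(counts.domain))
partition = fast_greedy_partition(net)
roles = zi_pi_roles(net, partition)
print(partition.Q, roles.table["role"].value_counts().to_dict())
```

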