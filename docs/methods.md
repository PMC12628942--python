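# Methods

## Overview

`drynet` reconstructs multitrophic soil co-occurrence networks from amplicon
count tables of four organism groups — bacteria (16S), fungi (ITS), protists
(18S) and nematodes (28S) — sampled across dryland climatic conditions, and
relates the resulting modules and keystone taxa to environmental gradients.
The chain is: rarefaction → domain merge → per-group prevalence filter →
log-abundance transform → pairwise association (Pearson + BH-FDR, or SparCC)
→ signed network at fixed cutoffs → topology metrics and null baselines →
fast-greedy modules → Zi–Pi roles → module eigengenes and environment
correlations → guild annotation and keystone–environment correlations.

## Preprocessing

Counts are rarefied per marker by seeded multivariate-hypergeometric
subsampling (without replacement); samples below the target depth cannot be
subsampled and are dropped with a logged warning.  Default depths are the
published per-marker values: 4,485 (bacteria), 10,526 (fungi), 1,079
(protists), 412 (nematodes) reads per sample.  The four tables are
row-concatenated with domain-prefixed ids (`B_`, `F_`, `P_`, `N_`) so ASV
labels cannot collide across markers.

Each climatic group (n = 18 samples by default) is analysed separately.
The prevalence filter is strict — a taxon must be detected in *more than*
half of the group's samples, so 9/18 fails — which matches the published
retention rule.  Retained counts are zero-filled with a pseudo-count
(default 0.01) and log10-transformed.  Both the pseudo-count and the filter
fraction are configurable because the upstream pipeline this emulates does
not document its internal fill value; 0.01/log10 follows that pipeline's
usual defaults, and results are insensitive to the choice for taxa passing
the prevalence filter (their counts are mostly positive).

## Association inference

Pearson r across samples with the exact two-sided t-distribution p-value
(t = r√((n−2)/(1−r²)), df = n−2).  Constant profiles get r = 0, p = 1 and a
logged flag rather than being dropped, keeping the matrix aligned with the
filtered table.  Benjamini–Hochberg q-values are computed once per unordered
pair (upper triangle) and mirrored.

SparCC is provided as the compositionally aware alternative: fractions are
posterior means of Dirichlet(counts + 1) draws (20 by default); log-ratio
variances T_ij = Var log(x_i/x_j) yield basis variances through the sparse
linear system t_i = (D−2)ω_i + Σ_k ω_k, and correlations
ρ_ij = (ω_i + ω_j − T_ij)/(2√(ω_i ω_j)), clipped to [−1, 1].  Up to 10
rounds exclude the strongest |ρ| pair above 0.1 from the estimation so the
sparsity assumption holds.  Non-positive basis variances (a known edge case)
are floored at 1e−6 with a warning.  Permutation p-values permute each
taxon's samples independently and use the add-one estimator
p = (1 + #{|ρ_null| ≥ |ρ_obs|})/(1 + n_boot), so p = 0 never occurs.

## Threshold selection

The network cutoff defaults to the published |r| ≥ 0.6 with FDR q < 0.001.
The random-matrix-theory scan that motivates such cutoffs is implemented as
a diagnostic: at each threshold the sub-threshold |r| entries are zeroed,
taxa without any retained partner are dropped, and the nearest-neighbour
spacing distribution (NNSD) of the unfolded eigenvalues is tested against
the Poisson density e^{−d} by a binned chi-square (bins of width 0.1 on
[0, 3] plus an overflow bin; adjacent bins merged until every expected count
is ≥ 1).  Unfolding smooths the cumulative spectral function with a monotone
cubic (PCHIP) fit over ⌈N/10⌉ knots, rescales to [0, N], and normalises the
spacings to mean exactly 1.  Eigen-decomposition acts on |r| with unit
diagonal: NNSD theory concerns magnitude structure, and the signed variant
gives the same conclusions on our synthetic spectra.  The selected threshold
is the smallest one accepted at α = 0.001 whose acceptance persists for
every larger evaluable threshold; degenerate spectra (< 20 distinct
eigenvalues after 1e−8 deduplication) are reported as such, never crashed
on.

On the synthetic recovery conditions the NNSD-selected threshold (0.51)
sits about 0.2 below the threshold maximising planted-edge F1 (0.72).  This
is a property of the two objectives, not a defect: the spacing criterion
accepts as soon as the GOE-like background spectrum is cleaned, while F1
keeps improving as long as discarding weak true edges also discards many
compositional false edges.  The pipeline therefore treats the scan as
provenance and diagnostics, with the fixed published 0.6 as the default
gatekeeper.

## Network construction and topology

Edges connect pairs with |r| ≥ r_min (inclusive) and q < q_max (strict);
the sign records the correlation's direction.  Isolated taxa are not nodes
— published node counts sit far below the filtered taxon counts, implying
edge-bearing nodes only.  Topology metrics are computed on the unsigned
skeleton: avgK = 2E/N; avgCC is the mean of C_i = 2T_i/(k_i(k_i−1)) with
C_i = 0 for degree < 2; GD is the mean unweighted shortest-path length over
connected unordered pairs (disconnected pairs are skipped, the usual
convention for fragmented co-occurrence graphs); the positive:negative
ratio is reported as missing when no negative edges exist.

Null ensembles come in two flavours, because "random networks with the same
number of nodes and edges" admits two readings: `rewire` (default) applies
10E attempted degree-preserving double edge swaps and then randomly
reassigns the observed sign multiset — a stronger null that also fixes the
degree sequence — and `er` draws uniform G(N, E) graphs.  Each replicate's
avgCC, GD and fast-greedy Q are summarised as mean ± sd; the manifest notes
the ambiguity.

## Modules and topological roles

Fast-greedy (Clauset–Newman–Moore) modularity maximisation is implemented
directly: starting from singletons, the connected community pair with
maximal ΔQ = e_ab/L − d_a d_b/(2L²) is merged, ties broken by the
lexicographically smallest community-id pair (a community is identified by
its smallest member), and the best-Q partition along the merge path is
returned.  The deterministic tie-break makes results platform-stable.  Q is
the standard unweighted Newman–Girvan modularity; on graphs of ≤ 8 nodes the
result is verified against exhaustive search over all set partitions.

Roles follow the within-module degree z-score Zi and participation
coefficient Pi = 1 − Σ_s (κ_is/k_i)², with the conventional cutoffs 2.5 and
0.62: peripherals (low/low), connectors (low Zi, high Pi), module hubs
(high Zi, low Pi), network hubs (high/high).  Boundary values fall in the
low class, following the strict "greater than" reading of the cutoffs.  A
module whose members all share the same within-module degree has zero
spread; such nodes get Zi = 0 (topologically average in their module).
Connectors, module hubs and network hubs together form the keystone set.

Module eigengenes are the first left singular vector of the samples ×
members matrix of z-scored profiles (sample-variance standardisation),
sign-oriented so the summed member correlation is non-negative; variance
explained is the leading squared singular value over the total.  Modules
below 5 members are omitted from eigengene reporting, matching the
"modules with five or more nodes" convention.  Module–environment
association uses Pearson r with raw-p significance flags (α = 0.05) plus
BH q reported alongside — raw p because that is how such module
correlations are conventionally reported, q so readers can apply
multiplicity control.

## Guild annotation

Bacteria: mean rRNA operon (rrn) copy number at the deepest matching rank
(genus, then one-level family fallback) classifies copiotrophs (≥ 5 copies)
versus oligotrophs (< 5).  Fungi: the first-listed trophic mode of the
guild string (pathotroph / saprotroph / symbiotroph); expert overrides are
supported only through an explicit user-supplied table, never inferred.
Protists: genus-level feeding groups (consumer / phototroph / pathotroph).
Nematodes: all trophic groups collapse to consumer.  Anything unmatched is
`unknown`, so the map is total.  The packaged lookup tables are small
constructed stand-ins (marked `.synthetic.tsv`) sufficient for testing and
for the synthetic generator; users with database access should supply full
tables.

Keystone–environment association uses Spearman rho (average ranks for
ties) on per-sample relative abundances of each keystone functional group
and each individual keystone taxon.

## Synthetic data generator

The generator emulates the study design: `n_groups` climatic groups ×
`n_samples` samples (default 3 × 18), four domains of unequal richness
(default fractions 0.62/0.27/0.09/0.02, mirroring the observed dominance of
bacteria over fungi, protists and nematodes), and the published per-marker
depths.  Per sample, module k has a latent factor f_k ~ N(0,1); taxon j in
module k has log-abundance λ_j = μ_j + s_j β f_k + ε_j with loading sign
s_j negative with probability `frac_negative` (default 0.3, giving the
mixed-sign edge structure real networks show), residual sd `sigma_noise`
(default 0.3) and per-taxon baseline spread `mu_spread` (default 1,
creating realistic abundance heterogeneity and zero patterns).  Background
taxa carry independent noise only and calibrate false-positive edges.
Counts are multinomial draws of the exp(λ) proportions per domain at that
domain's depth; environmental variables are linear maps of designated
factors plus unit noise, under the field's standard column names so
downstream stages run unchanged.  A single root generator seeded by
`seed` drives every draw.

Planted keystones load equally on min(3, K) factors with per-factor loading
β/√m, keeping their variance equal to ordinary members.  A consequence
worth knowing: equal loading on m orthogonal factors caps the keystone's
correlation with any single-module member at 1/√m ≈ 0.577 for m = 3 —
*below* the published 0.6 cutoff.  Keystone-recovery checks therefore build
the network at r_min = 0.45, q < 0.01, a setting derived from this bound
rather than from any test outcome; at the published cutoffs keystones are
(correctly) too weakly coupled to appear, which mirrors how few connectors
real dryland networks show at those cutoffs.

What the generator does not emulate: sequencing error, chimeras, primer
bias, phylogenetic signal in abundances, or overdispersed (non-multinomial)
count noise.  Passing recovery tests therefore demonstrates correctness of
the inference chain under the assumed latent-factor model, not robustness
to those real-data artefacts.  Compositional closure *is* present (counts
are proportions at fixed depth), which is why small-richness domains show
spurious negative correlations — realistic, and the reason SparCC is
offered.

## Problem sizes used in tests and the acceptance script

Recovery experiments use 3 modules × 20 taxa plus 3 keystones and 40
background taxa over 50 samples at 50k depth (generator seed 1); GOE
diagnostics use 200×200 matrices; the block-structure scan uses two
15-taxon blocks; null contrasts use 100 replicates.  These sizes make every
check deterministic and quick while keeping estimation error well inside
the asserted margins.

## Known limitations

- GD is averaged over connected pairs; largest-component-only GD is not yet
  exposed as a flag (fragmented graphs are rare at the default cutoffs).
- SparCC permutation p-values use a single Dirichlet draw per null
  replicate for speed; p-values below 1/(1+n_boot) are unattainable.
- The fast-greedy implementation is O(N·E) per network — fine for hundreds
  of nodes, not for tens of thousands.
- Guild fixtures are constructed stand-ins, not database exports; analyses
  of real data should supply full rrn / fungal-guild / protist tables.
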