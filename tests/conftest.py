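import networkx as nx
import pytest

from drynet import (DOMAINS, bh_fdr, build_network, pearson_with_p,
                    prevalence_filter, transform_abundance)
from drynet.netbuild import SignedNetwork
from drynet.synthetic import SynthSpec, generate_dataset

#: Settings for the planted-structure recovery experiments: three modules of
#: 20 taxa, 50 samples, moderate residual noise, even 50k depth per domain.
RECOVERY_SPEC = dict(
    n_samples=50, n_groups=1, module_sizes=[20, 20, 20],
    sigma_noise=0.3, beta=1.0,
    depth_by_domain={d: 50_000 for d in DOMAINS}, seed=1,
)

#: Network settings for keystone recovery.  A taxon loading equally on three
#: orthogonal factors correlates at most 1/sqrt(3) ~ 0.577 with any
#: single-module member, so keystone edges need a cutoff below that bound.
KEYSTONE_R_MIN = 0.45
KEYSTONE_Q_MAX = 0.01


@pytest.fixture(scope="session")
def recovery_bundle():
    return generate_dataset(SynthSpec(**RECOVERY_SPEC))


@pytest.fixture(scope="session")
def recovery_assoc(recovery_bundle):
    filtered = prevalence_filter(recovery_bundle.counts, 0.5)
    X = transform_abundance(filtered)
    return bh_fdr(pearson_with_p(X)), filtered, X


@pytest.fixture(scope="session")
def recovery_network(recovery_assoc):
    assoc, filtered, _ = recovery_assoc
    return build_network(assoc, 0.6, 0.001, dict(filtered.domain))


def make_signed_network(edges, default_sign="positive"):
    """Small handmade network helper: edges as (u, v) or (u, v, sign)."""
    graph = nx.Graph()
    for edge in edges:
        if len(edge) == 2:
            u, v = edge
            sign = default_sign
        else:
            u, v, sign = edge
        graph.add_edge(u, v, r=1.0 if sign == "positive" else -1.0,
                       sign=sign, q=0.0)
    return SignedNetwork(graph)
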