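import numpy as np
import pytest

from pnet import PNet, TrainingConfig, synthetic
from pnet.hierarchy import (
    GeneSetCollection,
    build_layered_network,
    parse_relations,
)


@pytest.fixture(scope="session")
def chain_net():
    """4-layer network from the chain root -> P1 -> P2, genes on P2, K=2.

    P2 (depth 2) is deeper than the two retained layers and collapses into
    P1, which inherits its gene annotation.
    """
    graph = parse_relations([("P1", "ROOT"), ("P2", "P1")], species_prefix=None)
    genesets = GeneSetCollection(membership={"P2": frozenset({"G1", "G2"})})
    return build_layered_network(graph, genesets, n_pathway_layers=2)


@pytest.fixture(scope="session")
def small_cohort():
    """Default-condition synthetic cohort, small enough for fast training."""
    return synthetic.generate(synthetic.SimulationConfig(n_samples=200, seed=7))


@pytest.fixture(scope="session")
def trained(small_cohort):
    """A fitted model on the small cohort (shared across read-only tests)."""
    net = small_cohort.build_network()
    model = PNet(
        small_cohort.tensor,
        small_cohort.labels,
        net,
        config=TrainingConfig(epochs=60, seed=11),
    )
    res = model.fit()
    return {
        "cohort": small_cohort,
        "net": net,
        "X": small_cohort.tensor.flatten(),
        "y": small_cohort.y,
        "results": res,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
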