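"""Shared fixtures: small synthetic studies and hand-built networks."""

import numpy as np
import pandas as pd
import pytest

from glvnet import (
    AbundanceTable,
    ConsensusNetwork,
    GlvParameters,
    StudyDesign,
    generate_interaction_matrix,
    generate_study,
)


@pytest.fixture(scope="session")
def tiny_study():
    """1 group x 2 replicates x 3 time points x 3 taxa, with ground truth."""
    design = StudyDesign(
        n_groups=1,
        replicates_per_group=2,
        time_grid=(0.0, 1.0, 2.0),
        n_taxa=3,
        library_size=5_000,
        noise_sd=0.02,
        seed=11,
    )
    params = generate_interaction_matrix(3, density=1.0, seed=7)
    table, truth = generate_study(design, [params])
    return table, truth


@pytest.fixture(scope="session")
def two_group_study():
    """2 groups x 3 replicates x 6 time points x 8 taxa."""
    design = StudyDesign(
        n_groups=2,
        replicates_per_group=3,
        time_grid=(-1.0, 0.0, 1.0, 2.0, 4.0, 7.0),
        n_taxa=8,
        library_size=8_000,
        noise_sd=0.05,
        seed=23,
    )
    params = {
        "sham": generate_interaction_matrix(8, density=0.3, seed=31),
        "sni": generate_interaction_matrix(8, density=0.3, positive_fraction=0.7, seed=37),
    }
    table, truth = generate_study(design, params)
    return table, truth


def build_network(edges, taxa=None):
    """ConsensusNetwork from (source, target, sign) triples."""
    frame = pd.DataFrame(
        [
            {
                "source": s,
                "target": t,
                "sign": sign,
                "support": 1.0,
                "mean_strength": float(sign),
            }
            for s, t, sign in edges
        ],
        columns=list(ConsensusNetwork.EDGE_COLUMNS),
    )
    if taxa is None:
        taxa = sorted({e[0] for e in edges} | {e[1] for e in edges})
    return ConsensusNetwork(taxa=list(taxa), edges=frame)


@pytest.fixture
def path_network():
    """A -> B -> C (all positive)."""
    return build_network([("A", "B", 1), ("B", "C", 1)])


@pytest.fixture
def single_taxon_params():
    """Logistic-style one-taxon community: growth 0.8, self-limitation -0.5."""
    return GlvParameters(
        growth=np.array([0.8]),
        interactions=np.array([[-0.5]]),
        taxa=["solo"],
    )
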