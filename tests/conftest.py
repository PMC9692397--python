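import numpy as np
import pandas as pd
import pytest

from hormonet.de import CountMatrix
from hormonet.network import InteractionNetwork, PathwayCollection, merge_pathways
from hormonet.simulate import SimulationConfig, simulate_counts


@pytest.fixture(scope="session")
def small_counts() -> CountMatrix:
    """Tiny 4-condition matrix with 2 replicates, hand-set counts."""
    rng = np.random.default_rng(7)
    genes = [f"g{i}" for i in range(50)]
    samples = [f"{c}_{r}" for c in ("CTRL", "T3", "CORT", "T3CORT")
               for r in (1, 2)]
    counts = pd.DataFrame(
        rng.poisson(100, size=(50, 8)), index=genes, columns=samples
    )
    return CountMatrix.from_dataframe(counts)


@pytest.fixture(scope="session")
def synthetic_dataset():
    """Default-condition synthetic dataset reused across tests."""
    return simulate_counts(SimulationConfig(n_genes=400, n_null_genes=340,
                                            seed=123))


def toy_network(edges, crosstalk=(), other_de=()) -> InteractionNetwork:
    """One-pathway network from an explicit edge list (helper)."""
    genes = sorted({g for e in edges for g in e} | set(crosstalk) | set(other_de))
    coll = PathwayCollection.from_dict({"PW": genes}, {"PW": list(edges)})
    de = set(crosstalk) | set(other_de)
    return merge_pathways(coll, de_genes=de, crosstalk_genes=set(crosstalk))
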