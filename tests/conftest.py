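import numpy as np
import pandas as pd
import pytest

from cernapipe.datatypes import ExpressionDataset, RNAClass
from cernapipe.network import CORRELATION_ONLY, CeRNANetwork
from cernapipe.simulate import GeneratorConfig, generate


def small_generator_config(seed: int = 0, **overrides) -> GeneratorConfig:
    """A scaled-down five-subtype world for fast tests."""
    kwargs = dict(
        seed=seed,
        subtypes=tuple(zip("ABCDE", (40, 40, 40, 40, 40))),
        n_genes={RNAClass.MRNA: 60, RNAClass.LNCRNA: 24,
                 RNAClass.CIRCRNA: 24, RNAClass.MIRNA: 24},
        n_common_triplets=1,
        n_specific_triplets=2,
        n_planted_biomarkers=1,
        n_outliers=2,
        n_decoy_interactions=30,
    )
    kwargs.update(overrides)
    return GeneratorConfig(**kwargs)


@pytest.fixture(scope="session")
def small_cohort():
    return generate(small_generator_config(seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_dataset(values: np.ndarray, classes: dict[str, RNAClass],
                 subtype: str = "test") -> ExpressionDataset:
    genes = list(classes)
    samples = [f"s{i}" for i in range(values.shape[1])]
    return ExpressionDataset(
        subtype=subtype,
        values=pd.DataFrame(values, index=genes, columns=samples),
        classes=pd.Series(classes),
    )


def make_network(edges, classes: dict[str, RNAClass], tag: str = "t",
                 weights=None) -> CeRNANetwork:
    """Build a network from (a, b) pairs with dummy miRNA evidence."""
    net = CeRNANetwork(tag=tag)
    for g, c in classes.items():
        net.add_node(g, c)
    for i, (a, b) in enumerate(edges):
        w = 0.5 if weights is None else weights[i]
        net.add_edge(a, b, classes[a], classes[b], w, ("mir_x",), CORRELATION_ONLY)
    return net
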