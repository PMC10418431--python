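import pandas as pd
import pytest

from jamqspr.components import COMPONENT_SMILES, reference_descriptor_table
from jamqspr.descriptors import compute_descriptors, parse_smiles


@pytest.fixture(scope="session")
def golden_table() -> pd.DataFrame:
    """Published five-component descriptor table."""
    return reference_descriptor_table()


@pytest.fixture(scope="session")
def component_graphs():
    return {name: parse_smiles(smi) for name, smi in COMPONENT_SMILES.items()}


@pytest.fixture(scope="session")
def component_vectors():
    return {name: compute_descriptors(smi) for name, smi in COMPONENT_SMILES.items()}


@pytest.fixture(scope="session")
def small_records() -> pd.DataFrame:
    """96-record dataset on the four analytic storage days."""
    from jamqspr.simulate import GeneratorConfig, generate_dataset

    cfg = GeneratorConfig(times=(0, 30, 90, 120), replicates=2, seed=11,
                          n_records=None)
    return generate_dataset(cfg=cfg)
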