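import numpy as np
import pandas as pd
import pytest

from amdtox import catalog as catalog_mod
from amdtox import fixtures


@pytest.fixture(scope="session")
def mrg_catalog():
    return catalog_mod.default_catalog()


@pytest.fixture(scope="session")
def water_chem():
    return fixtures.load_water_chemistry()


@pytest.fixture(scope="session")
def standards():
    return fixtures.load_standards()


@pytest.fixture(scope="session")
def free_fractions():
    return fixtures.load_free_fractions()


@pytest.fixture()
def toy_genes():
    """Six genes over two KOs, two domains, two MAGs; lengths chosen so TPM
    values come out round."""
    return pd.DataFrame(
        {
            "gene_id": [f"g{i}" for i in range(1, 7)],
            "length": [100, 400, 200, 200, 100, 500],
            "ko": ["K00001", "K00001", "K00002", None, "K00002", None],
            "domain": ["Bacteria", "Bacteria", "Archaea", "Archaea", "Bacteria", "Bacteria"],
            "mag_id": ["m1", "m1", "m1", "m2", "m2", "m2"],
        }
    )


@pytest.fixture()
def toy_counts(toy_genes):
    rng = np.random.default_rng(0)
    counts = pd.DataFrame(
        rng.integers(0, 50, size=(len(toy_genes), 3)),
        index=toy_genes["gene_id"],
        columns=["s1", "s2", "s3"],
    )
    counts.index.name = "gene_id"
    return counts
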