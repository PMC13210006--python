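import numpy as np
import pandas as pd
import pytest

from rhizonet.core_io import FeatureTable, SampleMetadata, TaxonomyMap
from rhizonet.synthetic import GeneratorConfig, generate_dataset


@pytest.fixture
def tiny_table():
    df = pd.DataFrame(
        [[2.0, 2.0, 0.0], [1.0, 0.0, 3.0]],
        index=["s1", "s2"], columns=["t1", "t2", "t3"],
    )
    return FeatureTable(df, mode="counts")


@pytest.fixture
def taxonomy():
    df = pd.DataFrame(
        {
            "kingdom": ["Bacteria"] * 4,
            "phylum": ["P1"] * 4,
            "class": ["C1"] * 4,
            "order": ["O1"] * 4,
            "family": ["F1", "F1", "F2", "unassigned"],
            "genus": ["G1", "G1", "unassigned", "unassigned"],
        },
        index=["t1", "t2", "t3", "t4"],
    )
    return TaxonomyMap(df)


@pytest.fixture
def metadata18():
    rows = []
    for t in ("NT", "MT"):
        for s in ("NS", "HS", "TS"):
            for r in (1, 2, 3):
                rows.append({"sample_id": f"{t}-{s}-{r}", "tillage": t,
                             "straw": s, "replicate": r})
    return SampleMetadata(pd.DataFrame(rows).set_index("sample_id"))


@pytest.fixture(scope="session")
def default_dataset():
    """One shared realisation of the default 18-sample generator."""
    return generate_dataset(GeneratorConfig(seed=42))


@pytest.fixture
def rng():
    return np.random.default_rng(7)
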