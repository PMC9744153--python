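import numpy as np
import pandas as pd
import pytest

from vagcst import AbundanceTable, default_registry


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture()
def small_counts():
    """3 samples x 4 taxa count table with clear dominance structure."""
    df = pd.DataFrame(
        {
            "Lactobacillus crispatus": [800.0, 10.0, 50.0],
            "Lactobacillus iners": [100.0, 900.0, 50.0],
            "Gardnerella vaginalis": [50.0, 50.0, 400.0],
            "Prevotella": [50.0, 40.0, 500.0],
        },
        index=pd.Index(["s1", "s2", "s3"], name="sample_id"),
    )
    return AbundanceTable(df, mode="counts")


@pytest.fixture()
def meta3():
    return pd.Series(
        ["g1", "g1", "g2"],
        index=pd.Index(["s1", "s2", "s3"], name="sample_id"),
        name="group",
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
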