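import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def null_de_table():
    """A DE-result-shaped table with no real signal, all 'significant'."""
    rng = np.random.default_rng(42)
    genes = [f"g{i}" for i in range(30)]
    return pd.DataFrame(
        {
            "log2FoldChange": rng.normal(0.0, 1.0, len(genes)),
            "padj": np.full(len(genes), 0.001),
        },
        index=pd.Index(genes, name="gene"),
    )
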