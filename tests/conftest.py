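import numpy as np
import pandas as pd
import pytest

from introkasp import GenotypeMatrix, default_panel


@pytest.fixture(scope="session")
def panel():
    return default_panel()


def make_matrix(dosages: dict, populations=None, periods=None) -> GenotypeMatrix:
    """Build a small GenotypeMatrix from per-marker dosage lists."""
    dosage = pd.DataFrame({k: [float(x) if x is not None else np.nan for x in v]
                           for k, v in dosages.items()})
    n = len(dosage)
    dosage.index = [f"ind{i}" for i in range(n)]
    meta = pd.DataFrame(
        {
            "population_id": populations if populations is not None else ["popA"] * n,
            "period": periods if periods is not None else ["P2012"] * n,
            "species_class": ["pure_intestinalis"] * n,
            "hybrid_index": [0.01] * n,
        },
        index=dosage.index,
    )
    return GenotypeMatrix(dosage, meta)


@pytest.fixture
def tiny_matrix():
    return make_matrix({"SNP15": [2, 1, 0, 0]})
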