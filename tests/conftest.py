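import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

from genospec.matrices import CountMatrix

GENOTYPES = ("Z+", "Z-", "A+", "A-")


def make_counts(values, genotypes=None, features=None):
    """Small CountMatrix helper: values is a 2-D list/array (features x samples)."""
    arr = np.asarray(values)
    n_feat, n_samp = arr.shape
    if genotypes is None:
        genotypes = [GENOTYPES[i % 4] for i in range(n_samp)]
    samples = [f"s{i}" for i in range(n_samp)]
    features = features or [f"f{i}" for i in range(n_feat)]
    return CountMatrix(
        counts=pd.DataFrame(arr, index=features, columns=samples),
        genotypes=pd.Series(list(genotypes), index=samples),
    )


@pytest.fixture(scope="session")
def demo_dataset():
    """One small synthetic study shared across tests (read-only)."""
    from genospec.simulate import default_config, simulate_dataset

    return simulate_dataset(default_config(seed=11, n_genes=2000, n_planted_down=40,
                                           n_planted_up=40, n_planted_protein_down=20,
                                           n_planted_protein_up=20, n_proteins=1200))
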