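import numpy as np
import pandas as pd
import pytest

import inflaclust as ic


@pytest.fixture(scope="session")
def scheme():
    return ic.load_scheme()


@pytest.fixture(scope="session")
def small_cohort(scheme):
    """A compact planted-six-cluster cohort for fast unit tests."""
    cfg = ic.SyntheticConfig(n_genes=400, samples_per_cluster=(30,) * 6, seed=7)
    return ic.generate(cfg, scheme)


@pytest.fixture(scope="session")
def small_scores(small_cohort, scheme):
    return ic.score_matrix(small_cohort.expr, scheme)


@pytest.fixture(scope="session")
def default_cohort(scheme):
    """The generator's default study conditions (600 samples, six clusters)."""
    return ic.generate(ic.SyntheticConfig(seed=1), scheme)


@pytest.fixture(scope="session")
def default_scores(default_cohort, scheme):
    return ic.score_matrix(default_cohort.expr, scheme)


@pytest.fixture()
def tiny_expr():
    """8 genes x 3 samples with distinct values, for running-sum oracles."""
    rng = np.random.default_rng(3)
    vals = rng.normal(5, 2, size=(8, 3))
    genes = [f"G{i}" for i in range(8)]
    return ic.ExpressionMatrix(
        pd.DataFrame(vals, index=genes, columns=["A", "B", "C"])
    )
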