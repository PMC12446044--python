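import numpy as np
import pytest

from mpeai.io import ExpressionMatrix, ModuleCatalog
from mpeai.simulate import SimulationParams, generate_paired_dataset


@pytest.fixture
def toy_expr():
    """2 module genes x 3 samples; both rows are affine images of (1, 2, 3)."""
    return ExpressionMatrix(
        gene_ids=["g1", "g2"],
        sample_ids=["s1", "s2", "s3"],
        values=np.array([[2.0, 4.0, 6.0], [10.0, 20.0, 30.0]]),
        layer="MT",
    )


@pytest.fixture
def toy_catalog():
    return ModuleCatalog({"g1": frozenset({"M00356"}), "g2": frozenset({"M00356"})})


@pytest.fixture(scope="session")
def default_dataset():
    """One simulated cohort at the default study conditions (seed 1)."""
    return generate_paired_dataset(SimulationParams(seed=1))


@pytest.fixture(scope="session")
def default_profile(default_dataset):
    from mpeai.activity import compute_mpeai

    return compute_mpeai(default_dataset.expr_mt, default_dataset.catalog)
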