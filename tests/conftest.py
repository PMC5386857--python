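import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from refstab.expression_io import ExpressionMatrix, SampleMeta, UNIT_FPKM

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

TISSUES = ("leaf", "stem", "petal", "calyx")


def make_matrix(values, unit=UNIT_FPKM, sample_ids=None, species="mim"):
    """Build an ExpressionMatrix from a 2-D array with generated metadata.

    Samples cycle through four tissues; batch is T1 for the first four
    columns and T2 afterwards, mirroring the 4-tissue x 2-batch design.
    """
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    if sample_ids is None:
        sample_ids = [f"s{j}" for j in range(n_samples)]
    samples = [
        SampleMeta(
            sample_id=sid,
            species=species,
            tissue=TISSUES[j % 4],
            batch="T1" if j < 4 else "T2",
        )
        for j, sid in enumerate(sample_ids)
    ]
    df = pd.DataFrame(
        values,
        index=pd.Index([f"g{i}" for i in range(n_genes)], name="gene_id"),
        columns=sample_ids,
    )
    return ExpressionMatrix(df, samples, unit)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def random_matrix(rng):
    """A 20-gene x 8-sample positive FPKM matrix for oracle comparisons."""
    return make_matrix(rng.uniform(1.0, 500.0, size=(20, 8)))
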