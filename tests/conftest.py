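import numpy as np
import pandas as pd
import pytest

from netage.expression_io import ExpressionDataset
from netage.synthetic import ModuleSpec, SyntheticSpec, generate_expression


@pytest.fixture(scope="session")
def two_block_spec() -> SyntheticSpec:
    return SyntheticSpec(
        n_genes=600,
        n_samples_per_group=(17, 21, 18),
        modules=(
            ModuleSpec(200, 0.85, (0.0, 1.0, 2.0)),
            ModuleSpec(200, 0.85, (0.0, -1.0, -2.0)),
        ),
        noise_sd=1.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def two_block_data(two_block_spec):
    return generate_expression(two_block_spec)


@pytest.fixture()
def tiny_dataset() -> ExpressionDataset:
    rng = np.random.default_rng(3)
    samples = [f"s{i}" for i in range(12)]
    matrix = pd.DataFrame(
        rng.normal(8, 1, size=(20, 12)),
        index=[f"g{i}" for i in range(20)],
        columns=samples,
    )
    meta = pd.DataFrame(
        {
            "group": ["young"] * 4 + ["aging"] * 4 + ["ad"] * 4,
            "age": [30, 35, 40, 45, 75, 80, 85, 90, 72, 78, 84, 95],
            "sex": ["F", "M"] * 6,
        },
        index=samples,
    )
    return ExpressionDataset(matrix, meta)
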