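import numpy as np
import pytest

from thyrocad.data_io import Dataset, LabeledCase
from thyrocad.phantom import PhantomConfig, generate_cases
from thyrocad.pipeline import feature_table


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def cases_to_dataset(cases) -> Dataset:
    return Dataset([LabeledCase(c.case_id, c.image, c.label, c.metadata) for c in cases])


@pytest.fixture(scope="session")
def phantom200_features():
    """Texture-feature table for the default 200-image phantom study (seed 7)."""
    cases = generate_cases(PhantomConfig(n_cases=200, seed=7))
    table, _ = feature_table(cases_to_dataset(cases))
    return table
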