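import numpy as np
import pytest

from ieto_automl import preprocess, schema, simulate


@pytest.fixture(scope="session")
def small_cohort():
    """A 600-record synthetic cohort with the default planted risk mechanism."""
    return simulate.generate(simulate.GeneratorConfig(n=600, seed=3))


@pytest.fixture(scope="session")
def small_design(small_cohort):
    """Design matrix + names + labels from the small cohort."""
    table = small_cohort.table
    model = preprocess.PreprocessModel().fit(table)
    X, names = model.transform(table)
    y = table[schema.OUTCOME].to_numpy()
    return X, names, y


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
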