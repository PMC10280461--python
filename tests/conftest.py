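import numpy as np
import pytest

from hawkselect import SyntheticSpec, TabularDataset, generate, worked_fixture


def make_dataset(values, labels, names=None, label_name="label") -> TabularDataset:
    values = np.asarray(values, dtype=float)
    if names is None:
        names = [f"f{j}" for j in range(values.shape[1])]
    return TabularDataset(values=values, labels=np.asarray(labels), feature_names=list(names),
                          label_name=label_name)


@pytest.fixture
def fixture_ds() -> TabularDataset:
    """The tiny hand-checkable worked table."""
    return worked_fixture()


@pytest.fixture
def small_ds() -> TabularDataset:
    """A 60x8 synthetic table with 3 planted informative symptoms."""
    ds, _ = generate(SyntheticSpec(n_rows=60, n_features=8, n_informative=3,
                                   positive_rate=0.2, seed=11))
    return ds
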