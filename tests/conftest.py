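import warnings

import numpy as np
import pytest

from benzoqsar import Dataset, DescriptorCalculator, make_library


@pytest.fixture(scope="session")
def calculator() -> DescriptorCalculator:
    return DescriptorCalculator().fit([])


@pytest.fixture(scope="session")
def library():
    """A 76-molecule synthetic benzodiazepine library, σ = 0.3."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return make_library(76, seed=20240720, sigma=0.3)


@pytest.fixture(scope="session")
def library_dataset(library) -> Dataset:
    ds = Dataset.from_records(library.records)
    ds.featurize()
    return ds


@pytest.fixture(scope="session")
def library_activities(library) -> np.ndarray:
    return np.array([r.activity for r in library.records])
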