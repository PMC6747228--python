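import numpy as np
import pytest

from dbpred import (FeatureMatrix, SyntheticSpec, extract_all_views,
                    generate_dataset)
from dbpred.io import AA_ORDER


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_dataset():
    """10 sequences per class, fully separated compositions."""
    records, pssms = generate_dataset(
        SyntheticSpec(n_per_class=10, shift=1.0, seed=101)
    )
    y = np.array([r.label for r in records], dtype=float)
    return records, pssms, y


@pytest.fixture(scope="session")
def small_views(small_dataset):
    records, pssms, y = small_dataset
    return extract_all_views(records, pssms), y


def random_sequence(rng, length):
    return "".join(rng.choice(list(AA_ORDER), size=length))


def random_feature_matrix(rng, n, d, view="mcd", prefix="s"):
    return FeatureMatrix(
        view=view,
        values=rng.normal(size=(n, d)),
        ids=tuple(f"{prefix}{i}" for i in range(n)),
    )
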