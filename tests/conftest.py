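import numpy as np
import pytest

from mogedn.preprocess import OmicsView


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_view(matrix, modality="mrna", prefix="f", sample_prefix="s",
              normalized=False):
    matrix = np.asarray(matrix, dtype=float)
    n, d = matrix.shape
    return OmicsView(
        modality_id=modality,
        matrix=matrix,
        feature_names=[f"{prefix}{j}" for j in range(d)],
        sample_ids=[f"{sample_prefix}{i}" for i in range(n)],
        normalized=normalized,
    )


@pytest.fixture
def random_view(rng):
    return make_view(rng.normal(size=(12, 6)))
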