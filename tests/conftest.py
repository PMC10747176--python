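import numpy as np
import pandas as pd
import pytest

from phytoraman import SpectraSet, Spectrum


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_set(matrix, axis=None, days=None, sessions=None):
    """Build a SpectraSet from a plain matrix with minimal metadata."""
    matrix = np.asarray(matrix, dtype=float)
    n, p = matrix.shape
    if axis is None:
        axis = np.arange(p, dtype=float)
    meta = pd.DataFrame(
        {
            "spectrum_id": [f"s{i}" for i in range(n)],
            "day": days if days is not None else [0] * n,
            "session": sessions if sessions is not None else [0] * n,
            "replicate": list(range(n)),
        }
    )
    return SpectraSet(axis=np.asarray(axis, dtype=float), matrix=matrix, meta=meta)


@pytest.fixture
def make_spectrum():
    def _make(intensities, axis=None, **kwargs):
        intensities = np.asarray(intensities, dtype=float)
        if axis is None:
            axis = np.arange(intensities.size, dtype=float)
        return Spectrum(axis=np.asarray(axis, dtype=float), intensities=intensities, **kwargs)

    return _make
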