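from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from trflp.distance import DistanceMatrix
from trflp.io_profiles import ProfileMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_matrix():
    """4 samples x 3 T-RFs with station/date/condition metadata."""
    values = pd.DataFrame(
        [[10.0, 5.0, 0.0], [8.0, 6.0, 1.0], [0.0, 2.0, 12.0], [1.0, 3.0, 9.0]],
        index=["s1", "s2", "s3", "s4"],
        columns=[100, 150, 200],
    )
    meta = pd.DataFrame(
        {
            "station": ["A", "A", "A", "A"],
            "date": ["2006-03-03", "2006-03-06", "2006-06-01", "2006-07-01"],
            "condition": ["storm", "storm", "non-storm", "non-storm"],
        },
        index=values.index,
    )
    return ProfileMatrix(values, meta)


def random_distance_matrix(n: int, seed: int, labels=None) -> DistanceMatrix:
    """A valid random dissimilarity (metric not required for rank tests)."""
    rng = np.random.default_rng(seed)
    pts = rng.normal(size=(n, 3))
    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    labels = labels or [f"x{i}" for i in range(n)]
    return DistanceMatrix(list(labels), d)
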