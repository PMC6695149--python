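from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from zsens import from_frame, generate_paperlike_study

CANONICAL_SEED = 20260922 % (2**31)


@pytest.fixture(scope="session")
def paperlike():
    """Canonical balanced fixture: 34 subjects x 4 sessions x 18 measures."""
    return generate_paperlike_study(CANONICAL_SEED)


@pytest.fixture()
def rng():
    return np.random.default_rng(987654321)


@pytest.fixture()
def tiny_study():
    """1 subject, 2 sessions, 2 measures — smallest valid long table."""
    frame = pd.DataFrame(
        {
            "subject": ["s1", "s1", "s1", "s1"],
            "session": [1, 2, 1, 2],
            "measure": ["rt", "rt", "mood", "mood"],
            "value": [0.31, 0.35, 12.0, 19.0],
        }
    )
    return from_frame(frame)


def random_matrix(rng, n=None, k=None):
    """A random subjects x levels matrix with subject heterogeneity."""
    n = n if n is not None else int(rng.integers(4, 12))
    k = k if k is not None else int(rng.integers(3, 6))
    subj = rng.normal(0, 1, size=(n, 1))
    return subj + rng.normal(0, 1, size=(n, k)) + rng.normal(0, 0.5, size=(1, k))
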