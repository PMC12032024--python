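from __future__ import annotations

import numpy as np
import pytest

from remsleep import CohortSpec, Hypnogram


def hyp(tokens: str | list, **kw) -> Hypnogram:
    """Build a hypnogram from 'W W S2 REM' style shorthand or a token list."""
    stages = tokens.split() if isinstance(tokens, str) else list(tokens)
    return Hypnogram(stages=tuple(stages), **kw)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def tiny_spec():
    """A scaled-down cohort for fast integration tests."""
    return CohortSpec(
        n_trd=10, n_hv=8, n_responders=4, n_missing_response=1, seed=11
    )


def random_night(rng: np.random.Generator, n: int = 600) -> Hypnogram:
    """A random stage sequence over the full vocabulary (not physiologic;
    used for oracle recounts)."""
    stages = rng.choice(
        ["W", "S1", "S2", "S3", "S4", "REM", "UNSCORED"],
        size=n,
        p=[0.12, 0.08, 0.38, 0.08, 0.06, 0.25, 0.03],
    )
    return Hypnogram(stages=tuple(stages))
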