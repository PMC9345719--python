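import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from rootsu.phantom import PhantomSpec, generate_slice


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def small_phantom():
    """One deterministic noise-free 160x160 phantom slice with truth."""
    spec = PhantomSpec(shape=(160, 160), seed=7)
    return generate_slice(spec)


def random_mask(rng, shape=(8, 8), p=0.4):
    return rng.random(shape) < p


def random_histogram(rng, max_levels=32, span=None):
    """Random 256-bin histogram with <= max_levels occupied levels placed
    inside a random contiguous span."""
    n_levels = int(rng.integers(4, max_levels + 1))
    span = span or int(rng.integers(n_levels, 3 * max_levels))
    lo = int(rng.integers(0, 256 - span))
    levels = lo + rng.choice(span, size=n_levels, replace=False)
    counts = np.zeros(256, dtype=np.int64)
    counts[levels] = rng.integers(1, 200, size=n_levels)
    return counts
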