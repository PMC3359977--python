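import sys
from pathlib import Path

import numpy as np
import pytest
from hypothesis import settings

# make the sibling oracles module importable regardless of invocation dir
sys.path.insert(0, str(Path(__file__).parent))

settings.register_profile("default", derandomize=True, deadline=None, max_examples=50)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20120524)


@pytest.fixture
def random_tracks(rng):
    """A bag of irregular random tracks for oracle comparisons."""
    from rpmkit.rpm import SpotTrack

    tracks = []
    for _ in range(100):
        n = int(rng.integers(4, 40))
        pos = rng.normal(0, 0.5, (n, 2))
        if rng.random() < 0.3:  # inject duplicate consecutive positions
            i = int(rng.integers(0, n - 1))
            pos[i + 1] = pos[i]
        tracks.append(SpotTrack(pos, dt_s=float(rng.choice([0.5, 1.0, 2.0]))))
    return tracks
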