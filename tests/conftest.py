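import numpy as np
import pytest

from fgbrush.models import AssemblyFrame, ChainRecord


def straight_chain(chain_id, n, origin=(0.0, 0.0, 0.0), axis=2, pitch=3.7,
                   sequence=None):
    """Straight line of beads along one axis (fixture helper)."""
    seq = sequence or ("SANQT" * (n // 5 + 1))[:n]
    coords = np.tile(np.asarray(origin, dtype=float), (n, 1))
    coords[:, axis] += pitch * np.arange(n)
    return ChainRecord(chain_id=chain_id, sequence=seq, coords=coords)


def two_parallel_chains(n=10, separation=5.0):
    """Two parallel chains along z, offset in x."""
    a = straight_chain("A", n)
    b = straight_chain("B", n, origin=(separation, 0.0, 0.0))
    return AssemblyFrame(chains=[a, b])


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
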