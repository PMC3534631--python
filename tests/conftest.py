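import numpy as np
import pytest

from gflseg import ProbeGrid, SignalMatrix


def make_grid(N: int, chrom: str = "1") -> ProbeGrid:
    return ProbeGrid(
        chrom=chrom,
        positions=np.arange(1, N + 1, dtype=np.int64) * 1000,
        names=np.array([f"rs{j}" for j in range(N)], dtype=object),
    )


def make_signal(values, mask=None, chrom: str = "1") -> SignalMatrix:
    """Wrap a 2-d array as a fully-observed SignalMatrix on a default grid."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    M, N = values.shape
    if mask is None:
        mask = np.ones((M, N), dtype=bool)
    return SignalMatrix(grid=make_grid(N, chrom), values=values, mask=mask)


@pytest.fixture
def rng():
    return np.random.default_rng(20231115)
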