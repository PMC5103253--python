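import numpy as np
import pytest

from voxgraph.volume_io import VoxelTimeSeries


def line_ts(values: np.ndarray) -> VoxelTimeSeries:
    """Wrap an N x T matrix as voxels along a 1D grid line."""
    values = np.asarray(values, dtype=np.float64)
    n = values.shape[0]
    coords = np.stack(
        [np.arange(n), np.zeros(n, dtype=int), np.zeros(n, dtype=int)], axis=1
    )
    return VoxelTimeSeries(values, coords, np.eye(4), (n, 1, 1))


def random_ts(rng: np.random.Generator, n: int, t: int) -> VoxelTimeSeries:
    return line_ts(rng.standard_normal((n, t)))


def brute_force_dc(values: np.ndarray, thr: float):
    """Exhaustive double-loop degree centrality oracle."""
    n = values.shape[0]
    binary = np.zeros(n, dtype=np.int64)
    weighted = np.zeros(n, dtype=np.float64)
    retained = 0
    for i in range(n):
        for j in range(i + 1, n):
            r = np.corrcoef(values[i], values[j])[0, 1]
            if r > thr:
                binary[i] += 1
                binary[j] += 1
                weighted[i] += r
                weighted[j] += r
                retained += 1
    return binary, weighted, retained


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
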