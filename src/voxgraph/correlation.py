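"""Blocked streaming of pairwise voxel correlations.

With N in-mask voxels there are N(N-1)/2 unique correlations; for
whole-brain grids the full N x N matrix does not fit in memory.  The
engine therefore standardizes each voxel's series (zero mean, unit L2
norm, so Pearson r is a plain dot product) and streams the upper triangle
block by block: a block of ``block_size`` rows is multiplied against all
later rows, the resulting strip is consumed, and the strip is released
before the next block.  Peak extra memory is O(block_size * N), never
O(N^2), and the pair order (i-major) is deterministic and independent of
``block_size``.

Spearman correlation is Pearson on within-row ranks (average ranks at
ties), obtained by applying :func:`rank_transform` before standardizing.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterator, Literal, NamedTuple

import numpy as np
from scipy.stats import rankdata

from voxgraph.errors import ConfigError, DegenerateInputError
from voxgraph.volume_io import VoxelTimeSeries


class ConnectionRecord(NamedTuple):
    """One unique voxel pair ``i < j`` with its correlation ``r``."""

    i: int
    j: int
    r: float


@dataclass(frozen=True)
class CorrelationConfig:
    """Correlation method and streaming granularity.

    ``block_size`` trades memory for matmul efficiency and must not affect
    results; 1024 rows keeps a whole-brain strip in tens of megabytes.
    """

    method: Literal["pearson", "spearman"] = "pearson"
    block_size: int = 1024

    def __post_init__(self) -> None:
        if self.method not in ("pearson", "spearman"):
            raise ConfigError(f"unknown correlation method {self.method!r}")
        if self.block_size < 1:
            raise ConfigError("block_size must be >= 1")


def rank_transform(ts: VoxelTimeSeries) -> VoxelTimeSeries:
    """Replace each voxel's series by its within-row ranks (ties averaged)."""
    if ts.n_timepoints < 3:
        raise DegenerateInputError("need at least 3 timepoints to rank")
    ranks = rankdata(ts.values, axis=1, method="average")
    return replace(ts, values=ranks, standardized=False)


def standardize(ts: VoxelTimeSeries) -> VoxelTimeSeries:
    """Center each row and scale it to unit L2 norm.

    After this transform the dot product of two rows equals their Pearson
    correlation.  Zero-variance rows (removed upstream under the default
    loading path) are rejected.
    """
    centered = ts.values - ts.values.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    if np.any(norms == 0):
        bad = int(np.count_nonzero(norms == 0))
        raise DegenerateInputError(
            f"{bad} zero-variance row(s); remove constant voxels first"
        )
    return replace(ts, values=centered / norms[:, None], standardized=True)


def prepare(ts: VoxelTimeSeries, cfg: CorrelationConfig) -> VoxelTimeSeries:
    """Apply the method's transform chain (rank for Spearman, then standardize)."""
    if ts.standardized:
        return ts
    if cfg.method == "spearman":
        ts = rank_transform(ts)
    return standardize(ts)


def stream_correlation_blocks(
    ts: VoxelTimeSeries, cfg: CorrelationConfig
) -> Iterator[tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Yield the upper triangle as ``(i, j, r)`` index/value array triples.

    ``ts`` must already be prepared (see :func:`prepare`).  Blocks arrive
    in i-major order; concatenating them enumerates every pair ``i < j``
    exactly once.  Accumulation is float64 throughout.
    """
    values = np.ascontiguousarray(ts.values, dtype=np.float64)
    n = values.shape[0]
    bs = cfg.block_size
    for a in range(0, n - 1, bs):
        b = min(a + bs, n)
        strip = values[a:b] @ values[a + 1:].T  # (b-a, n-a-1)
        for local, i in enumerate(range(a, b)):
            # row i pairs with j in (i, n); strip column 0 is voxel a+1
            row = strip[local, i - a:]
            if row.size == 0:
                continue
            j = np.arange(i + 1, n)
            yield np.full(j.shape, i, dtype=np.intp), j, np.clip(row, -1.0, 1.0)


def stream_correlations(
    ts: VoxelTimeSeries, cfg: CorrelationConfig | None = None
) -> Iterator[ConnectionRecord]:
    """Yield every unique voxel pair ``i < j`` as a :class:`ConnectionRecord`.

    Convenience record-at-a-time view of :func:`stream_correlation_blocks`;
    the heavy code paths consume the array blocks directly.
    """
    cfg = cfg or CorrelationConfig()
    ts = prepare(ts, cfg)
    for ii, jj, rr in stream_correlation_blocks(ts, cfg):
        for i, j, r in zip(ii.tolist(), jj.tolist(), rr.tolist()):
            yield ConnectionRecord(i, j, r)


def correlation_rows(
    ts: VoxelTimeSeries, targets: np.ndarray
) -> np.ndarray:
    """Correlation of each target voxel against all voxels.

    ``ts`` must be prepared.  Returns a ``(len(targets), N)`` strip; memory
    stays O(len(targets) * N).
    """
    values = ts.values
    strip = values[np.asarray(targets)] @ values.T
    return np.clip(strip, -1.0, 1.0)
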