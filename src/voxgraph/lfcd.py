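"""Local functional connectivity density by 26-connected region growing.

lFCD is the fast, local surrogate of degree centrality: instead of
counting a voxel's connections to the whole brain, it measures the
spatially contiguous cluster grown from the voxel (the *target*) through
adjacent suprathreshold neighbours.  Adjacency is the full 26-neighbour
rule — face-, edge- and corner-touching voxels in index space — and a
voxel joins the cluster iff its correlation *with the target* strictly
exceeds the threshold and it touches a voxel already in the cluster.
Growth never crosses the mask boundary.

Binary lFCD is the cluster size (the seed counts, so it is at least 1);
weighted lFCD sums the members' correlations with the target, the seed
contributing 1.0.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np

from voxgraph.correlation import CorrelationConfig, correlation_rows, prepare
from voxgraph.errors import ConfigError, DegenerateInputError, VoxgraphError
from voxgraph.volume_io import BrainMask, VoxelTimeSeries


@dataclass(frozen=True)
class LFCDConfig:
    """Region-growing threshold; adjacency is fixed at 26-connectivity.

    ``include_seed=False`` excludes the target itself from both maps, for
    the reading of cluster size as "neighbours connected to the target".
    """

    r_threshold: float = 0.0
    include_seed: bool = True

    def __post_init__(self) -> None:
        if not self.r_threshold < 1:
            raise ConfigError("r_threshold must be < 1")


@dataclass
class LFCDResult:
    """Per-voxel cluster sizes (binary) and summed correlations (weighted)."""

    binary_map: np.ndarray    # (N,) int64
    weighted_map: np.ndarray  # (N,) float64
    r_threshold: float


def neighbor_table(coords: np.ndarray, grid_shape: tuple[int, int, int]) -> list[np.ndarray]:
    """26-neighbourhood adjacency between in-mask voxels.

    Returns, for each voxel index, the array of in-mask voxel indices
    whose grid coordinates differ by at most 1 on every axis.
    """
    lookup = np.full(grid_shape, -1, dtype=np.intp)
    lookup[coords[:, 0], coords[:, 1], coords[:, 2]] = np.arange(len(coords))
    offsets = np.array(
        [
            (dx, dy, dz)
            for dx in (-1, 0, 1)
            for dy in (-1, 0, 1)
            for dz in (-1, 0, 1)
            if (dx, dy, dz) != (0, 0, 0)
        ],
        dtype=np.intp,
    )
    shape = np.asarray(grid_shape, dtype=np.intp)
    table: list[np.ndarray] = []
    for c in coords:
        nb = c + offsets
        ok = np.all((nb >= 0) & (nb < shape), axis=1)
        nb = nb[ok]
        idx = lookup[nb[:, 0], nb[:, 1], nb[:, 2]]
        table.append(idx[idx >= 0])
    return table


def grow_cluster(
    target: int,
    corr_with_target: np.ndarray,
    neighbors: list[np.ndarray],
    cfg: LFCDConfig | None = None,
) -> np.ndarray:
    """Flood-fill the target's cluster over suprathreshold in-mask voxels.

    Breadth-first search seeded at ``target``: a voxel is admitted iff its
    correlation with the target strictly exceeds the threshold and it is
    26-adjacent to an already admitted voxel.  Returns member indices in
    ascending order (always containing the target).
    """
    cfg = cfg or LFCDConfig()
    n = len(neighbors)
    if not 0 <= target < n:
        raise VoxgraphError(f"target {target} outside the mask (N={n})")
    thr = cfg.r_threshold
    member = np.zeros(n, dtype=bool)
    member[target] = True
    queue = deque([target])
    while queue:
        v = queue.popleft()
        for u in neighbors[v]:
            if not member[u] and corr_with_target[u] > thr:
                member[u] = True
                queue.append(u)
    return np.flatnonzero(member)


def lfcd_all(
    ts: VoxelTimeSeries,
    cfg: LFCDConfig | None = None,
    corr: CorrelationConfig | None = None,
) -> LFCDResult:
    """lFCD maps for every in-mask voxel.

    Correlations are computed on demand, one strip of target rows at a
    time (memory O(block_size * N)); each target's cluster is grown
    independently.
    """
    cfg = cfg or LFCDConfig()
    corr = corr or CorrelationConfig()
    if ts.n_vox < 2:
        raise DegenerateInputError("need at least 2 voxels")
    ts = prepare(ts, corr)
    n = ts.n_vox
    neighbors = neighbor_table(ts.coords, ts.grid_shape)
    binary = np.zeros(n, dtype=np.int64)
    weighted = np.zeros(n, dtype=np.float64)
    bs = corr.block_size
    for a in range(0, n, bs):
        b = min(a + bs, n)
        strip = correlation_rows(ts, np.arange(a, b))
        for local, target in enumerate(range(a, b)):
            row = strip[local].copy()
            row[target] = 1.0  # self-correlation by convention
            members = grow_cluster(target, row, neighbors, cfg)
            if cfg.include_seed:
                binary[target] = members.size
                weighted[target] = row[members].sum()
            else:
                others = members[members != target]
                binary[target] = others.size
                weighted[target] = row[others].sum()
    return LFCDResult(
        binary_map=binary, weighted_map=weighted, r_threshold=cfg.r_threshold
    )
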