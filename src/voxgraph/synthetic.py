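"""Synthetic 4D volumes with analytically known correlation structure.

Real validation data for connectivity metrics is large and external; the
generator here builds small volumes whose pairwise correlations are known
in closed form, so every metric can be checked against exact predictions.

Each *block* is a set of voxels sharing one latent signal: voxel v in a
block with latent g_k gets the series

    x_v(t) = w * g_k(t) + (1 - w) * eps_v(t)

with g_k and eps_v independent standard-normal draws (eps scaled by
``noise_sd``).  Within a block the expected Pearson correlation is

    r = w^2 / (w^2 + (1 - w)^2 * noise_sd^2)

(unit-variance latents); across blocks with different latents it is 0 in
expectation.  Unassigned in-mask voxels (the optional shell) carry pure
noise.  The mask is the union of blocks and shell.  A fixed seed gives
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from voxgraph.errors import ConfigError
from voxgraph.volume_io import BrainMask

Coords = np.ndarray  # (k, 3) int voxel coordinates


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the block-correlated fixture generator."""

    grid_shape: tuple[int, int, int]
    t: int
    blocks: tuple[tuple[Coords, int], ...]  # (coordinates, latent id) pairs
    signal_weight: float = 0.8
    noise_sd: float = 1.0
    seed: int = 0
    shell: Coords | None = None  # pure-noise voxels added to the mask

    def __post_init__(self) -> None:
        if self.t < 3:
            raise ConfigError("need at least 3 timepoints")
        if not 0.0 <= self.signal_weight <= 1.0:
            raise ConfigError("signal_weight must be in [0, 1]")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be nonnegative")
        if self.signal_weight == 0 and self.noise_sd == 0:
            raise ConfigError("all-zero volume: set signal_weight or noise_sd")
        shape = np.asarray(self.grid_shape)
        seen: set[tuple[int, int, int]] = set()
        for coords, _ in self.blocks:
            coords = np.asarray(coords)
            if coords.ndim != 2 or coords.shape[1] != 3:
                raise ConfigError("block coordinates must be (k, 3)")
            if np.any(coords < 0) or np.any(coords >= shape):
                raise ConfigError("block voxel outside the grid")
            for c in map(tuple, coords.tolist()):
                if c in seen:
                    raise ConfigError(f"blocks overlap at voxel {c}")
                seen.add(c)
        if self.shell is not None:
            for c in map(tuple, np.asarray(self.shell).tolist()):
                if c in seen:
                    raise ConfigError(f"shell overlaps a block at voxel {c}")


def expected_within_block_r(spec: SyntheticSpec) -> float:
    """Expected Pearson correlation between two voxels of the same block."""
    w = spec.signal_weight
    s2 = (1.0 - w) ** 2 * spec.noise_sd**2
    if w == 0:
        return 0.0
    return w**2 / (w**2 + s2)


def generate(spec: SyntheticSpec) -> tuple[np.ndarray, BrainMask]:
    """Realize the fixture: a 4D float array and its brain mask.

    Draw order is fixed (latents by ascending id, then block voxels in
    listed order, then shell voxels), so identical specs give
    bit-identical volumes.
    """
    rng = np.random.default_rng(spec.seed)
    x, y, z = spec.grid_shape
    data = np.zeros((x, y, z, spec.t), dtype=np.float64)
    mask = np.zeros(spec.grid_shape, dtype=bool)

    latent_ids = sorted({lid for _, lid in spec.blocks})
    latents = {lid: rng.standard_normal(spec.t) for lid in latent_ids}

    w = spec.signal_weight
    for coords, lid in spec.blocks:
        coords = np.asarray(coords)
        g = latents[lid]
        for c in coords:
            eps = rng.standard_normal(spec.t) * spec.noise_sd
            data[c[0], c[1], c[2]] = w * g + (1.0 - w) * eps
            mask[c[0], c[1], c[2]] = True
    if spec.shell is not None:
        sd = spec.noise_sd if spec.noise_sd > 0 else 1.0
        for c in np.asarray(spec.shell):
            data[c[0], c[1], c[2]] = rng.standard_normal(spec.t) * sd
            mask[c[0], c[1], c[2]] = True
    return data, BrainMask(mask)


def cuboid(lo: tuple[int, int, int], hi: tuple[int, int, int]) -> Coords:
    """All voxel coordinates in the half-open box [lo, hi)."""
    xs, ys, zs = (np.arange(a, b) for a, b in zip(lo, hi))
    grid = np.stack(np.meshgrid(xs, ys, zs, indexing="ij"), axis=-1)
    return grid.reshape(-1, 3)


def two_block_spec(
    block_side: int = 3,
    gap: int = 2,
    t: int = 100,
    signal_weight: float = 0.8,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> SyntheticSpec:
    """Two separated cubic blocks with independent latents.

    The cubes sit along the x axis with ``gap`` empty planes between
    them, so they are spatially contiguous internally but never
    26-adjacent to each other.  With ``noise_sd=0`` (or
    ``signal_weight=1``) every within-block correlation is exactly 1 and
    DC / lFCD maps are exactly predictable from the block sizes.
    """
    s = block_side
    grid = (2 * s + gap, s, s)
    block_a = cuboid((0, 0, 0), (s, s, s))
    block_b = cuboid((s + gap, 0, 0), (2 * s + gap, s, s))
    return SyntheticSpec(
        grid_shape=grid,
        t=t,
        blocks=((block_a, 0), (block_b, 1)),
        signal_weight=signal_weight,
        noise_sd=noise_sd,
        seed=seed,
    )


def demo_spec(seed: int = 0, t: int = 50) -> SyntheticSpec:
    """A 10x10x10 fixture with two 5^3 coherent blocks and a 350-voxel
    pure-noise shell (600 in-mask voxels in total)."""
    grid = (10, 10, 10)
    block_a = cuboid((0, 0, 0), (5, 5, 5))
    block_b = cuboid((5, 5, 5), (10, 10, 10))
    taken = {tuple(c) for c in block_a.tolist()} | {
        tuple(c) for c in block_b.tolist()
    }
    rest = np.array(
        [
            (i, j, k)
            for i in range(10)
            for j in range(10)
            for k in range(10)
            if (i, j, k) not in taken
        ]
    )
    rng = np.random.default_rng(seed)
    shell = rest[rng.choice(len(rest), size=350, replace=False)]
    return SyntheticSpec(
        grid_shape=grid,
        t=t,
        blocks=((block_a, 0), (block_b, 1)),
        signal_weight=0.8,
        noise_sd=1.0,
        seed=seed,
        shell=shell,
    )
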