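"""NIfTI input/output and the masked voxel-by-time data container.

All connectivity metrics operate on a :class:`VoxelTimeSeries`: the in-mask
voxels of a 4D volume flattened to an ``N x T`` matrix in a fixed raster
order (C order over the grid: x slowest, z fastest), together with the
index-to-coordinate table needed to write per-voxel results back out as 3D
maps on the original grid.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import nibabel as nib
import numpy as np

from voxgraph.errors import DegenerateInputError, DimensionError, EmptyMaskError

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]


@dataclass(frozen=True)
class BrainMask:
    """Binary voxel-membership mask on a 3D grid.

    Any nonzero voxel is in-mask; masks stored as float images therefore
    behave as expected.
    """

    membership: np.ndarray  # boolean, shape == grid_shape

    def __post_init__(self) -> None:
        m = np.asarray(self.membership, dtype=bool)
        if m.ndim != 3:
            raise DimensionError(f"mask must be 3D, got {m.ndim}D")
        object.__setattr__(self, "membership", m)

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.membership.shape

    @property
    def n_vox(self) -> int:
        return int(self.membership.sum())

    def coordinates(self) -> np.ndarray:
        """In-mask voxel coordinates, (n_vox, 3), in C raster order."""
        return np.argwhere(self.membership)


@dataclass
class VoxelTimeSeries:
    """In-mask voxel time series as an ``N x T`` matrix.

    Row ``i`` is the time series of the voxel at ``coords[i]``; rows follow
    the C raster order of the mask, so identical inputs always produce
    identical row ordering.
    """

    values: np.ndarray             # (N, T) float64
    coords: np.ndarray             # (N, 3) int, 0-based grid coordinates
    affine: np.ndarray             # (4, 4) grid-to-world transform
    grid_shape: tuple[int, int, int]
    standardized: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.coords = np.asarray(self.coords, dtype=np.intp)
        if self.values.ndim != 2:
            raise DimensionError("values must be an N x T matrix")
        if self.coords.shape != (self.values.shape[0], 3):
            raise DimensionError("coords must be (N, 3)")
        self.grid_shape = tuple(int(s) for s in self.grid_shape)

    @property
    def n_vox(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]

    @property
    def index_to_coord(self) -> list[tuple[int, int, int]]:
        return [tuple(int(c) for c in row) for row in self.coords]


def load_masked_timeseries(
    volume_4d: PathLike, mask: PathLike, drop_constant: bool = True
) -> VoxelTimeSeries:
    """Load a 4D NIfTI volume restricted to a 3D mask.

    Parameters
    ----------
    volume_4d : path
        4D NIfTI image, shape ``(X, Y, Z, T)``.
    mask : path
        3D NIfTI image on the same grid; any nonzero voxel is in-mask.
    drop_constant : bool
        Remove in-mask voxels with a flat (zero-variance) time series, for
        which correlation is undefined. They are reported with a warning
        and come out as 0 in any written map.

    Returns
    -------
    VoxelTimeSeries
        One row per retained in-mask voxel, in C raster order.
    """
    img = nib.load(str(volume_4d))
    mask_img = nib.load(str(mask))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4:
        raise DimensionError(f"expected 4D volume, got {data.ndim}D")
    mask_arr = np.asanyarray(mask_img.dataobj)
    if mask_arr.ndim == 4 and mask_arr.shape[3] == 1:
        mask_arr = mask_arr[..., 0]
    if mask_arr.ndim != 3:
        raise DimensionError(f"expected 3D mask, got {mask_arr.ndim}D")
    if data.shape[:3] != mask_arr.shape:
        raise DimensionError(
            f"volume grid {data.shape[:3]} != mask grid {mask_arr.shape}"
        )
    if data.shape[3] < 3:
        raise DegenerateInputError(
            f"need at least 3 timepoints, got {data.shape[3]}"
        )
    bmask = BrainMask(mask_arr != 0)
    return extract_timeseries(data, bmask, img.affine, drop_constant=drop_constant)


def extract_timeseries(
    data: np.ndarray,
    mask: BrainMask,
    affine: np.ndarray | None = None,
    drop_constant: bool = True,
) -> VoxelTimeSeries:
    """Build a :class:`VoxelTimeSeries` from in-memory arrays.

    Same contract as :func:`load_masked_timeseries` but without file I/O;
    the synthetic-fixture workflow uses this directly.
    """
    data = np.asarray(data, dtype=np.float64)
    if data.ndim != 4:
        raise DimensionError("data must be 4D (X, Y, Z, T)")
    if data.shape[:3] != mask.grid_shape:
        raise DimensionError("data grid does not match mask grid")
    if data.shape[3] < 3:
        raise DegenerateInputError("need at least 3 timepoints")
    if mask.n_vox == 0:
        raise EmptyMaskError("mask selects no voxels")
    coords = mask.coordinates()
    values = data[mask.membership]  # (N, T), rows in C raster order
    if drop_constant:
        keep = values.std(axis=1) > 0
        n_dropped = int((~keep).sum())
        if n_dropped:
            msg = (
                f"dropping {n_dropped} in-mask voxel(s) with constant time "
                "series; correlation is undefined for them"
            )
            logger.warning(msg)
            warnings.warn(msg, stacklevel=2)
            values = values[keep]
            coords = coords[keep]
        if values.shape[0] == 0:
            raise EmptyMaskError("all in-mask voxels have constant series")
    if affine is None:
        affine = np.eye(4)
    return VoxelTimeSeries(
        values=values,
        coords=coords,
        affine=np.asarray(affine, dtype=np.float64),
        grid_shape=mask.grid_shape,
    )


def map_to_volume(values: np.ndarray, ts: VoxelTimeSeries) -> np.ndarray:
    """Scatter per-voxel scalars onto the 3D grid; out-of-mask voxels are 0."""
    values = np.asarray(values)
    if values.ndim != 1 or values.shape[0] != ts.n_vox:
        raise DimensionError(
            f"expected {ts.n_vox} values, got shape {values.shape}"
        )
    if ts.n_vox == 0:
        raise EmptyMaskError("no voxels to write")
    vol = np.zeros(ts.grid_shape, dtype=np.float32)
    vol[ts.coords[:, 0], ts.coords[:, 1], ts.coords[:, 2]] = values
    return vol


def write_map(values: np.ndarray, ts: VoxelTimeSeries, path: PathLike) -> None:
    """Write per-voxel scalars as a 3D float32 NIfTI map.

    The affine of the source 4D volume is passed through unchanged, so the
    output overlays the input in any viewer.
    """
    vol = map_to_volume(values, ts)
    img = nib.Nifti1Image(vol, ts.affine)
    img.header.set_data_dtype(np.float32)
    nib.save(img, str(path))


def read_map(path: PathLike, ts: VoxelTimeSeries) -> np.ndarray:
    """Read a 3D map back to the per-voxel vector matching ``ts`` row order."""
    img = nib.load(str(path))
    vol = np.asanyarray(img.dataobj)
    if vol.ndim == 4 and vol.shape[3] == 1:
        vol = vol[..., 0]
    if vol.shape != ts.grid_shape:
        raise DimensionError("map grid does not match time-series grid")
    return vol[ts.coords[:, 0], ts.coords[:, 1], ts.coords[:, 2]]
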