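"""Voxel-wise degree centrality under correlation and sparsity thresholds.

Degree centrality (DC) treats each in-mask voxel as a node of the
whole-brain connectivity graph.  Binary DC counts a voxel's suprathreshold
connections; weighted DC sums their correlation weights.  Two thresholding
modes are supported:

* **correlation threshold** — a pair (i, j) contributes iff its correlation
  strictly exceeds ``r_threshold`` (default 0.0);
* **sparsity threshold** — only the top ``P`` % strongest of all
  N(N-1)/2 unique correlations contribute.

The sparsity mode is the hard one: selecting the top k of ~10^10 streamed
values must not require retaining or sorting them all.  It is solved with
a two-level adaptive histogram.  Correlations above a moving admission
threshold are dropped into a 50-bin histogram spanning
``[floor_threshold, 1.0]``; whenever the bins *above* the lowest retained
bin already hold at least k records, the lowest bin is discarded and the
admission threshold rises by one bin width, bounding memory by roughly the
k survivors.  After the stream ends the histogram is traversed from high
to low; the boundary bin that would overshoot k is re-histogrammed into
100 equal sub-bins over its own range and traversed the same way.  The
whole final sub-bin is admitted, so the selection may exceed k, but only
by values within one sub-bin width — ties closer than
``span / (50 * 100)`` of the primary span are not broken, anything
farther apart cannot be conflated.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from voxgraph.correlation import (
    ConnectionRecord,
    CorrelationConfig,
    prepare,
    stream_correlation_blocks,
)
from voxgraph.errors import ConfigError, DegenerateInputError
from voxgraph.volume_io import VoxelTimeSeries


@dataclass(frozen=True)
class ThresholdConfig:
    """Fixed correlation cutoff; pairs with ``r > r_threshold`` count."""

    r_threshold: float = 0.0

    def __post_init__(self) -> None:
        if not self.r_threshold < 1:
            raise ConfigError("r_threshold must be < 1")


@dataclass(frozen=True)
class SparsityConfig:
    """Sparsity target and histogram geometry.

    ``sparsity_percent`` is expressed in percent: 0.1 keeps the strongest
    0.1 % of all unique pairs.  ``floor_threshold`` is the initial
    admission threshold; the primary histogram spans
    ``[floor_threshold, 1.0]``, so lowering the floor below 0 widens the
    bins accordingly.
    """

    sparsity_percent: float
    primary_bins: int = 50
    secondary_bins: int = 100
    floor_threshold: float = 0.0

    def __post_init__(self) -> None:
        if not 0 < self.sparsity_percent <= 100:
            raise ConfigError("sparsity_percent must be in (0, 100]")
        if self.primary_bins < 2 or self.secondary_bins < 2:
            raise ConfigError("need at least 2 bins at each level")
        if not -1.0 <= self.floor_threshold < 1.0:
            raise ConfigError("floor_threshold must be in [-1, 1)")

    @property
    def span(self) -> float:
        return 1.0 - self.floor_threshold

    @property
    def bin_width(self) -> float:
        return self.span / self.primary_bins


def tie_break_precision(cfg: SparsityConfig) -> float:
    """Smallest value separation the two-level histogram is guaranteed to
    resolve at the sparsity boundary: one secondary sub-bin width,
    ``span / (primary_bins * secondary_bins)``."""
    return cfg.span / (cfg.primary_bins * cfg.secondary_bins)


class SparsitySelection(NamedTuple):
    """Connections retained by a sparsity run, as parallel arrays."""

    i: np.ndarray
    j: np.ndarray
    r: np.ndarray
    final_threshold: float
    shortfall: bool

    def to_records(self) -> list[ConnectionRecord]:
        return [
            ConnectionRecord(int(a), int(b), float(c))
            for a, b, c in zip(self.i, self.j, self.r)
        ]


class AdaptiveHistogram:
    """Primary 50-bin histogram with a rising admission threshold.

    Records are stored per bin as chunks of parallel (i, j, r) arrays —
    the vector analogue of an array of linked lists.  ``admission
    threshold`` starts at the floor and only ever increases, one bin width
    at a time, when the bins above the lowest retained bin already satisfy
    the sparsity goal on their own.
    """

    def __init__(self, k_target: int, cfg: SparsityConfig | None = None):
        if k_target < 1:
            raise ConfigError("k_target must be >= 1")
        self.cfg = cfg or SparsityConfig(sparsity_percent=100.0)
        self.k_target = int(k_target)
        self.n_bins = self.cfg.primary_bins
        self.floor = self.cfg.floor_threshold
        self.width = self.cfg.bin_width
        self.edges = self.floor + self.width * np.arange(self.n_bins + 1)
        self.edges[-1] = 1.0
        self.lowest_bin = 0  # index of the lowest retained bin
        self.counts = np.zeros(self.n_bins, dtype=np.int64)
        self._chunks: list[list[tuple[np.ndarray, np.ndarray, np.ndarray]]] = [
            [] for _ in range(self.n_bins)
        ]

    @property
    def admission_threshold(self) -> float:
        return float(self.edges[self.lowest_bin])

    @property
    def total_stored(self) -> int:
        return int(self.counts.sum())

    @property
    def count_above_lowest(self) -> int:
        return int(self.counts[self.lowest_bin + 1:].sum())

    def insert(self, rec: ConnectionRecord) -> None:
        self.insert_many(
            np.array([rec.i]), np.array([rec.j]), np.array([rec.r])
        )

    def insert_many(
        self, i: np.ndarray, j: np.ndarray, r: np.ndarray
    ) -> None:
        """Admit all records with ``r`` strictly above the admission
        threshold, then prune the lowest bin while it is not needed."""
        keep = r > self.admission_threshold
        if not np.any(keep):
            return
        i, j, r = i[keep], j[keep], r[keep]
        b = ((r - self.floor) / self.width).astype(np.int64)
        np.clip(b, self.lowest_bin, self.n_bins - 1, out=b)
        for bin_idx in np.unique(b):
            sel = b == bin_idx
            self._chunks[bin_idx].append(
                (
                    np.ascontiguousarray(i[sel]),
                    np.ascontiguousarray(j[sel]),
                    np.ascontiguousarray(r[sel], dtype=np.float64),
                )
            )
            self.counts[bin_idx] += int(sel.sum())
        self._prune()

    def _prune(self) -> None:
        while (
            self.lowest_bin < self.n_bins - 1
            and self.count_above_lowest >= self.k_target
        ):
            self.counts[self.lowest_bin] = 0
            self._chunks[self.lowest_bin] = []
            self.lowest_bin += 1

    def bin_records(
        self, bin_idx: int
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        chunks = self._chunks[bin_idx]
        if not chunks:
            empty = np.empty(0)
            return empty.astype(np.intp), empty.astype(np.intp), empty
        return (
            np.concatenate([c[0] for c in chunks]),
            np.concatenate([c[1] for c in chunks]),
            np.concatenate([c[2] for c in chunks]),
        )

    def records(self) -> list[ConnectionRecord]:
        out: list[ConnectionRecord] = []
        for b in range(self.n_bins):
            i, j, r = self.bin_records(b)
            out.extend(
                ConnectionRecord(int(a), int(bb), float(c))
                for a, bb, c in zip(i, j, r)
            )
        return out


def hist_insert(
    h: AdaptiveHistogram, rec: ConnectionRecord, k_target: int | None = None
) -> AdaptiveHistogram:
    """Insert one record; prune the lowest bin if no longer needed."""
    if k_target is not None and k_target != h.k_target:
        h.k_target = int(k_target)
    h.insert(rec)
    return h


def finalize_sparsity(
    h: AdaptiveHistogram,
    k_target: int | None = None,
    secondary_bins: int | None = None,
) -> SparsitySelection:
    """Select the top-k records from a filled histogram.

    Whole primary bins are taken from high to low while they fit under
    ``k_target``; the boundary bin is re-histogrammed into equal-width
    sub-bins over its own range and sub-bins are taken high to low until
    the target is met or exceeded, the final sub-bin in full.
    """
    k = int(k_target) if k_target is not None else h.k_target
    n_sub = int(secondary_bins) if secondary_bins is not None else h.cfg.secondary_bins
    total = h.total_stored
    if total == 0:
        raise DegenerateInputError("histogram holds no records")
    shortfall = total < k
    if shortfall:
        warnings.warn(
            f"only {total} connections available above the admission "
            f"threshold; sparsity target of {k} cannot be met",
            stacklevel=2,
        )
    taken: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = []
    cum = 0
    boundary = None
    for b in range(h.n_bins - 1, h.lowest_bin - 1, -1):
        c = int(h.counts[b])
        if c == 0:
            continue
        if shortfall or cum + c <= k:
            taken.append(h.bin_records(b))
            cum += c
            if not shortfall and cum == k:
                break
        else:
            boundary = b
            break
    if boundary is not None and cum < k:
        bi, bj, br = h.bin_records(boundary)
        lo_edge = h.edges[boundary]
        sub_width = (h.edges[boundary + 1] - lo_edge) / n_sub
        sb = ((br - lo_edge) / sub_width).astype(np.int64)
        np.clip(sb, 0, n_sub - 1, out=sb)
        for s in range(n_sub - 1, -1, -1):
            sel = sb == s
            c = int(sel.sum())
            if c == 0:
                continue
            taken.append((bi[sel], bj[sel], br[sel]))
            cum += c
            if cum >= k:
                break
    i = np.concatenate([t[0] for t in taken]).astype(np.intp)
    j = np.concatenate([t[1] for t in taken]).astype(np.intp)
    r = np.concatenate([t[2] for t in taken]).astype(np.float64)
    return SparsitySelection(
        i=i,
        j=j,
        r=r,
        final_threshold=float(r.min()),
        shortfall=shortfall,
    )


@dataclass
class CentralityResult:
    """Binary and weighted DC maps with run provenance."""

    binary_map: np.ndarray            # (N,) int64 connection counts
    weighted_map: np.ndarray          # (N,) float64 summed weights
    mode: str                         # "threshold" or "sparsity"
    retained_connections: int
    final_threshold: float | None = None
    shortfall: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        assert self.binary_map.sum() == 2 * self.retained_connections


def _accumulate(
    n: int, i: np.ndarray, j: np.ndarray, r: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Scatter retained pairs into per-voxel maps, in (i, j) order so the
    float reduction is reproducible regardless of how pairs arrived."""
    order = np.lexsort((j, i))
    i, j, r = i[order], j[order], r[order]
    binary = np.zeros(n, dtype=np.int64)
    weighted = np.zeros(n, dtype=np.float64)
    np.add.at(binary, i, 1)
    np.add.at(binary, j, 1)
    np.add.at(weighted, i, r)
    np.add.at(weighted, j, r)
    return binary, weighted


def dc_threshold(
    ts: VoxelTimeSeries,
    cfg: ThresholdConfig | None = None,
    corr: CorrelationConfig | None = None,
) -> CentralityResult:
    """Degree centrality under a fixed correlation threshold.

    Every pair with ``r > r_threshold`` (strict) increments both voxels'
    binary DC by 1 and weighted DC by ``r``.
    """
    cfg = cfg or ThresholdConfig()
    corr = corr or CorrelationConfig()
    if ts.n_vox < 2:
        raise DegenerateInputError("need at least 2 voxels")
    ts = prepare(ts, corr)
    n = ts.n_vox
    thr = cfg.r_threshold
    binary = np.zeros(n, dtype=np.int64)
    weighted = np.zeros(n, dtype=np.float64)
    retained = 0
    values = np.ascontiguousarray(ts.values)
    bs = corr.block_size
    for a in range(0, n - 1, bs):
        b = min(a + bs, n)
        strip = values[a:b] @ values[a + 1:].T  # rows i=a..b-1, cols j=a+1..n-1
        np.clip(strip, -1.0, 1.0, out=strip)
        rows = np.arange(b - a)[:, None]
        cols = np.arange(n - a - 1)[None, :]
        supra = (strip > thr) & (cols >= rows)  # j > i
        binary[a:b] += supra.sum(axis=1)
        binary[a + 1:] += supra.sum(axis=0)
        w = np.where(supra, strip, 0.0)
        weighted[a:b] += w.sum(axis=1)
        weighted[a + 1:] += w.sum(axis=0)
        retained += int(supra.sum())
    return CentralityResult(
        binary_map=binary,
        weighted_map=weighted,
        mode="threshold",
        retained_connections=retained,
        final_threshold=thr,
    )


def sparsity_k_target(n_vox: int, sparsity_percent: float) -> int:
    """Number of connections implied by a ``P`` % sparsity target:
    ``ceil(P/100 * N(N-1)/2)``, read as at-least-P%."""
    m = n_vox * (n_vox - 1) // 2
    return max(1, math.ceil(sparsity_percent / 100.0 * m))


def dc_sparsity(
    ts: VoxelTimeSeries,
    cfg: SparsityConfig,
    corr: CorrelationConfig | None = None,
) -> CentralityResult:
    """Degree centrality keeping the top ``P`` % strongest connections.

    Streams all unique correlations through the adaptive histogram, then
    accumulates the selected records exactly as in threshold mode.  The
    result is independent of streaming order and block size; the retained
    count can exceed the target only through ties inside the final
    secondary sub-bin.
    """
    corr = corr or CorrelationConfig()
    if ts.n_vox < 2:
        raise DegenerateInputError("need at least 2 voxels")
    ts = prepare(ts, corr)
    n = ts.n_vox
    k = sparsity_k_target(n, cfg.sparsity_percent)
    h = AdaptiveHistogram(k_target=k, cfg=cfg)
    for i, j, r in stream_correlation_blocks(ts, corr):
        h.insert_many(i, j, r)
    if h.total_stored == 0:
        warnings.warn(
            "no correlation exceeded the floor threshold; maps are empty",
            stacklevel=2,
        )
        return CentralityResult(
            binary_map=np.zeros(n, dtype=np.int64),
            weighted_map=np.zeros(n, dtype=np.float64),
            mode="sparsity",
            retained_connections=0,
            final_threshold=None,
            shortfall=True,
        )
    sel = finalize_sparsity(h)
    binary, weighted = _accumulate(n, sel.i, sel.j, sel.r)
    return CentralityResult(
        binary_map=binary,
        weighted_map=weighted,
        mode="sparsity",
        retained_connections=int(sel.i.size),
        final_threshold=sel.final_threshold,
        shortfall=sel.shortfall,
    )


def dc_sparsity_exact(
    ts: VoxelTimeSeries,
    cfg: SparsityConfig,
    corr: CorrelationConfig | None = None,
) -> CentralityResult:
    """Reference sparsity DC by full sort of all pair correlations.

    Materializes every unique correlation above the floor, sorts, and
    keeps exactly the top k (ties at the k-th value broken by sort
    order).  O(N^2) memory — validation sizes only.
    """
    corr = corr or CorrelationConfig()
    if ts.n_vox < 2:
        raise DegenerateInputError("need at least 2 voxels")
    ts = prepare(ts, corr)
    n = ts.n_vox
    k = sparsity_k_target(n, cfg.sparsity_percent)
    ii: list[np.ndarray] = []
    jj: list[np.ndarray] = []
    rr: list[np.ndarray] = []
    for i, j, r in stream_correlation_blocks(ts, corr):
        keep = r > cfg.floor_threshold
        ii.append(i[keep])
        jj.append(j[keep])
        rr.append(r[keep])
    i = np.concatenate(ii)
    j = np.concatenate(jj)
    r = np.concatenate(rr)
    shortfall = r.size < k
    if shortfall:
        warnings.warn("sparsity target exceeds available connections",
                      stacklevel=2)
        kk = r.size
    else:
        kk = k
    if kk == 0:
        return CentralityResult(
            binary_map=np.zeros(n, dtype=np.int64),
            weighted_map=np.zeros(n, dtype=np.float64),
            mode="sparsity",
            retained_connections=0,
            final_threshold=None,
            shortfall=True,
        )
    order = np.argsort(-r, kind="stable")[:kk]
    i, j, r = i[order], j[order], r[order]
    binary, weighted = _accumulate(n, i, j, r)
    return CentralityResult(
        binary_map=binary,
        weighted_map=weighted,
        mode="sparsity",
        retained_connections=kk,
        final_threshold=float(r.min()),
        shortfall=shortfall,
    )
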