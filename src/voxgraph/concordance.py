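"""Spatial agreement between two maps: concordance correlation coefficient.

Lin's CCC penalizes both decorrelation and location/scale shifts:

    rho_c = 2 cov(a, b) / (var(a) + var(b) + (mean(a) - mean(b))^2)

with population (1/n) moments.  It equals 1 only when the maps are
identical, so it is stricter than Pearson r (|rho_c| <= |r|), which makes
it the right statistic for checking that two implementations of the same
metric produce the same map.
"""

from __future__ import annotations

import warnings

import numpy as np

from voxgraph.errors import DimensionError


def concordance(a: np.ndarray, b: np.ndarray) -> float:
    """Concordance correlation coefficient between two per-voxel maps.

    Returns 1.0 for identical maps (even constant ones); NaN with a
    warning when both maps are constant but unequal, where the statistic
    is undefined.
    """
    a = np.asarray(a, dtype=np.float64).ravel()
    b = np.asarray(b, dtype=np.float64).ravel()
    if a.shape != b.shape:
        raise DimensionError("maps must have equal length")
    if a.size < 2:
        raise DimensionError("need at least 2 voxels")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("maps must be finite")
    if np.array_equal(a, b):
        return 1.0
    mu_a, mu_b = a.mean(), b.mean()
    var_a = a.var()   # population moments (ddof=0)
    var_b = b.var()
    if var_a == 0 and var_b == 0:
        warnings.warn(
            "both maps are constant and unequal; concordance is undefined",
            stacklevel=2,
        )
        return float("nan")
    denom = var_a + var_b + (mu_a - mu_b) ** 2
    cov = ((a - mu_a) * (b - mu_b)).mean()
    return float(2.0 * cov / denom)


def pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation of two maps, reported alongside rho_c."""
    a = np.asarray(a, dtype=np.float64).ravel()
    b = np.asarray(b, dtype=np.float64).ravel()
    if a.shape != b.shape:
        raise DimensionError("maps must have equal length")
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])
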