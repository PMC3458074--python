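"""Seed-based resting-state functional connectivity (RSFC) maps and
hemispheric-asymmetry contrasts.

The analysis works on a left-right symmetric voxel grid whose first axis is
the flip axis: voxel ``i`` mirrors voxel ``N-1-i``.  For a pair of
mirror-image seed regions (left and right), each subject contributes

* a Pearson correlation map of every voxel with the seed's mean timeseries,
* its Fisher transform ``z = atanh(r)`` (the subject-level Z-map),
* and, for laterality analysis, the contrast ``z_left - flip(z_right)``:
  subtracting the left-right-flipped right-seed Z-map from the left-seed
  Z-map makes homotopic voxels directly comparable, so a nonzero contrast
  means the two hemispheres' seeds connect with different strength to
  mirror-symmetric locations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "StatMap",
    "RoiPair",
    "lr_flip_array",
    "lr_flip",
    "seed_timeseries",
    "correlation_map",
    "fisher_z",
    "asymmetry_contrast",
]

log = logging.getLogger(__name__)

#: kinds a StatMap may carry
STAT_KINDS = ("r", "z", "t", "diff", "binary")

#: r values are clipped to +/-(1 - R_CLIP) before atanh so z stays finite
R_CLIP = 1e-7

FLIP_AXIS = 0


@dataclass
class StatMap:
    """A 3D voxel map of statistics.

    Parameters
    ----------
    values : 3D array of the statistic.
    kind : one of ``r``, ``z``, ``t``, ``diff``, ``binary``.
    df : degrees of freedom, for ``t`` maps.
    side : provenance tag — ``left-seed``, ``right-seed``,
        ``flipped-right-seed`` or ``contrast``.
    meta : free-form counters (clipped voxels, degenerate voxels, ...).
    """

    values: np.ndarray
    kind: str
    df: Optional[int] = None
    side: Optional[str] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"StatMap values must be 3D, got {self.values.ndim}D")
        if self.kind not in STAT_KINDS:
            raise ValueError(f"unknown StatMap kind {self.kind!r}")
        if self.kind == "r" and self.values.size:
            lo, hi = np.nanmin(self.values), np.nanmax(self.values)
            if lo < -1 - 1e-12 or hi > 1 + 1e-12:
                raise ValueError("r-kind StatMap has values outside [-1, 1]")
        if self.kind == "binary" and self.values.size:
            vals = np.unique(self.values)
            if not np.isin(vals, (0, 1)).all():
                raise ValueError("binary StatMap must contain only 0/1")

    @property
    def shape(self) -> tuple:
        return self.values.shape


def lr_flip_array(values: np.ndarray, axis: int = FLIP_AXIS) -> np.ndarray:
    """Mirror an array across the grid midline.

    The flip axis must have even extent so every voxel has an exact mirror
    partner (no midline voxel); the operation is then a pure index
    permutation with no interpolation.
    """
    values = np.asarray(values)
    if values.shape[axis] % 2 != 0:
        raise ValueError(
            f"flip axis {axis} has odd extent {values.shape[axis]}; "
            "a symmetric grid requires an even extent"
        )
    return np.flip(values, axis=axis)


_FLIP_SIDE = {
    "right-seed": "flipped-right-seed",
    "flipped-right-seed": "right-seed",
    "left-seed": "flipped-left-seed",
    "flipped-left-seed": "left-seed",
}


def lr_flip(stat_map: StatMap) -> StatMap:
    """LR-flip a :class:`StatMap`, updating its side tag."""
    return StatMap(
        values=lr_flip_array(stat_map.values),
        kind=stat_map.kind,
        df=stat_map.df,
        side=_FLIP_SIDE.get(stat_map.side, stat_map.side),
        meta=dict(stat_map.meta),
    )


@dataclass
class RoiPair:
    """Mirror-image left/right binary region masks.

    ``right`` must equal ``lr_flip_array(left)`` exactly; both masks must be
    non-empty and disjoint.
    """

    left: np.ndarray
    right: np.ndarray

    def __post_init__(self) -> None:
        self.left = np.asarray(self.left, dtype=bool)
        self.right = np.asarray(self.right, dtype=bool)
        if self.left.shape != self.right.shape:
            raise ValueError("left/right masks differ in shape")
        if not self.left.any() or not self.right.any():
            raise ValueError("ROI masks must be non-empty")
        if np.logical_and(self.left, self.right).any():
            raise ValueError("left and right ROI masks overlap")
        if not np.array_equal(lr_flip_array(self.left), self.right):
            raise ValueError("right mask is not the LR-flip of the left mask")


def seed_timeseries(data4d: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Mean timeseries over a seed mask.

    ``data4d`` is (X, Y, Z, T); the seed signal is the unweighted arithmetic
    mean over mask voxels at each timepoint.
    """
    data4d = np.asarray(data4d)
    mask = np.asarray(mask, dtype=bool)
    if data4d.ndim != 4:
        raise ValueError("data must be 4D (X, Y, Z, T)")
    if mask.shape != data4d.shape[:3]:
        raise ValueError("mask shape does not match the data grid")
    if not mask.any():
        raise ValueError("seed mask is empty")
    return data4d[mask].mean(axis=0)


def correlation_map(data4d: np.ndarray, seed_series: np.ndarray,
                    side: Optional[str] = None) -> StatMap:
    """Voxelwise Pearson correlation of every voxel with a seed series.

    Constant (zero-variance) voxels get r = 0; their count is logged and
    recorded in ``meta['n_constant_voxels']``.
    """
    data4d = np.asarray(data4d)
    if data4d.dtype != np.float32:  # single precision passes through
        data4d = data4d.astype(np.float64, copy=False)
    seed = np.asarray(seed_series, dtype=data4d.dtype)
    if data4d.ndim != 4:
        raise ValueError("data must be 4D (X, Y, Z, T)")
    n_t = data4d.shape[-1]
    if seed.shape != (n_t,):
        raise ValueError("seed series length does not match the data")
    if n_t < 3:
        raise ValueError("need at least 3 timepoints")
    seed_c = seed - seed.mean()
    seed_norm = np.sqrt((seed_c ** 2).sum())
    if seed_norm == 0:
        raise ValueError("seed series is constant")

    flat = data4d.reshape(-1, n_t)
    flat_c = flat - flat.mean(axis=1, keepdims=True)
    vox_norm = np.sqrt((flat_c ** 2).sum(axis=1))
    # constant up to rounding: centering residue scales with the mean
    tol = np.finfo(data4d.dtype).eps * n_t * np.maximum(
        1.0, np.abs(flat).max(axis=1))
    constant = vox_norm <= tol
    denom = np.where(constant, 1.0, vox_norm * seed_norm)
    r = (flat_c @ seed_c) / denom
    r[constant] = 0.0
    # guard against floating-point spill just over +/-1
    np.clip(r, -1.0, 1.0, out=r)
    n_constant = int(constant.sum())
    if n_constant:
        log.warning("correlation_map: %d constant voxels set to r=0", n_constant)
    return StatMap(r.reshape(data4d.shape[:3]), kind="r", side=side,
                   meta={"n_constant_voxels": n_constant})


def fisher_z(r_map: StatMap) -> StatMap:
    """Fisher r-to-Z transform, ``z = atanh(r)``, elementwise.

    Correlations at exactly +/-1 are clipped to +/-(1 - 1e-7) first so the
    result stays finite; the clip count is logged and kept in meta.
    """
    if r_map.kind != "r":
        raise ValueError(f"fisher_z expects an r-kind map, got {r_map.kind!r}")
    r = np.asarray(r_map.values, dtype=np.float64)
    clipped = np.abs(r) >= 1.0 - R_CLIP
    n_clipped = int(clipped.sum())
    if n_clipped:
        log.info("fisher_z: clipped %d voxels at |r| >= 1 - %g", n_clipped, R_CLIP)
    z = np.arctanh(np.clip(r, -(1.0 - R_CLIP), 1.0 - R_CLIP))
    meta = dict(r_map.meta)
    meta["n_clipped_voxels"] = n_clipped
    return StatMap(z, kind="z", side=r_map.side, meta=meta)


def asymmetry_contrast(z_left: StatMap, z_right: StatMap) -> StatMap:
    """Per-subject laterality contrast: ``z_left - lr_flip(z_right)``.

    ``z_left`` must be a left-seed map and ``z_right`` a right-seed map on
    the same grid.  The result compares each voxel's connectivity with the
    left seed against its mirror voxel's connectivity with the right seed.
    """
    if z_left.shape != z_right.shape:
        raise ValueError("maps are on different grids")
    if z_left.side not in (None, "left-seed"):
        raise ValueError(f"z_left has side {z_left.side!r}, expected left-seed")
    if z_right.side not in (None, "right-seed"):
        raise ValueError(f"z_right has side {z_right.side!r}, expected right-seed")
    values = z_left.values - lr_flip_array(z_right.values)
    return StatMap(values, kind="diff", side="contrast")
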