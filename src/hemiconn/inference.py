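"""Voxelwise group statistics and Monte-Carlo cluster-extent inference.

The multiple-comparison strategy follows the classic AlphaSim recipe:
simulate smooth Gaussian null volumes, threshold at the analysis'
per-voxel p, and record the largest suprathreshold cluster per iteration.
The corrected extent threshold k*(alpha) is the smallest cluster size whose
null max-extent exceedance probability is <= alpha; observed t-maps are then
thresholded at the same per-voxel p and only clusters larger than the
extent cutoff survive.

Extent cutoffs are expressed as a strict lower bound (``extent > min_extent``
survives), matching the convention "cluster size > 14 voxels"; a null table's
``k_star`` is the minimal *surviving* extent, so callers pass
``min_extent = k_star - 1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .rsfc import StatMap

__all__ = [
    "ClusterNullTable",
    "one_sample_tmap",
    "paired_tmap",
    "two_sample_tmap",
    "simulate_cluster_null",
    "label_clusters",
    "correct_map",
    "asymmetry_within_group_mask",
    "extent_to_mm3",
    "connectivity_structure",
    "fwhm_to_sigma_voxels",
]

#: voxel volume on the default 3 mm isotropic grid
DEFAULT_VOXEL_VOLUME_MM3 = 27.0

_CONNECTIVITY_RANK = {"faces": 1, "faces+edges": 2, "faces+edges+corners": 3}


def connectivity_structure(connectivity: str = "faces") -> np.ndarray:
    """3D binary structuring element for the named neighborhood."""
    try:
        rank = _CONNECTIVITY_RANK[connectivity]
    except KeyError:
        raise ValueError(
            f"connectivity must be one of {sorted(_CONNECTIVITY_RANK)}, "
            f"got {connectivity!r}"
        ) from None
    return ndimage.generate_binary_structure(3, rank)


def extent_to_mm3(extent_voxels: int,
                  voxel_volume_mm3: float = DEFAULT_VOXEL_VOLUME_MM3) -> float:
    """Cluster extent in voxels -> volume in mm^3 (27 mm^3/voxel at 3 mm)."""
    return float(extent_voxels) * float(voxel_volume_mm3)


def _stack(maps: Sequence) -> np.ndarray:
    """Stack StatMaps or arrays into (n_subjects, X, Y, Z) float64."""
    arrays = [m.values if isinstance(m, StatMap) else np.asarray(m) for m in maps]
    if not arrays:
        raise ValueError("no maps supplied")
    shapes = {a.shape for a in arrays}
    if len(shapes) > 1:
        raise ValueError(f"maps are on different grids: {sorted(shapes)}")
    return np.stack(arrays).astype(np.float64)


def _t_from_mean_sd(mean: np.ndarray, sd: np.ndarray, n: int) -> Tuple[np.ndarray, int]:
    """One-sample t with the zero-variance rule: sd == 0 -> t = 0, counted."""
    zero_var = sd == 0
    denom = np.where(zero_var, 1.0, sd / np.sqrt(n))
    t = mean / denom
    t[zero_var] = 0.0
    return t, int(zero_var.sum())


def one_sample_tmap(maps: Sequence) -> StatMap:
    """Voxelwise one-sample t-test against zero over subjects.

    t = mean / (sd / sqrt(n)) with ddof=1, df = n - 1 (two-tailed
    convention).  Zero-variance voxels get t = 0; the count is recorded in
    ``meta['n_zero_variance']``.
    """
    data = _stack(maps)
    n = data.shape[0]
    if n < 3:
        raise ValueError(f"one-sample t needs n >= 3 subjects, got {n}")
    mean = data.mean(axis=0)
    sd = data.std(axis=0, ddof=1)
    t, n_zero = _t_from_mean_sd(mean, sd, n)
    return StatMap(t, kind="t", df=n - 1, meta={"n_zero_variance": n_zero})


def paired_tmap(a_maps: Sequence, b_maps: Sequence) -> StatMap:
    """Voxelwise paired-samples t-test (one-sample t on a - b).

    Subject order must align between the two sequences.
    """
    if len(a_maps) != len(b_maps):
        raise ValueError(
            f"paired test needs equal counts, got {len(a_maps)} vs {len(b_maps)}"
        )
    a = _stack(a_maps)
    b = _stack(b_maps)
    return one_sample_tmap(a - b)


def two_sample_tmap(group1_maps: Sequence, group2_maps: Sequence,
                    variance_rule: str = "pooled") -> StatMap:
    """Voxelwise independent-samples t-test (group1 - group2).

    ``variance_rule``: ``pooled`` (default, df = n1 + n2 - 2) or ``welch``
    (Satterthwaite df, stored rounded down).  Zero-variance voxels (both
    groups constant) get t = 0.
    """
    g1 = _stack(group1_maps)
    g2 = _stack(group2_maps)
    n1, n2 = g1.shape[0], g2.shape[0]
    if n1 < 2 or n2 < 2:
        raise ValueError(f"two-sample t needs n >= 2 per group, got {n1}/{n2}")
    m1, m2 = g1.mean(axis=0), g2.mean(axis=0)
    v1 = g1.var(axis=0, ddof=1)
    v2 = g2.var(axis=0, ddof=1)
    diff = m1 - m2
    if variance_rule == "pooled":
        pooled = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        se2 = pooled * (1.0 / n1 + 1.0 / n2)
        df = n1 + n2 - 2
    elif variance_rule == "welch":
        se2 = v1 / n1 + v2 / n2
        with np.errstate(divide="ignore", invalid="ignore"):
            df_map = se2 ** 2 / (
                (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
            )
        df = int(np.floor(np.nanmedian(df_map))) if np.isfinite(df_map).any() else 1
    else:
        raise ValueError("variance_rule must be 'pooled' or 'welch'")
    zero = se2 == 0
    t = diff / np.sqrt(np.where(zero, 1.0, se2))
    t[zero] = 0.0
    return StatMap(t, kind="t", df=df, meta={"n_zero_variance": int(zero.sum())})


# ---------------------------------------------------------------------------
# Monte-Carlo cluster-extent null
# ---------------------------------------------------------------------------

def fwhm_to_sigma_voxels(fwhm_mm: float, voxel_size_mm: float) -> float:
    """Gaussian FWHM in mm -> kernel sigma in voxel units."""
    return fwhm_mm / (voxel_size_mm * 2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class ClusterNullTable:
    """Null distribution of the per-iteration maximum cluster extent.

    ``extent_counts[k]`` is the number of iterations whose largest
    suprathreshold cluster had exactly k voxels (k = 0 when no voxel
    survived).  ``k_star(alpha)`` is the smallest extent k with
    Pr(max extent >= k) <= alpha, or None when no finite threshold exists
    (e.g. voxel_p so large that the whole mask always survives).
    """

    extent_counts: Dict[int, int]
    n_iter: int
    voxel_p: float
    fwhm_mm: float
    connectivity: str
    mask_size: int

    def __post_init__(self) -> None:
        if sum(self.extent_counts.values()) != self.n_iter:
            raise ValueError("extent frequencies must sum to n_iter")

    def p_max_ge(self, k: int) -> float:
        """Null probability that the maximum cluster extent is >= k."""
        hits = sum(c for size, c in self.extent_counts.items() if size >= k)
        return hits / self.n_iter

    def k_star(self, alpha: float = 0.05) -> Optional[int]:
        """Minimal significant extent at corrected level alpha, or None.

        None means no extent threshold within the mask controls the
        family-wise rate (e.g. voxel_p = 1 makes the whole mask survive
        every iteration).
        """
        if not (0 < alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        sizes = sorted(self.extent_counts)
        max_size = sizes[-1] if sizes else 0
        for k in range(1, min(max_size + 1, self.mask_size) + 1):
            if self.p_max_ge(k) <= alpha:
                return k
        return None  # no finite threshold within the mask

    def alpha_to_extent(self, alphas: Sequence[float] = (0.01, 0.05, 0.10)) -> Dict[float, Optional[int]]:
        return {a: self.k_star(a) for a in alphas}


def simulate_cluster_null(mask: np.ndarray, fwhm_mm: float, voxel_p: float,
                          connectivity: str = "faces", n_iter: int = 2000,
                          voxel_size_mm: float = 3.0,
                          rng: Optional[np.random.Generator] = None,
                          seed: Optional[int] = None) -> ClusterNullTable:
    """Monte-Carlo null of the maximum suprathreshold cluster extent.

    Per iteration: draw an i.i.d. standard-normal volume on the mask's
    grid, smooth with a Gaussian kernel of the given FWHM (skipped when
    fwhm_mm == 0), re-standardize within the mask, apply a two-tailed
    threshold at ``voxel_p``, and record the largest connected cluster of
    suprathreshold voxels (either sign) inside the mask.

    Smoothing uses periodic boundaries so the null field is exactly
    stationary; reflective boundaries would inflate edge variance and,
    after global re-standardization, concentrate spurious suprathreshold
    voxels at the grid faces, biasing the extent threshold upward.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 3:
        raise ValueError("mask must be 3D")
    if not mask.any():
        raise ValueError("mask is empty")
    if n_iter < 200:
        raise ValueError("n_iter must be >= 200 for a usable null")
    if not (0 < voxel_p <= 1):
        raise ValueError("voxel_p must be in (0, 1]")
    if rng is None:
        rng = np.random.default_rng(seed)
    structure = connectivity_structure(connectivity)
    sigma = fwhm_to_sigma_voxels(fwhm_mm, voxel_size_mm) if fwhm_mm > 0 else 0.0
    thr = stats.norm.isf(voxel_p / 2.0)
    counts: Dict[int, int] = {}
    for _ in range(n_iter):
        vol = rng.standard_normal(mask.shape)
        if sigma > 0:
            # smoothing shrinks the variance; re-standardize within the
            # mask so the voxel threshold keeps its nominal rate.  An
            # unsmoothed draw is already exactly standard.
            vol = ndimage.gaussian_filter(vol, sigma, mode="wrap")
            inside = vol[mask]
            sd = inside.std()
            vol = (vol - inside.mean()) / (sd if sd > 0 else 1.0)
        supra = (np.abs(vol) > thr) & mask
        if supra.any():
            labels, n_lab = ndimage.label(supra, structure=structure)
            max_extent = int(np.bincount(labels.ravel())[1:].max()) if n_lab else 0
        else:
            max_extent = 0
        counts[max_extent] = counts.get(max_extent, 0) + 1
    return ClusterNullTable(
        extent_counts=counts, n_iter=n_iter, voxel_p=voxel_p, fwhm_mm=fwhm_mm,
        connectivity=connectivity, mask_size=int(mask.sum()),
    )


# ---------------------------------------------------------------------------
# Cluster labeling and corrected maps
# ---------------------------------------------------------------------------

_CLUSTER_COLUMNS = ["label", "sign", "extent_voxels", "extent_mm3",
                    "peak_value", "peak_i", "peak_j", "peak_k"]


def label_clusters(values: np.ndarray, connectivity: str = "faces",
                   voxel_volume_mm3: float = DEFAULT_VOXEL_VOLUME_MM3
                   ) -> Tuple[pd.DataFrame, np.ndarray]:
    """Connected components of a (possibly signed) map's nonzero voxels.

    Positive and negative voxels are labeled separately so a cluster never
    mixes signs.  Returns a cluster table (one row per cluster, sorted by
    extent descending) and an int label image; label ids match the table.
    An all-zero map yields an empty table.
    """
    values = np.asarray(values, dtype=np.float64)
    if values.ndim != 3:
        raise ValueError("map must be 3D")
    structure = connectivity_structure(connectivity)
    labels_out = np.zeros(values.shape, dtype=np.int32)
    rows = []
    next_label = 1
    for sign, part in ((1, values > 0), (-1, values < 0)):
        if not part.any():
            continue
        lab, n_lab = ndimage.label(part, structure=structure)
        for comp in range(1, n_lab + 1):
            where = lab == comp
            extent = int(where.sum())
            comp_vals = values[where]
            peak_pos = np.argmax(np.abs(comp_vals))
            peak_value = float(comp_vals[peak_pos])
            idx = np.argwhere(where)[peak_pos]
            labels_out[where] = next_label
            rows.append({
                "label": next_label, "sign": sign, "extent_voxels": extent,
                "extent_mm3": extent_to_mm3(extent, voxel_volume_mm3),
                "peak_value": peak_value,
                "peak_i": int(idx[0]), "peak_j": int(idx[1]), "peak_k": int(idx[2]),
            })
            next_label += 1
    table = pd.DataFrame(rows, columns=_CLUSTER_COLUMNS)
    if len(table):
        table = table.sort_values("extent_voxels", ascending=False,
                                  kind="stable").reset_index(drop=True)
    return table, labels_out


def correct_map(tmap: StatMap, voxel_p: float, min_extent: int,
                analysis_mask: Optional[np.ndarray] = None,
                connectivity: str = "faces",
                voxel_volume_mm3: float = DEFAULT_VOXEL_VOLUME_MM3
                ) -> Tuple[StatMap, pd.DataFrame]:
    """Threshold a t-map at a per-voxel p, then by cluster extent.

    Voxels outside ``analysis_mask`` are zeroed first.  |t| is converted to
    a two-tailed p with the map's df; suprathreshold voxels whose cluster
    extent is strictly greater than ``min_extent`` survive (">14 voxels"
    semantics).  Returns the thresholded map and the surviving-cluster
    table.
    """
    if tmap.kind != "t":
        raise ValueError(f"correct_map expects a t-map, got {tmap.kind!r}")
    if tmap.df is None:
        raise ValueError("t-map has no degrees of freedom recorded")
    if min_extent < 1:
        raise ValueError("min_extent must be >= 1")
    t = np.asarray(tmap.values, dtype=np.float64)
    if analysis_mask is not None:
        analysis_mask = np.asarray(analysis_mask, dtype=bool)
        if analysis_mask.shape != t.shape:
            raise ValueError("analysis_mask shape does not match the map")
        t = np.where(analysis_mask, t, 0.0)
    t_crit = stats.t.isf(voxel_p / 2.0, tmap.df)
    supra = np.where(np.abs(t) > t_crit, t, 0.0)
    table, labels = label_clusters(supra, connectivity, voxel_volume_mm3)
    if len(table):
        surviving = table[table["extent_voxels"] > min_extent]
        keep = np.isin(labels, surviving["label"].to_numpy())
        supra = np.where(keep, supra, 0.0)
        table = surviving.reset_index(drop=True)
    out = StatMap(supra, kind="t", df=tmap.df, side=tmap.side,
                  meta={"voxel_p": voxel_p, "min_extent": min_extent,
                        "connectivity": connectivity})
    return out, table


def asymmetry_within_group_mask(lacc_corrected: StatMap,
                                flipped_racc_corrected: StatMap,
                                paired_t_corrected: StatMap) -> StatMap:
    """Two-criterion within-group asymmetry mask.

    A voxel counts as asymmetric only if (1) it lies in a significant
    cluster of the paired left-vs-flipped-right t-map AND (2) it is
    significant in the left-seed map or the flipped-right-seed map (their
    union).  Intersected clusters are not re-checked against the extent
    cutoff.
    """
    shapes = {lacc_corrected.shape, flipped_racc_corrected.shape,
              paired_t_corrected.shape}
    if len(shapes) > 1:
        raise ValueError("maps are on different grids")
    union = (lacc_corrected.values != 0) | (flipped_racc_corrected.values != 0)
    out = (paired_t_corrected.values != 0) & union
    return StatMap(out.astype(np.uint8), kind="binary", side="contrast")
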