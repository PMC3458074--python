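"""Diffusion-tensor fractional anisotropy (FA) and hemispheric asymmetry.

FA is the standard normalized eigenvalue dispersion,

    FA = sqrt(3/2) * sqrt(sum_i (lam_i - mean(lam))^2) / sqrt(sum_i lam_i^2),

a 0-1 index of diffusion directionality used as a white-matter-integrity
proxy.  Laterality of a bilateral tract is summarized by the asymmetry
index

    AI = (right - left) / [0.5 * (right + left)],

negative when the left side has the larger FA (leftward asymmetry).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .stats import one_sample_t, pooled_two_sample_t

__all__ = [
    "EigenvalueImage",
    "fa_from_eigenvalues",
    "fa_skeleton_mask",
    "roi_mean_fa",
    "asymmetry_index",
    "fa_summary_table",
    "group_fa_tests",
]


@dataclass
class EigenvalueImage:
    """Per-voxel diffusion-tensor eigenvalues (lam1 >= lam2 >= lam3 >= 0).

    ``eigenvalues`` is (X, Y, Z, 3) in mm^2/s; ``mask`` marks brain voxels.
    The ordering/non-negativity invariant is enforced inside the mask.
    """

    eigenvalues: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=np.float64)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.eigenvalues.ndim != 4 or self.eigenvalues.shape[-1] != 3:
            raise ValueError("eigenvalues must be (X, Y, Z, 3)")
        if self.mask.shape != self.eigenvalues.shape[:3]:
            raise ValueError("mask shape does not match eigenvalue grid")
        inside = self.eigenvalues[self.mask]
        n_negative = int((inside < 0).any(axis=-1).sum())
        if n_negative:
            raise ValueError(
                f"{n_negative} voxels have negative eigenvalues")
        if not (np.diff(inside, axis=-1) <= 1e-15).all():
            raise ValueError("eigenvalues must be sorted lam1 >= lam2 >= lam3")


def fa_from_eigenvalues(img: EigenvalueImage) -> np.ndarray:
    """FA map from an eigenvalue image; voxels with zero trace get FA = 0."""
    lam = img.eigenvalues
    mean_lam = lam.mean(axis=-1, keepdims=True)
    num = np.sqrt(((lam - mean_lam) ** 2).sum(axis=-1))
    den = np.sqrt((lam ** 2).sum(axis=-1))
    fa = np.zeros(lam.shape[:3])
    nz = den > 0
    fa[nz] = np.sqrt(1.5) * num[nz] / den[nz]
    fa[~img.mask] = 0.0
    return fa


def fa_skeleton_mask(mean_fa_map: np.ndarray, threshold: float = 0.2) -> np.ndarray:
    """Voxels whose mean FA strictly exceeds the threshold.

    Mirrors the skeleton-thresholding step that excludes grey-matter/CSF
    voxels (conventional cutoff 0.2).
    """
    if not (0 < threshold < 1):
        raise ValueError("threshold must be in (0, 1)")
    return np.asarray(mean_fa_map) > threshold


def roi_mean_fa(fa_map: np.ndarray, roi_mask: np.ndarray) -> float:
    """Arithmetic mean FA over a region of interest."""
    fa_map = np.asarray(fa_map)
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if roi_mask.shape != fa_map.shape:
        raise ValueError("ROI mask shape does not match the FA map")
    if not roi_mask.any():
        raise ValueError("ROI mask is empty")
    return float(fa_map[roi_mask].mean())


def asymmetry_index(right: float, left: float) -> float:
    """AI = (right - left) / [0.5 * (right + left)]; negative = leftward."""
    denom = 0.5 * (right + left)
    if denom <= 0:
        raise ValueError("right + left must be positive")
    return (right - left) / denom


def fa_summary_table(subjects: Sequence[str], groups: Sequence[str],
                     left_fa: Sequence[float], right_fa: Sequence[float]
                     ) -> pd.DataFrame:
    """Per-subject FA summary (subject, group, left_fa, right_fa, ai)."""
    if not (len(subjects) == len(groups) == len(left_fa) == len(right_fa)):
        raise ValueError("column lengths differ")
    ai = [asymmetry_index(r, l) for r, l in zip(right_fa, left_fa)]
    return pd.DataFrame({
        "subject": list(subjects), "group": list(groups),
        "left_fa": np.asarray(left_fa, dtype=float),
        "right_fa": np.asarray(right_fa, dtype=float),
        "ai": ai,
    })


def group_fa_tests(summary: pd.DataFrame, group1: str = "control",
                   group2: str = "patient",
                   variance_rule: str = "pooled") -> pd.DataFrame:
    """Group statistics on an FA summary table.

    Between-group two-sample t (group1 - group2) on left_fa, right_fa and
    ai, plus a within-group one-sample t of the AI against zero (the
    laterality test).  Returns one row per test with t, df, p.
    """
    for col in ("group", "left_fa", "right_fa", "ai"):
        if col not in summary.columns:
            raise ValueError(f"summary table lacks column {col!r}")
    g1 = summary[summary["group"] == group1]
    g2 = summary[summary["group"] == group2]
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("need at least 2 subjects per group")
    rows = []
    for measure in ("left_fa", "right_fa", "ai"):
        a, b = g1[measure].to_numpy(), g2[measure].to_numpy()
        if variance_rule == "pooled":
            res = pooled_two_sample_t(a.mean(), a.std(ddof=1), len(a),
                                      b.mean(), b.std(ddof=1), len(b))
        elif variance_rule == "welch":
            from scipy import stats as _st
            r = _st.ttest_ind(a, b, equal_var=False)
            res = type("R", (), {"t": r.statistic, "df": r.df, "p": r.pvalue})
        else:
            raise ValueError("variance_rule must be 'pooled' or 'welch'")
        rows.append({"test": f"between_group_{measure}", "group": f"{group1}-{group2}",
                     "t": res.t, "df": res.df, "p": res.p})
    for name, grp in ((group1, g1), (group2, g2)):
        ai = grp["ai"].to_numpy()
        res = one_sample_t(ai.mean(), ai.std(ddof=1), len(ai))
        rows.append({"test": "ai_vs_zero", "group": name,
                     "t": res.t, "df": res.df, "p": res.p})
    return pd.DataFrame(rows)
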