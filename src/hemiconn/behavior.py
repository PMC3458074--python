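"""Behavioral scoring, demographic group tests, sphere-ROI extraction, and
imaging-behavior correlations.

Covers the clinical/behavioral side of the study design: Stroop
interference scoring, a chi-square for the sex table, per-subject sphere
extraction of connectivity values around group-difference peaks, the
post-hoc direction test for a difference region, Pearson correlations with
Bonferroni adjustment, and a demographics comparison table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _st

from .rsfc import StatMap
from .stats import one_sample_t

__all__ = [
    "stroop_interference",
    "chi_square_2x2",
    "sphere_roi_values",
    "posthoc_region_direction",
    "CorrelationResult",
    "correlate",
    "group_compare_table",
]


def stroop_interference(color_naming_time: float, incongruent_time: float) -> float:
    """Stroop interference effect: incongruent minus color-naming time (s)."""
    if color_naming_time <= 0 or incongruent_time <= 0:
        raise ValueError("completion times must be positive")
    return incongruent_time - color_naming_time


def chi_square_2x2(table) -> tuple:
    """Pearson chi-square for a 2x2 count table, df=1, no continuity
    correction.

    Closed form: n*(ad - bc)^2 / [(a+b)(c+d)(a+c)(b+d)].
    """
    arr = np.asarray(table, dtype=np.float64)
    if arr.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    a, b = arr[0]
    c, d = arr[1]
    margins = [(a + b), (c + d), (a + c), (b + d)]
    if any(m == 0 for m in margins):
        raise ValueError("a zero marginal makes expected counts undefined")
    n = arr.sum()
    stat = n * (a * d - b * c) ** 2 / np.prod(margins)
    p = float(_st.chi2.sf(stat, df=1))
    return float(stat), p


def sphere_roi_values(maps: Sequence, center_index: Sequence[int],
                      radius_mm: float, voxel_size_mm: float = 3.0
                      ) -> np.ndarray:
    """Mean map value within a sphere around a voxel, per subject.

    Membership is inclusive: a voxel belongs to the sphere when the
    Euclidean distance between voxel centers is <= radius_mm.  On a 3 mm
    grid a 3 mm radius therefore yields the 7-voxel face-neighbor cross.
    Out-of-grid positions are dropped.
    """
    if radius_mm < 0:
        raise ValueError("radius must be >= 0")
    arrays = [m.values if isinstance(m, StatMap) else np.asarray(m) for m in maps]
    shape = arrays[0].shape
    center = np.asarray(center_index, dtype=int)
    if center.shape != (3,):
        raise ValueError("center_index must have 3 components")
    if not ((center >= 0).all() and (center < shape).all()):
        raise ValueError(f"center {tuple(center)} outside grid {shape}")
    reach = int(np.floor(radius_mm / voxel_size_mm))
    offsets = []
    for di in range(-reach, reach + 1):
        for dj in range(-reach, reach + 1):
            for dk in range(-reach, reach + 1):
                dist = voxel_size_mm * np.sqrt(di ** 2 + dj ** 2 + dk ** 2)
                if dist <= radius_mm:
                    offsets.append((di, dj, dk))
    members = []
    for off in offsets:
        idx = center + off
        if (idx >= 0).all() and (idx < shape).all():
            members.append(tuple(idx))
    out = np.empty(len(arrays))
    for s, arr in enumerate(arrays):
        if arr.shape != shape:
            raise ValueError("maps are on different grids")
        out[s] = np.mean([arr[idx] for idx in members])
    return out


def posthoc_region_direction(subject_maps_by_group: Mapping[str, Sequence],
                             region_mask: np.ndarray) -> pd.DataFrame:
    """Direction of connectivity in a group-difference region, per group.

    For each subject the map is averaged over the region; each group's
    means then enter a one-sample t against zero.  The sign of the group
    mean gives the direction (positive/negative connectivity); a
    non-significant t flags the sign as unreliable.
    """
    region_mask = np.asarray(region_mask, dtype=bool)
    if not region_mask.any():
        raise ValueError("region mask is empty")
    rows = []
    for group, maps in subject_maps_by_group.items():
        vals = []
        for m in maps:
            arr = m.values if isinstance(m, StatMap) else np.asarray(m)
            if arr.shape != region_mask.shape:
                raise ValueError("map grid does not match region mask")
            vals.append(float(arr[region_mask].mean()))
        if len(vals) < 2:
            raise ValueError(f"group {group!r} has fewer than 2 subjects")
        vals = np.asarray(vals)
        res = one_sample_t(vals.mean(), vals.std(ddof=1), len(vals))
        rows.append({
            "group": group, "n": len(vals), "mean": vals.mean(),
            "t": res.t, "p": res.p,
            "sign": int(np.sign(vals.mean())),
            "sign_reliable": bool(res.p < 0.05),
        })
    return pd.DataFrame(rows)


@dataclass
class CorrelationResult:
    r: float
    n: int
    p: float
    p_bonferroni: float
    n_dropped: int


def correlate(imaging: Sequence[float], clinical: Sequence[float],
              m_tests: int = 1) -> CorrelationResult:
    """Pearson correlation with two-tailed p and Bonferroni adjustment.

    Pairs with a missing value in either variable are dropped (pairwise
    deletion) and counted.  p comes from t = r*sqrt((n-2)/(1-r^2)) on
    n-2 df; the adjusted p is min(1, m_tests * p).
    """
    if m_tests < 1:
        raise ValueError("m_tests must be >= 1")
    x = np.asarray(imaging, dtype=np.float64)
    y = np.asarray(clinical, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("imaging and clinical must be 1D and equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    n_dropped = int((~ok).sum())
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 4:
        raise ValueError(f"need n >= 4 complete pairs, got {n}")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in one of the variables")
    xc, yc = x - x.mean(), y - y.mean()
    r = float(xc @ yc / np.sqrt((xc @ xc) * (yc @ yc)))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r ** 2))
        p = float(2.0 * _st.t.sf(abs(t), n - 2))
    return CorrelationResult(r=r, n=n, p=p,
                             p_bonferroni=min(1.0, m_tests * p),
                             n_dropped=n_dropped)


#: continuous demographic/behavioral columns compared by two-sample t
DEFAULT_CONTINUOUS = [
    "age", "education",
    "stroop_word_time", "stroop_color_time", "stroop_incongruent_time",
    "stroop_interference",
    "stroop_word_acc", "stroop_color_acc", "stroop_incongruent_acc",
]


def group_compare_table(behavior: pd.DataFrame,
                        group1: str = "control", group2: str = "patient",
                        continuous: Optional[Sequence[str]] = None
                        ) -> pd.DataFrame:
    """Demographics/behavior comparison between two groups.

    Continuous variables get a pooled two-sample t (two-tailed, pairwise
    deletion of missing values); ``sex`` gets a chi-square on the 2x2
    female/male table.  Variables absent from the table are skipped and
    listed in the DataFrame attribute ``skipped``.
    """
    if "group" not in behavior.columns:
        raise ValueError("behavior table lacks a 'group' column")
    groups = set(behavior["group"])
    if not {group1, group2} <= groups:
        raise ValueError(f"groups {group1!r}/{group2!r} not both present")
    g1 = behavior[behavior["group"] == group1]
    g2 = behavior[behavior["group"] == group2]
    rows, skipped = [], []
    if "sex" in behavior.columns:
        counts = [
            [(g1["sex"] == "F").sum(), (g1["sex"] != "F").sum()],
            [(g2["sex"] == "F").sum(), (g2["sex"] != "F").sum()],
        ]
        stat, p = chi_square_2x2(counts)
        rows.append({"variable": "sex", "test": "chi2", "statistic": stat,
                     "df": 1.0, "p": p})
    cols = list(continuous) if continuous is not None else DEFAULT_CONTINUOUS
    for col in cols:
        if col not in behavior.columns:
            skipped.append(col)
            continue
        a = g1[col].dropna().to_numpy(dtype=float)
        b = g2[col].dropna().to_numpy(dtype=float)
        if len(a) < 2 or len(b) < 2:
            skipped.append(col)
            continue
        if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
            # degenerate: both groups constant
            t_stat, p = (0.0, 1.0) if a.mean() == b.mean() else (np.inf, 0.0)
            df = float(len(a) + len(b) - 2)
        else:
            with warnings.catch_warnings():
                # near-constant columns (ceiling-effect accuracies) trip
                # scipy's precision-loss warning; the t is still valid
                warnings.simplefilter("ignore", RuntimeWarning)
                res = _st.ttest_ind(a, b)
            t_stat, p, df = float(res.statistic), float(res.pvalue), float(len(a) + len(b) - 2)
        rows.append({"variable": col, "test": "t", "statistic": t_stat,
                     "df": df, "p": p})
    table = pd.DataFrame(rows, columns=["variable", "test", "statistic", "df", "p"])
    table.attrs["skipped"] = skipped
    return table
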