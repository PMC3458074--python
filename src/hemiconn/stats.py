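"""Scalar group statistics computable from summary numbers alone.

These helpers reproduce published group comparisons when only means, SDs
and group sizes are available (no subject-level data), e.g. a pooled
two-sample t on printed ROI means or a one-sample t on a printed
asymmetry-index summary.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
from scipy import stats as _st

__all__ = ["TTestResult", "pooled_two_sample_t", "one_sample_t"]


class TTestResult(NamedTuple):
    t: float
    df: float
    p: float  # two-tailed


def pooled_two_sample_t(mean1: float, sd1: float, n1: int,
                        mean2: float, sd2: float, n2: int) -> TTestResult:
    """Independent-samples t with pooled variance, from summary statistics.

    df = n1 + n2 - 2; the p-value is two-tailed.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("SDs must be non-negative")
    df = n1 + n2 - 2
    pooled_var = ((n1 - 1) * sd1 ** 2 + (n2 - 1) * sd2 ** 2) / df
    se = np.sqrt(pooled_var * (1.0 / n1 + 1.0 / n2))
    if se == 0:
        raise ValueError("zero pooled variance")
    t = (mean1 - mean2) / se
    p = 2.0 * _st.t.sf(abs(t), df)
    return TTestResult(float(t), float(df), float(p))


def one_sample_t(mean: float, sd: float, n: int, popmean: float = 0.0) -> TTestResult:
    """One-sample t against ``popmean`` from a printed mean/SD/n summary."""
    if n < 2:
        raise ValueError("need n >= 2")
    if sd <= 0:
        raise ValueError("SD must be positive")
    df = n - 1
    t = (mean - popmean) / (sd / np.sqrt(n))
    p = 2.0 * _st.t.sf(abs(t), df)
    return TTestResult(float(t), float(df), float(p))
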