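"""Contract-level cleaning of voxel timeseries before connectivity mapping.

Three steps in a fixed order: polynomial detrend, band-pass filter,
nuisance regression.  Filtering is done by masking bins of the real FFT —
an idealized brick-wall response chosen for exactness and testability over
any particular filter design.  Confound regressors are passed through the
same band-pass before regression so that cleaning is idempotent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = ["CleaningSpec", "detrend", "bandpass", "regress_confounds", "clean"]


@dataclass
class CleaningSpec:
    """Parameters of the timeseries cleaner.

    detrend_order : 0 removes the mean, 1 removes a linear trend.
    band_hz : (low, high) passband in Hz, or None to skip filtering.
        Must satisfy 0 <= low < high < Nyquist = 1/(2*tr_s).
    tr_s : repetition time in seconds.
    regress_global : include the global (whole-grid) mean signal as a
        nuisance regressor.  Conventional but debated; configurable.
    """

    detrend_order: int = 1
    band_hz: Optional[tuple] = (0.01, 0.08)
    tr_s: float = 2.0
    regress_global: bool = True

    def validate(self) -> None:
        if self.detrend_order not in (0, 1):
            raise ValueError("detrend_order must be 0 or 1")
        if self.band_hz is not None:
            low, high = self.band_hz
            nyquist = 1.0 / (2.0 * self.tr_s)
            if not (0 <= low < high < nyquist):
                raise ValueError(
                    f"band {self.band_hz} invalid: need 0 <= low < high < "
                    f"Nyquist ({nyquist:g} Hz at TR={self.tr_s} s)"
                )


def _as_time_major(series: np.ndarray) -> np.ndarray:
    """Accept (T,) or (T, n) arrays; return a (T, n) float view.

    float32 input stays float32 (cleaning large 4D data in single
    precision halves time and memory); everything else becomes float64.
    """
    arr = np.asarray(series)
    if arr.dtype != np.float32:
        arr = arr.astype(np.float64, copy=False)
    if arr.ndim == 1:
        return arr[:, None]
    if arr.ndim == 2:
        return arr
    raise ValueError("series must be 1D (T,) or 2D (T, n_series)")


def detrend(series: np.ndarray, order: int = 1) -> np.ndarray:
    """Remove the least-squares polynomial of the given order (0 or 1).

    The output has exactly zero mean for any order >= 0.
    """
    if order not in (0, 1):
        raise ValueError("order must be 0 or 1")
    arr = _as_time_major(series)
    n_t = arr.shape[0]
    if n_t < order + 2:
        raise ValueError(f"need at least {order + 2} timepoints for order {order}")
    # centered/scaled time keeps the 2x2 normal equations well conditioned
    t = np.linspace(-1.0, 1.0, n_t)
    design = np.vander(t, order + 1, increasing=True).astype(arr.dtype)
    gram = design.T @ design
    coef = np.linalg.solve(gram, design.T @ arr)
    out = arr - design @ coef
    return out.reshape(np.asarray(series).shape)


def bandpass(series: np.ndarray, band_hz: tuple, tr_s: float) -> np.ndarray:
    """Band-pass by zeroing real-FFT bins outside [low, high] Hz (inclusive).

    DC is removed whenever low > 0.  An in-band pure sinusoid passes
    unchanged; a bin-aligned out-of-band sinusoid is removed exactly.
    """
    low, high = band_hz
    nyquist = 1.0 / (2.0 * tr_s)
    if not (0 <= low < high < nyquist):
        raise ValueError(f"band ({low}, {high}) outside (0, Nyquist={nyquist:g})")
    from scipy import fft as _fft

    arr = _as_time_major(series)
    n_t = arr.shape[0]
    freqs = np.fft.rfftfreq(n_t, d=tr_s)
    keep = (freqs >= low) & (freqs <= high)
    spectrum = _fft.rfft(arr, axis=0)  # scipy.fft preserves float32
    spectrum[~keep] = 0.0
    out = _fft.irfft(spectrum, n=n_t, axis=0)
    return out.reshape(np.asarray(series).shape)


def regress_confounds(series: np.ndarray, confounds: np.ndarray,
                      add_intercept: bool = True) -> np.ndarray:
    """Residualize timeseries against a confound matrix.

    Residuals are orthogonal to every confound column (least squares).
    A rank-deficient design (after adding the intercept) is rejected.
    """
    arr = _as_time_major(series)
    conf = np.asarray(confounds, dtype=np.float64)
    if conf.ndim == 1:
        conf = conf[:, None]
    if conf.shape[0] != arr.shape[0]:
        raise ValueError(
            f"confounds have {conf.shape[0]} rows, series has {arr.shape[0]} timepoints"
        )
    design = conf
    if add_intercept:
        design = np.column_stack([np.ones(arr.shape[0]), conf])
    design = design.astype(arr.dtype, copy=False)
    # reduced QR: fast with many right-hand sides, and the diagonal of R
    # exposes rank deficiency
    q, r = np.linalg.qr(design)
    diag = np.abs(np.diag(r))
    tol = max(design.shape) * np.finfo(design.dtype).eps * (diag.max() if diag.size else 0)
    if (diag <= tol).any():
        rank = int((diag > tol).sum())
        raise ValueError(
            f"confound design is rank deficient (rank {rank} < {design.shape[1]} "
            "columns); remove collinear regressors"
        )
    out = arr - q @ (q.T @ arr)
    return out.reshape(np.asarray(series).shape)


def clean(series: np.ndarray, spec: CleaningSpec,
          confounds: Optional[np.ndarray] = None) -> np.ndarray:
    """Full cleaner: detrend -> band-pass -> confound regression.

    ``series`` is (T,) or (T, n_voxels).  If ``spec.regress_global`` the
    band-passed grid mean is appended to the confounds; all confounds are
    band-pass filtered with the data's filter before regression.  The
    band-passed trend regressors are regressed out again in the final
    step: this makes the whole cleaner a single orthogonal projection, so
    applying it twice equals applying it once to machine precision.
    """
    spec.validate()
    arr = _as_time_major(series)
    out = detrend(arr, spec.detrend_order)
    if spec.band_hz is not None:
        out = bandpass(out, spec.band_hz, spec.tr_s)
    conf_cols: list = []
    if spec.detrend_order >= 1 and spec.band_hz is not None:
        # in-band component of the trend basis (the constant is already
        # annihilated by the filter)
        t = np.linspace(-1.0, 1.0, arr.shape[0], dtype=arr.dtype)
        trend = np.vander(t, spec.detrend_order + 1, increasing=True)[:, 1:]
        conf_cols.append(bandpass(trend.astype(arr.dtype), spec.band_hz,
                                  spec.tr_s))
    if confounds is not None:
        conf = np.asarray(confounds, dtype=np.float64)
        if conf.ndim == 1:
            conf = conf[:, None]
        conf = detrend(conf, spec.detrend_order)
        if spec.band_hz is not None:
            conf = bandpass(conf, spec.band_hz, spec.tr_s)
        conf_cols.append(conf)
    if spec.regress_global:
        conf_cols.append(out.mean(axis=1, keepdims=True))
    if conf_cols:
        design = np.column_stack(conf_cols)
        # a confound that is (numerically) zero after filtering carries no
        # information; drop it rather than reject the design
        keep = np.linalg.norm(design, axis=0) > 1e-12 * np.sqrt(design.shape[0])
        if keep.any():
            out = regress_confounds(out, design[:, keep], add_intercept=False)
    return out.reshape(np.asarray(series).shape)


def clean_bold(bold4d: np.ndarray, spec: CleaningSpec,
               confounds: Optional[np.ndarray] = None) -> np.ndarray:
    """Apply :func:`clean` to a (X, Y, Z, T) volume, voxelwise."""
    bold4d = np.asarray(bold4d)
    if bold4d.ndim != 4:
        raise ValueError("bold must be 4D (X, Y, Z, T)")
    shape = bold4d.shape
    flat = bold4d.reshape(-1, shape[-1]).T  # (T, n_voxels)
    cleaned = clean(flat, spec, confounds=confounds)
    return cleaned.T.reshape(shape)
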