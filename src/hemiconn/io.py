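"""NIfTI and TSV input/output with consistency checks.

Volumes are NIfTI-1 via nibabel; tables are tab-separated UTF-8 with a
header row via pandas.  A run's volumes must share one affine — a
mismatch is a hard error naming the offending file.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Optional, Sequence, Tuple

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = ["read_volume", "write_volume", "read_table", "write_table",
           "check_affines"]


def read_volume(path) -> Tuple[np.ndarray, np.ndarray]:
    """Read a NIfTI volume; returns (data array, affine).

    Volumes containing NaN are rejected (they indicate an upstream
    failure, not valid data).
    """
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # malformed file
        raise ValueError(f"cannot read NIfTI file {path}: {exc}") from exc
    data = np.asarray(img.dataobj)
    if np.issubdtype(data.dtype, np.floating) and np.isnan(data).any():
        raise ValueError(f"volume {path} contains NaN values")
    return data, img.affine


def write_volume(path, data: np.ndarray, affine: np.ndarray) -> None:
    """Write an array as NIfTI-1; round-trips bit-exactly via read_volume."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = np.asarray(data)
    if data.dtype == bool:
        data = data.astype(np.uint8)
    img = nib.Nifti1Image(data, np.asarray(affine, dtype=np.float64))
    nib.save(img, str(path))


def check_affines(paths: Iterable) -> np.ndarray:
    """Verify all volumes share one affine; return it.

    Raises with the name of the first offending file.
    """
    reference = None
    ref_path = None
    for p in paths:
        _, aff = read_volume(p)
        if reference is None:
            reference, ref_path = aff, p
        elif not np.allclose(aff, reference, atol=1e-6):
            raise ValueError(
                f"affine of {p} does not match {ref_path}; all volumes in a "
                "run must share one grid")
    if reference is None:
        raise ValueError("no volumes supplied")
    return reference


def read_table(path, required: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Read a TSV table with a header row, checking required columns."""
    path = Path(path)
    table = pd.read_csv(path, sep="\t")
    if required:
        missing = [c for c in required if c not in table.columns]
        if missing:
            raise ValueError(f"table {path} is missing column(s): {missing}")
    return table


def write_table(table: pd.DataFrame, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, sep="\t", index=False)
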