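"""Synthetic two-group imaging/behavior datasets with planted effects.

Emulates the study design the analysis targets: two groups (controls and
patients, ~30 each), bilateral seed regions on a left-right symmetric 3 mm
grid, target regions coupled to the seeds positively or negatively with a
right>left strength asymmetry, group-dependent coupling reductions, ROI
fractional anisotropy with leftward (left>right) asymmetry plus a planted
right-hemisphere deficit in patients, and a behavioral table with a
planted imaging-symptom correlation.

Generative model, per subject:

* each seed side has a latent unit-variance AR(1) series ``s``;
* seed voxels carry ``s`` plus AR(1) noise of SD ``noise_sd``;
* a target voxel coupled with weight ``w`` carries
  ``w*s + sqrt(1-w^2)*noise``;
* every other voxel is pure noise.

With unit noise SD the population correlation between a coupled voxel and
the latent series is exactly ``w``; :func:`expected_seed_target_r` gives
the closed form against the *mean* seed series.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from typing import Dict, Iterator, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as _st

from .dti import EigenvalueImage, asymmetry_index, fa_summary_table
from .rsfc import RoiPair, lr_flip_array

__all__ = [
    "CouplingSpec",
    "PlantedCorrelation",
    "SimulationConfig",
    "SubjectDataset",
    "default_rois",
    "default_couplings",
    "generate_bold",
    "iter_bold_subjects",
    "generate_fa",
    "generate_behavior",
    "expected_seed_target_r",
    "eigenvalues_for_fa",
    "cingulum_roi_masks",
]

GROUPS = ("control", "patient")


@dataclass(frozen=True)
class CouplingSpec:
    """Coupling of one target region to one seed side.

    ``region`` names a mask in the target-mask dictionary; ``seed`` is
    ``left`` or ``right``; ``weight`` maps group -> w in [-1, 1].
    """

    region: str
    seed: str
    weight: Mapping[str, float]

    def validate(self) -> None:
        if self.seed not in ("left", "right"):
            raise ValueError(f"seed must be 'left' or 'right', got {self.seed!r}")
        for group, w in self.weight.items():
            if not -1.0 <= w <= 1.0:
                raise ValueError(f"weight {w} for group {group!r} outside [-1, 1]")


@dataclass(frozen=True)
class PlantedCorrelation:
    """Planted Pearson correlation between a behavioral variable and an
    imaging measure (within the patient group)."""

    variable: str
    imaging_measure: str
    rho: float

    def validate(self) -> None:
        if not -1.0 <= self.rho <= 1.0:
            raise ValueError(f"rho {self.rho} outside [-1, 1]")


def default_couplings() -> List[CouplingSpec]:
    """Study-condition couplings.

    A "striatum"-like bilateral target is positively coupled (stronger on
    the right: right>left asymmetry) and loses 0.3 of its weight in
    patients; a "pcc"-like bilateral target is negatively coupled and
    becomes more negative in patients.
    """
    return [
        CouplingSpec("striatum_left", "left", {"control": 0.5, "patient": 0.2}),
        CouplingSpec("striatum_right", "right", {"control": 0.6, "patient": 0.3}),
        CouplingSpec("pcc_left", "left", {"control": -0.30, "patient": -0.50}),
        CouplingSpec("pcc_right", "right", {"control": -0.35, "patient": -0.55}),
    ]


def _default_fa_spec() -> Dict[str, Dict[str, Tuple[float, float]]]:
    # ROI FA mean/SD per group: leftward asymmetry in both groups, planted
    # right-hemisphere reduction in patients (printed study summaries)
    return {
        "left": {"control": (0.525, 0.060), "patient": (0.505, 0.047)},
        "right": {"control": (0.471, 0.064), "patient": (0.433, 0.038)},
    }


def _default_behavior_spec() -> Dict[str, Dict[str, Tuple[float, float]]]:
    # per-variable (mean, SD) per group; patient-only clinical variables
    # carry only a "patient" entry
    return {
        "age": {"control": (23.0, 3.2), "patient": (23.1, 3.6)},
        "education": {"control": (14.3, 2.0), "patient": (13.7, 2.0)},
        "stroop_word_time": {"control": (11.4, 2.6), "patient": (12.5, 2.4)},
        "stroop_color_time": {"control": (15.2, 3.3), "patient": (18.3, 4.4)},
        "stroop_incongruent_time": {"control": (31.4, 7.6), "patient": (37.7, 9.4)},
        "stroop_word_acc": {"control": (1.0, 0.0), "patient": (0.999, 0.006)},
        "stroop_color_acc": {"control": (0.997, 0.014), "patient": (1.0, 0.0)},
        "stroop_incongruent_acc": {"control": (0.922, 0.085), "patient": (0.879, 0.096)},
        "PANSS_P": {"patient": (19.4, 4.6)},
        "PANSS_N": {"patient": (16.1, 4.7)},
        "PANSS_G": {"patient": (31.8, 5.4)},
        "onset_age": {"patient": (19.4, 3.2)},
        "duration_months": {"patient": (39.0, 33.3)},
        "medication_mg": {"patient": (407.7, 240.6)},
    }


@dataclass
class SimulationConfig:
    """Study-design parameters of the synthetic dataset.

    The flip axis is axis 0 and must have even extent so every voxel has
    an exact mirror partner.  Defaults encode the emulated study: a
    24x28x24 grid of 3 mm voxels, 120 timepoints at TR = 2 s (stand-ins
    for unavailable acquisition details), 30 subjects per group for the
    functional arm, 29 controls / 24 patients for the diffusion arm, AR(1)
    temporal noise with rho = 0.3.
    """

    grid_dims: Tuple[int, int, int] = (24, 28, 24)
    voxel_size_mm: float = 3.0
    n_timepoints: int = 120
    tr_s: float = 2.0
    n_per_group: Mapping[str, int] = field(
        default_factory=lambda: {"control": 30, "patient": 30})
    couplings: Sequence[CouplingSpec] = field(default_factory=default_couplings)
    noise_sd: float = 1.0
    ar1_rho: float = 0.3
    fa_spec: Mapping[str, Mapping[str, Tuple[float, float]]] = field(
        default_factory=_default_fa_spec)
    dti_n_per_group: Mapping[str, int] = field(
        default_factory=lambda: {"control": 29, "patient": 24})
    behavior_spec: Mapping[str, Mapping[str, Tuple[float, float]]] = field(
        default_factory=_default_behavior_spec)
    behavior_correlations: Sequence[PlantedCorrelation] = field(
        default_factory=lambda: [PlantedCorrelation("PANSS_N", "ai", -0.532)])
    rng_seed: int = 0

    def validate(self) -> None:
        if len(self.grid_dims) != 3 or any(d < 2 for d in self.grid_dims):
            raise ValueError("grid_dims must be three extents >= 2")
        if self.grid_dims[0] % 2 != 0:
            raise ValueError(
                f"flip-axis extent {self.grid_dims[0]} is odd; every voxel "
                "needs a mirror partner")
        if self.n_timepoints < 8:
            raise ValueError("n_timepoints must be >= 8")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not 0 <= self.ar1_rho < 1:
            raise ValueError("ar1_rho must be in [0, 1)")
        for c in self.couplings:
            c.validate()
        for roi, per_group in self.fa_spec.items():
            for group, (mean, sd) in per_group.items():
                if not 0 < mean < 1:
                    raise ValueError(
                        f"FA mean {mean} for {roi}/{group} outside (0, 1)")
                if sd < 0:
                    raise ValueError("FA SD must be >= 0")
        for pc in self.behavior_correlations:
            pc.validate()

    def affine(self) -> np.ndarray:
        """RAS-oriented affine with isotropic voxels, centered on the grid."""
        aff = np.diag([self.voxel_size_mm] * 3 + [1.0])
        aff[:3, 3] = -self.voxel_size_mm * (np.asarray(self.grid_dims) - 1) / 2.0
        return aff

    def subject_ids(self, arm: str = "bold") -> List[Tuple[str, str]]:
        counts = self.n_per_group if arm == "bold" else self.dti_n_per_group
        out = []
        for group in GROUPS:
            for i in range(counts.get(group, 0)):
                out.append((f"{group}_{i + 1:02d}", group))
        return out


@dataclass
class SubjectDataset:
    """One subject's synthetic 4D BOLD volume plus provenance."""

    subject: str
    group: str
    bold: np.ndarray  # (X, Y, Z, T)
    latents: Dict[str, np.ndarray]  # seed side -> latent series


# ---------------------------------------------------------------------------
# ROI geometry
# ---------------------------------------------------------------------------

def _box(shape: Tuple[int, int, int], lo: Sequence[int], hi: Sequence[int]) -> np.ndarray:
    m = np.zeros(shape, dtype=bool)
    m[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = True
    return m


def default_rois(config: SimulationConfig
                 ) -> Tuple[RoiPair, Dict[str, np.ndarray]]:
    """Seed pair and target masks on the configured grid.

    The left seed is a 3x3x3 block just left of the midline in the
    anterior-superior quadrant (an ACC-like placement); the right seed is
    its mirror.  Targets: a deep bilateral "striatum" pair (3x4x3 each)
    and a posterior bilateral "pcc" pair (3x3x3 each), all mirror-accurate
    and disjoint from the seeds.  Placement is relative to the grid
    extents; the grid must be at least 12 x 10 x 8.
    """
    nx, ny, nz = config.grid_dims
    if nx < 12 or ny < 10 or nz < 8:
        raise ValueError(
            f"default ROI layout needs a grid of at least 12x10x8, got "
            f"{config.grid_dims}")
    half = nx // 2
    seed_left = _box(config.grid_dims, (half - 3, ny - 5, nz - 5),
                     (half, ny - 2, nz - 2))
    seeds = RoiPair(seed_left, lr_flip_array(seed_left))
    striatum_left = _box(config.grid_dims, (half - 6, ny - 9, nz - 8),
                         (half - 3, ny - 5, nz - 5))
    pcc_left = _box(config.grid_dims, (half - 3, 2, nz - 6),
                    (half, 5, nz - 3))
    targets = {
        "striatum_left": striatum_left,
        "striatum_right": lr_flip_array(striatum_left),
        "pcc_left": pcc_left,
        "pcc_right": lr_flip_array(pcc_left),
    }
    return seeds, targets


def cingulum_roi_masks(config: SimulationConfig) -> Dict[str, np.ndarray]:
    """Synthetic left/right anterior-cingulum ROI masks for the FA arm.

    Sizes follow the emulated tract ROIs — 99 voxels on the left, 135 on
    the right — and are deliberately not mirror images (real tract ROIs
    are not), so they are plain masks rather than a RoiPair.
    """
    nx, ny, nz = config.grid_dims
    if nx < 12 or ny < 13 or nz < 7:
        raise ValueError(
            f"cingulum ROI layout needs a grid of at least 12x13x7, got "
            f"{config.grid_dims}")
    half = nx // 2
    left = _box(config.grid_dims, (half - 3, ny - 12, 2),
                (half, ny - 1, 5))                    # 3 x 11 x 3 = 99
    right = _box(config.grid_dims, (half, ny - 10, 2),
                 (half + 3, ny - 1, 7))               # 3 x 9 x 5 = 135
    return {"left": left, "right": right}


# ---------------------------------------------------------------------------
# BOLD generation
# ---------------------------------------------------------------------------

def _ar1(rng: np.random.Generator, n_t: int, n_series: int, rho: float,
         dtype=np.float64) -> np.ndarray:
    """Stationary unit-variance AR(1) series, shape (T, n_series).

    x_0 = z_0, x_t = rho*x_{t-1} + sqrt(1-rho^2)*z_t keeps the marginal
    variance at exactly 1 for every t.
    """
    if dtype == np.float32:
        z = rng.standard_normal((n_t, n_series), dtype=np.float32)
    else:
        z = rng.standard_normal((n_t, n_series)).astype(dtype, copy=False)
    if rho == 0 or n_t == 1:
        return z
    from scipy.signal import lfilter
    z[1:] *= np.sqrt(1.0 - rho ** 2, dtype=dtype)
    return lfilter([1.0], [1.0, -rho], z, axis=0).astype(dtype, copy=False)


def expected_seed_target_r(w: float, noise_sd: float, k_seed: int) -> float:
    """Population correlation between a coupled target voxel and the mean
    seed series.

    seed mean = s + mean of k_seed independent noises (variance sd^2/k);
    target voxel = w*s + sqrt(1-w^2)*noise (variance w^2 + (1-w^2)*sd^2);
    covariance = w.
    """
    s2 = noise_sd ** 2
    return w / np.sqrt((w ** 2 + (1 - w ** 2) * s2) * (1 + s2 / k_seed))


def _check_masks(seeds: RoiPair, targets: Mapping[str, np.ndarray],
                 shape: Tuple[int, int, int]) -> None:
    seed_union = seeds.left | seeds.right
    if seeds.left.shape != shape:
        raise ValueError("seed masks are not on the configured grid")
    covered = np.zeros(shape, dtype=bool)
    for name, mask in targets.items():
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != shape:
            raise ValueError(f"target mask {name!r} is not on the grid")
        if (mask & seed_union).any():
            raise ValueError(f"target mask {name!r} overlaps a seed ROI")
        if (mask & covered).any():
            raise ValueError(f"target mask {name!r} overlaps another target")
        covered |= mask


def iter_bold_subjects(config: SimulationConfig,
                       seeds: Optional[RoiPair] = None,
                       targets: Optional[Mapping[str, np.ndarray]] = None,
                       dtype=np.float32) -> Iterator[SubjectDataset]:
    """Generate subjects one at a time (memory-friendly).

    Deterministic in ``config.rng_seed``: each subject draws from its own
    spawned random stream, so the full dataset is bit-reproducible.
    """
    config.validate()
    if seeds is None or targets is None:
        d_seeds, d_targets = default_rois(config)
        seeds = seeds if seeds is not None else d_seeds
        targets = targets if targets is not None else d_targets
    _check_masks(seeds, targets, tuple(config.grid_dims))
    coupling_by_region = {c.region: c for c in config.couplings}
    unknown = set(coupling_by_region) - set(targets)
    if unknown:
        raise ValueError(f"couplings reference unknown masks: {sorted(unknown)}")

    n_vox = int(np.prod(config.grid_dims))
    flat_idx = {name: np.flatnonzero(np.asarray(mask, bool).ravel())
                for name, mask in targets.items()}
    seed_idx = {"left": np.flatnonzero(seeds.left.ravel()),
                "right": np.flatnonzero(seeds.right.ravel())}

    root = np.random.SeedSequence(config.rng_seed)
    subjects = config.subject_ids("bold")
    streams = root.spawn(len(subjects))
    for (subject, group), ss in zip(subjects, streams):
        rng = np.random.default_rng(ss)
        latents = {side: _ar1(rng, config.n_timepoints, 1, config.ar1_rho)[:, 0]
                   for side in ("left", "right")}
        noise = config.noise_sd * _ar1(rng, config.n_timepoints, n_vox,
                                       config.ar1_rho, dtype=dtype)
        bold = noise  # (T, n_vox); modified in place below
        for side in ("left", "right"):
            bold[:, seed_idx[side]] += latents[side][:, None].astype(dtype)
        for name, spec in coupling_by_region.items():
            w = float(spec.weight.get(group, 0.0))
            s = latents[spec.seed].astype(dtype)
            idx = flat_idx[name]
            bold[:, idx] = (w * s[:, None]
                            + np.sqrt(1.0 - w ** 2) * noise[:, idx])
        vol = bold.T.reshape(*config.grid_dims, config.n_timepoints)
        yield SubjectDataset(subject=subject, group=group, bold=vol,
                             latents=latents)


def generate_bold(config: SimulationConfig, **kwargs) -> List[SubjectDataset]:
    """All subjects at once; see :func:`iter_bold_subjects`."""
    return list(iter_bold_subjects(config, **kwargs))


# ---------------------------------------------------------------------------
# FA generation
# ---------------------------------------------------------------------------

def _truncnorm(rng: np.random.Generator, mean: float, sd: float, n: int,
               lo: float, hi: float) -> np.ndarray:
    if sd == 0:
        return np.full(n, mean)
    a, b = (lo - mean) / sd, (hi - mean) / sd
    u = rng.uniform(size=n)
    return _st.truncnorm.ppf(u, a, b, loc=mean, scale=sd)


def eigenvalues_for_fa(fa: float, trace: float = 2.4e-3) -> Tuple[float, float, float]:
    """Prolate tensor eigenvalues (lam1, lam2, lam2) realizing a given FA.

    For an axially symmetric tensor with ratio x = lam1/lam2,
    FA = (x - 1)/sqrt(x^2 + 2), which inverts to
    x = (1 + FA*sqrt(3 - 2 FA^2)) / (1 - FA^2).  The trace fixes the scale.
    """
    if not 0 <= fa < 1:
        raise ValueError("fa must be in [0, 1)")
    if fa == 0:
        lam = trace / 3.0
        return lam, lam, lam
    x = (1.0 + fa * np.sqrt(3.0 - 2.0 * fa ** 2)) / (1.0 - fa ** 2)
    lam2 = trace / (x + 2.0)
    return x * lam2, lam2, lam2


def generate_fa(config: SimulationConfig,
                eigenvalue_maps: bool = False,
                rng: Optional[np.random.Generator] = None):
    """Per-subject ROI FA values for the diffusion arm.

    FA ~ Normal(mean, SD) truncated to (0, 1), per ROI side and group.
    Returns an FA summary table (subject, group, left_fa, right_fa, ai);
    with ``eigenvalue_maps=True`` also returns a dict of per-subject
    :class:`EigenvalueImage` built so that the FA computation recovers the
    drawn ROI FA exactly.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(
            np.random.SeedSequence((config.rng_seed, 7001)))
    subjects = config.subject_ids("dti")
    left_spec = config.fa_spec["left"]
    right_spec = config.fa_spec["right"]
    rows = {"subject": [], "group": [], "left": [], "right": []}
    for subject, group in subjects:
        lm, lsd = left_spec[group]
        rm, rsd = right_spec[group]
        rows["subject"].append(subject)
        rows["group"].append(group)
        rows["left"].append(float(_truncnorm(rng, lm, lsd, 1, 0.0, 1.0)[0]))
        rows["right"].append(float(_truncnorm(rng, rm, rsd, 1, 0.0, 1.0)[0]))
    table = fa_summary_table(rows["subject"], rows["group"],
                             rows["left"], rows["right"])
    if not eigenvalue_maps:
        return table
    masks = cingulum_roi_masks(config)
    images: Dict[str, EigenvalueImage] = {}
    for _, row in table.iterrows():
        eig = np.zeros((*config.grid_dims, 3))
        mask = np.zeros(config.grid_dims, dtype=bool)
        for side, fa_val in (("left", row["left_fa"]), ("right", row["right_fa"])):
            lam = eigenvalues_for_fa(float(fa_val))
            eig[masks[side]] = lam
            mask |= masks[side]
        images[row["subject"]] = EigenvalueImage(eig, mask)
    return table, images


# ---------------------------------------------------------------------------
# Behavior generation
# ---------------------------------------------------------------------------

#: variables rounded to integers (PANSS subscales are item sums)
_INTEGER_VARS = {"PANSS_P", "PANSS_N", "PANSS_G"}
_POSITIVE_VARS = {"stroop_word_time", "stroop_color_time",
                  "stroop_incongruent_time", "age", "education",
                  "onset_age", "duration_months", "medication_mg"}
_FRACTION_VARS = {"stroop_word_acc", "stroop_color_acc",
                  "stroop_incongruent_acc"}


def generate_behavior(config: SimulationConfig,
                      imaging_measures: Optional[Mapping[str, Mapping[str, float]]] = None,
                      missing_stroop_per_group: int = 1,
                      rng: Optional[np.random.Generator] = None) -> pd.DataFrame:
    """Behavioral/clinical table with planted imaging correlations.

    ``imaging_measures`` maps measure name (e.g. ``"ai"``) to a
    subject -> value mapping; a variable listed in
    ``config.behavior_correlations`` is generated as
    ``rho * standardized imaging + sqrt(1 - rho^2) * noise`` within the
    patient group, then rescaled to its configured mean/SD.  Stroop
    variables are NaN for ``missing_stroop_per_group`` subjects per group
    (task non-completion, handled downstream by pairwise deletion).
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(
            np.random.SeedSequence((config.rng_seed, 7002)))
    planted = {pc.variable: pc for pc in config.behavior_correlations}
    if imaging_measures is None and planted:
        raise ValueError(
            "behavior_correlations configured but no imaging_measures given")
    subjects = config.subject_ids("bold")
    table = pd.DataFrame({"subject": [s for s, _ in subjects],
                          "group": [g for _, g in subjects]})
    # sex: fixed female counts per group (12 controls, 13 patients at n=30),
    # scaled proportionally for other group sizes
    female_frac = {"control": 12 / 30, "patient": 13 / 30}
    sex = []
    for group in GROUPS:
        n = config.n_per_group.get(group, 0)
        n_f = int(round(female_frac[group] * n))
        sex.extend(["F"] * n_f + ["M"] * (n - n_f))
    table["sex"] = sex

    for var, per_group in config.behavior_spec.items():
        values = np.full(len(table), np.nan)
        for group, (mean, sd) in per_group.items():
            sel = (table["group"] == group).to_numpy()
            n = int(sel.sum())
            if n == 0:
                continue
            if var in planted and group == "patient":
                pc = planted[var]
                if pc.imaging_measure not in imaging_measures:
                    raise ValueError(
                        f"imaging measure {pc.imaging_measure!r} required for "
                        f"planted correlation with {var!r} was not supplied")
                measure = imaging_measures[pc.imaging_measure]
                missing = [s for s in table.loc[sel, "subject"]
                           if s not in measure]
                if missing:
                    raise ValueError(
                        f"imaging measure {pc.imaging_measure!r} lacks values "
                        f"for subjects {missing[:3]}...")
                img = np.asarray([measure[s] for s in table.loc[sel, "subject"]],
                                 dtype=float)
                img_sd = img.std()
                z_img = (img - img.mean()) / (img_sd if img_sd > 0 else 1.0)
                latent = (pc.rho * z_img
                          + np.sqrt(1.0 - pc.rho ** 2) * rng.standard_normal(n))
                draw = mean + sd * latent
            else:
                draw = mean + sd * rng.standard_normal(n)
            if var in _POSITIVE_VARS:
                draw = np.maximum(draw, 1e-3)
            if var in _FRACTION_VARS:
                draw = np.clip(draw, 0.0, 1.0)
            if var in _INTEGER_VARS:
                draw = np.round(draw)
            values[sel] = draw
        table[var] = values

    if {"PANSS_P", "PANSS_N", "PANSS_G"} <= set(table.columns):
        table["PANSS_T"] = table["PANSS_P"] + table["PANSS_N"] + table["PANSS_G"]
    if {"stroop_color_time", "stroop_incongruent_time"} <= set(table.columns):
        table["stroop_interference"] = (table["stroop_incongruent_time"]
                                        - table["stroop_color_time"])
    # plant Stroop non-completion
    stroop_cols = [c for c in table.columns if c.startswith("stroop")]
    for group in GROUPS:
        idx = table.index[table["group"] == group]
        for i in idx[:missing_stroop_per_group]:
            table.loc[i, stroop_cols] = np.nan
    return table


def dataset_digest(subjects: Sequence[SubjectDataset]) -> str:
    """SHA-256 over all subjects' data, for determinism checks."""
    h = hashlib.sha256()
    for s in subjects:
        h.update(s.subject.encode())
        h.update(np.ascontiguousarray(s.bold).tobytes())
    return h.hexdigest()
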