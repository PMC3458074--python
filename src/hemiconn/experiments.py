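"""Replication experiments on synthetic data.

Each function runs one self-contained experiment of the study design on
generated data and returns summary rates: family-wise error calibration
of the Monte-Carlo extent correction, recovery of the planted group
coupling difference, power for the planted right-hemisphere FA deficit,
and sign recovery of the planted AI-symptom correlation.  They are used
by the validation suite and the reproduction script; all randomness is
controlled by an explicit seed.
"""

from __future__ import annotations

from typing import Dict, Optional

import numpy as np
from scipy import ndimage

from .behavior import correlate
from .inference import (correct_map, fwhm_to_sigma_voxels, one_sample_tmap,
                        simulate_cluster_null, two_sample_tmap)
from .preprocess import CleaningSpec
from .stats import pooled_two_sample_t
from .synth import (PlantedCorrelation, SimulationConfig, default_rois,
                    generate_behavior, generate_fa, iter_bold_subjects)

__all__ = [
    "fwe_calibration",
    "coupling_detection",
    "fa_deficit_power",
    "ai_correlation_recovery",
]


def fwe_calibration(seed: int, n_subjects: int = 30, n_null_iter: int = 2000,
                    n_replicates: int = 1000, grid: tuple = (20, 20, 20),
                    fwhm_mm: float = 6.0, voxel_p: float = 0.001,
                    alpha: float = 0.05) -> Dict[str, float]:
    """Family-wise error of the cluster-extent correction on null groups.

    The extent threshold k*(alpha) comes from the Monte-Carlo null at the
    given smoothness and voxel p.  Each replicate then draws ``n_subjects``
    independent null subject maps (white noise smoothed to the same FWHM,
    periodic boundaries), runs the voxelwise one-sample t-test, and applies
    ``correct_map`` with that threshold; the returned rate is the fraction
    of replicates with at least one surviving cluster.
    """
    ss = np.random.SeedSequence(seed)
    null_seed, group_seed = [int(s.generate_state(1)[0] % (2 ** 31))
                             for s in ss.spawn(2)]
    mask = np.ones(grid, dtype=bool)
    null = simulate_cluster_null(mask, fwhm_mm, voxel_p, n_iter=n_null_iter,
                                 seed=null_seed)
    k_star = null.k_star(alpha)
    if k_star is None:
        raise RuntimeError("no finite extent threshold at this alpha")
    sigma = fwhm_to_sigma_voxels(fwhm_mm, 3.0)
    rng = np.random.default_rng(group_seed)
    hits = 0
    for _ in range(n_replicates):
        subs = rng.standard_normal((n_subjects, *grid))
        for i in range(n_subjects):
            subs[i] = ndimage.gaussian_filter(subs[i], sigma, mode="wrap")
        tmap = one_sample_tmap(subs)
        _, table = correct_map(tmap, voxel_p, k_star - 1)
        hits += bool(len(table))
    return {"fwe_rate": hits / n_replicates, "k_star": float(k_star),
            "n_replicates": n_replicates}


def coupling_detection(seed: int, n_seeds: int = 100,
                       config: Optional[SimulationConfig] = None
                       ) -> Dict[str, float]:
    """Recovery of the planted between-group coupling reduction.

    For each simulation seed: generate the two groups with the default
    couplings (the striatum-like target loses 0.3 of its weight in the
    patient group), clean each subject (detrend + band-pass; the generator
    plants no global nuisance so global-signal regression is off), map the
    left seed, build the combined within-group mask, and run the
    between-group two-sample t with cluster correction (voxel p < 0.001,
    extent > 10 inside the mask).  A hit is a surviving cluster
    overlapping the planted left target region.
    """
    from .pipeline import subject_zmaps

    base = config if config is not None else SimulationConfig()
    cleaning = CleaningSpec(regress_global=False, tr_s=base.tr_s)
    hits = 0
    for i in range(n_seeds):
        cfg = SimulationConfig(
            grid_dims=base.grid_dims, voxel_size_mm=base.voxel_size_mm,
            n_timepoints=base.n_timepoints, tr_s=base.tr_s,
            n_per_group=base.n_per_group, couplings=base.couplings,
            noise_sd=base.noise_sd, ar1_rho=base.ar1_rho,
            rng_seed=(seed + i) % (2 ** 31))
        seeds_pair, targets = default_rois(cfg)
        zmaps = {"control": [], "patient": []}
        for subj in iter_bold_subjects(cfg, seeds=seeds_pair, targets=targets):
            maps = subject_zmaps(subj.bold, seeds_pair, cleaning)
            zmaps[subj.group].append(maps["left"])
        combined = np.zeros(cfg.grid_dims, dtype=bool)
        for group_maps in zmaps.values():
            tmap = one_sample_tmap(group_maps)
            corrected, _ = correct_map(tmap, 0.001, 14)
            combined |= corrected.values != 0
        between = two_sample_tmap(zmaps["control"], zmaps["patient"])
        corrected, table = correct_map(between, 0.001, 10,
                                       analysis_mask=combined)
        planted = targets["striatum_left"]
        hits += bool(((corrected.values != 0) & planted).any())
    return {"detection_rate": hits / n_seeds, "n_seeds": n_seeds}


def fa_deficit_power(seed: int, n_replicates: int = 500) -> Dict[str, float]:
    """Power for the planted right-hemisphere FA reduction.

    Each replicate draws the diffusion arm at the study summary values
    (right FA 0.471 +/- 0.064 in 29 controls vs 0.433 +/- 0.038 in 24
    patients) through the generator and tests the group difference with
    the pooled two-sample t at p < 0.05.
    """
    hits = 0
    for i in range(n_replicates):
        cfg = SimulationConfig(rng_seed=(seed + i) % (2 ** 31))
        table = generate_fa(cfg)
        a = table.loc[table["group"] == "control", "right_fa"].to_numpy()
        b = table.loc[table["group"] == "patient", "right_fa"].to_numpy()
        res = pooled_two_sample_t(a.mean(), a.std(ddof=1), len(a),
                                  b.mean(), b.std(ddof=1), len(b))
        hits += res.p < 0.05
    return {"power": hits / n_replicates, "n_replicates": n_replicates}


def ai_correlation_recovery(seed: int, n_replicates: int = 500,
                            rho: float = -0.532) -> Dict[str, float]:
    """Sign recovery of the planted AI-negative-symptom correlation.

    Each replicate generates the diffusion arm, plants a correlation of
    ``rho`` between the patients' FA asymmetry index and the PANSS
    negative subscale through the behavioral generator, and re-estimates
    the Pearson correlation (n = 24 patients).  Returns the fraction of
    replicates recovering the correct (negative) sign and the mean
    estimated r.
    """
    correct_sign = 0
    r_values = []
    for i in range(n_replicates):
        cfg = SimulationConfig(
            rng_seed=(seed + i) % (2 ** 31),
            behavior_correlations=[PlantedCorrelation("PANSS_N", "ai", rho)])
        fa = generate_fa(cfg)
        ai = dict(zip(fa["subject"], fa["ai"]))
        group_mean = fa.groupby("group")["ai"].mean().to_dict()
        for subject, group in cfg.subject_ids("bold"):
            ai.setdefault(subject, group_mean[group])
        behavior = generate_behavior(cfg, imaging_measures={"ai": ai})
        patients = behavior[behavior["group"] == "patient"]
        # correlate over the diffusion-arm patients (those with a drawn AI)
        dti_patients = set(fa.loc[fa["group"] == "patient", "subject"])
        rows = patients[patients["subject"].isin(dti_patients)]
        x = [ai[s] for s in rows["subject"]]
        res = correlate(x, rows["PANSS_N"].to_numpy())
        correct_sign += res.r < 0
        r_values.append(res.r)
    return {"sign_rate": correct_sign / n_replicates,
            "mean_r": float(np.mean(r_values)),
            "n_replicates": n_replicates}
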