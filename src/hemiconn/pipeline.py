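"""End-to-end analysis chain on a synthetic two-group study.

simulate -> clean -> per-subject seed Z-maps (left, right, flipped-right,
asymmetry contrast) -> within-group one-sample t-maps and paired
asymmetry t-maps -> between-group two-sample t-maps corrected inside the
combined within-group mask -> between-group asymmetry inside the explicit
asymmetry mask -> DTI FA/AI group tests -> behavioral comparisons and
imaging-behavior correlations.  Deterministic under a fixed seed; a
provenance record logs every inference parameter actually used.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import __version__
from .behavior import correlate, group_compare_table, sphere_roi_values
from .config import RunConfig
from .dti import group_fa_tests
from .inference import (asymmetry_within_group_mask, correct_map,
                        one_sample_tmap, paired_tmap, two_sample_tmap)
from .preprocess import clean_bold
from .rsfc import (StatMap, asymmetry_contrast, correlation_map, fisher_z,
                   lr_flip, seed_timeseries)
from .synth import (GROUPS, default_rois, generate_behavior, generate_fa,
                    iter_bold_subjects)

__all__ = ["PipelineResult", "subject_zmaps", "run_pipeline"]

log = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    """Everything the full chain produces, in memory."""

    zmaps: Dict[str, Dict[str, List[StatMap]]]      # group -> side -> maps
    contrasts: Dict[str, List[StatMap]]             # group -> contrast maps
    within_tables: Dict[str, pd.DataFrame]          # regime tag -> clusters
    between_tables: Dict[str, pd.DataFrame]
    between_maps: Dict[str, StatMap]
    fa_summary: pd.DataFrame
    fa_tests: pd.DataFrame
    behavior: pd.DataFrame
    behavior_compare: pd.DataFrame
    correlations: pd.DataFrame
    provenance: dict


def subject_zmaps(bold4d: np.ndarray, seeds, cleaning,
                  confounds: Optional[np.ndarray] = None) -> Dict[str, StatMap]:
    """Clean one subject's data and map both seeds.

    Returns left-seed and right-seed Fisher Z-maps plus the flipped-right
    map and the left-vs-flipped-right asymmetry contrast.
    """
    cleaned = clean_bold(bold4d, cleaning, confounds=confounds)
    out: Dict[str, StatMap] = {}
    for side, mask in (("left", seeds.left), ("right", seeds.right)):
        series = seed_timeseries(cleaned, mask)
        rmap = correlation_map(cleaned, series, side=f"{side}-seed")
        out[side] = fisher_z(rmap)
    out["flipped_right"] = lr_flip(out["right"])
    out["contrast"] = asymmetry_contrast(out["left"], out["right"])
    return out


def run_pipeline(config: RunConfig, out_dir: Optional[Path] = None
                 ) -> PipelineResult:
    """Run the full analysis chain; optionally write reports to disk."""
    config.validate()
    sim = config.simulation
    seeds, targets = default_rois(sim)

    # ---- stage 1-2: simulate + clean + per-subject connectivity maps ------
    zmaps: Dict[str, Dict[str, List[StatMap]]] = {
        g: {"left": [], "right": [], "flipped_right": []} for g in GROUPS}
    contrasts: Dict[str, List[StatMap]] = {g: [] for g in GROUPS}
    subject_order: Dict[str, List[str]] = {g: [] for g in GROUPS}
    for subj in iter_bold_subjects(sim, seeds=seeds, targets=targets):
        maps = subject_zmaps(subj.bold, seeds, config.cleaning)
        for side in ("left", "right", "flipped_right"):
            zmaps[subj.group][side].append(maps[side])
        contrasts[subj.group].append(maps["contrast"])
        subject_order[subj.group].append(subj.subject)
        log.debug("mapped subject %s", subj.subject)

    # ---- stage 3: within-group inference ----------------------------------
    within_tables: Dict[str, pd.DataFrame] = {}
    within_corrected: Dict[str, Dict[str, StatMap]] = {g: {} for g in GROUPS}
    asym_masks: Dict[str, StatMap] = {}
    for group in GROUPS:
        for side in ("left", "right", "flipped_right"):
            tmap = one_sample_tmap(zmaps[group][side])
            regime = config.within_group
            corrected, table = correct_map(
                tmap, regime.voxel_p, regime.min_extent,
                connectivity=config.connectivity,
                voxel_volume_mm3=sim.voxel_size_mm ** 3)
            within_corrected[group][side] = corrected
            within_tables[f"{group}_{side}"] = table
        # two-criterion asymmetry: paired t of left vs flipped-right,
        # intersected with the union of the two within-group maps
        paired = paired_tmap(zmaps[group]["left"], zmaps[group]["flipped_right"])
        regime = config.asymmetry_within
        paired_corrected, paired_table = correct_map(
            paired, regime.voxel_p, regime.min_extent,
            connectivity=config.connectivity,
            voxel_volume_mm3=sim.voxel_size_mm ** 3)
        asym_masks[group] = asymmetry_within_group_mask(
            within_corrected[group]["left"],
            within_corrected[group]["flipped_right"],
            paired_corrected)
        within_tables[f"{group}_asymmetry"] = paired_table

    # ---- stage 4: between-group inference ---------------------------------
    between_tables: Dict[str, pd.DataFrame] = {}
    between_maps: Dict[str, StatMap] = {}
    for side in ("left", "right"):
        tmap = two_sample_tmap(zmaps["control"][side], zmaps["patient"][side])
        combined_mask = np.zeros(sim.grid_dims, dtype=bool)
        for group in GROUPS:
            combined_mask |= within_corrected[group][side].values != 0
        regime = config.between_group
        corrected, table = correct_map(
            tmap, regime.voxel_p, regime.min_extent,
            analysis_mask=combined_mask, connectivity=config.connectivity,
            voxel_volume_mm3=sim.voxel_size_mm ** 3)
        between_maps[side] = corrected
        between_tables[side] = table

    asym_t = two_sample_tmap(contrasts["control"], contrasts["patient"])
    explicit_mask = (asym_masks["control"].values != 0) | \
                    (asym_masks["patient"].values != 0)
    regime = config.asymmetry_between
    asym_corrected, asym_table = correct_map(
        asym_t, regime.voxel_p, regime.min_extent,
        analysis_mask=explicit_mask, connectivity=config.connectivity,
        voxel_volume_mm3=sim.voxel_size_mm ** 3)
    between_maps["asymmetry"] = asym_corrected
    between_tables["asymmetry"] = asym_table

    # ---- stage 5: diffusion arm -------------------------------------------
    fa_summary = generate_fa(sim)
    fa_tests = group_fa_tests(fa_summary)

    # ---- stage 6: behavior + correlations ---------------------------------
    ai_by_subject = dict(zip(fa_summary["subject"], fa_summary["ai"]))
    # BOLD-arm patients without a DTI AI draw get none (arm sizes differ);
    # planted correlations use the DTI patients present in both tables
    imaging = {"ai": ai_by_subject}
    behavior = generate_behavior(sim, imaging_measures=_complete_ai(
        sim, ai_by_subject))
    behavior_compare = group_compare_table(behavior)

    correlations = _imaging_behavior_correlations(
        config, behavior, fa_summary, between_tables, zmaps)

    provenance = {
        "hemiconn_version": __version__,
        "seed": sim.rng_seed,
        "grid_dims": list(sim.grid_dims),
        "n_per_group": dict(sim.n_per_group),
        "band_hz": list(config.cleaning.band_hz) if config.cleaning.band_hz else None,
        "global_signal_regression": config.cleaning.regress_global,
        "connectivity": config.connectivity,
        "fwhm_mm": config.fwhm_mm,
        "extent_rule": "strict: cluster extent must exceed min_extent",
        "regimes": {
            "within_group": vars(config.within_group),
            "between_group": vars(config.between_group),
            "asymmetry_within": vars(config.asymmetry_within),
            "asymmetry_between": vars(config.asymmetry_between),
        },
        "sphere_radius_mm": config.sphere_radius_mm,
    }
    provenance["config_hash"] = hashlib.sha256(
        json.dumps(provenance, sort_keys=True).encode()).hexdigest()

    result = PipelineResult(
        zmaps=zmaps, contrasts=contrasts, within_tables=within_tables,
        between_tables=between_tables, between_maps=between_maps,
        fa_summary=fa_summary, fa_tests=fa_tests, behavior=behavior,
        behavior_compare=behavior_compare, correlations=correlations,
        provenance=provenance)
    if out_dir is not None:
        _write_reports(result, Path(out_dir))
    return result


def _complete_ai(sim, ai_by_subject: Dict[str, float]) -> Dict[str, Dict[str, float]]:
    """AI per BOLD-arm subject; arm-size mismatches filled with the group
    mean so the behavioral generator has a value for every subject."""
    out = dict(ai_by_subject)
    means: Dict[str, List[float]] = {}
    for subject, value in ai_by_subject.items():
        means.setdefault(subject.rsplit("_", 1)[0], []).append(value)
    for subject, group in sim.subject_ids("bold"):
        if subject not in out:
            out[subject] = float(np.mean(means.get(group, [0.0])))
    return {"ai": out}


def _imaging_behavior_correlations(config, behavior, fa_summary,
                                   between_tables, zmaps) -> pd.DataFrame:
    """Pearson correlations of imaging measures with clinical measures in
    patients, Bonferroni-adjusted over all tested pairs."""
    clinical_vars = [v for v in ("PANSS_P", "PANSS_N", "PANSS_G",
                                 "onset_age", "duration_months",
                                 "medication_mg", "stroop_interference")
                     if v in behavior.columns]
    patients = behavior[behavior["group"] == "patient"]
    measures: Dict[str, Dict[str, float]] = {}
    # sphere extraction at between-group peaks of each seed network
    for side in ("left", "right"):
        table = between_tables.get(side)
        if table is None or not len(table):
            continue
        peak = table.iloc[0]
        center = (int(peak["peak_i"]), int(peak["peak_j"]), int(peak["peak_k"]))
        maps = zmaps["patient"][side]
        vals = sphere_roi_values(maps, center, config.sphere_radius_mm,
                                 config.simulation.voxel_size_mm)
        subject_ids = [s for s, g in config.simulation.subject_ids("bold")
                       if g == "patient"]
        measures[f"{side}_seed_peak_z"] = dict(zip(subject_ids, vals))
    # AI from the diffusion arm
    fa_pat = fa_summary[fa_summary["group"] == "patient"]
    measures["ai"] = dict(zip(fa_pat["subject"], fa_pat["ai"]))

    pairs = [(m, c) for m in measures for c in clinical_vars]
    m_tests = len(pairs)
    rows = []
    for measure, clin in pairs:
        lookup = measures[measure]
        x, y = [], []
        for _, row in patients.iterrows():
            if row["subject"] in lookup:
                x.append(lookup[row["subject"]])
                y.append(row[clin])
        try:
            res = correlate(x, y, m_tests=m_tests)
        except ValueError:
            continue
        rows.append({"imaging": measure, "clinical": clin, "r": res.r,
                     "n": res.n, "p": res.p, "p_bonferroni": res.p_bonferroni})
    return pd.DataFrame(rows, columns=["imaging", "clinical", "r", "n",
                                       "p", "p_bonferroni"])


def _write_reports(result: PipelineResult, out_dir: Path) -> None:
    from .io import write_table

    out_dir.mkdir(parents=True, exist_ok=True)
    for tag, table in {**result.within_tables,
                       **{f"between_{k}": v
                          for k, v in result.between_tables.items()}}.items():
        write_table(table, out_dir / f"clusters_{tag}.tsv")
    write_table(result.fa_summary, out_dir / "fa_summary.tsv")
    write_table(result.fa_tests, out_dir / "fa_tests.tsv")
    write_table(result.behavior, out_dir / "behavior.tsv")
    write_table(result.behavior_compare, out_dir / "behavior_compare.tsv")
    write_table(result.correlations, out_dir / "correlations.tsv")
    with open(out_dir / "provenance.json", "w") as fh:
        json.dump(result.provenance, fh, indent=2, sort_keys=True)
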