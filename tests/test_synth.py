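"""Synthetic dataset generator: determinism, planted couplings, FA and
behavioral structure."""

import numpy as np
import pandas as pd
import pytest

from hemiconn.rsfc import RoiPair, lr_flip_array
from hemiconn.synth import (CouplingSpec, PlantedCorrelation,
                            SimulationConfig, dataset_digest, default_rois,
                            expected_seed_target_r, generate_behavior,
                            generate_bold, generate_fa, iter_bold_subjects)


def _config(**kw):
    base = dict(grid_dims=(12, 10, 8), n_timepoints=100,
                n_per_group={"control": 2, "patient": 2},
                dti_n_per_group={"control": 4, "patient": 4}, rng_seed=5)
    base.update(kw)
    return SimulationConfig(**base)


class TestConfigValidation:
    def test_odd_flip_axis_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            _config(grid_dims=(13, 10, 8)).validate()

    def test_out_of_range_weight_rejected(self):
        bad = [CouplingSpec("striatum_left", "left", {"control": 1.5})]
        with pytest.raises(ValueError, match="outside"):
            _config(couplings=bad).validate()

    def test_out_of_range_rho_rejected(self):
        bad = [PlantedCorrelation("PANSS_N", "ai", -2.0)]
        with pytest.raises(ValueError, match="outside"):
            _config(behavior_correlations=bad).validate()

    def test_fa_mean_outside_unit_interval_rejected(self):
        spec = {"left": {"control": (1.2, 0.1), "patient": (0.5, 0.1)},
                "right": {"control": (0.4, 0.1), "patient": (0.4, 0.1)}}
        with pytest.raises(ValueError, match="FA mean"):
            _config(fa_spec=spec).validate()


class TestBoldGeneration:
    def test_deterministic_under_fixed_seed(self):
        cfg = _config()
        assert dataset_digest(generate_bold(cfg)) == \
            dataset_digest(generate_bold(cfg))

    def test_different_seeds_differ(self):
        assert dataset_digest(generate_bold(_config(rng_seed=1))) != \
            dataset_digest(generate_bold(_config(rng_seed=2)))

    def test_zero_coupling_gives_near_zero_correlation(self):
        """With w=0 everywhere the seed and target means are independent:
        |r| stays below 3/sqrt(T)."""
        zero = [CouplingSpec("striatum_left", "left",
                             {"control": 0.0, "patient": 0.0})]
        cfg = _config(couplings=zero, n_timepoints=200, ar1_rho=0.0)
        seeds, targets = default_rois(cfg)
        for subj in iter_bold_subjects(cfg, seeds=seeds, targets=targets):
            seed_mean = subj.bold[seeds.left].mean(axis=0)
            target_mean = subj.bold[targets["striatum_left"]].mean(axis=0)
            r = np.corrcoef(seed_mean, target_mean)[0, 1]
            assert abs(r) < 3 / np.sqrt(200)

    def test_unit_coupling_voxel_equals_latent(self):
        one = [CouplingSpec("striatum_left", "left",
                            {"control": 1.0, "patient": 1.0})]
        cfg = _config(couplings=one)
        seeds, targets = default_rois(cfg)
        subj = next(iter(iter_bold_subjects(cfg, seeds=seeds, targets=targets)))
        voxel = subj.bold[targets["striatum_left"]][0]
        r = np.corrcoef(voxel, subj.latents["left"])[0, 1]
        assert r == pytest.approx(1.0, abs=1e-5)

    def test_partial_coupling_calibrated_against_closed_form(self):
        """w=0.6 with unit-variance latent and noise: the population
        correlation between a target voxel and the latent is 0.6; sample
        correlations at T=200 concentrate there."""
        spec = [CouplingSpec("striatum_left", "left",
                             {"control": 0.6, "patient": 0.6})]
        rs = []
        for seed in range(50):
            cfg = _config(couplings=spec, n_timepoints=200, rng_seed=seed,
                          n_per_group={"control": 1, "patient": 1})
            seeds, targets = default_rois(cfg)
            subj = next(iter(iter_bold_subjects(cfg, seeds=seeds,
                                                targets=targets)))
            voxel = subj.bold[targets["striatum_left"]][0]
            rs.append(np.corrcoef(voxel, subj.latents["left"])[0, 1])
        rs = np.asarray(rs)
        assert abs(rs.mean() - 0.6) < 0.04
        assert (np.abs(rs - 0.6) < 0.2).all()

    @pytest.mark.parametrize("n_t,tol", [(100, 0.05), (400, 0.025)])
    def test_seed_mean_correlation_converges_to_closed_form(self, n_t, tol):
        """Empirical correlation between a coupled voxel and the mean
        seed series approaches expected_seed_target_r as T grows."""
        spec = [CouplingSpec("striatum_left", "left",
                             {"control": 0.5, "patient": 0.5})]
        rs = []
        for seed in range(30):
            cfg = _config(couplings=spec, n_timepoints=n_t, rng_seed=seed,
                          n_per_group={"control": 1, "patient": 0})
            seeds, targets = default_rois(cfg)
            subj = next(iter(iter_bold_subjects(cfg, seeds=seeds,
                                                targets=targets)))
            seed_mean = subj.bold[seeds.left].mean(axis=0)
            voxel = subj.bold[targets["striatum_left"]][0]
            rs.append(np.corrcoef(voxel, seed_mean)[0, 1])
        expected = expected_seed_target_r(0.5, 1.0, int(seeds.left.sum()))
        assert abs(np.mean(rs) - expected) < tol

    def test_overlapping_masks_rejected(self):
        cfg = _config()
        seeds, targets = default_rois(cfg)
        targets["bad"] = seeds.left.copy()
        cfg2 = _config(couplings=list(cfg.couplings) +
                       [CouplingSpec("bad", "left", {"control": 0.1})])
        with pytest.raises(ValueError, match="overlaps a seed"):
            list(iter_bold_subjects(cfg2, seeds=seeds, targets=targets))

    def test_unknown_coupling_region_rejected(self):
        cfg = _config(couplings=[CouplingSpec("nowhere", "left",
                                              {"control": 0.5})])
        with pytest.raises(ValueError, match="unknown masks"):
            list(iter_bold_subjects(cfg))


class TestFaGeneration:
    def test_zero_sd_reproduces_configured_means(self):
        spec = {"left": {"control": (0.525, 0.0), "patient": (0.505, 0.0)},
                "right": {"control": (0.471, 0.0), "patient": (0.433, 0.0)}}
        table = generate_fa(_config(fa_spec=spec))
        controls = table[table["group"] == "control"]
        assert np.allclose(controls["left_fa"], 0.525)
        assert np.allclose(controls["right_fa"], 0.471)

    def test_leftward_asymmetry_sign_forced_by_means(self):
        """With left mean 0.525 and right mean 0.471 the group-mean AI
        must be negative (leftward)."""
        table = generate_fa(_config(dti_n_per_group={"control": 40,
                                                     "patient": 40}))
        assert table[table["group"] == "control"]["ai"].mean() < 0

    def test_deterministic(self):
        cfg = _config()
        pd.testing.assert_frame_equal(generate_fa(cfg), generate_fa(cfg))

    def test_values_inside_unit_interval(self):
        table = generate_fa(_config(dti_n_per_group={"control": 50,
                                                     "patient": 50}))
        for col in ("left_fa", "right_fa"):
            assert table[col].between(0, 1).all()


class TestBehaviorGeneration:
    def _ai(self, cfg, rho_rng=None):
        rng = rho_rng or np.random.default_rng(0)
        return {"ai": {s: rng.normal(-0.1, 0.1)
                       for s, _ in cfg.subject_ids("bold")}}

    def test_zero_rho_gives_near_zero_correlation(self):
        cfg = _config(n_per_group={"control": 30, "patient": 30},
                      behavior_correlations=[
                          PlantedCorrelation("PANSS_N", "ai", 0.0)])
        imaging = self._ai(cfg)
        table = generate_behavior(cfg, imaging_measures=imaging)
        pat = table[table["group"] == "patient"]
        x = np.array([imaging["ai"][s] for s in pat["subject"]])
        r = np.corrcoef(x, pat["PANSS_N"])[0, 1]
        assert abs(r) < 2 / np.sqrt(30)

    def test_perfect_rho_gives_exact_linear_agreement(self):
        cfg = _config(n_per_group={"control": 2, "patient": 24},
                      behavior_correlations=[
                          PlantedCorrelation("onset_age", "ai", 1.0)])
        imaging = self._ai(cfg)
        table = generate_behavior(cfg, imaging_measures=imaging)
        pat = table[table["group"] == "patient"]
        x = np.array([imaging["ai"][s] for s in pat["subject"]])
        r = np.corrcoef(x, pat["onset_age"])[0, 1]
        assert r == pytest.approx(1.0, abs=1e-9)

    def test_negative_rho_recovered_across_replicates(self):
        """rho=-0.5 at n=24: the sample correlation lands in
        [-0.8, -0.1] in at least 95% of 200 replicates (Fisher-z
        sampling spread)."""
        hits = 0
        for seed in range(200):
            cfg = _config(rng_seed=seed,
                          n_per_group={"control": 2, "patient": 24},
                          behavior_correlations=[
                              PlantedCorrelation("PANSS_N", "ai", -0.5)])
            imaging = self._ai(cfg, np.random.default_rng(seed + 1000))
            table = generate_behavior(cfg, imaging_measures=imaging)
            pat = table[table["group"] == "patient"]
            x = np.array([imaging["ai"][s] for s in pat["subject"]])
            r = np.corrcoef(x, pat["PANSS_N"])[0, 1]
            hits += -0.8 <= r <= -0.1
        assert hits / 200 >= 0.95

    def test_stroop_incongruent_exceeds_color_naming_in_expectation(self):
        cfg = _config(n_per_group={"control": 40, "patient": 40})
        table = generate_behavior(cfg, imaging_measures=self._ai(cfg))
        for group in ("control", "patient"):
            rows = table[table["group"] == group]
            assert rows["stroop_incongruent_time"].mean() > \
                rows["stroop_color_time"].mean()

    def test_panss_total_is_sum_of_subscales(self):
        cfg = _config()
        table = generate_behavior(cfg, imaging_measures=self._ai(cfg))
        pat = table[table["group"] == "patient"]
        assert np.array_equal(pat["PANSS_T"],
                              pat[["PANSS_P", "PANSS_N", "PANSS_G"]].sum(axis=1))

    def test_planted_stroop_missingness(self):
        cfg = _config()
        table = generate_behavior(cfg, imaging_measures=self._ai(cfg))
        for group in ("control", "patient"):
            rows = table[table["group"] == group]
            assert rows["stroop_interference"].isna().sum() == 1

    def test_missing_imaging_subject_rejected(self):
        cfg = _config()
        with pytest.raises(ValueError, match="lacks values"):
            generate_behavior(cfg, imaging_measures={"ai": {}})

    def test_deterministic(self):
        cfg = _config()
        imaging = self._ai(cfg)
        pd.testing.assert_frame_equal(
            generate_behavior(cfg, imaging_measures=imaging),
            generate_behavior(cfg, imaging_measures=imaging))


class TestSymmetricConstruction:
    def test_equal_couplings_produce_no_asymmetry_clusters(self):
        """When left and right couplings are equal, the corrected paired
        left-vs-flipped-right t-map is empty in almost every run."""
        from hemiconn.inference import correct_map, paired_tmap
        from hemiconn.pipeline import subject_zmaps
        from hemiconn.preprocess import CleaningSpec

        clean = 0
        n_rep = 15
        for seed in range(n_rep):
            sym = [CouplingSpec("striatum_left", "left",
                                {"control": 0.5, "patient": 0.5}),
                   CouplingSpec("striatum_right", "right",
                                {"control": 0.5, "patient": 0.5})]
            cfg = _config(couplings=sym, rng_seed=seed, n_timepoints=60,
                          n_per_group={"control": 10, "patient": 0})
            seeds, targets = default_rois(cfg)
            left, flipped = [], []
            spec = CleaningSpec(regress_global=False)
            for subj in iter_bold_subjects(cfg, seeds=seeds, targets=targets):
                maps = subject_zmaps(subj.bold, seeds, spec)
                left.append(maps["left"])
                flipped.append(maps["flipped_right"])
            paired = paired_tmap(left, flipped)
            _, table = correct_map(paired, 0.001, 10)
            clean += len(table) == 0
        assert clean >= n_rep - 1
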