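"""Generator contracts: geometry oracles, determinism, trajectory classes,
planted survival signal, and the on-disk round trip."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from desep.phantoms import (PhantomConfig, generate_cohort, generate_lesion,
                            load_cohort, simulate_survival, simulate_trajectory,
                            write_cohort)
from desep.recist_engine import (ResponseCategory, categorize_unidimensional,
                                 longest_axial_diameter, worst_category)


class TestConfig:
    def test_invariants(self):
        with pytest.raises(ValueError):
            PhantomConfig(n_patients=0)
        with pytest.raises(ValueError):
            PhantomConfig(trajectory_mix=(0.5, 0.5, 0.5))
        with pytest.raises(ValueError):
            PhantomConfig(baseline_hazard=0.0)
        with pytest.raises(ValueError, match="out of bounds"):
            PhantomConfig(grid_shape=(32, 32, 16), radius_range=(5, 20))

    def test_followup_schedule(self):
        cfg = PhantomConfig()
        assert cfg.followup_times_months == [2.0, 5.0, 8.0, 11.0]


class TestLesion:
    def test_sphere_voxel_count_matches_analytic_volume(self):
        cfg = PhantomConfig(radius_range=(10, 10), spiculation_strength=0.0,
                            seed=0)
        _, mask, _, _ = generate_lesion(cfg, np.random.default_rng(0),
                                        semi_axes=(10, 10, 10))
        analytic = 4 / 3 * np.pi * 10 ** 3
        assert abs(int(mask.sum()) - analytic) / analytic < 0.05

    def test_zero_spiculation_gives_exact_ellipsoid(self):
        cfg = PhantomConfig(spiculation_strength=0.0, seed=1)
        _, mask, raw, geom = generate_lesion(cfg, np.random.default_rng(1))
        shape = np.asarray(cfg.grid_shape)
        center = (shape - 1) / 2
        idx = np.indices(cfg.grid_shape)
        r = np.sqrt(sum(((idx[i] - center[i]) / geom.semi_axes[i]) ** 2
                        for i in range(3)))
        np.testing.assert_array_equal(mask.astype(bool), r <= 1)
        assert raw == 0.0   # no perturbation -> cohort minimum of the raw score

    def test_seed_determinism(self):
        cfg = PhantomConfig(seed=3)
        v1, m1, s1, _ = generate_lesion(cfg, np.random.default_rng(99))
        v2, m2, s2, _ = generate_lesion(cfg, np.random.default_rng(99))
        np.testing.assert_array_equal(v1, v2)
        np.testing.assert_array_equal(m1, m2)
        assert s1 == s2

    def test_oversized_lesion_rejected(self):
        cfg = PhantomConfig(seed=0)
        with pytest.raises(ValueError, match="out of bounds"):
            generate_lesion(cfg, np.random.default_rng(0),
                            semi_axes=(10, 10, 30))

    def test_lesion_density_brighter_than_background(self):
        cfg = PhantomConfig.desk(seed=2)
        vol, mask, _, _ = generate_lesion(cfg, np.random.default_rng(2))
        assert vol[mask.astype(bool)].mean() > 0.4
        assert abs(vol[~mask.astype(bool)].mean()) < 0.05


@pytest.fixture(scope="module")
def cohort():
    cfg = PhantomConfig(n_patients=24, seed=7)
    return generate_cohort(cfg), cfg


class TestTrajectories:

    def test_volume_conservation_every_scan(self, cohort):
        patients, cfg = cohort
        for p in patients:
            masks = [p.baseline_mask] + p.followup_masks
            for v, m in zip(p.true_volumes, masks):
                assert v == m.sum() * cfg.voxel_volume

    def test_stable_class_diameters_within_ten_percent(self, cohort):
        patients, _ = cohort
        stable = [p for p in patients if p.trajectory_class == "stable"]
        assert stable
        for p in stable:
            d0 = p.true_diameters[0]
            assert all(abs(d / d0 - 1) <= 0.10 for d in p.true_diameters[1:])

    def test_progressor_meets_pd_rule(self, cohort):
        patients, _ = cohort
        prog = [p for p in patients if p.trajectory_class == "progressor"]
        assert prog
        for p in prog:
            d = p.true_diameters
            nadir = d[0]
            rel = max(x / nadir - 1 for x in d[1:])
            absm = max(x - nadir for x in d[1:])
            assert rel >= 0.20 and absm >= 5.0
            cats = categorize_unidimensional(p.measurement_series())
            assert worst_category(cats) == ResponseCategory.PD
            assert p.progression_time_yr is not None

    def test_responder_monotone(self, cohort):
        patients, _ = cohort
        resp = [p for p in patients if p.trajectory_class == "responder"]
        assert resp
        for p in resp:
            d = p.true_diameters
            assert all(b <= a for a, b in zip(d, d[1:]))

    def test_fully_resolving_responder_records_zeros(self):
        # small desk lesions shrink past the renderable size -> CR
        cfg = PhantomConfig.desk(n_patients=16, seed=31)
        patients = generate_cohort(cfg)
        vanished = [p for p in patients if p.trajectory_class == "responder"
                    and p.true_diameters[-1] == 0]
        assert vanished
        for p in vanished:
            assert p.true_volumes[-1] == 0.0
            assert p.followup_masks[-1].sum() == 0
            cats = categorize_unidimensional(p.measurement_series())
            assert cats[-1] == ResponseCategory.CR

    def test_auto_vs_manual_consistency(self, cohort):
        """Categorizing diameters measured from the ground-truth masks agrees
        with categorizing the recorded true diameters."""
        patients, cfg = cohort
        for p in patients:
            series = p.measurement_series()
            mask_d = [longest_axial_diameter(m, cfg.voxel_spacing)
                      for m in [p.baseline_mask] + p.followup_masks]
            series_auto = p.measurement_series()
            series_auto.diameters_mm = mask_d
            a = categorize_unidimensional(series)
            b = categorize_unidimensional(series_auto)
            assert a == b, (p.patient_id, p.trajectory_class)


class TestSurvival:
    def test_exponential_mean_oracle(self):
        cfg = PhantomConfig(baseline_hazard=0.35, log_hr_morphology=0.0,
                            censoring_rate=1e-9, seed=0)
        rng = np.random.default_rng(0)
        recs = simulate_survival(np.zeros(2000), cfg, rng)
        t = np.array([r["os_time"] for r in recs])
        e = np.array([r["os_event"] for r in recs])
        assert e.mean() > 0.99
        assert t[e == 1].mean() == pytest.approx(1 / 0.35, rel=0.06)

    def test_dss_subset_of_os(self):
        cfg = PhantomConfig(seed=1)
        recs = simulate_survival(np.random.default_rng(1).standard_normal(500),
                                 cfg, np.random.default_rng(2))
        for r in recs:
            if r["dss_event"]:
                assert r["os_event"] == 1
                assert r["dss_time"] == r["os_time"]

    def test_two_year_label_logic(self):
        cfg = PhantomConfig(seed=2)
        recs = simulate_survival(np.zeros(500), cfg,
                                 np.random.default_rng(3))
        for r in recs:
            if r["os_event"] and r["os_time"] <= 2:
                assert r["two_year_os"] == 1
            elif r["os_time"] >= 2:
                assert r["two_year_os"] == 0
            else:
                assert r["two_year_os"] is None

    def test_lpfs_uses_progression_time(self):
        cfg = PhantomConfig(seed=3, censoring_rate=1e-9)
        rng = np.random.default_rng(4)
        recs = simulate_survival(np.zeros(50), cfg, rng,
                                 progression_times_yr=[0.25] * 50)
        for r in recs:
            assert r["lpfs_time"] <= 0.25 + 1e-12
            assert r["lpfs_event"] == 1

    def test_cox_recovers_positive_effect(self):
        """With beta=1.5 the high-score half has an estimated hazard ratio
        above 1 in nearly all replicates."""
        from desep.survival_stats import SurvivalRecord, cox_hr_binary
        cfg = PhantomConfig(seed=0, log_hr_morphology=1.5)
        wins = 0
        n_rep = 100
        for rep in range(n_rep):
            rng = np.random.default_rng(1000 + rep)
            z = rng.standard_normal(200)
            z = (z - z.mean()) / z.std()
            recs = simulate_survival(z, cfg, rng)
            hi = (z > np.median(z)).astype(float)
            sr = [SurvivalRecord(r["os_time"], r["os_event"], g)
                  for r, g in zip(recs, hi)]
            if cox_hr_binary(sr).hr > 1:
                wins += 1
        assert wins >= 0.95 * n_rep

    def test_null_signal_uncorrelated(self):
        cfg = PhantomConfig.desk(n_patients=60, seed=9, log_hr_morphology=0.0)
        patients = generate_cohort(cfg, with_followups=False)
        z = [p.morphology_score for p in patients]
        t = [p.os_time for p in patients]
        e = [p.os_event for p in patients]
        rho = spearmanr([zi for zi, ei in zip(z, e) if ei],
                        [ti for ti, ei in zip(t, e) if ei]).statistic
        assert abs(rho) < 0.35


class TestCohort:
    def test_signal_planting_negative_rank_correlation(self, small_cohort):
        patients, _ = small_cohort
        z = [p.morphology_score for p in patients]
        unc = [(zi, p.os_time) for zi, p in zip(z, patients) if p.os_event]
        rho = spearmanr([a for a, _ in unc], [b for _, b in unc]).statistic
        assert rho < -0.2

    def test_morphology_scores_standardized(self, small_cohort):
        patients, _ = small_cohort
        z = np.array([p.morphology_score for p in patients])
        assert z.mean() == pytest.approx(0.0, abs=1e-9)
        assert z.std() == pytest.approx(1.0, abs=1e-9)

    def test_cohort_determinism_and_counter_based_streams(self):
        cfg = PhantomConfig.desk(n_patients=6, seed=21)
        c1 = generate_cohort(cfg)
        c2 = generate_cohort(cfg)
        for a, b in zip(c1, c2):
            np.testing.assert_array_equal(a.baseline_volume, b.baseline_volume)
            assert a.os_time == b.os_time and a.true_diameters == b.true_diameters
        # patient i does not depend on cohort size (counter-derived streams)
        c3 = generate_cohort(PhantomConfig.desk(n_patients=3, seed=21))
        np.testing.assert_array_equal(c1[2].baseline_mask, c3[2].baseline_mask)

    def test_write_load_roundtrip(self, tmp_path):
        cfg = PhantomConfig.desk(n_patients=3, seed=13)
        patients = generate_cohort(cfg)
        out = write_cohort(patients, cfg, tmp_path / "cohort")
        loaded, df = load_cohort(out)
        assert len(loaded) == 3
        assert set(df.columns) >= {
            "patient_id", "scan_time_months", "diameter_mm", "volume_mm3",
            "os_time_yr", "os_event", "dss_time_yr", "dss_event",
            "lpfs_time_yr", "lpfs_event", "two_year_os", "two_year_dss",
            "two_year_lpfs"}
        for p, q in zip(patients, loaded):
            np.testing.assert_allclose(p.baseline_volume, q.baseline_volume,
                                       atol=1e-6)
            np.testing.assert_array_equal(p.baseline_mask, q.baseline_mask)
            assert q.os_time == pytest.approx(p.os_time)
            assert q.two_year_os == p.two_year_os
            np.testing.assert_allclose(q.true_diameters, p.true_diameters)

    def test_nifti_affine_carries_spacing(self, tmp_path):
        import nibabel as nib
        cfg = PhantomConfig.desk(n_patients=1, seed=14,
                                 voxel_spacing=(1.0, 1.0, 2.0),
                                 grid_shape=(32, 32, 16),
                                 radius_range=(2.5, 4.0))
        patients = generate_cohort(cfg)
        out = write_cohort(patients, cfg, tmp_path / "c")
        img = nib.load(out / "images" / "P0000_scan00_ct.nii.gz")
        assert tuple(img.header.get_zooms()) == (1.0, 1.0, 2.0)
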