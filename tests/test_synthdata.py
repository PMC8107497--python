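import numpy as np
import pytest

from nflreflect import azfilter, grid as gm, maps, metrics, pipeline, stats as st
from nflreflect import synthdata as sd


class TestTemplate:
    def test_linear_annulus_mean_is_unity(self):
        cfg = sd.SimulationConfig()
        tt = np.linspace(0, 2 * np.pi, 4096, endpoint=False)
        t = sd.angular_template(cfg, tt)
        assert np.mean(10 ** (t / 10)) == pytest.approx(1.0, abs=1e-6)

    def test_double_hump_peaks(self):
        cfg = sd.SimulationConfig()
        t_it = sd.angular_template(cfg, gm.THETA_IT)
        t_st = sd.angular_template(cfg, gm.THETA_ST)
        t_nasal = sd.angular_template(cfg, np.pi)
        assert t_it > t_nasal + 2 and t_st > t_nasal + 2


class TestNoiseFreePipelineIdentity:
    def test_template_recovered_exactly(self):
        """With zero noise, zero bias and no vessels, the processed map
        equals the angular template after normalization."""
        cfg = sd.SimulationConfig(grid_n=128, population_sd_db=0.0,
                                  bias_amplitude_db=0.0, pixel_noise_sd_db=0.0,
                                  n_vessels=0)
        rng = np.random.default_rng(0)
        nfl, ppec = sd.make_normal_map(cfg, 50.0, 23.6, rng)
        ratio = pipeline.ratio_pipeline(nfl, ppec)
        const = maps.annulus_mean(ratio)
        refl = maps.normalize_to_db(ratio, const)
        r = refl.radius()
        ann = (r >= 1.1) & (r <= 2.0)
        x, y = maps.pixel_grid_mm(refl.shape, refl.pixel_size_mm)
        expected = sd.angular_template(cfg, np.arctan2(y, x))
        # the only discrepancy is the pixelated annulus-mean estimate
        assert np.nanmax(np.abs(refl.values_db[ann] - expected[ann])) < 0.02


class TestDefects:
    cfg = sd.SimulationConfig(grid_n=128, population_sd_db=0.0,
                              bias_amplitude_db=0.0, pixel_noise_sd_db=0.0,
                              n_vessels=0, trajectory_bend=0.0)

    def _noise_free_eye(self, defects):
        return sd.EyeTruth(eye_id="e", group="PG", age=50.0, axial_length=23.6,
                           gender="female", vf_md=0.0, noise_coeffs=np.zeros((1, 720)),
                           bias_amp=0.0, bias_phase=0.0, defects=defects)

    def test_zero_depth_is_identity(self):
        rng = np.random.default_rng(1)
        nfl, _ = sd.make_normal_map(self.cfg, 50.0, 23.6, rng)
        out, gt = sd.inject_defect(nfl, sd.DefectSpec(1.0, 0.5, 0.0), config=self.cfg)
        assert np.allclose(out.values, nfl.values)

    def test_wedge_defect_classified_as_wedge(self):
        cfg = self.cfg
        grid = pipeline.build_default_grid((128, 128), cfg.pixel_size_mm, bend=0.0)
        rng = np.random.default_rng(2)
        nfl, ppec = sd.make_normal_map(cfg, 50.0, 23.6, rng)
        wedge = sd.DefectSpec(np.deg2rad(60), 3 * 2 * np.pi / 32, 6.0)
        nfl2, gt = sd.inject_defect(nfl, wedge, grid=grid, config=cfg)
        assert gt.sum() >= 10  # roughly 3 tracks x 5 segments
        assert metrics.classify_pattern(gt) == "wedge"

    def test_diffuse_defect_classified_as_diffuse(self):
        cfg = self.cfg
        grid = pipeline.build_default_grid((128, 128), cfg.pixel_size_mm, bend=0.0)
        rng = np.random.default_rng(3)
        nfl, _ = sd.make_normal_map(cfg, 50.0, 23.6, rng)
        spec = sd.DefectSpec(1.0, 12 * 2 * np.pi / 32, 6.0, kind="diffuse")
        _, gt = sd.inject_defect(nfl, spec, grid=grid, config=cfg)
        assert metrics.classify_pattern(gt) == "diffuse"


class TestRepeatScans:
    def test_zero_noise_fixed_bias_identical(self):
        cfg = sd.SimulationConfig(grid_n=96, population_sd_db=0.0,
                                  bias_amplitude_db=0.0, pixel_noise_sd_db=0.0,
                                  repeat_noise_sd_db=0.0, bias_jitter_db=0.0,
                                  n_vessels=0)
        truth = sd.EyeTruth("e", "normal", 55.0, 24.0, "male", 0.0,
                            np.zeros((1, 720)), 1.0, 0.7)
        rng = np.random.default_rng(4)
        scans = sd.make_repeat_scans(cfg, truth, 2, rng)
        assert np.allclose(scans[0][0].values, scans[1][0].values)

    def test_pooled_sd_scales_with_noise(self):
        grid128 = pipeline.build_default_grid((128, 128), 4.5 / 128)

        def run(noise_sd, seed):
            cfg = sd.SimulationConfig(grid_n=128, population_sd_db=0.0,
                                      bias_amplitude_db=0.0, bias_jitter_db=0.0,
                                      pixel_noise_sd_db=0.0, n_vessels=0,
                                      repeat_noise_sd_db=noise_sd)
            rng = np.random.default_rng(seed)
            reps = []
            for i in range(6):
                truth = sd.EyeTruth(f"e{i}", "normal", 55.0, 24.0, "f", 0.0,
                                    np.zeros((1, 720)), 0.0, 0.0)
                vecs = []
                for nfl, ppec in sd.make_repeat_scans(cfg, truth, 2, rng):
                    ratio = pipeline.ratio_pipeline(nfl, ppec)
                    refl = maps.normalize_to_db(ratio, 0.8)
                    vecs.append(gm.aggregate(refl, grid128))
                reps.append(np.array(vecs))
            return st.pooled_sd(reps)

        s1 = run(0.4, 5)
        s2 = run(0.8, 5)
        assert s2 / s1 == pytest.approx(2.0, rel=0.15)

    def test_filtering_reduces_pooled_sd(self):
        cfg = sd.SimulationConfig(grid_n=128, seed=6)
        grid128 = pipeline.build_default_grid((128, 128), cfg.pixel_size_mm,
                                              bend=cfg.trajectory_bend)
        rng = np.random.default_rng(6)
        before, after = [], []
        for i in range(8):
            truth = sd.make_eye(cfg, "normal", rng, f"e{i}")
            vu, vf = [], []
            for nfl, ppec in sd.make_repeat_scans(cfg, truth, 2, rng):
                ratio = pipeline.ratio_pipeline(nfl, ppec)
                refl = maps.normalize_to_db(ratio, cfg.ratio_scale)
                vu.append(gm.aggregate(refl, grid128))
                vf.append(gm.aggregate(azfilter.azimuthal_filter(refl), grid128))
            before.append(np.array(vu))
            after.append(np.array(vf))
        assert st.pooled_sd(after) < st.pooled_sd(before)


class TestCohort:
    def test_seed_reproducibility_bit_exact(self):
        cfg = sd.SimulationConfig(seed=8, n_normal=3, n_ppg=1, n_pg=1, grid_n=96)
        e1 = sd.make_cohort(cfg)
        e2 = sd.make_cohort(cfg)
        for a, b in zip(e1, e2):
            assert a.age == b.age and a.bias_amp == b.bias_amp
            assert np.array_equal(a.noise_coeffs, b.noise_coeffs)

    def test_population_sd_near_configured(self):
        """Per-superpixel population SD of processed filtered normals is
        within 15% of the configured intrinsic SD (covariate effects
        disabled to isolate the noise model)."""
        cfg = sd.SimulationConfig(seed=9, n_normal=30, n_ppg=0, n_pg=0, grid_n=128,
                                  beta_age=0.0, beta_axl=0.0)
        eyes = sd.make_cohort(cfg)
        cohort, _ = pipeline.process_cohort(eyes, cfg)
        sds = np.nanstd(cohort.vectors, axis=0, ddof=1)
        assert np.mean(sds) == pytest.approx(cfg.population_sd_db, rel=0.15)

    def test_every_pattern_branch_attainable(self):
        """Config-level defect specs can produce all five pattern labels."""
        cfg = sd.SimulationConfig(grid_n=128, population_sd_db=0, bias_amplitude_db=0,
                                  pixel_noise_sd_db=0, n_vessels=0, trajectory_bend=0.0)
        grid = pipeline.build_default_grid((128, 128), cfg.pixel_size_mm, bend=0.0)
        rng = np.random.default_rng(10)
        nfl, _ = sd.make_normal_map(cfg, 50.0, 23.6, rng)
        # align the small defects with track/segment boundaries so the
        # >=50% coverage rule marks whole superpixels
        b = np.concatenate([grid.boundaries, [grid.boundaries[0] + 2 * np.pi]])
        c10 = 0.5 * (b[10] + b[11])
        tw = 2 * np.pi / 32
        cases = {
            "none": None,
            "wedge": sd.DefectSpec(0.5, 3 * tw, 6.0),
            "diffuse": sd.DefectSpec(0.5, 12 * tw, 6.0, kind="diffuse"),
            "other_grouping": sd.DefectSpec(c10, b[11] - b[10], 6.0,
                                            r_min_mm=1.28, r_max_mm=1.82),
            "isolated": sd.DefectSpec(c10, b[11] - b[10], 6.0,
                                      r_min_mm=1.28, r_max_mm=1.46),
        }
        for expected, spec in cases.items():
            if spec is None:
                gt = np.zeros(160, dtype=bool)
            else:
                _, gt = sd.inject_defect(nfl, spec, grid=grid, config=cfg)
            assert metrics.classify_pattern(gt) == expected, expected

    def test_focal_loss_tracks_defect_burden(self):
        cfg = sd.SimulationConfig(seed=12, n_normal=14, n_ppg=6, n_pg=8, grid_n=128)
        eyes = sd.make_cohort(cfg)
        cohort, gt = pipeline.process_cohort(eyes, cfg)
        ev = pipeline.evaluate_cohort(cohort, fit_method="ols")
        r = np.corrcoef(ev["results"].focal_loss, -gt.defect_burden_db)[0, 1]
        assert r > 0.9
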