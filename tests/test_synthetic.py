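import numpy as np
import pytest

from rpe_granulyzer.stack_io import ConfigError
from rpe_granulyzer.synthetic import (
    DEFAULT_TREND_TABLE,
    MorphologyParams,
    SceneConfig,
    generate_mosaic,
    plant_granules,
    render,
    simulate_scene,
    trend_group_of,
)


class TestConfigValidation:
    def test_bad_mix_rejected(self):
        with pytest.raises(ConfigError):
            SceneConfig(phenotype_mix={"L1": 0.5, "M1": 0.4})

    def test_bad_nuclei_probs_rejected(self):
        with pytest.raises(ConfigError):
            SceneConfig(nuclei_probs=(0.5, 0.4, 0.2, 0.1))

    def test_too_small_frame_rejected(self):
        with pytest.raises(ConfigError):
            SceneConfig(n_cells=100, image_size=(64, 64))


class TestMosaic:
    def test_single_cell_covers_frame(self):
        cfg = SceneConfig(n_cells=1, image_size=(64, 64), granule_rate_per_cell=0.0)
        rois, truth = generate_mosaic(cfg)
        assert len(rois) == 1
        assert rois[0].area_px2 == pytest.approx(64 * 64)

    def test_determinism(self):
        cfg = SceneConfig(n_cells=50, seed=7)
        rois_a, _ = generate_mosaic(cfg)
        rois_b, _ = generate_mosaic(cfg)
        assert [r.polygon for r in rois_a] == [r.polygon for r in rois_b]

    def test_side_count_targets_are_met(self):
        # high-dose day-1 morphology: mean target side count 8.5
        cfg = SceneConfig(
            n_cells=200,
            image_size=(1024, 1024),
            dose="HIGH_60",
            day=1,
            seed=5,
            granule_rate_per_cell=0.0,
        )
        assert cfg.resolved_morphology().mean_sides == 8.5
        _, truth = generate_mosaic(cfg)
        mean_sides = np.mean([c.side_count for c in truth.cells])
        assert abs(mean_sides - 8.5) <= 0.5

    def test_cells_do_not_overlap(self):
        from shapely.geometry import Polygon

        cfg = SceneConfig(n_cells=30, seed=3, granule_rate_per_cell=0.0)
        rois, _ = generate_mosaic(cfg)
        polys = [Polygon(r.polygon) for r in rois]
        for i in range(len(polys)):
            for j in range(i + 1, len(polys)):
                inter = polys[i].intersection(polys[j]).area
                assert inter < 1e-6


class TestPlanting:
    def test_zero_rate_plants_nothing(self):
        cfg = SceneConfig(n_cells=5, granule_rate_per_cell=0.0, seed=1)
        rois, truth = generate_mosaic(cfg)
        truth = plant_granules(cfg, rois, truth)
        assert truth.granules == []

    def test_melanin_rises_with_low_dose_time(self):
        # the configured day-30 melanin multiplier exceeds day 1: planted
        # counts must reflect it over 200 cells
        means = {}
        for day in (1, 30):
            cfg = SceneConfig(
                n_cells=200, image_size=(1024, 1024), dose="LOW_40", day=day, seed=9
            )
            rois, truth = generate_mosaic(cfg)
            truth = plant_granules(cfg, rois, truth)
            n_mel = sum(1 for g in truth.granules if trend_group_of(g.phenotype) == "melanin")
            means[day] = n_mel / len(rois)
        assert DEFAULT_TREND_TABLE[("LOW_40", 30)][0] > DEFAULT_TREND_TABLE[("LOW_40", 1)][0]
        assert means[30] > means[1]

    def test_delta_mix_on_m2_gives_spindles(self):
        cfg = SceneConfig(
            n_cells=20,
            phenotype_mix={"L1": 0, "L2": 0, "ML1": 0, "ML2": 0, "M1": 0, "M2": 1.0},
            seed=2,
        )
        rois, truth = generate_mosaic(cfg)
        truth = plant_granules(cfg, rois, truth)
        assert len(truth.granules) > 50
        assert all(g.phenotype == "M2" for g in truth.granules)
        assert all(g.aspect_ratio >= 2.0 for g in truth.granules)

    def test_granules_inside_their_cell_and_zone_consistent(self):
        from shapely.geometry import Point, Polygon

        from rpe_granulyzer.zonal import zone_of

        cfg = SceneConfig(n_cells=30, seed=4)
        rois, truth = generate_mosaic(cfg)
        truth = plant_granules(cfg, rois, truth)
        polys = {r.cell_id: Polygon(r.polygon) for r in rois}
        by_id = {r.cell_id: r for r in rois}
        for g in truth.granules:
            assert polys[g.cell_id].buffer(1e-9).contains(Point(g.x, g.y))
            roi = by_id[g.cell_id]
            assert roi.z_top <= g.z <= roi.z_bottom
            assert g.zone == zone_of(g.z, roi.z_top, roi.z_bottom)

    def test_zonal_priors_respected(self):
        cfg = SceneConfig(n_cells=100, image_size=(724, 724), seed=6)
        rois, truth = generate_mosaic(cfg)
        truth = plant_granules(cfg, rois, truth)
        mel = [g.zone for g in truth.granules if g.family != "LIPOFUSCIN"]
        lip = [g.zone for g in truth.granules if g.family == "LIPOFUSCIN"]
        assert np.mean([z in ("C1", "C2") for z in mel]) >= 0.9
        assert np.mean([z == "C3" for z in lip]) >= 0.9

    def test_trend_table_recoverable_from_truth(self):
        """Configured multipliers are recovered by Poisson MLE within 10%."""
        base = {}
        for day in (1, 7, 30):
            cfg = SceneConfig(
                n_cells=200, image_size=(1024, 1024), dose="LOW_40", day=day, seed=13
            )
            rois, truth = generate_mosaic(cfg)
            truth = plant_granules(cfg, rois, truth)
            n_lip = sum(1 for g in truth.granules if g.family == "LIPOFUSCIN")
            base[day] = n_lip / len(rois)  # Poisson MLE of the day rate
        for day in (7, 30):
            expected = DEFAULT_TREND_TABLE[("LOW_40", day)][1]
            assert base[day] / base[1] == pytest.approx(expected, rel=0.10)


class TestRender:
    def test_empty_truth_is_flat_background(self):
        cfg = SceneConfig(n_cells=5, granule_rate_per_cell=0.0, seed=1)
        rois, truth = generate_mosaic(cfg)
        stack = render(cfg, truth)
        af = stack.channel("AF488").astype(float)
        apical = af[: cfg.n_slices // 2]  # basal slices carry faint texture
        tol = 3 * cfg.noise_sd / np.sqrt(apical.size)
        assert abs(apical.mean() - cfg.af_background) < max(tol, 0.5)

    def test_single_l1_granule_is_bright_in_af(self):
        from rpe_granulyzer.synthetic import GranuleTruth, SceneTruth

        cfg = SceneConfig(n_cells=1, image_size=(64, 64), seed=0)
        truth = SceneTruth(config=cfg)
        truth.granules.append(
            GranuleTruth("c000", "L1", x=32, y=32, z=6, r_major=2.5, r_minor=2.5,
                         orientation_deg=0.0, zone="C3")
        )
        stack = render(cfg, truth)
        af = stack.channel("AF488").astype(float)
        inside = af[6, 30:35, 30:35].mean()
        assert inside > cfg.af_background + 5 * cfg.noise_sd

    def test_single_m1_granule_dark_in_trans_flat_in_af(self):
        from rpe_granulyzer.synthetic import GranuleTruth, SceneTruth

        cfg = SceneConfig(n_cells=1, image_size=(64, 64), seed=0)
        truth = SceneTruth(config=cfg)
        truth.granules.append(
            GranuleTruth("c000", "M1", x=32, y=32, z=3, r_major=2.5, r_minor=2.5,
                         orientation_deg=0.0, zone="C1")
        )
        stack = render(cfg, truth)
        tr = stack.channel("TRANS").astype(float)
        af = stack.channel("AF488").astype(float)
        assert tr[3, 30:35, 30:35].mean() < cfg.trans_background - 5 * cfg.noise_sd
        assert abs(af[3, 30:35, 30:35].mean() - cfg.af_background) < 2 * cfg.noise_sd


def test_scene_determinism_is_byte_identical():
    cfg = SceneConfig(n_cells=10, image_size=(160, 160), granule_rate_per_cell=8.0, seed=21)
    s1, r1, t1 = simulate_scene(cfg)
    s2, r2, t2 = simulate_scene(cfg)
    np.testing.assert_array_equal(s1.voxels, s2.voxels)
    assert [r.polygon for r in r1] == [r.polygon for r in r2]
    assert t1.granule_frame().equals(t2.granule_frame())
    assert s1.voxels.tobytes() == s2.voxels.tobytes()
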