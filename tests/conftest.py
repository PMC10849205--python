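import logging

import pytest

from rpe_granulyzer import SceneConfig, analyze_scene, match_to_truth, simulate_scene

logging.disable(logging.WARNING)


@pytest.fixture(scope="session")
def default_scene():
    """The reference 50-cell scene: 20 granules/cell mean, seed 7."""
    cfg = SceneConfig(n_cells=50, granule_rate_per_cell=20.0, seed=7)
    stack, rois, truth = simulate_scene(cfg)
    return cfg, stack, rois, truth


@pytest.fixture(scope="session")
def default_analysis(default_scene):
    cfg, stack, rois, truth = default_scene
    analysis = analyze_scene(stack, rois)
    match = match_to_truth(analysis.granules, truth)
    return analysis, match


@pytest.fixture(scope="session")
def large_scene():
    """A larger cohort spanning all six phenotypes, >= 1000 planted granules."""
    cfg = SceneConfig(n_cells=60, granule_rate_per_cell=20.0, seed=11)
    stack, rois, truth = simulate_scene(cfg)
    analysis = analyze_scene(stack, rois)
    match = match_to_truth(analysis.granules, truth)
    return cfg, truth, analysis, match


@pytest.fixture()
def tiny_scene():
    """A fast 6-cell scene for I/O and CLI tests."""
    cfg = SceneConfig(
        n_cells=6, image_size=(128, 128), granule_rate_per_cell=6.0, seed=3
    )
    return (cfg, *simulate_scene(cfg))
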