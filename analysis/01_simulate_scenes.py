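"""Generate the reference synthetic flat-mount scenes used by the analyses.

Writes, under results/scenes/: the reference 50-cell scene (TIFF + metadata
sidecar + ROI JSON + ground-truth CSVs) and a small gallery scene per
(dose, day) condition, so later steps can be rerun without touching the
generator.
"""

from pathlib import Path

from rpe_granulyzer import SceneConfig, simulate_scene, write_rois, write_zstack

OUT = Path(__file__).resolve().parent.parent / "results" / "scenes"


def dump(cfg: SceneConfig, name: str) -> None:
    stack, rois, truth = simulate_scene(cfg)
    d = OUT / name
    d.mkdir(parents=True, exist_ok=True)
    write_zstack(stack, d / "scene.tif")
    write_rois(rois, d / "rois.json")
    truth.granule_frame().to_csv(d / "truth_granules.csv", index=False)
    truth.cell_frame().to_csv(d / "truth_cells.csv", index=False)
    print(
        f"{name}: {len(rois)} cells, {len(truth.granules)} granules "
        f"({cfg.dose}, day {cfg.day}, seed {cfg.seed})"
    )


def main() -> None:
    dump(SceneConfig(n_cells=50, granule_rate_per_cell=20.0, seed=7), "reference")
    for dose in ("LOW_40", "HIGH_60"):
        for day in (1, 7, 30):
            cfg = SceneConfig(
                n_cells=20, image_size=(320, 320), granule_rate_per_cell=12.0,
                dose=dose, day=day, seed=101,
            )
            dump(cfg, f"{dose.lower()}_day{day:02d}")


if __name__ == "__main__":
    main()
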