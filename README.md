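# rpe-granulyzer

Quantification of cytoplasmic granules in retinal pigment epithelium (RPE)
flat mounts from multi-channel fluorescence z-stacks — for vision scientists
studying oxidative RPE injury (e.g. the sodium-iodate AMD model) who need
per-cell granule counts, phenotypes, zonal distributions and
autofluorescence totals instead of manual ImageJ point-and-click.

## What it computes

Given a z-stack with a 488 nm-excitation autofluorescence channel (`AF488`,
lipofuscin bright), a transmitted-light channel (`TRANS`, melanin dark) and
manually drawn cell-boundary polygons, the pipeline:

* detects granules per cell (per-cell Otsu thresholds on both channels,
  3-D connected components, watershed separation of touching granules) and
  measures each one: cross-section area *A*, Crofton perimeter *P*,
  circularity 4π*A*/*P*², ellipse aspect ratio, mean intensities, and a
  bull's-eye ring score;
* classifies each granule into the six phenotypes of injured rat RPE —
  lipofuscin **L1** (monolithic) / **L2** (irregular aggregate),
  melanolipofuscin **ML1** (large round) / **ML2** (bull's-eye),
  melanosome **M1** (round) / **M2** (spindle) — via an auditable
  first-match decision list, and rolls them up into the
  melanin : lipofuscin family ratio;
* assigns granules to four equal apical-basal zones C1–C4 (melanin lives
  apically in C1–C2, lipofuscin in the middle C3);
* quantifies AF: green-channel histogram, plot profile, and per-cell total
  AF = Σ AF488 over every voxel from apex to base (raw and
  background-subtracted);
* summarises per cell in the classic particle-analysis columns
  (Count, Total area, Average size = Total area / Count, % Area, Mean),
  counts nuclei (≥ 3 = multinucleated giant cell), scores cell morphology
  (unusual 7+-sided polygons, swollen cells), and labels granule-rich/poor
  cells;
* tests dose × time group effects with repeated-measures one-way ANOVA +
  Tukey (RM error term) and paired two-tailed t-tests, with Prism-style
  significance codes.

Because no raw images of this kind are publicly deposited, the package
includes a first-class synthetic scene generator
(`rpe_granulyzer.synthetic`) that plants ground-truthed granules with the
dose × time trend structure of sodium-iodate injury (low dose: melanin and
lipofuscin rise day 1 → 30; high dose: melanin falls, lipofuscin and AF peak
at day 7, multinucleated giant cells peak at day 7). Every quantitative
claim in the test suite is scored against that ground truth. See
`docs/methods.md` for the model and all numeric conventions.

## Worked example

```python
from rpe_granulyzer import SceneConfig, simulate_scene, analyze_scene, match_to_truth

cfg = SceneConfig(n_cells=50, granule_rate_per_cell=20.0, seed=7)
stack, rois, truth = simulate_scene(cfg)        # 512x512x12, 3 channels
analysis = analyze_scene(stack, rois)           # detect + classify + zones + AF
m = match_to_truth(analysis.granules, truth)
print(f"recall={m.recall:.3f} precision={m.precision:.3f}")
print(analysis.summary_frame()[["cell_id", "Count", "Total area",
                                "Average size", "% Area", "Mean"]].head(3))
```

prints

```
recall=0.909 precision=0.953
  cell_id  Count  Total area  Average size     % Area       Mean
0    c000     18       532.0     29.555556  10.953859  98.536000
1    c001     19       540.0     28.421053  11.094702  89.480952
2    c002     22       540.0     24.545455  12.337375  80.095990
```

Reading: on the reference synthetic flat mount, 90.9 % of the planted
granules are recovered and 95.3 % of detections are real; cell `c000`
carries 18 granules covering 11.0 % of its surface with a mean granule AF of
98.5 grey levels. Per-phenotype classification accuracy on this scene is
≥ 0.94 for all six phenotypes (`analysis.granule_frame()` holds the labels
and the rule that fired for each).

The same pipeline runs from the shell:

```sh
rpe-granulyzer simulate --config sim.yaml --out scene/
rpe-granulyzer run --stack scene/scene.tif --rois scene/rois.json --out out/
```

## The analysis scripts

The numbered drivers under `analysis/` rebuild the study end to end and
write their tables under `results/` (regenerated, never committed):

1. `01_simulate_scenes.py` — reference + per-condition synthetic scenes;
2. `02_detect_and_classify.py` — granule table, per-cell summary table,
   detection/classification scoreboard;
3. `03_zonal_af_analysis.py` — C1–C4 zone tables, green histogram, plot
   profile, per-cell total AF;
4. `04_dose_time_trends.py` — the full 2 doses × 3 days × 200 cells ×
   5 seeds experiment, trend tests and the per-dose AF t-test table
   (~7 min single-core; `--quick` for a smoke run).

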