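# Methods

This note records how the pipeline works, what its synthetic data does and
does not emulate, and the numerical choices a maintainer would want to know.

## Problem setting

Sodium-iodate (SI) injury of the retinal pigment epithelium (RPE) is a
standard animal model of AMD-like degeneration. The readout this package
reimplements is cytoplasmic-granule analysis of RPE flat mounts imaged as
multi-channel fluorescence z-stacks: granules are detected per cell,
assigned one of six phenotypes — lipofuscin L1 (monolithic disc) and L2
(irregular aggregate), melanolipofuscin ML1 (large round) and ML2
(bull's-eye: bright ring, dark melanin core), melanosome M1 (round) and M2
(spindle) — rolled up into melanin / melanolipofuscin / lipofuscin families,
localised along the apical–basal axis into four equal-thickness zones C1–C4,
and summarised per cell in the classic particle-analysis columns (Count,
Total area, Average size, % Area, Mean). Group statistics compare doses
(40 vs 60 mg/kg) and times (day 1, 7, 30 after injection).

The raw images behind the published tables are not deposited anywhere, so
all quantitative testing runs against a ground-truthed synthetic scene
generator; the published table rows themselves are used only for a
printed-precision self-consistency audit (below).

## Conventions

* Voxels are indexed `(z, y, x, channel)`; slice 0 is apical (the flat mount
  is imaged microvilli-first). TIFF pages are z-major, channel-minor.
* Coordinates are pixel-centre, 0-based, x = column. A pixel belongs to a
  cell if its centre is inside or on the cell polygon (shapely `covers`
  semantics). Boundary-tied granule centroids go to the lexicographically
  first cell id.
* Physical quantities are in µm / µm²; tables also report raw px² because
  the published tables print unitless areas.
* Zones: the cell's inclusive slice extent `[z_top, z_bottom]` is split into
  four equal-thickness intervals; a slice index is the apical edge of its
  interval, so a slice straddling a fractional boundary lands in the more
  apical zone. Boundary fractions are configurable (default quartiles).

## Synthetic scene generator

The generator emulates the *statistical structure* the analysis relies on,
not optics. Defaults (all configurable in `SceneConfig`):

* Frame 512×512 px at 0.2 µm/px, 12 slices at 0.5 µm, 8-bit; granules of
  0.7–1.8 µm diameter then span 2–9 px, matching the small published
  "Average size" values relative to counts.
* Mosaic: Voronoi tessellation of Poisson-disk-sampled seeds, mirrored at
  the frame edges so cells tile the frame. Per-cell side-count targets are
  drawn from a normal distribution (mean 5.9, sd 0.7 normally; day-1
  conditions shift to 7.0/8.5 to emulate injury-related "unusual polygon"
  shapes) and met by least-area vertex removal or inward edge splitting —
  both shrink convex cells, so the mosaic stays overlap-free. A swollen-cell
  fraction is produced by letting designated seeds absorb their nearest
  neighbour before tessellation (~2× area).
* Granules: per cell and phenotype, counts are Poisson with mean
  `rate × mix[phenotype] × trend multiplier`. The trend table encodes the
  qualitative injury findings as multipliers (low dose: melanin 1.0/1.3/1.8
  and lipofuscin 1.0/1.5/2.2 for days 1/7/30; high dose: melanin
  1.0/0.7/0.4, lipofuscin 1.0/1.4/0.6, i.e. a day-7 lipofuscin peak). These
  are fixtures, not measured values. z placement is normal around the home
  zone (melanin family centred in C1–C2, sd 1.3 slices; lipofuscin centred
  in C3, sd 0.7), clipped to the cell extent. Placement rejects
  interpenetration (granules are solid organelles): a candidate must clear
  existing granules by the sum of their extents in xy or 3 slices in z.
* Rendering: two imaging channels plus nuclei. AF488 — lipofuscin families
  bright (peak 180 on background 30), ML1 intermediate (+55), the ML2 ring
  at +100 with a core at background; melanin is *not* excited at 488 nm.
  TRANS — melanin-containing material dark (−80 on background 120),
  lipofuscin neutral. NUC — nuclei as bright basal discs. Granules are
  sigmoid-edged solids (edge width 0.35 px) with a Gaussian z profile
  (σ = 0.8 slices, ~3 slices). Additive Gaussian noise (sd 8), clipped to
  8 bits. Mitochondria appear only as sub-noise basal texture, not as
  countable particles.
* The AF amplitude budget is deliberately lipofuscin-dominated (the ML2 ring
  is dimmer and smaller than pure lipofuscin): 488 nm autofluorescence is
  primarily a lipofuscin signal, and the generator's total-AF trend must
  follow the lipofuscin-family multiplier for the downstream trend analysis
  to be a meaningful recovery test.
* Nuclei counts are drawn from (0.55, 0.43, 0.015, 0.005) over 1–4 nuclei;
  the high-dose day-7 condition overrides to (0.35, 0.45, 0.13, 0.07) to
  embed the multinucleated-giant-cell excess.
* Determinism: everything derives from `SceneConfig.seed` through fixed
  `SeedSequence` children; identical configs give byte-identical stacks.
  `mosaic_seed` lets several days share one mosaic so cells can act as
  repeated-measures subjects.

What the generator does **not** emulate: PSF blur and optical sectioning
cross-talk, photobleaching, spectral overlap, shading/vignetting, real
granule texture, cell-boundary drawing error. Passing tests therefore show
the algorithms are correct under the declared statistical model, not that
they are robust to every microscope artefact.

## Detection

Per cell: the AF488 and TRANS crops are lightly smoothed (σ = 0.7 px);
bright candidates are AF voxels above a per-cell Otsu threshold and dark
candidates are TRANS voxels below the mirrored Otsu threshold, each clamped
so it can never fall below background + 2 MAD (a granule-free cell must not
push the threshold into the noise floor). The union is labelled in 3-D
(26-connectivity; a per-slice 2-D mode exists behind `mode="2d"`). Touching
granules are separated by marker-controlled watershed on the pooled contrast
response `max(AF z-score, −TRANS z-score)`, and watershed fragments whose
separating valley exceeds half the weaker peak are re-merged — that keeps a
multi-lobed L2 aggregate one granule while splitting abutting distinct
granules. Components are filtered by maximal-cross-section area
(3 px² ≤ A ≤ 5 % of the cell) and by a peak-contrast floor of 3 raw noise
sd. Each surviving granule is measured on its half-max-refined mask
(thresholding alone dilates footprints by ~1 px, which biases shape
features): maximal cross-section area and Crofton (4-direction) perimeter →
circularity (capped at 1; the estimator reads ~0.88 for an ideal r = 5 px
digital disc — the classification cut-offs are calibrated against this
scale), second-moment ellipse → aspect ratio, raw-intensity means, and a
ring score = mean(annulus 0.5–1 r_eq) − mean(core 0–0.5 r_eq) on the filled
section. Single-voxel components take circularity = aspect = 1 by
convention.

## Classification

A first-match decision list so every label carries an auditable rationale;
thresholds are config fixtures (AF levels as background-relative z-scores
2/5/8, ring ≥ 3 noise-sd, "large" = cohort 90th-percentile area, circularity
cut-offs 0.6/0.7/0.8, spindle aspect ≥ 2):

R1 ring + mid AF → ML2; R2 dark + elongated → M2; R3 dark + round → M1;
R4 bright + (irregular or large) → L2; R5 bright + round → L1;
R6 intermediate AF + large round → ML1; R7 nearest-prototype fallback,
flagged `fallback` in the rationale (intermediate melanosome-to-lipofuscin
conversion states land here or in ML1 — there is no seventh label).

The family ratio is reported in both readings: (melanin + melanolipofuscin)
/ lipofuscin (the published "melanin + melanosome to lipofuscin" wording)
and pure melanin / lipofuscin.

## AF quantification

"RGB stack" analysis maps AF488 to green (16-bit inputs rescale as
`floor(v·255/65535)`); the 256-bin histogram and the rectangular-selection
plot profile follow ImageJ semantics. Total AF of a cell sums the AF488
channel over every in-polygon voxel from apex to base. The
background-subtracted variant subtracts one background level per voxel
*linearly* (total clipped at zero): the background estimate is anchored on
the out-of-cell histogram mode but refined to sub-integer precision (mean
within one noise-width of the mode), because a ±1 grey-level quantization
jump of the raw mode, multiplied by a cell's voxel count, would exceed the
biological AF differences being tested.

## Per-cell summary and group statistics

`Average size = Total area / Count` (missing, not 0, for empty cells);
`% Area` is granule cross-section area over cell area; `Mean` is the
volume-weighted mean AF of granule voxels (ImageJ Summarize semantics), with
`granules_per_um2` emitted alongside because the published captions can also
be read as a count density. Granule-poor cells are those with
above-median melanin:lipofuscin ratio *and* below-median count (cohort
medians, ≥ 5 cells). Nuclei are counted on the max-projected nuclei channel
(Otsu clamped at median + 3 MAD, hole filling, components ≥ 12 px²);
≥ 3 nuclei marks a multinucleated giant cell.

Inference follows the original workflow: repeated-measures one-way ANOVA
across days with cells as subjects (statsmodels `AnovaRM`), with post-hoc
Tukey computed against the *RM error term* (studentized range,
df = (n−1)(k−1)) — the pooled-variance Tukey of independent-groups software
is wrong for paired designs and in practice buries paired effects under
between-cell variance. When subjects are not fully crossed with levels the
code falls back to an ordinary one-way ANOVA plus standard Tukey HSD, with a
logged warning. Dose comparisons use the paired two-tailed t-test.
Significance codes follow the Prism convention (ns / * / ** / *** / ****
at 0.05 / 0.01 / 0.001 / 0.0001). Degenerate inputs are handled explicitly:
all-zero paired differences give t = 0, p = 1; a constant non-zero
difference reports p = 0 with an infinite statistic; identical ANOVA groups
give F = 0, p = 1.

The tests validate these engines against independent oracles: exact
sign-flip enumeration (2ⁿ) for the paired t, within-subject label
permutation (10⁵ reps) for the RM-ANOVA F, and a max-|q| permutation for the
Tukey-adjusted p. Parametric and permutation p-values differ systematically
at n ≤ 12 (order 0.01, far above permutation Monte-Carlo error), so the
agreement tolerances are 0.02 absolute for t/F and 0.05 for Tukey on
near-normal fixtures, with exact agreement required on null cases.

## Printed-precision audit

`rpe_granulyzer.audit_rows` ships the previously reported summary rows used
to audit the identity `Average size = Total area / Count` at each cell's own
printed precision (3 decimals, or significant figures for scientific
notation; round-half-even). Rows whose printed values violate the identity
by more than printed-precision rounding — most of the 60 mg columns of the
per-cell mean tables, plus one internally inconsistent day-30 row — are
retained in the fixture file with their recomputed values but excluded from
the audit.

## Problem sizes

The acceptance workflow uses: the 50-cell reference scene (≈1000 granules,
seed 7) for detection and zonal fidelity; a 60-cell scene (≥1000 planted
granules) for classification fidelity; and the full dose × time experiment
at 200 cells × 2 doses × 3 days × 5 seeds (≈30k planted granules) for trend
recovery, with mosaics shared across days. The pytest acceptance suite runs
the same experiment at 3 seeds; both sizes give the four headline trends
Tukey p ≪ 0.05 with consistent directions.

## Known limitations

* Cell boundaries are inputs (as in the original manual workflow); there is
  no automatic segmentation, and boundary errors propagate directly into
  per-cell quantities.
* Classification thresholds are calibrated once against the generator's
  contrast model; real stacks with different AF dynamic range need the
  background-relative thresholds re-anchored (they are config values).
* Abutting granules closer than the watershed valley criterion (~half-peak
  overlap) merge into one detection; sub-resolution granule clusters are
  counted as one, as in any intensity-threshold particle analysis.
* The melanin:lipofuscin ratio is reported as +inf when a cell has melanin
  but no lipofuscin; downstream medians use finite values only.
* The 2-D per-slice detection mode exists for comparison but is untuned.
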