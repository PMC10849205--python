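"""Ground-truthed synthetic RPE flat-mount scenes.

The generator emulates the statistical structure the downstream analysis
assumes, so that every stage can be exercised and scored without real data
(no public image deposit exists for this kind of study):

* a polygonal cell mosaic (Voronoi tessellation of Poisson-disk-sampled
  seeds, clipped to the frame) with controllable side-count distribution and
  a fraction of swollen cells,
* six granule phenotypes — L1 monolithic lipofuscin discs, L2 irregular
  lipofuscin aggregates, ML1 large round melanolipofuscin, ML2 bull's-eye
  melanolipofuscin (bright ring, dark melanin core), M1 round melanosomes and
  M2 spindle-shaped melanosomes — planted per cell at Poisson rates,
* apical–basal zonal placement priors: melanin-family granules concentrate
  in the apical C1–C2 zones, lipofuscin in the middle C3 zone,
* sodium-iodate dose x time trends encoded as per-(dose, day) rate
  multipliers for the melanin- and lipofuscin-family rates,
* nuclei (1–4 per cell, with a multinucleated-giant-cell excess for the
  high-dose day-7 condition) in a dedicated channel,
* two imaging channels: AF488 (488 nm-excitation autofluorescence — the
  lipofuscin families are bright, melanin is not excited) and TRANS
  (transmitted light — melanin-containing granules are dark).

All intensity levels are fixtures: no study of this tissue publishes absolute
per-phenotype brightness, so the defaults are chosen once for clear contrast
at 8 bits and documented in the methods note.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace


import numpy as np
import pandas as pd
import shapely
from scipy.ndimage import gaussian_filter
from scipy.spatial import Voronoi
from shapely.geometry import Polygon, box

from .stack_io import CellROI, ConfigError, ZStack
from .zonal import zone_of

log = logging.getLogger(__name__)

__all__ = [
    "PHENOTYPES",
    "FAMILY_OF",
    "trend_group_of",
    "MorphologyParams",
    "SceneConfig",
    "GranuleTruth",
    "CellTruth",
    "SceneTruth",
    "generate_mosaic",
    "plant_granules",
    "render",
    "simulate_scene",
    "DEFAULT_TREND_TABLE",
    "DEFAULT_NUCLEI_PROBS",
    "NUCLEI_PROBS_OVERRIDES",
    "DEFAULT_MORPHOLOGY_TABLE",
]

PHENOTYPES = ("L1", "L2", "ML1", "ML2", "M1", "M2")

FAMILY_OF = {
    "L1": "LIPOFUSCIN",
    "L2": "LIPOFUSCIN",
    "ML1": "MELANOLIPOFUSCIN",
    "ML2": "MELANOLIPOFUSCIN",
    "M1": "MELANIN",
    "M2": "MELANIN",
}


def trend_group_of(phenotype: str) -> str:
    """Trend family: melanin-containing granules (M*, ML*) follow the melanin
    multiplier, pure lipofuscin (L*) the lipofuscin multiplier."""
    return "lipofuscin" if phenotype.startswith("L") else "melanin"


#: per-(dose, day) multipliers (melanin-family, lipofuscin-family) encoding
#: the qualitative injury trends: low dose — both families rise over time;
#: high dose — melanin falls monotonically while lipofuscin peaks at day 7.
#: These are generator fixtures, not measured values.
DEFAULT_TREND_TABLE: dict[tuple[str, int], tuple[float, float]] = {
    ("LOW_40", 1): (1.0, 1.0),
    ("LOW_40", 7): (1.3, 1.5),
    ("LOW_40", 30): (1.8, 2.2),
    ("HIGH_60", 1): (1.0, 1.0),
    ("HIGH_60", 7): (0.7, 1.4),
    ("HIGH_60", 30): (0.4, 0.6),
}

#: probabilities of 1, 2, 3, 4 nuclei per cell; baseline mosaics are mostly
#: mono/binucleate, the high-dose day-7 override plants a clear excess of
#: multinucleated (>= 3 nuclei) giant cells.
DEFAULT_NUCLEI_PROBS = (0.55, 0.43, 0.015, 0.005)
NUCLEI_PROBS_OVERRIDES: dict[tuple[str, int], tuple[float, ...]] = {
    ("HIGH_60", 7): (0.35, 0.45, 0.13, 0.07),
}


@dataclass(frozen=True)
class MorphologyParams:
    """Polygon side-count distribution and swollen-cell fraction."""

    mean_sides: float = 5.9
    sd_sides: float = 0.7
    swollen_frac: float = 0.02


#: injury-related shape change is strongest on day 1 in both doses
DEFAULT_MORPHOLOGY_TABLE: dict[tuple[str, int], MorphologyParams] = {
    ("LOW_40", 1): MorphologyParams(7.0, 1.0, 0.10),
    ("HIGH_60", 1): MorphologyParams(8.5, 1.0, 0.15),
}


def _default_phenotype_mix() -> dict[str, float]:
    return {"L1": 0.30, "L2": 0.10, "ML1": 0.08, "ML2": 0.12, "M1": 0.25, "M2": 0.15}


@dataclass
class SceneConfig:
    n_cells: int = 50
    image_size: tuple[int, int] = (512, 512)  # (y, x)
    n_slices: int = 12
    pixel_size_um: float = 0.2
    z_step_um: float = 0.5
    dose: str = "LOW_40"
    day: int = 1
    seed: int = 0
    mosaic_seed: int | None = None  # share a mosaic across days by fixing this
    granule_rate_per_cell: float = 20.0
    phenotype_mix: dict[str, float] = field(default_factory=_default_phenotype_mix)
    trend_table: dict[tuple[str, int], tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_TREND_TABLE)
    )
    nuclei_probs: tuple[float, ...] | None = None  # None -> dose/day default
    morphology_params: MorphologyParams | None = None  # None -> dose/day default
    noise_sd: float = 8.0
    # intensity fixtures (8-bit scale)
    af_background: float = 30.0
    trans_background: float = 120.0
    nuc_background: float = 20.0
    lipofuscin_peak: float = 180.0  # AF488 peak of L1/L2 and the ML2 ring
    ml1_af_amplitude: float = 55.0  # intermediate AF of ML1 above background
    ml2_ring_amplitude: float = 100.0  # the bull's-eye ring: dimmer than pure lipofuscin
    melanin_trans_dip: float = 80.0  # TRANS darkening of melanin-family cores
    # zonal placement priors (slice units)
    z_sd_melanin: float = 1.3
    z_sd_lipofuscin: float = 0.7

    def __post_init__(self) -> None:
        if self.dose not in ("LOW_40", "HIGH_60"):
            raise ConfigError(f"unknown dose {self.dose!r}")
        if self.day not in (1, 7, 30):
            raise ConfigError(f"unknown day {self.day!r}")
        if self.n_cells < 1:
            raise ConfigError("n_cells must be >= 1")
        mix = np.array([self.phenotype_mix.get(p, 0.0) for p in PHENOTYPES])
        if abs(mix.sum() - 1.0) > 1e-9:
            raise ConfigError("phenotype_mix must sum to 1")
        if (mix < 0).any() or self.granule_rate_per_cell < 0:
            raise ConfigError("rates and probabilities must be >= 0")
        probs = self.resolved_nuclei_probs()
        if abs(sum(probs) - 1.0) > 1e-9 or any(p < 0 for p in probs):
            raise ConfigError("nuclei_probs must be a probability vector over 1..4")
        mean_area = self.image_size[0] * self.image_size[1] / self.n_cells
        if mean_area < 200:
            raise ConfigError("image too small: mean cell area must be >= 200 px^2")

    def resolved_nuclei_probs(self) -> tuple[float, ...]:
        if self.nuclei_probs is not None:
            return self.nuclei_probs
        return NUCLEI_PROBS_OVERRIDES.get((self.dose, self.day), DEFAULT_NUCLEI_PROBS)

    def resolved_morphology(self) -> MorphologyParams:
        if self.morphology_params is not None:
            return self.morphology_params
        return DEFAULT_MORPHOLOGY_TABLE.get((self.dose, self.day), MorphologyParams())

    def trend_multipliers(self) -> tuple[float, float]:
        try:
            return self.trend_table[(self.dose, self.day)]
        except KeyError:
            raise ConfigError(f"trend_table has no entry for {(self.dose, self.day)}")

    def expected_rate(self, phenotype: str) -> float:
        """Expected granules of one phenotype per cell under this condition."""
        mel_mult, lip_mult = self.trend_multipliers()
        mult = lip_mult if trend_group_of(phenotype) == "lipofuscin" else mel_mult
        return self.granule_rate_per_cell * self.phenotype_mix.get(phenotype, 0.0) * mult


@dataclass
class GranuleTruth:
    cell_id: str
    phenotype: str
    x: float
    y: float
    z: float
    r_major: float  # semi-axis along orientation, px
    r_minor: float
    orientation_deg: float
    zone: str
    core_frac: float = 0.0  # ML2 dark-core radius fraction
    blob_offsets: tuple[tuple[float, float], ...] = ()  # L2 sub-disc offsets

    @property
    def family(self) -> str:
        return FAMILY_OF[self.phenotype]

    @property
    def aspect_ratio(self) -> float:
        return self.r_major / self.r_minor


@dataclass
class CellTruth:
    cell_id: str
    polygon: list[tuple[float, float]]
    area_px2: float
    side_count: int
    n_nuclei: int
    swollen: bool
    nuclei_xy: tuple[tuple[float, float], ...]


@dataclass
class SceneTruth:
    config: SceneConfig
    cells: list[CellTruth] = field(default_factory=list)
    granules: list[GranuleTruth] = field(default_factory=list)

    def granule_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "cell_id": g.cell_id,
                    "phenotype": g.phenotype,
                    "family": g.family,
                    "x": g.x,
                    "y": g.y,
                    "z": g.z,
                    "r_major": g.r_major,
                    "r_minor": g.r_minor,
                    "orientation_deg": g.orientation_deg,
                    "zone": g.zone,
                }
                for g in self.granules
            ]
        )

    def cell_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "cell_id": c.cell_id,
                    "area_px2": c.area_px2,
                    "side_count": c.side_count,
                    "n_nuclei": c.n_nuclei,
                    "swollen": c.swollen,
                }
                for c in self.cells
            ]
        )


# --------------------------------------------------------------------------
# mosaic


def _poisson_disk(rng: np.random.Generator, n: int, h: int, w: int) -> np.ndarray:
    """Dart-throwing Poisson-disk sample of n points in the frame."""
    r = 0.72 * math.sqrt(h * w / n)
    pts: list[tuple[float, float]] = []
    attempts = 0
    while len(pts) < n:
        cand = rng.uniform((0.02 * w, 0.02 * h), (0.98 * w, 0.98 * h), size=(64, 2))
        for x, y in cand:
            if len(pts) >= n:
                break
            if all((x - px) ** 2 + (y - py) ** 2 >= r * r for px, py in pts):
                pts.append((x, y))
        attempts += 64
        if attempts > 400 * max(n, 16):
            r *= 0.85
            attempts = 0
    return np.asarray(pts)


def _bounded_voronoi(points: np.ndarray, h: int, w: int) -> list[Polygon]:
    """Voronoi cells clipped to the frame via edge mirroring."""
    mirrored = [points]
    for axis, bound in ((0, 0.0), (0, float(w)), (1, 0.0), (1, float(h))):
        m = points.copy()
        m[:, axis] = 2 * bound - m[:, axis]
        mirrored.append(m)
    vor = Voronoi(np.vstack(mirrored))
    frame = box(0.0, 0.0, float(w), float(h))
    cells = []
    for i in range(len(points)):
        region = vor.regions[vor.point_region[i]]
        poly = Polygon(vor.vertices[region]).intersection(frame)
        cells.append(shapely.geometry.polygon.orient(poly))
    return cells


def _remove_vertex_least_area(pts: np.ndarray) -> np.ndarray:
    """Remove the vertex whose removal loses the least area (convex shrink)."""
    n = len(pts)
    areas = np.empty(n)
    for i in range(n):
        a, b, c = pts[i - 1], pts[i], pts[(i + 1) % n]
        areas[i] = abs((b[0] - a[0]) * (c[1] - a[1]) - (c[0] - a[0]) * (b[1] - a[1]))
    return np.delete(pts, int(np.argmin(areas)), axis=0)


def _split_longest_edge(pts: np.ndarray) -> np.ndarray:
    """Split the longest edge at its midpoint, displaced inward so the new
    vertex survives collinear merging (turning angle ~11 degrees)."""
    nxt = np.roll(pts, -1, axis=0)
    lengths = np.hypot(*(nxt - pts).T)
    i = int(np.argmax(lengths))
    a, b = pts[i], nxt[i]
    mid = (a + b) / 2.0
    centroid = pts.mean(axis=0)
    direction = centroid - mid
    norm = np.hypot(*direction)
    if norm == 0:
        direction, norm = np.array([1.0, 0.0]), 1.0
    mid = mid + direction / norm * (0.05 * lengths[i])
    return np.insert(pts, i + 1, mid, axis=0)


def _adjust_side_count(poly: Polygon, target: int) -> Polygon:
    from .geometry import merge_collinear

    pts = np.asarray(poly.exterior.coords[:-1], dtype=float)
    pts = merge_collinear(pts)
    guard = 0
    while len(pts) > target and len(pts) > 4 and guard < 40:
        pts = _remove_vertex_least_area(pts)
        pts = merge_collinear(pts)
        guard += 1
    while len(pts) < target and guard < 60:
        pts = _split_longest_edge(pts)
        pts = merge_collinear(pts)
        guard += 1
    out = Polygon(pts)
    return out if out.is_valid and out.area > 0 else poly


def _sample_nuclei_xy(
    rng: np.random.Generator, poly: Polygon, n: int, r_nuc: float
) -> list[tuple[float, float]]:
    inner = poly.buffer(-(r_nuc + 1.0))
    if inner.is_empty:
        inner = poly
    minx, miny, maxx, maxy = inner.bounds
    placed: list[tuple[float, float]] = []
    for _ in range(n):
        for _attempt in range(200):
            x = rng.uniform(minx, maxx)
            y = rng.uniform(miny, maxy)
            if not shapely.intersects_xy(inner, x, y):
                continue
            if all((x - px) ** 2 + (y - py) ** 2 >= (2.6 * r_nuc) ** 2 for px, py in placed):
                placed.append((x, y))
                break
        else:
            log.warning("could not place nucleus %d in cell; skipping", len(placed) + 1)
    return placed


def generate_mosaic(config: SceneConfig) -> tuple[list[CellROI], SceneTruth]:
    """Voronoi mosaic of Poisson-disk seeds with per-cell side-count targets,
    nuclei counts, and a swollen-cell fraction.

    Swelling is produced geometrically: each designated swollen seed absorbs
    its nearest neighbouring seed before tessellation, roughly doubling the
    cell's area relative to the cohort.  Side-count targets above the natural
    Voronoi count are met by splitting edges with a small inward kink, targets
    below it by removing the least-important vertices (cells are convex, so
    both operations only shrink the cell and the mosaic stays overlap-free).
    """
    morph = config.resolved_morphology()
    mseed = config.mosaic_seed if config.mosaic_seed is not None else config.seed
    rng = np.random.default_rng(np.random.SeedSequence([int(mseed), 11]))
    h, w = config.image_size
    n = config.n_cells
    n_swollen = int(round(morph.swollen_frac * n))

    truth = SceneTruth(config=config)
    if n == 1:
        polys = [box(0.0, 0.0, float(w), float(h))]
        swollen_set: set[int] = set()
    else:
        pts = _poisson_disk(rng, n + n_swollen, h, w)
        keep = np.ones(len(pts), dtype=bool)
        swollen_idx = rng.choice(len(pts), size=n_swollen, replace=False) if n_swollen else []
        for si in swollen_idx:
            d2 = ((pts - pts[si]) ** 2).sum(axis=1)
            d2[si] = np.inf
            d2[~keep] = np.inf
            for sj in swollen_idx:
                d2[sj] = np.inf
            j = int(np.argmin(d2))
            if np.isfinite(d2[j]):
                keep[j] = False
        pts = pts[keep]
        swollen_set = {int(np.flatnonzero(keep).tolist().index(si)) for si in swollen_idx if keep[si]}
        polys = _bounded_voronoi(pts, h, w)

    rois: list[CellROI] = []
    nuclei_probs = np.asarray(config.resolved_nuclei_probs())
    from .geometry import merge_collinear

    for i, poly in enumerate(polys):
        if n > 1:  # a single cell keeps the whole frame
            target = int(np.clip(round(rng.normal(morph.mean_sides, morph.sd_sides)), 4, 12))
            poly = _adjust_side_count(poly, target)
        n_nuc = int(rng.choice((1, 2, 3, 4), p=nuclei_probs))
        cid = f"c{i:03d}"
        verts = [(float(x), float(y)) for x, y in poly.exterior.coords[:-1]]
        roi = CellROI(cell_id=cid, polygon=verts, z_top=0, z_bottom=config.n_slices - 1)
        rois.append(roi)
        nuclei_xy = _sample_nuclei_xy(rng, poly, n_nuc, r_nuc=4.0)
        truth.cells.append(
            CellTruth(
                cell_id=cid,
                polygon=verts,
                area_px2=poly.area,
                side_count=len(merge_collinear(np.asarray(verts))),
                n_nuclei=len(nuclei_xy),
                swollen=i in swollen_set,
                nuclei_xy=tuple(nuclei_xy),
            )
        )
    return rois, truth


# --------------------------------------------------------------------------
# granule planting

#: per-phenotype base shape parameters in px: (mean semi-major, rel. sd)
_SHAPE_BASE = {
    "L1": (2.2, 0.12),
    "L2": (2.1, 0.12),  # per sub-disc of the aggregate
    "ML1": (4.5, 0.08),
    "ML2": (3.2, 0.08),
    "M1": (2.5, 0.10),
    "M2": (4.5, 0.08),
}


def _zone_extent(roi: CellROI) -> float:
    return roi.z_bottom - roi.z_top + 1.0


def _sample_z(rng: np.random.Generator, roi: CellROI, phenotype: str, cfg: SceneConfig) -> float:
    t = _zone_extent(roi)
    if trend_group_of(phenotype) == "melanin":
        mean = roi.z_top - 0.5 + 0.25 * t  # centre of C1-C2
        sd = cfg.z_sd_melanin
    else:
        mean = roi.z_top - 0.5 + 0.625 * t  # centre of C3
        sd = cfg.z_sd_lipofuscin
    return float(np.clip(rng.normal(mean, sd), roi.z_top, roi.z_bottom))


def _sample_shape(
    rng: np.random.Generator, phenotype: str
) -> tuple[float, float, float, float, tuple[tuple[float, float], ...]]:
    """Return (r_major, r_minor, orientation_deg, core_frac, blob_offsets)."""
    base, rel_sd = _SHAPE_BASE[phenotype]
    r = float(base * rng.lognormal(0.0, rel_sd))
    theta = float(rng.uniform(0.0, 180.0))
    if phenotype == "M2":
        ratio = float(rng.uniform(2.3, 3.2))
        return r, r / ratio, theta, 0.0, ()
    if phenotype == "L2":
        k = int(rng.integers(3, 6))
        step = 2.3 * r
        ang = rng.uniform(0, 2 * math.pi)
        offs = [(0.0, 0.0)]
        pos = np.zeros(2)
        for _ in range(k - 1):
            ang += rng.uniform(-1.1, 1.1)
            pos = pos + step * np.array([math.cos(ang), math.sin(ang)])
            offs.append((float(pos[0]), float(pos[1])))
        offs_arr = np.asarray(offs) - np.asarray(offs).mean(axis=0)
        return r, r, theta, 0.0, tuple((float(a), float(b)) for a, b in offs_arr)
    if phenotype == "ML2":
        return r, r, theta, 0.45, ()
    return r, r, theta, 0.0, ()


def _granule_extent(g_r_major: float, blob_offsets) -> float:
    ext = g_r_major
    for ox, oy in blob_offsets:
        ext = max(ext, math.hypot(ox, oy) + g_r_major)
    return ext


def plant_granules(
    config: SceneConfig, rois: list[CellROI], truth: SceneTruth
) -> SceneTruth:
    """Plant granules cell by cell at Poisson rates with zonal priors.

    Counts per phenotype are Poisson with mean rate x the (dose, day) trend
    multiplier of the phenotype's family; z follows a normal prior centred in
    the family's home zone (melanin-family in C1–C2, lipofuscin in C3),
    clipped to the cell's z extent; (x, y) is uniform inside the polygon
    eroded by the granule's own extent so the whole granule fits.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 23]))
    for roi in rois:
        poly = roi.shapely
        placed: list[tuple[float, float, float, float]] = []  # (x, y, z, extent)
        for phenotype in PHENOTYPES:
            rate = config.expected_rate(phenotype)
            n = int(rng.poisson(rate)) if rate > 0 else 0
            for _ in range(n):
                r_major, r_minor, theta, core_frac, offs = _sample_shape(rng, phenotype)
                extent = _granule_extent(r_major, offs)
                inner = poly.buffer(-(extent + 0.5))
                target = inner if not inner.is_empty else poly
                minx, miny, maxx, maxy = target.bounds
                placed_ok = False
                for _attempt in range(100):
                    x = rng.uniform(minx, maxx)
                    y = rng.uniform(miny, maxy)
                    if not shapely.intersects_xy(target, x, y):
                        continue
                    z = _sample_z(rng, roi, phenotype, config)
                    # granules are solid organelles: reject interpenetration
                    if all(
                        math.hypot(x - px, y - py) >= (extent + pext) * 0.9
                        or abs(z - pz) >= 3.0
                        for px, py, pz, pext in placed
                    ):
                        placed_ok = True
                        break
                if not placed_ok:
                    log.warning(
                        "cell %s too crowded for a %s granule; skipping",
                        roi.cell_id,
                        phenotype,
                    )
                    continue
                placed.append((x, y, z, extent))
                zone = zone_of(z, roi.z_top, roi.z_bottom)
                truth.granules.append(
                    GranuleTruth(
                        cell_id=roi.cell_id,
                        phenotype=phenotype,
                        x=float(x),
                        y=float(y),
                        z=z,
                        r_major=r_major,
                        r_minor=r_minor,
                        orientation_deg=theta,
                        zone=zone,
                        core_frac=core_frac,
                        blob_offsets=offs,
                    )
                )
    return truth


# --------------------------------------------------------------------------
# rendering

_EDGE_W = 0.35  # px, sigmoid edge width of granule footprints
_Z_SIGMA = 0.8  # slices; granules span ~3 slices


def _footprint(g: GranuleTruth, xx: np.ndarray, yy: np.ndarray) -> np.ndarray:
    """Soft footprint in [0, 1] on the local grid."""
    if g.blob_offsets:
        d = np.full(xx.shape, np.inf)
        for ox, oy in g.blob_offsets:
            d = np.minimum(d, np.hypot(xx - (g.x + ox), yy - (g.y + oy)))
        return 1.0 / (1.0 + np.exp((d - g.r_major) / _EDGE_W))
    th = math.radians(g.orientation_deg)
    u = (xx - g.x) * math.cos(th) + (yy - g.y) * math.sin(th)
    v = -(xx - g.x) * math.sin(th) + (yy - g.y) * math.cos(th)
    q = np.sqrt((u / g.r_major) ** 2 + (v / g.r_minor) ** 2)
    return 1.0 / (1.0 + np.exp((q - 1.0) * g.r_minor / _EDGE_W))


def _core_footprint(g: GranuleTruth, xx: np.ndarray, yy: np.ndarray) -> np.ndarray:
    d = np.hypot(xx - g.x, yy - g.y)
    return 1.0 / (1.0 + np.exp((d - g.core_frac * g.r_major) / _EDGE_W))


def render(config: SceneConfig, truth: SceneTruth) -> ZStack:
    """Render the scene into an AF488 / TRANS / NUC z-stack.

    AF488: lipofuscin-family granules bright, ML1 intermediate, the ML2 ring
    bright around a dark core, melanin at background (melanin is not excited
    at 488 nm).  TRANS: melanin-containing material dark, pure lipofuscin
    neutral.  NUC: nuclei bright.  Granules are Gaussian-edged solids spanning
    ~3 slices; additive Gaussian noise, clipped to 8 bits.  Mitochondria only
    contribute a faint unstructured basal texture to AF488.
    """
    h, w = config.image_size
    nz = config.n_slices
    af = np.full((nz, h, w), config.af_background, dtype=np.float64)
    trans = np.full((nz, h, w), config.trans_background, dtype=np.float64)
    nuc = np.full((nz, h, w), config.nuc_background, dtype=np.float64)
    amp_l = config.lipofuscin_peak - config.af_background

    zs = np.arange(nz)
    for g in truth.granules:
        ext = _granule_extent(g.r_major, g.blob_offsets) + 3.0
        x0, x1 = max(0, int(g.x - ext)), min(w - 1, int(g.x + ext) + 1)
        y0, y1 = max(0, int(g.y - ext)), min(h - 1, int(g.y + ext) + 1)
        if x1 <= x0 or y1 <= y0:
            continue
        yy, xx = np.mgrid[y0 : y1 + 1, x0 : x1 + 1].astype(float)
        foot = _footprint(g, xx, yy)
        wz = np.exp(-0.5 * ((zs - g.z) / _Z_SIGMA) ** 2)
        zsel = np.flatnonzero(wz > 0.02)
        for zi in zsel:
            f = foot * wz[zi]
            sl = (zi, slice(y0, y1 + 1), slice(x0, x1 + 1))
            if g.phenotype in ("L1", "L2"):
                af[sl] += amp_l * f
            elif g.phenotype == "ML1":
                af[sl] += config.ml1_af_amplitude * f
                trans[sl] -= 0.75 * config.melanin_trans_dip * f
            elif g.phenotype == "ML2":
                core = _core_footprint(g, xx, yy) * wz[zi]
                af[sl] += config.ml2_ring_amplitude * np.clip(f - core, 0.0, 1.0)
                trans[sl] -= config.melanin_trans_dip * core
            else:  # M1 / M2
                trans[sl] -= config.melanin_trans_dip * f

    # nuclei: bright discs in the NUC channel, basal z position
    for cell in truth.cells:
        for nx, ny in cell.nuclei_xy:
            r_nuc = 4.0
            x0, x1 = max(0, int(nx - r_nuc - 3)), min(w - 1, int(nx + r_nuc + 3) + 1)
            y0, y1 = max(0, int(ny - r_nuc - 3)), min(h - 1, int(ny + r_nuc + 3) + 1)
            if x1 <= x0 or y1 <= y0:
                continue
            yy, xx = np.mgrid[y0 : y1 + 1, x0 : x1 + 1].astype(float)
            d = np.hypot(xx - nx, yy - ny)
            foot = 1.0 / (1.0 + np.exp((d - r_nuc) / 0.5))
            zc = nz - 2.5
            wz = np.exp(-0.5 * ((zs - zc) / 1.2) ** 2)
            for zi in np.flatnonzero(wz > 0.02):
                nuc[zi, y0 : y1 + 1, x0 : x1 + 1] += 170.0 * foot * wz[zi]

    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 47]))
    # faint basal texture standing in for the mitochondria-rich C4 zone;
    # kept below the noise floor so it never reads as countable particles
    basal0 = int(math.ceil(0.75 * nz))
    texture = gaussian_filter(rng.normal(0.0, 1.0, size=(h, w)), 3.0)
    sd = texture.std() or 1.0
    for zi in range(basal0, nz):
        af[zi] += 0.6 * config.noise_sd * texture / sd

    out = np.empty((nz, h, w, 3), dtype=np.uint8)
    for ci, chan in enumerate((af, trans, nuc)):
        noisy = chan + rng.normal(0.0, config.noise_sd, size=chan.shape)
        out[..., ci] = np.clip(np.rint(noisy), 0, 255).astype(np.uint8)
    return ZStack(
        voxels=out,
        pixel_size_um=config.pixel_size_um,
        z_step_um=config.z_step_um,
        channel_names=("AF488", "TRANS", "NUC"),
    )


def simulate_scene(config: SceneConfig) -> tuple[ZStack, list[CellROI], SceneTruth]:
    """Generate mosaic, plant granules, render: one fully ground-truthed scene."""
    rois, truth = generate_mosaic(config)
    truth = plant_granules(config, rois, truth)
    stack = render(config, truth)
    return stack, rois, truth
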