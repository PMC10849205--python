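"""Reading and writing of every external artifact the pipeline touches.

Z-stacks travel as multi-page TIFF plus a JSON metadata sidecar (pixel size,
z-step, channel order); cell boundaries as a JSON list of closed polygons with
an apical/basal z extent; results as CSV.  Page order in the TIFF is z-major,
channel-minor: page = z * n_channels + c, with slice 0 the apical-most plane.

Coordinates are pixel-centre, 0-based, x = column, y = row.  A pixel belongs
to a cell if its centre lies inside (or exactly on the boundary of) the cell
polygon.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile
from shapely.geometry import Polygon

__all__ = [
    "FormatError",
    "ConfigError",
    "ValidationError",
    "ZStack",
    "CellROI",
    "read_zstack",
    "write_zstack",
    "read_rois",
    "write_rois",
    "write_summary_tables",
    "SUMMARY_COLUMNS",
]


class FormatError(ValueError):
    """An external file violates the declared format."""


class ConfigError(ValueError):
    """Metadata / configuration is missing or inconsistent."""


class ValidationError(ValueError):
    """An input object violates a domain invariant."""


@dataclass
class ZStack:
    """Multi-channel 3-D fluorescence stack.

    voxels are indexed ``(z, y, x, channel)``; slice 0 is the apical-most
    plane (the flat mount is imaged apical side up, microvilli first).
    """

    voxels: np.ndarray
    pixel_size_um: float
    z_step_um: float
    channel_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        self.channel_names = tuple(self.channel_names)
        if self.voxels.ndim != 4:
            raise ValidationError(
                f"voxels must be (z, y, x, channel), got ndim={self.voxels.ndim}"
            )
        if self.voxels.shape[3] != len(self.channel_names):
            raise ValidationError(
                f"{self.voxels.shape[3]} channels in array but "
                f"{len(self.channel_names)} channel names"
            )
        if not self.pixel_size_um > 0:
            raise ValidationError("pixel_size_um must be > 0")
        if not self.z_step_um > 0:
            raise ValidationError("z_step_um must be > 0")
        if self.voxels.dtype == np.uint8:
            self.bit_depth = 8
        elif self.voxels.dtype == np.uint16:
            self.bit_depth = 16
        else:
            raise ValidationError(
                f"voxels must be uint8 or uint16, got {self.voxels.dtype}"
            )

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    @property
    def shape_yx(self) -> tuple[int, int]:
        return self.voxels.shape[1], self.voxels.shape[2]

    def channel(self, name: str) -> np.ndarray:
        """Return the (z, y, x) array for one named channel."""
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise ConfigError(
                f"channel {name!r} not present; have {self.channel_names}"
            ) from None
        return self.voxels[..., idx]

    def has_channel(self, name: str) -> bool:
        return name in self.channel_names


@dataclass
class CellROI:
    """Closed polygon delimiting one RPE cell plus its apical/basal z extent.

    ``z_top`` is the apical-most slice index of the cell, ``z_bottom`` the
    basal-most (inclusive); 0 <= z_top < z_bottom.
    """

    cell_id: str
    polygon: list[tuple[float, float]]
    z_top: int
    z_bottom: int
    _shapely: Polygon = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        pts = [(float(x), float(y)) for x, y in self.polygon]
        if len(pts) >= 2 and pts[0] == pts[-1]:  # accept explicitly closed rings
            pts = pts[:-1]
        if len(pts) < 3:
            raise ValidationError(f"cell {self.cell_id}: polygon needs >= 3 vertices")
        poly = Polygon(pts)
        if not poly.is_valid:
            raise ValidationError(
                f"cell {self.cell_id}: polygon is not simple (self-intersecting?)"
            )
        if not poly.area > 0:
            raise ValidationError(f"cell {self.cell_id}: polygon area is 0")
        if not (0 <= self.z_top < self.z_bottom):
            raise ValidationError(
                f"cell {self.cell_id}: need 0 <= z_top < z_bottom, "
                f"got {self.z_top}..{self.z_bottom}"
            )
        self.polygon = pts
        self._shapely = poly

    @property
    def shapely(self) -> Polygon:
        return self._shapely

    @property
    def area_px2(self) -> float:
        return self._shapely.area

    def contains_xy(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Vectorised point-in-cell test, boundary inclusive."""
        import shapely

        return shapely.intersects_xy(self._shapely, np.asarray(x), np.asarray(y))

    def raster_mask(self, shape_yx: tuple[int, int]) -> np.ndarray:
        """Boolean (y, x) mask of pixels whose centres fall in the cell.

        Cached per frame shape (polygons are immutable once validated).
        """
        cache = getattr(self, "_mask_cache", None)
        if cache is None:
            cache = {}
            object.__setattr__(self, "_mask_cache", cache)
        if shape_yx in cache:
            return cache[shape_yx]
        mask = self._compute_mask(shape_yx)
        cache[shape_yx] = mask
        return mask

    def _compute_mask(self, shape_yx: tuple[int, int]) -> np.ndarray:
        h, w = shape_yx
        minx, miny, maxx, maxy = self._shapely.bounds
        x0, x1 = max(0, int(np.floor(minx))), min(w - 1, int(np.ceil(maxx)))
        y0, y1 = max(0, int(np.floor(miny))), min(h - 1, int(np.ceil(maxy)))
        mask = np.zeros((h, w), dtype=bool)
        if x1 < x0 or y1 < y0:
            return mask
        yy, xx = np.mgrid[y0 : y1 + 1, x0 : x1 + 1]
        inside = self.contains_xy(xx.ravel().astype(float), yy.ravel().astype(float))
        mask[y0 : y1 + 1, x0 : x1 + 1] = inside.reshape(yy.shape)
        return mask


# --------------------------------------------------------------------------
# TIFF z-stack + sidecar

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_zstack(stack: ZStack, path: str | Path) -> None:
    """Write a multi-page TIFF (z-major, channel-minor) plus JSON sidecar."""
    path = Path(path)
    z, y, x, c = stack.voxels.shape
    pages = stack.voxels.transpose(0, 3, 1, 2).reshape(z * c, y, x)
    tifffile.imwrite(path, pages)
    meta = {
        "pixel_size_um": stack.pixel_size_um,
        "z_step_um": stack.z_step_um,
        "channel_names": list(stack.channel_names),
        "n_slices": z,
        "page_order": "z_major_channel_minor",
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def read_zstack(path: str | Path, metadata: dict | None = None) -> ZStack:
    """Read a multi-page TIFF into a ZStack.

    Metadata (pixel size, z-step, channel names) comes from the JSON sidecar
    written next to the TIFF, or from the ``metadata`` mapping when supplied
    explicitly (the mapping wins).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if metadata is None:
        sidecar = _sidecar_path(path)
        if not sidecar.exists():
            raise ConfigError(f"no metadata sidecar found at {sidecar}")
        metadata = json.loads(sidecar.read_text())
    for key in ("pixel_size_um", "z_step_um", "channel_names"):
        if key not in metadata:
            raise ConfigError(f"metadata missing required key {key!r}")
    order = metadata.get("page_order", "z_major_channel_minor")
    if order != "z_major_channel_minor":
        raise ConfigError(f"unsupported page order {order!r}")
    with tifffile.TiffFile(path) as tif:
        shapes = {p.shape for p in tif.pages}
        if len(shapes) != 1:
            raise FormatError(f"TIFF pages have inconsistent shapes: {sorted(shapes)}")
        pages = tif.asarray()
    if pages.ndim == 2:
        pages = pages[None]
    channels = [str(c) for c in metadata["channel_names"]]
    n_c = len(channels)
    if pages.shape[0] % n_c != 0:
        raise FormatError(
            f"{pages.shape[0]} pages not divisible by {n_c} channels"
        )
    z = pages.shape[0] // n_c
    voxels = pages.reshape(z, n_c, *pages.shape[1:]).transpose(0, 2, 3, 1)
    return ZStack(
        voxels=voxels,
        pixel_size_um=float(metadata["pixel_size_um"]),
        z_step_um=float(metadata["z_step_um"]),
        channel_names=tuple(channels),
    )


# --------------------------------------------------------------------------
# ROI JSON

def read_rois(path: str | Path) -> list[CellROI]:
    """Read cell-boundary ROIs from the package's JSON schema.

    Schema: ``{"cells": [{"id", "polygon": [[x, y], ...], "z_top",
    "z_bottom"}, ...]}``.  Duplicate ids and invalid polygons are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    doc = json.loads(path.read_text())
    if "cells" not in doc:
        raise FormatError("ROI file has no 'cells' key")
    rois: list[CellROI] = []
    seen: set[str] = set()
    for entry in doc["cells"]:
        cid = str(entry["id"])
        if cid in seen:
            raise ValidationError(f"duplicate cell id {cid!r}")
        seen.add(cid)
        rois.append(
            CellROI(
                cell_id=cid,
                polygon=[(p[0], p[1]) for p in entry["polygon"]],
                z_top=int(entry["z_top"]),
                z_bottom=int(entry["z_bottom"]),
            )
        )
    return rois


def write_rois(rois: Sequence[CellROI], path: str | Path) -> None:
    doc = {
        "cells": [
            {
                "id": r.cell_id,
                "polygon": [[float(x), float(y)] for x, y in r.polygon],
                "z_top": r.z_top,
                "z_bottom": r.z_bottom,
            }
            for r in rois
        ]
    }
    Path(path).write_text(json.dumps(doc, indent=1))


# --------------------------------------------------------------------------
# Summary CSV

SUMMARY_COLUMNS = [
    "cell_id",
    "dose",
    "day",
    "Count",
    "Total area",
    "Average size",
    "% Area",
    "Mean",
    "total_area_um2",
    "granules_per_um2",
    "n_L1",
    "n_L2",
    "n_ML1",
    "n_ML2",
    "n_M1",
    "n_M2",
    "n_lipofuscin",
    "n_melanolipofuscin",
    "n_melanin",
    "melanin_to_lipofuscin_ratio",
    "melanin_only_to_lipofuscin_ratio",
    "n_nuclei",
    "richness",
]


def write_summary_tables(summaries, path: str | Path) -> None:
    """Write per-cell summaries as CSV with a fixed, deterministic column order.

    Columns mirror the classic particle-analysis report (Count, Total area,
    Average size, % Area, Mean) plus phenotype-stratified counts.  Raises if
    there is nothing to write; output carries no timestamps so identical
    inputs give byte-identical files.
    """
    import pandas as pd

    rows = [s.as_row() for s in summaries]
    if not rows:
        raise ValidationError("nothing to write: empty summary list")
    df = pd.DataFrame(rows)
    df = df[[c for c in SUMMARY_COLUMNS if c in df.columns]]
    df.to_csv(path, index=False, float_format="%.6f")
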