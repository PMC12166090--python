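"""Invasive-front estimation and front/center partitioning.

Colorectal tumors grow into the muscularis and adipose tissue, so the
invasive front is estimated as the equidistant midline between the
tumor-epithelium mask and the union of the muscle and adipose masks: the
zero level set of d_tumor − d_invaded, where both are Euclidean distance
transforms in μm.  Midline segments whose nearest non-tumor context is
normal mucosa are omitted, as are segments where tumor and invaded tissue
are farther apart than the full band diameter.

Tumor cells within ``front_band_halfwidth_um`` (500 μm, i.e. a 1000 μm
diameter band) of the surviving line are the tumor front; all remaining
tumor cells are the tumor center.  When no front can be estimated (e.g. a
biopsy fragment without invaded muscle) the slide is flagged and excluded
from region-specific analyses downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import shapely
from scipy import ndimage
from shapely.geometry import LineString, MultiLineString
from skimage import measure

from .cells import CellTable
from .config import PipelineConfig
from .tissue import (
    ADIPOSE,
    MUSCLE,
    NORMAL_EPITHELIUM,
    TUMOR_EPITHELIUM,
    TissueMap,
)


@dataclass
class FrontLine:
    """Estimated invasive front as polyline(s) in μm slide coordinates."""

    polylines: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.polylines = [np.asarray(p, dtype=float) for p in self.polylines]
        for p in self.polylines:
            if p.ndim != 2 or p.shape[1] != 2 or len(p) < 2:
                raise ValueError("each polyline needs ≥2 (x, y) vertices")
            if not np.isfinite(p).all():
                raise ValueError("polyline vertices must be finite")

    @property
    def detected(self) -> bool:
        return len(self.polylines) > 0

    @property
    def total_length_um(self) -> float:
        return float(sum(LineString(p).length for p in self.polylines))

    def as_multilinestring(self) -> MultiLineString:
        if not self.detected:
            raise ValueError("no front detected")
        return MultiLineString([LineString(p) for p in self.polylines])

    def to_geojson(self, path: str | Path) -> None:
        geom = {
            "type": "MultiLineString",
            "coordinates": [p.tolist() for p in self.polylines],
        }
        obj = {
            "type": "Feature",
            "properties": {
                "detected": self.detected,
                "total_length_um": self.total_length_um,
                "units": "um",
            },
            "geometry": geom if self.detected else None,
        }
        with open(path, "w") as fh:
            json.dump(obj, fh)
            fh.write("\n")

    @classmethod
    def from_geojson(cls, path: str | Path) -> "FrontLine":
        with open(path) as fh:
            obj = json.load(fh)
        geom = obj.get("geometry")
        if geom is None:
            return cls([])
        if geom["type"] == "LineString":
            coords = [geom["coordinates"]]
        elif geom["type"] == "MultiLineString":
            coords = geom["coordinates"]
        else:
            raise ValueError(f"unsupported geometry {geom['type']}")
        return cls([np.asarray(c, dtype=float) for c in coords])


@dataclass
class RegionPartition:
    """Front/center labels for the tumor cells of one slide."""

    n_tumor_front: int
    n_tumor_center: int
    front_missing: bool

    @property
    def n_tumor_total(self) -> int:
        return self.n_tumor_front + self.n_tumor_center


def estimate_front_line(tmap: TissueMap, cfg: PipelineConfig | None = None) -> FrontLine:
    """Estimate the invasive-front midline from an (unmerged) tissue map.

    Needs the original muscle/adipose labels, so it must run on the raster
    before class merging (lymphoid-aggregate pixels are ignored here either
    way since they are neither tumor nor invaded tissue).  Absence of a
    front is a valid outcome reported through ``FrontLine.detected``.
    """
    cfg = cfg or PipelineConfig()
    mpp = tmap.mpp
    tumor = tmap.mask(TUMOR_EPITHELIUM)
    invaded = tmap.mask(MUSCLE, ADIPOSE)
    if not tumor.any() or not invaded.any():
        return FrontLine([])

    d_tumor = ndimage.distance_transform_edt(~tumor, sampling=mpp)
    d_invaded = ndimage.distance_transform_edt(~invaded, sampling=mpp)
    f = d_tumor - d_invaded

    normal = tmap.mask(NORMAL_EPITHELIUM)
    if normal.any():
        d_normal = ndimage.distance_transform_edt(~normal, sampling=mpp)
    else:
        d_normal = None

    max_gap = 2.0 * cfg.front_band_halfwidth_um
    h, w = tmap.shape
    polylines: list[np.ndarray] = []
    for contour in measure.find_contours(f, 0.0):
        rows = np.clip(np.rint(contour[:, 0]).astype(int), 0, h - 1)
        cols = np.clip(np.rint(contour[:, 1]).astype(int), 0, w - 1)
        keep = (d_tumor[rows, cols] + d_invaded[rows, cols]) <= max_gap
        # omit any stretch bordering the normal mucosa: vertex dropped when
        # normal epithelium is nearer than the invaded tissue
        if d_normal is not None:
            keep &= d_normal[rows, cols] >= d_invaded[rows, cols]
        # vertices on the raster border are distance-transform artifacts
        keep &= (rows > 0) & (rows < h - 1) & (cols > 0) & (cols < w - 1)
        for run in _runs(keep):
            seg = contour[run]
            if len(seg) < 2:
                continue
            xy = np.column_stack(
                ((seg[:, 1] + 0.5) * mpp, (seg[:, 0] + 0.5) * mpp)
            )
            line = LineString(xy).simplify(mpp)
            if line.length >= cfg.min_front_length_um:
                polylines.append(np.asarray(line.coords, dtype=float))
    return FrontLine(polylines)


def _runs(mask: np.ndarray) -> list[slice]:
    """Maximal slices of consecutive True values."""
    out = []
    start = None
    for i, v in enumerate(mask):
        if v and start is None:
            start = i
        elif not v and start is not None:
            out.append(slice(start, i))
            start = None
    if start is not None:
        out.append(slice(start, len(mask)))
    return out


def distance_to_front(points: np.ndarray, front: FrontLine) -> np.ndarray:
    """Euclidean μm distance of each (x, y) point to the nearest polyline."""
    points = np.asarray(points, dtype=float)
    if not front.detected:
        return np.full(len(points), np.inf)
    mls = front.as_multilinestring()
    geoms = shapely.points(points)
    return shapely.distance(geoms, mls)


def assign_regions(
    cells: CellTable, front: FrontLine, cfg: PipelineConfig | None = None
) -> RegionPartition:
    """Partition tumor cells into front and center; mutates ``cells``.

    Front membership is distance ≤ band half-width (ties count as front).
    With an undetected front every tumor cell is labelled center and the
    slide is flagged ``front_missing`` so region scores report as missing.
    """
    cfg = cfg or PipelineConfig()
    tumor_mask = cells.mask("tumor_epithelial")
    idx = np.flatnonzero(tumor_mask)
    if not front.detected:
        cells.df.loc[cells.df.index[idx], "region"] = "center"
        cells.front_missing = True
        return RegionPartition(0, int(len(idx)), front_missing=True)
    d = distance_to_front(cells.coords[idx], front)
    is_front = d <= cfg.front_band_halfwidth_um
    labels = np.where(is_front, "front", "center")
    cells.df.loc[cells.df.index[idx], "region"] = labels
    cells.front_missing = False
    return RegionPartition(
        int(is_front.sum()), int((~is_front).sum()), front_missing=False
    )
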