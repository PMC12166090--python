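"""Tissue-type label rasters and nucleus/tissue reconciliation.

Tissue maps are single-channel rasters with nine classes; the physical
resolution is carried as μm per pixel (mpp).  Pixel (r, c) covers the
half-open square [c·mpp, (c+1)·mpp) × [r·mpp, (r+1)·mpp) in slide space.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from .cells import CellTable
from .config import PipelineConfig

logger = logging.getLogger(__name__)

TISSUE_CLASSES = (
    "background",        # 0
    "adipose",           # 1
    "muscle",            # 2
    "stroma",            # 3
    "lymphoid_aggregate",  # 4
    "debris",            # 5
    "normal_epithelium",  # 6
    "tumor_epithelium",  # 7
    "mucin",             # 8
)

BACKGROUND, ADIPOSE, MUSCLE, STROMA, LYMPHOID_AGGREGATE, DEBRIS, \
    NORMAL_EPITHELIUM, TUMOR_EPITHELIUM, MUCIN = range(9)


@dataclass
class TissueMap:
    """2D grid of tissue-class codes 0–8 with physical resolution."""

    labels: np.ndarray
    mpp: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("tissue map must be a 2D label raster")
        if not self.mpp > 0:
            raise ValueError(f"mpp must be > 0, got {self.mpp}")
        if self.labels.size and self.labels.max() > MUCIN:
            raise ValueError(
                f"tissue codes must be 0–8, found {int(self.labels.max())}"
            )
        if self.labels.size and self.labels.min() < 0:
            raise ValueError("tissue codes must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    @property
    def extent_um(self) -> tuple[float, float]:
        """(width, height) of the mapped area in μm."""
        h, w = self.labels.shape
        return (w * self.mpp, h * self.mpp)

    def mask(self, *codes: int) -> np.ndarray:
        return np.isin(self.labels, codes)

    def copy(self) -> "TissueMap":
        return TissueMap(self.labels.copy(), self.mpp)


def read_tissue_map(path: str | Path, mpp: float | None = None) -> TissueMap:
    """Read an indexed PNG/TIFF tissue raster.

    ``mpp`` may be given explicitly or via a JSON sidecar ``<stem>.json``
    containing ``{"mpp": <float>}``.
    """
    path = Path(path)
    if mpp is None:
        sidecar = path.with_suffix(".json")
        if not sidecar.exists():
            raise ValueError(f"no mpp given and no sidecar {sidecar}")
        with open(sidecar) as fh:
            mpp = float(json.load(fh)["mpp"])
    labels = np.asarray(Image.open(path))
    if labels.ndim == 3:
        raise ValueError("tissue map must be single-channel")
    return TissueMap(labels.astype(np.uint8), float(mpp))


def write_tissue_map(tmap: TissueMap, path: str | Path) -> None:
    path = Path(path)
    Image.fromarray(tmap.labels.astype(np.uint8), mode="L").save(path)
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump({"mpp": tmap.mpp}, fh)
        fh.write("\n")


def merge_tissue_classes(tmap: TissueMap) -> TissueMap:
    """Merge muscle into stroma and recode lymphoid-aggregate pixels as stroma.

    Muscle and stroma are analysed as a single stromal working class, and
    lymphoid-aggregate tissue pixels are recoded to that class so they never
    act as tumor, invaded-tissue or normal-epithelium context; dense
    lymphocyte structures are instead detected (and excluded) at cell level.
    Idempotent.
    """
    out = tmap.copy()
    out.labels[out.labels == MUSCLE] = STROMA
    out.labels[out.labels == LYMPHOID_AGGREGATE] = STROMA
    return out


def assign_epithelial_context(
    cells: CellTable,
    tmap: TissueMap,
    cfg: PipelineConfig | None = None,
) -> CellTable:
    """Resolve epithelial nuclei to tumor / normal epithelium via tissue context.

    The context of a nucleus is the majority tissue class over the pixels
    within ``iel_dilation_um`` (25 μm) of its centroid; ties go to the class
    of the nearest pixel among the tied classes.  Tumor-epithelium context
    makes the nucleus ``tumor_epithelial``, normal-epithelium context makes
    it ``normal_epithelial``, anything else (including an empty neighborhood
    for nuclei beyond the raster) makes it ``other``.  Mutates and returns
    ``cells``.
    """
    cfg = cfg or PipelineConfig()
    radius_um = cfg.iel_dilation_um
    mpp = tmap.mpp
    labels = tmap.labels
    h, w = labels.shape

    r_px = int(np.ceil(radius_um / mpp))
    dy, dx = np.mgrid[-r_px : r_px + 1, -r_px : r_px + 1]
    # offsets from the nucleus pixel, distances between pixel centers
    disk = (dx * mpp) ** 2 + (dy * mpp) ** 2 <= radius_um**2
    off_r = dy[disk].ravel()
    off_c = dx[disk].ravel()
    off_d2 = (off_r.astype(float) ** 2 + off_c.astype(float) ** 2)

    pending = cells.df["derived_class"] == "epithelial_pending"
    idx = np.flatnonzero(pending.to_numpy())
    xs = cells.df["x_um"].to_numpy()[idx]
    ys = cells.df["y_um"].to_numpy()[idx]
    cc = np.floor(xs / mpp).astype(int)
    rr = np.floor(ys / mpp).astype(int)

    out = np.empty(len(idx), dtype=object)
    n_outside = 0
    for k in range(len(idx)):
        pr = rr[k] + off_r
        pc = cc[k] + off_c
        inb = (pr >= 0) & (pr < h) & (pc >= 0) & (pc < w)
        if not inb.any():
            out[k] = "other"
            n_outside += 1
            continue
        lab = labels[pr[inb], pc[inb]]
        counts = np.bincount(lab, minlength=9)
        top = counts.max()
        tied = np.flatnonzero(counts == top)
        if len(tied) == 1:
            ctx = tied[0]
        else:
            d2 = off_d2[inb]
            best = np.inf
            ctx = tied[0]
            for t in tied:
                dt = d2[lab == t].min()
                if dt < best:
                    best, ctx = dt, t
        if ctx == TUMOR_EPITHELIUM:
            out[k] = "tumor_epithelial"
        elif ctx == NORMAL_EPITHELIUM:
            out[k] = "normal_epithelial"
        else:
            out[k] = "other"
    if n_outside:
        logger.warning(
            "%d epithelial nuclei beyond the tissue raster, classed as other",
            n_outside,
        )
    cells.df.loc[cells.df.index[idx], "derived_class"] = out
    return cells
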