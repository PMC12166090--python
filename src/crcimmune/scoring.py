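"""Distance-binned immune profiles, region scores and normalization.

The region score for an immune group (lymphocytes or eosinophils) in a
region (tumor front, tumor center, or anywhere) is

    #{unique immune cells within 200 μm of their nearest tumor cell,
      attributed to the region} / #{tumor cells in the region}

An immune cell is attributed to the region of its *nearest* tumor cell, so
it can never be counted twice across front and center.  Cells belonging to
lymphoid aggregates or lymph nodes are excluded before any counting.

Slide scores are aggregated to patients by tumor-cell-weighted averaging,
and patient scores are min-max scaled per cohort using the 5th and 95th
percentile of the cohort's stage II cases (values outside [0, 1] pass
through unclipped).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .cells import CellTable
from .config import PipelineConfig
from .structures import iel_ratio

logger = logging.getLogger(__name__)

SCORE_GROUPS = {"lymphocyte": "Lym", "eosinophil": "Eos"}
REGION_SUFFIX = {"front": "F", "center": "C", "all": "A"}
SCORE_NAMES = ("LymF", "LymC", "LymA", "EosF", "EosC", "EosA", "IEL")
#: scores whose patient-level weight is the front / center tumor-cell count
_REGION_WEIGHTS = {"LymF": "front", "LymC": "center", "EosF": "front", "EosC": "center"}


@dataclass
class DistanceProfile:
    """Unique immune-cell counts binned by distance to the nearest tumor cell."""

    group: str
    bin_edges: np.ndarray  # length n_bins + 1, in μm
    counts: np.ndarray  # per-bin unique immune-cell count
    n_tumor_total: int

    @property
    def per_tumor_cell(self) -> np.ndarray:
        if self.n_tumor_total == 0:
            return np.full(len(self.counts), np.nan)
        return self.counts / self.n_tumor_total

    def to_frame(self, slide_id: str = "") -> pd.DataFrame:
        return pd.DataFrame(
            {
                "slide_id": slide_id,
                "group": self.group,
                "bin_lo_um": self.bin_edges[:-1],
                "bin_hi_um": self.bin_edges[1:],
                "count": self.counts,
                "per_tumor_cell": self.per_tumor_cell,
            }
        )


@dataclass
class SlideScoreSet:
    """Raw per-slide scores plus the tumor-cell counts needed to aggregate."""

    slide_id: str
    patient_id: str
    cohort_id: str
    scores: dict[str, float]
    n_tumor_front: int
    n_tumor_center: int
    front_missing: bool

    @property
    def n_tumor_total(self) -> int:
        return self.n_tumor_front + self.n_tumor_center

    def weight_for(self, score_name: str) -> int:
        region = _REGION_WEIGHTS.get(score_name)
        if region == "front":
            return self.n_tumor_front
        if region == "center":
            return self.n_tumor_center
        return self.n_tumor_total

    def to_row(self) -> dict:
        row = {
            "slide_id": self.slide_id,
            "patient_id": self.patient_id,
            "cohort_id": self.cohort_id,
            "n_tumor_front": self.n_tumor_front,
            "n_tumor_center": self.n_tumor_center,
            "n_tumor_total": self.n_tumor_total,
            "front_missing": self.front_missing,
        }
        row.update({k: self.scores.get(k, float("nan")) for k in SCORE_NAMES})
        return row


@dataclass
class PatientScoreSet:
    """Tumor-cell-weighted patient-level scores."""

    patient_id: str
    cohort_id: str
    scores: dict[str, float]
    n_slides: int
    n_tumor_total: int

    def to_row(self) -> dict:
        row = {
            "patient_id": self.patient_id,
            "cohort_id": self.cohort_id,
            "n_slides": self.n_slides,
            "n_tumor_total": self.n_tumor_total,
        }
        row.update({k: self.scores.get(k, float("nan")) for k in SCORE_NAMES})
        return row


def _nearest_tumor(cells: CellTable, group: str):
    """Distance and nearest-tumor-cell region for each scorable immune cell."""
    tumor_mask = cells.mask("tumor_epithelial")
    imm_mask = cells.mask(group, include_excluded=False)
    tumor_pts = cells.coords[tumor_mask]
    imm_pts = cells.coords[imm_mask]
    if len(tumor_pts) == 0 or len(imm_pts) == 0:
        return (
            np.full(len(imm_pts), np.inf),
            np.empty(len(imm_pts), dtype=object),
            tumor_mask,
        )
    tree = cKDTree(tumor_pts)
    d, j = tree.query(imm_pts, k=1)
    regions = cells.df["region"].to_numpy()[tumor_mask][j]
    return d, regions, tumor_mask


def distance_profile(
    cells: CellTable, group: str, cfg: PipelineConfig | None = None
) -> DistanceProfile:
    """Bin each immune cell once, by distance to its nearest tumor cell.

    Cells farther than ``max_profile_radius_um`` from every tumor cell are
    not counted.  Normalization uses the whole-slide tumor-cell count.
    """
    cfg = cfg or PipelineConfig()
    edges = np.arange(
        0.0, cfg.max_profile_radius_um + cfg.profile_bin_um, cfg.profile_bin_um
    )
    d, _, tumor_mask = _nearest_tumor(cells, group)
    n_tumor = int(tumor_mask.sum())
    if n_tumor == 0:
        logger.warning("slide %s: no tumor cells, empty profile", cells.slide_id)
        return DistanceProfile(group, edges, np.zeros(len(edges) - 1, dtype=int), 0)
    counts, _ = np.histogram(d[np.isfinite(d)], bins=edges)
    return DistanceProfile(group, edges, counts.astype(int), n_tumor)


def region_score(
    cells: CellTable,
    group: str,
    region: str,
    cfg: PipelineConfig | None = None,
) -> float:
    """Unique immune count within 200 μm per tumor cell of the region.

    ``region`` is ``front``, ``center`` or ``all``.  Distance ties at
    exactly the counting radius are inside.  Returns NaN when the region
    holds no tumor cells, or for front/center on a front-missing slide.
    """
    cfg = cfg or PipelineConfig()
    if region not in ("front", "center", "all"):
        raise ValueError(f"region must be front|center|all, got {region!r}")
    if region != "all" and cells.front_missing:
        return float("nan")
    d, nearest_region, tumor_mask = _nearest_tumor(cells, group)
    if region == "all":
        n_tumor = int(tumor_mask.sum())
    else:
        n_tumor = int(
            (cells.df["region"].to_numpy()[tumor_mask] == region).sum()
        )
    if n_tumor == 0:
        return float("nan")
    within = d <= cfg.count_radius_um
    if region != "all":
        within &= nearest_region == region
    return float(within.sum()) / n_tumor


def slide_scores(cells: CellTable, cfg: PipelineConfig | None = None) -> SlideScoreSet:
    """All six region scores plus the IEL ratio for one processed slide.

    Expects region labels, structure exclusion and IEL flags to be set.
    """
    cfg = cfg or PipelineConfig()
    scores: dict[str, float] = {}
    for group, prefix in SCORE_GROUPS.items():
        for region, suffix in REGION_SUFFIX.items():
            scores[prefix + suffix] = region_score(cells, group, region, cfg)
    scores["IEL"] = iel_ratio(cells, cfg)
    region_col = cells.df["region"].to_numpy()[cells.mask("tumor_epithelial")]
    return SlideScoreSet(
        slide_id=cells.slide_id,
        patient_id=cells.patient_id,
        cohort_id=cells.cohort_id,
        scores=scores,
        n_tumor_front=int((region_col == "front").sum()),
        n_tumor_center=int((region_col == "center").sum()),
        front_missing=cells.front_missing,
    )


def aggregate_patient(slide_sets: list[SlideScoreSet]) -> PatientScoreSet:
    """Tumor-cell-weighted average of slide scores for one patient.

    Each score is weighted by the slide's tumor-cell count in the score's
    scope (front / center count for region scores, total otherwise); slides
    with a missing value for a score are dropped from that score's average.
    """
    if not slide_sets:
        raise ValueError("aggregate_patient needs at least one slide")
    pids = {s.patient_id for s in slide_sets}
    if len(pids) > 1:
        raise ValueError(f"slides from multiple patients: {sorted(pids)}")
    scores: dict[str, float] = {}
    for name in SCORE_NAMES:
        num = den = 0.0
        for s in slide_sets:
            v = s.scores.get(name, float("nan"))
            w = s.weight_for(name)
            if not math.isnan(v) and w > 0:
                num += v * w
                den += w
        scores[name] = num / den if den > 0 else float("nan")
    return PatientScoreSet(
        patient_id=slide_sets[0].patient_id,
        cohort_id=slide_sets[0].cohort_id,
        scores=scores,
        n_slides=len(slide_sets),
        n_tumor_total=sum(s.n_tumor_total for s in slide_sets),
    )


@dataclass
class NormalizationParams:
    """Per-cohort × score 5th/95th stage-II percentiles for min-max scaling."""

    table: pd.DataFrame = field(default_factory=pd.DataFrame)
    # columns: cohort_id, score, p_lo, p_hi

    def lookup(self, cohort_id: str, score: str) -> tuple[float, float]:
        sub = self.table[
            (self.table["cohort_id"] == cohort_id) & (self.table["score"] == score)
        ]
        if len(sub) != 1:
            raise KeyError(f"no normalization params for ({cohort_id}, {score})")
        return float(sub["p_lo"].iloc[0]), float(sub["p_hi"].iloc[0])


def fit_normalization(
    patients: pd.DataFrame,
    score_cols: list[str] | tuple[str, ...] = SCORE_NAMES,
    stage_col: str = "stage",
    cohort_col: str = "cohort_id",
    cfg: PipelineConfig | None = None,
    stage_ii_value=2,
) -> NormalizationParams:
    """Percentiles of the stage II score distribution, per cohort.

    Percentiles use the linear-interpolation definition.  Raises when a
    cohort has fewer than two stage II patients with a non-missing score.
    """
    cfg = cfg or PipelineConfig()
    rows = []
    for cohort_id, sub in patients.groupby(cohort_col, sort=True):
        stage2 = sub[sub[stage_col] == stage_ii_value]
        for score in score_cols:
            vals = stage2[score].dropna().to_numpy(dtype=float)
            if len(vals) < 2:
                raise ValueError(
                    f"cohort {cohort_id!r}: fewer than 2 stage II patients "
                    f"with non-missing {score}"
                )
            p_lo, p_hi = np.percentile(
                vals, [cfg.norm_lo_percentile, cfg.norm_hi_percentile]
            )
            rows.append(
                {"cohort_id": cohort_id, "score": score, "p_lo": p_lo, "p_hi": p_hi}
            )
    return NormalizationParams(pd.DataFrame(rows))


def apply_normalization(x, p_lo: float, p_hi: float):
    """Min-max scale; values outside [0, 1] pass through unclipped."""
    if not p_hi > p_lo:
        raise ValueError(f"degenerate normalization range [{p_lo}, {p_hi}]")
    return (np.asarray(x, dtype=float) - p_lo) / (p_hi - p_lo)


def normalize_patients(
    patients: pd.DataFrame,
    params: NormalizationParams,
    score_cols: list[str] | tuple[str, ...] = SCORE_NAMES,
    cohort_col: str = "cohort_id",
) -> pd.DataFrame:
    """Return a copy with each score column min-max scaled per cohort."""
    out = patients.copy()
    for cohort_id, sub in patients.groupby(cohort_col, sort=True):
        for score in score_cols:
            p_lo, p_hi = params.lookup(cohort_id, score)
            out.loc[sub.index, score] = apply_normalization(
                sub[score].to_numpy(dtype=float), p_lo, p_hi
            )
    return out


def slide_scores_frame(slide_sets: list[SlideScoreSet]) -> pd.DataFrame:
    return pd.DataFrame([s.to_row() for s in slide_sets])


def patient_scores_frame(patient_sets: list[PatientScoreSet]) -> pd.DataFrame:
    return pd.DataFrame([p.to_row() for p in patient_sets])
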