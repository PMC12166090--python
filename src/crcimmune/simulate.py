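"""Synthetic slides and cohorts with known ground truth.

Real inputs to this pipeline are nuclei detections and tissue-type maps
from H&E whole-slide images plus clinical follow-up — none of which can be
bundled.  This module generates stand-ins with the structural features the
pipeline exploits, each with recorded ground truth:

* layered tissue geometry: an optional normal-mucosa band, a tumor band,
  a stroma gap and a muscle band (with optional adipose strip), laid out
  along x so the true invasive front is a known vertical midline;
* tumor cells as a homogeneous Poisson process on the tumor band and
  immune cells as an inhomogeneous Poisson process whose intensity decays
  exponentially with distance to the nearest tumor cell (highest abundance
  close to tumor, declining toward 500 μm);
* planted Gaussian lymphocyte clusters dense enough that 20 μm linkage is
  guaranteed, emulating lymphoid aggregates and lymph nodes;
* intraepithelial lymphocytes planted next to a controlled fraction of
  tumor cells;
* patient cohorts with clinicopathological covariates, a correlated
  log-normal score block (Gaussian copula) and survival times drawn under
  a proportional-hazards model with specified per-covariate log hazard
  ratios, followed by random censoring.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .cells import CellTable, cell_table_from_arrays
from .config import PipelineConfig
from .tissue import (
    ADIPOSE,
    MUSCLE,
    NORMAL_EPITHELIUM,
    STROMA,
    TUMOR_EPITHELIUM,
    TissueMap,
)

# ---------------------------------------------------------------------------
# slides


@dataclass
class AggregateSpec:
    """A planted dense lymphocyte cluster (aggregate or lymph node).

    Points follow an isotropic Gaussian truncated at 1.5σ; with the default
    dispersion the expected number of linkage neighbors stays ≳20 even at
    the truncation edge, so every planted cell links into one connected
    component at the 20 μm radius with overwhelming probability.
    """

    center_um: tuple[float, float]
    n_cells: int
    sigma_um: float | None = None  # default keeps NN spacing ≪ 20 μm
    truncate_sigmas: float = 1.5

    def resolved_sigma(self) -> float:
        return self.sigma_um if self.sigma_um is not None else 2.0 * math.sqrt(self.n_cells)


@dataclass
class SlideSimSpec:
    """Geometry and intensity model for one synthetic slide.

    Bands are laid out along x: ``[0, normal_band_um)`` normal epithelium,
    then stroma, ``[tumor_x0_um, tumor_x1_um)`` tumor epithelium, a stroma
    gap of ``gap_um``, then muscle to the right edge (the last
    ``adipose_band_um`` of it adipose).  The analytic invasive front is the
    vertical line ``x = tumor_x1_um + gap_um / 2``.

    Intensities are cells/mm².  Immune intensity at a point s is
    ``base · exp(−d(s)/λ)`` with d(s) the distance to the nearest tumor
    cell, emulating the observed decay of immune abundance with distance
    to tumor.
    """

    width_um: float = 4000.0
    height_um: float = 3000.0
    mpp: float = 4.0
    normal_band_um: float = 0.0
    tumor_x0_um: float = 1200.0
    tumor_x1_um: float = 2400.0
    gap_um: float = 200.0
    adipose_band_um: float = 0.0
    tumor_cell_density_per_mm2: float = 1500.0
    connective_density_per_mm2: float = 200.0
    lymphocyte_base_per_mm2: float = 800.0
    lymphocyte_decay_um: float = 150.0
    # lymphocyte intensity multiplier inside the tumor epithelium band:
    # stromal lymphocytes are far denser than intraepithelial ones, whose
    # supply is governed separately by iel_rate
    lymphocyte_intraepithelial_factor: float = 0.1
    eosinophil_base_per_mm2: float = 120.0
    eosinophil_decay_um: float = 120.0
    iel_rate: float = 0.15
    aggregates: list[AggregateSpec] = field(default_factory=list)
    rng_seed: int = 0

    def validate(self) -> None:
        if not (0 <= self.tumor_x0_um < self.tumor_x1_um <= self.width_um):
            raise ValueError("tumor band must lie inside the canvas")
        if self.normal_band_um > self.tumor_x0_um:
            raise ValueError("normal band overlaps the tumor band")
        if not 0 <= self.iel_rate <= 1:
            raise ValueError("iel_rate must be in [0, 1]")
        for name in (
            "tumor_cell_density_per_mm2",
            "connective_density_per_mm2",
            "lymphocyte_base_per_mm2",
            "eosinophil_base_per_mm2",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be ≥ 0")

    @property
    def front_x_um(self) -> float:
        return self.tumor_x1_um + self.gap_um / 2.0


@dataclass
class SlideGroundTruth:
    """What the generator knows about a simulated slide."""

    spec: SlideSimSpec
    front_x_um: float
    tumor_region: np.ndarray  # 'front' | 'center' per tumor cell (gen order)
    tumor_index: np.ndarray  # row indices of tumor cells in the CellTable
    aggregate_members: list[np.ndarray]  # row indices per planted cluster
    n_planted_iels: int


def _poisson_uniform(rng, density_per_mm2, x0, x1, y0, y1):
    area_mm2 = (x1 - x0) * (y1 - y0) / 1e6
    n = rng.poisson(density_per_mm2 * area_mm2)
    xs = rng.uniform(x0, x1, n)
    ys = rng.uniform(y0, y1, n)
    return xs, ys


def _thinned_immune(rng, spec: SlideSimSpec, base, lam, tumor_pts, intra_factor=1.0):
    """Inhomogeneous Poisson via thinning of a homogeneous process at rate base."""
    xs, ys = _poisson_uniform(rng, base, 0, spec.width_um, 0, spec.height_um)
    if len(xs) == 0 or len(tumor_pts) == 0:
        return xs[:0], ys[:0]
    d, _ = cKDTree(tumor_pts).query(np.column_stack([xs, ys]), k=1)
    accept = np.exp(-d / lam)
    if intra_factor != 1.0:
        in_band = (xs >= spec.tumor_x0_um) & (xs < spec.tumor_x1_um)
        accept = np.where(in_band, accept * intra_factor, accept)
    keep = rng.random(len(xs)) < accept
    return xs[keep], ys[keep]


def build_tissue_raster(spec: SlideSimSpec) -> TissueMap:
    """Rasterize the band geometry at the spec's resolution."""
    w_px = int(round(spec.width_um / spec.mpp))
    h_px = int(round(spec.height_um / spec.mpp))
    labels = np.full((h_px, w_px), STROMA, dtype=np.uint8)
    xc = (np.arange(w_px) + 0.5) * spec.mpp
    if spec.normal_band_um > 0:
        labels[:, xc < spec.normal_band_um] = NORMAL_EPITHELIUM
    labels[:, (xc >= spec.tumor_x0_um) & (xc < spec.tumor_x1_um)] = TUMOR_EPITHELIUM
    muscle_x0 = spec.tumor_x1_um + spec.gap_um
    labels[:, xc >= muscle_x0] = MUSCLE
    if spec.adipose_band_um > 0:
        labels[:, xc >= spec.width_um - spec.adipose_band_um] = ADIPOSE
    return TissueMap(labels, spec.mpp)


def simulate_slide(
    spec: SlideSimSpec,
    slide_id: str = "S1",
    patient_id: str = "P1",
    cohort_id: str = "C1",
    rng: np.random.Generator | None = None,
) -> tuple[TissueMap, CellTable, SlideGroundTruth]:
    """Draw one synthetic slide: tissue raster, cell table, ground truth."""
    spec.validate()
    rng = rng or np.random.default_rng(spec.rng_seed)
    cfg = PipelineConfig()
    tmap = build_tissue_raster(spec)

    tx, ty = _poisson_uniform(
        rng, spec.tumor_cell_density_per_mm2,
        spec.tumor_x0_um, spec.tumor_x1_um, 0, spec.height_um,
    )
    tumor_pts = np.column_stack([tx, ty])
    true_region = np.where(
        np.abs(tx - spec.front_x_um) <= cfg.front_band_halfwidth_um, "front", "center"
    )

    lx, ly = _thinned_immune(
        rng, spec, spec.lymphocyte_base_per_mm2, spec.lymphocyte_decay_um, tumor_pts,
        intra_factor=spec.lymphocyte_intraepithelial_factor,
    )
    ex, ey = _thinned_immune(
        rng, spec, spec.eosinophil_base_per_mm2, spec.eosinophil_decay_um, tumor_pts
    )
    cx, cy = _poisson_uniform(
        rng, spec.connective_density_per_mm2, 0, spec.width_um, 0, spec.height_um
    )

    # planted IELs: a lymphocyte 2–8 μm from a random subset of tumor cells
    iel_mask = rng.random(len(tx)) < spec.iel_rate
    n_iel = int(iel_mask.sum())
    ang = rng.uniform(0, 2 * np.pi, n_iel)
    rad = rng.uniform(2.0, 8.0, n_iel)
    ix = tx[iel_mask] + rad * np.cos(ang)
    iy = ty[iel_mask] + rad * np.sin(ang)

    # planted dense clusters (truncated Gaussian, see AggregateSpec)
    agg_xy = []
    for agg in spec.aggregates:
        sigma = agg.resolved_sigma()
        center = np.asarray(agg.center_um, dtype=float)
        r_max2 = (agg.truncate_sigmas * sigma) ** 2
        pts = np.empty((0, 2))
        while len(pts) < agg.n_cells:
            cand = rng.normal(loc=center, scale=sigma, size=(agg.n_cells * 2, 2))
            ok = ((cand - center) ** 2).sum(axis=1) <= r_max2
            pts = np.vstack([pts, cand[ok]])
        agg_xy.append(pts[: agg.n_cells])

    parts = [
        (tx, ty, "epithelial"),
        (lx, ly, "lymphocyte"),
        (ix, iy, "lymphocyte"),
        (ex, ey, "eosinophil"),
        (cx, cy, "connective"),
    ]
    xs = [p[0] for p in parts]
    ys = [p[1] for p in parts]
    cls = [np.full(len(p[0]), p[2], dtype=object) for p in parts]
    agg_members: list[np.ndarray] = []
    offset = sum(len(x) for x in xs)
    for pts in agg_xy:
        xs.append(pts[:, 0])
        ys.append(pts[:, 1])
        cls.append(np.full(len(pts), "lymphocyte", dtype=object))
        agg_members.append(np.arange(offset, offset + len(pts)))
        offset += len(pts)

    x_all = np.concatenate(xs) if xs else np.empty(0)
    y_all = np.concatenate(ys) if ys else np.empty(0)
    c_all = np.concatenate(cls) if cls else np.empty(0, dtype=object)
    table = cell_table_from_arrays(
        x_all, y_all, c_all,
        slide_id=slide_id, patient_id=patient_id, cohort_id=cohort_id,
    )
    truth = SlideGroundTruth(
        spec=spec,
        front_x_um=spec.front_x_um,
        tumor_region=true_region,
        tumor_index=np.arange(len(tx)),
        aggregate_members=agg_members,
        n_planted_iels=n_iel,
    )
    return tmap, table, truth


def expected_score(
    tumor_pts: np.ndarray,
    base_per_mm2: float,
    decay_um: float,
    spec: SlideSimSpec,
    radius_um: float = 200.0,
    grid_um: float = 4.0,
    intra_factor: float = 1.0,
) -> float:
    """Expected immune cells within ``radius_um`` of tumor, per tumor cell.

    Numerical integral of the generating intensity over the canvas region
    within ``radius_um`` of the nearest tumor cell, divided by the tumor
    cell count — the generator-side expectation of the unique-count score.
    """
    if len(tumor_pts) == 0:
        return float("nan")
    gx = np.arange(grid_um / 2, spec.width_um, grid_um)
    gy = np.arange(grid_um / 2, spec.height_um, grid_um)
    xx, yy = np.meshgrid(gx, gy)
    pts = np.column_stack([xx.ravel(), yy.ravel()])
    d, _ = cKDTree(tumor_pts).query(pts, k=1)
    inside = d <= radius_um
    rate = base_per_mm2 * np.exp(-d[inside] / decay_um)
    if intra_factor != 1.0:
        in_band = (pts[inside, 0] >= spec.tumor_x0_um) & (
            pts[inside, 0] < spec.tumor_x1_um
        )
        rate = np.where(in_band, rate * intra_factor, rate)
    cell_mm2 = grid_um * grid_um / 1e6
    return float(np.sum(rate) * cell_mm2) / len(tumor_pts)


# ---------------------------------------------------------------------------
# cohorts


@dataclass
class CohortSimSpec:
    """Generating model for a synthetic patient cohort.

    Scores are drawn from a Gaussian copula with log-normal marginals; the
    latent structure ties the front scores together (target rank
    correlation ``rho_lymf_eosf``, default 0.64), front to center scores at
    ~0.63, and leaves the IEL ratio essentially independent of the
    eosinophil scores, mirroring the observed correlation structure of
    region-resolved immune scores.

    Survival: TTR is exponential with rate
    ``baseline_hazard_per_month · exp(Σ β_j z_j)`` where z are the analysis
    covariates (log1p of lymphocyte/eosinophil scores, raw IEL ratio,
    centered/scaled clinical covariates) and β = log of ``true_hr``.
    Censoring time is uniform on ``censoring_range_months``; the five-year
    endpoint cutoff is applied downstream, not here.
    """

    n_patients: int = 1122
    cohort_id: str = "SIM"
    rho_lymf_eosf: float = 0.64
    rho_front_center: float = 0.63
    rho_iel_lymc: float = 0.35
    score_log_mean: float = math.log(0.45)
    score_log_sd: float = 0.55
    iel_log_mean: float = math.log(0.20)
    iel_log_sd: float = 0.60
    msi_prevalence: float = 0.19
    stage_probs: tuple[float, ...] = (0.15, 0.42, 0.28, 0.15)
    pt_probs: tuple[float, ...] = (0.08, 0.17, 0.55, 0.20)
    pn_probs: tuple[float, ...] = (0.55, 0.25, 0.20)
    chemo_rate: float = 0.30
    right_sided_rate: float = 0.40
    true_hr: dict[str, float] = field(
        default_factory=lambda: {
            "LymF": 0.59,
            "EosF": 0.70,
            "IEL": 0.34,
            "age_dec": 1.15,
            "sex": 1.05,
            "location": 1.05,
            "pT": 1.45,
            "pN": 1.60,
            "chemo": 0.90,
            "msi": 0.70,
        }
    )
    # calibrated so the five-year TTR analysis sees ≈229 events at n=1122
    baseline_hazard_per_month: float = 0.0066
    censoring_range_months: tuple[float, float] = (6.0, 120.0)
    rng_seed: int = 0

    def validate(self) -> None:
        for p in (self.msi_prevalence, self.chemo_rate, self.right_sided_rate):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must be in [0, 1]")
        for probs in (self.stage_probs, self.pt_probs, self.pn_probs):
            if abs(sum(probs) - 1) > 1e-9:
                raise ValueError("categorical probabilities must sum to 1")
        if any(h <= 0 for h in self.true_hr.values()):
            raise ValueError("hazard ratios must be > 0")


def _rank_to_pearson(rho_s: float) -> float:
    """Pearson correlation of a bivariate normal with Spearman rho_s."""
    return 2.0 * math.sin(math.pi * rho_s / 6.0)


def _simulate_scores(rng, spec: CohortSimSpec, n: int) -> pd.DataFrame:
    r_fe = _rank_to_pearson(spec.rho_lymf_eosf)
    r_fc = _rank_to_pearson(spec.rho_front_center)
    r_il = _rank_to_pearson(spec.rho_iel_lymc)
    z_lymf = rng.standard_normal(n)
    z_eosf = r_fe * z_lymf + math.sqrt(1 - r_fe**2) * rng.standard_normal(n)
    z_lymc = r_fc * z_lymf + math.sqrt(1 - r_fc**2) * rng.standard_normal(n)
    z_eosc = r_fc * z_eosf + math.sqrt(1 - r_fc**2) * rng.standard_normal(n)
    z_lyma = (z_lymf + z_lymc) / math.sqrt(2 * (1 + r_fc))
    z_eosa = (z_eosf + z_eosc) / math.sqrt(2 * (1 + r_fc))
    z_iel = r_il * z_lymc + math.sqrt(1 - r_il**2) * rng.standard_normal(n)

    def lognorm(z, mu, sd):
        return np.exp(mu + sd * z)

    return pd.DataFrame(
        {
            "LymF": lognorm(z_lymf, spec.score_log_mean, spec.score_log_sd),
            "LymC": lognorm(z_lymc, spec.score_log_mean, spec.score_log_sd),
            "LymA": lognorm(z_lyma, spec.score_log_mean, spec.score_log_sd),
            "EosF": lognorm(z_eosf, spec.score_log_mean, spec.score_log_sd),
            "EosC": lognorm(z_eosc, spec.score_log_mean, spec.score_log_sd),
            "EosA": lognorm(z_eosa, spec.score_log_mean, spec.score_log_sd),
            "IEL": lognorm(z_iel, spec.iel_log_mean, spec.iel_log_sd),
        }
    )


def analysis_covariates(frame: pd.DataFrame) -> pd.DataFrame:
    """Covariates on the scale the Cox models (and the generator) use."""
    z = pd.DataFrame(index=frame.index)
    for col in ("LymF", "LymC", "LymA", "EosF", "EosC", "EosA"):
        if col in frame:
            z[col] = np.log1p(np.clip(frame[col].to_numpy(dtype=float), 0, None))
    if "IEL" in frame:
        z["IEL"] = frame["IEL"].astype(float)
    z["age_dec"] = (frame["age"].astype(float) - 65.0) / 10.0
    for col in ("sex", "location", "chemo", "msi"):
        z[col] = frame[col].astype(float)
    z["pT"] = frame["pT"].astype(float) - 3.0
    z["pN"] = frame["pN"].astype(float)
    return z


def simulate_cohort(
    spec: CohortSimSpec, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, dict]:
    """Draw one synthetic cohort; returns (CohortFrame, truth bundle)."""
    spec.validate()
    rng = rng or np.random.default_rng(spec.rng_seed)
    n = spec.n_patients

    frame = pd.DataFrame(
        {
            "patient_id": [f"{spec.cohort_id}-{i:05d}" for i in range(n)],
            "cohort_id": spec.cohort_id,
            "age": np.clip(rng.normal(68, 11, n), 30, 95).round(1),
            "sex": rng.binomial(1, 0.5, n),
            "location": rng.binomial(1, spec.right_sided_rate, n),
            "pT": rng.choice([1, 2, 3, 4], n, p=spec.pt_probs),
            "pN": rng.choice([0, 1, 2], n, p=spec.pn_probs),
            "stage": rng.choice([1, 2, 3, 4], n, p=spec.stage_probs),
            "grade": rng.choice([1, 2, 3], n, p=[0.2, 0.6, 0.2]),
            "msi": rng.binomial(1, spec.msi_prevalence, n),
            "chemo": rng.binomial(1, spec.chemo_rate, n),
        }
    )
    frame = pd.concat([frame, _simulate_scores(rng, spec, n)], axis=1)

    z = analysis_covariates(frame)
    eta = np.zeros(n)
    for name, hr in spec.true_hr.items():
        if name not in z.columns:
            raise ValueError(f"true_hr key {name!r} is not an analysis covariate")
        eta += math.log(hr) * z[name].to_numpy(dtype=float)
    rate = spec.baseline_hazard_per_month * np.exp(eta)
    t_event = rng.exponential(1.0 / rate)
    c_lo, c_hi = spec.censoring_range_months
    t_cens = rng.uniform(c_lo, c_hi, n)
    frame["followup_months"] = np.minimum(t_event, t_cens)
    frame["event"] = (t_event <= t_cens).astype(int)

    truth = {
        "true_hr": dict(spec.true_hr),
        "true_log_hr": {k: math.log(v) for k, v in spec.true_hr.items()},
        "baseline_hazard_per_month": spec.baseline_hazard_per_month,
        "rng_seed": spec.rng_seed,
        "n_patients": n,
        "n_events": int(frame["event"].sum()),
    }
    return frame, truth


def simulate_study(
    out_dir,
    n_patients: int = 5,
    seed: int = 0,
    two_slide_patients: int = 1,
    slide_spec: SlideSimSpec | None = None,
) -> None:
    """Write a small end-to-end study: slide files plus a cohort table.

    Produces ``<slide_id>_cells.csv`` / ``<slide_id>_tissue.png`` (+ mpp
    sidecar) per slide, ``cohort.csv`` with covariates and follow-up, and
    ``truth.json``.  The first ``two_slide_patients`` patients get two
    slides to exercise tumor-cell-weighted aggregation; per-patient immune
    levels vary through a log-normal multiplier on the base intensities.
    At least two patients are forced to stage II so percentile
    normalization is identifiable.
    """
    import json
    from pathlib import Path

    from .cells import write_detections
    from .tissue import write_tissue_map

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    base = slide_spec or SlideSimSpec(
        width_um=3000.0,
        height_um=1500.0,
        tumor_x0_um=1000.0,
        tumor_x1_um=1800.0,
        gap_um=200.0,
    )
    cohort_spec = CohortSimSpec(n_patients=n_patients, cohort_id="SIM")
    cohort, truth = simulate_cohort(cohort_spec, rng=rng)
    cohort.loc[cohort.index[: max(2, min(2, n_patients))], "stage"] = 2
    cohort = cohort.drop(columns=["LymF", "LymC", "LymA", "EosF", "EosC", "EosA", "IEL"])

    slide_rows = []
    for i in range(n_patients):
        pid = cohort["patient_id"].iloc[i]
        n_slides = 2 if i < two_slide_patients else 1
        lym_mult = float(np.exp(rng.normal(0, 0.4)))
        eos_mult = float(np.exp(rng.normal(0, 0.5)))
        for s in range(n_slides):
            sid = f"{pid}-s{s}"
            spec = SlideSimSpec(
                **{
                    **base.__dict__,
                    "lymphocyte_base_per_mm2": base.lymphocyte_base_per_mm2 * lym_mult,
                    "eosinophil_base_per_mm2": base.eosinophil_base_per_mm2 * eos_mult,
                }
            )
            tmap, cells, _ = simulate_slide(
                spec, slide_id=sid, patient_id=pid, cohort_id="SIM", rng=rng
            )
            write_detections(cells, out_dir / f"{sid}_cells.csv")
            write_tissue_map(tmap, out_dir / f"{sid}_tissue.png")
            slide_rows.append({"slide_id": sid, "patient_id": pid})
    cohort.to_csv(out_dir / "cohort.csv", index=False)
    with open(out_dir / "truth.json", "w") as fh:
        json.dump({**truth, "seed": seed, "slides": slide_rows}, fh, indent=2)
        fh.write("\n")


def simulate_null_cohort(
    n: int, rng: np.random.Generator, spec: CohortSimSpec | None = None
) -> pd.DataFrame:
    """A cohort whose scores have zero true effect on the hazard."""
    spec = spec or CohortSimSpec()
    null_spec = CohortSimSpec(
        **{
            **spec.__dict__,
            "n_patients": n,
            "true_hr": {k: 1.0 for k in ("LymF", "EosF", "IEL")},
        }
    )
    frame, _ = simulate_cohort(null_spec, rng=rng)
    return frame
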