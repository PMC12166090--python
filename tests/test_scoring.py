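"""Distance profiles, unique-count region scores, aggregation, normalization."""

import numpy as np
import pandas as pd
import pytest

from crcimmune import PipelineConfig
from crcimmune.cells import cell_table_from_arrays
from crcimmune.scoring import (
    SCORE_NAMES,
    SlideScoreSet,
    aggregate_patient,
    apply_normalization,
    distance_profile,
    fit_normalization,
    normalize_patients,
    region_score,
)


def build_slide(tumor_xy, immune_xy, group="eosinophil", regions=None):
    """CellTable with explicit tumor and immune positions; regions optional."""
    tumor_xy = np.asarray(tumor_xy, dtype=float).reshape(-1, 2)
    immune_xy = np.asarray(immune_xy, dtype=float).reshape(-1, 2)
    n_t, n_i = len(tumor_xy), len(immune_xy)
    raw_imm = "eosinophil" if group == "eosinophil" else "lymphocyte"
    cells = cell_table_from_arrays(
        np.concatenate([tumor_xy[:, 0], immune_xy[:, 0]]),
        np.concatenate([tumor_xy[:, 1], immune_xy[:, 1]]),
        ["epithelial"] * n_t + [raw_imm] * n_i,
    )
    cells.df.loc[: n_t - 1, "derived_class"] = "tumor_epithelial"
    cells.df.loc[: n_t - 1, "region"] = regions if regions is not None else "front"
    return cells


class TestDistanceProfile:
    def test_binning_and_truncation(self, cfg):
        cells = build_slide([(0, 0)], [(5, 0), (15, 0), (0, 15), (600, 0)])
        prof = distance_profile(cells, "eosinophil", cfg)
        assert prof.counts[0] == 1 and prof.counts[1] == 2
        assert prof.counts[2:].sum() == 0  # the 600 μm cell is uncounted
        assert len(prof.counts) == 50

    def test_counted_once_at_nearer_tumor_cell(self, cfg):
        # one lymphocyte between two tumor cells 10 μm apart: single count
        cells = build_slide([(0, 0), (10, 0)], [(4, 0)], group="lymphocyte")
        prof = distance_profile(cells, "lymphocyte", cfg)
        assert prof.counts.sum() == 1
        assert prof.counts[0] == 1  # nearer distance 4 μm, bin [0, 10)

    def test_matches_brute_force_nearest_neighbor(self, cfg):
        rng = np.random.default_rng(12)
        tumor = rng.uniform(0, 800, size=(60, 2))
        imm = rng.uniform(-100, 900, size=(440, 2))
        cells = build_slide(tumor, imm)
        prof = distance_profile(cells, "eosinophil", cfg)
        d = np.sqrt(((imm[:, None, :] - tumor[None, :, :]) ** 2).sum(-1)).min(1)
        ref, _ = np.histogram(d, bins=prof.bin_edges)
        assert np.array_equal(prof.counts, ref)
        assert prof.counts.sum() == (d < 500).sum()

    def test_no_tumor_cells_empty_profile(self, cfg):
        cells = build_slide(np.empty((0, 2)), [(0, 0)])
        prof = distance_profile(cells, "eosinophil", cfg)
        assert prof.counts.sum() == 0 and np.isnan(prof.per_tumor_cell).all()

    def test_excluded_cells_uncounted(self, cfg):
        cells = build_slide([(0, 0)], [(5, 0)])
        cells.df.loc[cells.df.index[-1], "excluded"] = True
        assert distance_profile(cells, "eosinophil", cfg).counts.sum() == 0


class TestRegionScore:
    def test_front_score(self, cfg):
        cells = build_slide(
            [(0, 0), (100, 0)], [(10, 0), (50, 50), (150, 0)], regions="front"
        )
        assert region_score(cells, "eosinophil", "front", cfg) == pytest.approx(1.5)

    def test_beyond_radius_contributes_zero(self, cfg):
        cells = build_slide([(0, 0)], [(250, 0)])
        assert region_score(cells, "eosinophil", "all", cfg) == 0.0

    def test_tie_at_radius_counts(self, cfg):
        cells = build_slide([(0, 0)], [(200.0, 0)])
        assert region_score(cells, "eosinophil", "all", cfg) == 1.0

    def test_front_missing_region_scores_nan(self, cfg):
        cells = build_slide([(0, 0)], [(10, 0)], regions="center")
        cells.front_missing = True
        assert np.isnan(region_score(cells, "eosinophil", "front", cfg))
        assert region_score(cells, "eosinophil", "all", cfg) == 1.0

    def test_empty_region_missing(self, cfg):
        cells = build_slide([(0, 0)], [(10, 0)], regions="center")
        assert np.isnan(region_score(cells, "eosinophil", "front", cfg))

    def test_conservation_front_plus_center(self, cfg):
        """EosF·n_front + EosC·n_center = unique eosinophils ≤200 μm of tumor."""
        rng = np.random.default_rng(21)
        for trial in range(20):
            n_t, n_i = 40, 150
            tumor = rng.uniform(0, 1000, size=(n_t, 2))
            imm = rng.uniform(-200, 1200, size=(n_i, 2))
            regions = rng.choice(["front", "center"], n_t)
            cells = build_slide(tumor, imm, regions=regions)
            f = region_score(cells, "eosinophil", "front", cfg)
            c = region_score(cells, "eosinophil", "center", cfg)
            n_f = int((regions == "front").sum())
            n_c = n_t - n_f
            d = np.sqrt(((imm[:, None, :] - tumor[None, :, :]) ** 2).sum(-1)).min(1)
            total = int((d <= 200.0).sum())
            f = 0.0 if np.isnan(f) else f
            c = 0.0 if np.isnan(c) else c
            assert f * n_f + c * n_c == pytest.approx(total)

    def test_monotone_in_count_radius(self, cfg):
        rng = np.random.default_rng(22)
        cells = build_slide(
            rng.uniform(0, 500, size=(20, 2)), rng.uniform(0, 500, size=(100, 2))
        )
        scores = [
            region_score(cells, "eosinophil", "all", PipelineConfig(count_radius_um=r))
            for r in (50, 100, 200, 400)
        ]
        assert all(a <= b for a, b in zip(scores, scores[1:]))


def make_set(scores, n_front, n_center, slide_id="s", front_missing=False):
    return SlideScoreSet(
        slide_id=slide_id, patient_id="P1", cohort_id="C1",
        scores=scores, n_tumor_front=n_front, n_tumor_center=n_center,
        front_missing=front_missing,
    )


class TestAggregatePatient:
    def test_tumor_cell_weighted_mean(self):
        a = make_set({"EosF": 0.10}, 1000, 0, "a")
        b = make_set({"EosF": 0.40}, 3000, 0, "b")
        pat = aggregate_patient([a, b])
        assert pat.scores["EosF"] == pytest.approx(0.325)

    def test_single_slide_identity(self):
        a = make_set(dict.fromkeys(SCORE_NAMES, 0.2), 10, 20)
        pat = aggregate_patient([a])
        for name in SCORE_NAMES:
            assert pat.scores[name] == pytest.approx(0.2)

    def test_front_missing_slide_dropped_from_region_scores(self):
        a = make_set({"EosF": 0.10, "EosA": 0.05}, 1000, 0, "a")
        b = make_set(
            {"EosF": float("nan"), "EosA": 0.15}, 0, 2000, "b", front_missing=True
        )
        pat = aggregate_patient([a, b])
        assert pat.scores["EosF"] == pytest.approx(0.10)
        assert pat.scores["EosA"] == pytest.approx((0.05 * 1000 + 0.15 * 2000) / 3000)

    def test_within_min_max_bounds(self):
        rng = np.random.default_rng(3)
        sets = [
            make_set({"LymA": float(v)}, int(w), int(w), str(i))
            for i, (v, w) in enumerate(zip(rng.uniform(0, 1, 8),
                                           rng.integers(100, 5000, 8)))
        ]
        pat = aggregate_patient(sets)
        vals = [s.scores["LymA"] for s in sets]
        assert min(vals) <= pat.scores["LymA"] <= max(vals)

    def test_all_missing_gives_missing(self):
        a = make_set({"EosF": float("nan")}, 0, 100, front_missing=True)
        assert np.isnan(aggregate_patient([a]).scores["EosF"])


def patient_frame(values, stage=2, cohort="C1", score="EosF"):
    return pd.DataFrame(
        {
            "patient_id": [f"p{i}" for i in range(len(values))],
            "cohort_id": cohort,
            "stage": stage,
            score: values,
        }
    )


class TestNormalization:
    def test_uniform_grid_percentiles(self, cfg):
        frame = patient_frame(np.linspace(0, 100, 101))
        params = fit_normalization(frame, ["EosF"], cfg=cfg)
        p_lo, p_hi = params.lookup("C1", "EosF")
        assert p_lo == pytest.approx(5.0) and p_hi == pytest.approx(95.0)

    def test_stage_ii_only(self, cfg):
        frame = patient_frame(np.linspace(0, 100, 101))
        other = patient_frame(np.full(50, 1e6), stage=3)
        other["patient_id"] = [f"q{i}" for i in range(50)]
        both = pd.concat([frame, other], ignore_index=True)
        params = fit_normalization(both, ["EosF"], cfg=cfg)
        assert params.lookup("C1", "EosF") == fit_normalization(
            frame, ["EosF"], cfg=cfg
        ).lookup("C1", "EosF")

    def test_insufficient_stage_ii_raises(self, cfg):
        frame = patient_frame([1.0, 2.0, 3.0], stage=3)
        with pytest.raises(ValueError, match="C1"):
            fit_normalization(frame, ["EosF"], cfg=cfg)

    def test_endpoints_map_to_unit_interval(self):
        assert apply_normalization(2.0, 2.0, 10.0) == 0.0
        assert apply_normalization(10.0, 2.0, 10.0) == 1.0

    def test_values_above_p95_exceed_one_unclipped(self):
        out = apply_normalization(np.array([-1.0, 20.0]), 2.0, 10.0)
        assert out[0] < 0 and out[1] > 1.0

    def test_degenerate_range_raises(self):
        with pytest.raises(ValueError, match="degenerate"):
            apply_normalization(1.0, 3.0, 3.0)

    def test_affine_invariance(self, cfg):
        rng = np.random.default_rng(6)
        x = rng.uniform(0, 10, 60)
        a, b = 3.7, -1.2
        f1 = patient_frame(x)
        f2 = patient_frame(a * x + b)
        n1 = normalize_patients(f1, fit_normalization(f1, ["EosF"], cfg=cfg), ["EosF"])
        n2 = normalize_patients(f2, fit_normalization(f2, ["EosF"], cfg=cfg), ["EosF"])
        assert np.allclose(n1["EosF"], n2["EosF"])

    def test_per_cohort_independence(self, cfg):
        f1 = patient_frame(np.linspace(0, 1, 30), cohort="A")
        f2 = patient_frame(np.linspace(0, 100, 30), cohort="B")
        f2["patient_id"] = [f"q{i}" for i in range(30)]
        both = pd.concat([f1, f2], ignore_index=True)
        params = fit_normalization(both, ["EosF"], cfg=cfg)
        normed = normalize_patients(both, params, ["EosF"])
        a = normed[normed.cohort_id == "A"]["EosF"].to_numpy()
        b = normed[normed.cohort_id == "B"]["EosF"].to_numpy()
        assert np.allclose(a, b)  # same shape after per-cohort scaling
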