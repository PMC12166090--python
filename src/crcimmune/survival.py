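"""Cohort statistics: correlations, group tests, Kaplan-Meier and Cox models.

The survival endpoint is time to recurrence (TTR) with an administrative
five-year cutoff: events after 60 months are recoded as censored at 60.
Normalized lymphocyte and eosinophil scores are log1p-transformed before
regression; the IEL ratio enters untransformed.  Cox models use the Efron
approximation for ties, report hazard ratios with 95% CIs and Wald
p-values, and are compared by AIC on identical patient subsets.  No
multiple-testing correction is applied anywhere; conclusions are drawn
from individual comparisons.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from scipy import stats

from .config import PipelineConfig

logger = logging.getLogger(__name__)

#: score columns that get the log1p transform (IEL stays raw)
LOG_TRANSFORM_SCORES = ("LymF", "LymC", "LymA", "EosF", "EosC", "EosA")


def build_ttr(
    frame: pd.DataFrame,
    cfg: PipelineConfig | None = None,
    time_col: str = "followup_months",
    event_col: str = "event",
) -> pd.DataFrame:
    """Apply the five-year endpoint rule.

    Returns a copy with ``ttr_months`` and ``ttr_event``: times are
    truncated at the cutoff and events beyond it are recoded as censored.
    """
    cfg = cfg or PipelineConfig()
    t = frame[time_col].to_numpy(dtype=float)
    e = frame[event_col].to_numpy(dtype=int)
    if (t < 0).any():
        raise ValueError("negative follow-up time")
    cutoff = cfg.followup_cutoff_months
    out = frame.copy()
    out["ttr_months"] = np.minimum(t, cutoff)
    out["ttr_event"] = np.where(t > cutoff, 0, e)
    return out


def transform_scores(
    frame: pd.DataFrame, score_cols=LOG_TRANSFORM_SCORES
) -> pd.DataFrame:
    """log1p the (normalized) lymphocyte/eosinophil scores for regression.

    Normalized scores can be ≤ 0 (values below the cohort's stage II 5th
    percentile), so x ↦ log(1 + max(x, 0)); the transform is monotone on
    the retained range and keeps 0 at 0.
    """
    out = frame.copy()
    for col in score_cols:
        if col in out.columns:
            x = out[col].to_numpy(dtype=float)
            out[col] = np.log1p(np.clip(x, 0.0, None))
    return out


def correlation_matrix(
    frame: pd.DataFrame, cols: list[str], min_pairs: int = 3
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Spearman rank correlations with p-values.

    Entries with fewer than ``min_pairs`` complete pairs are NaN.
    """
    k = len(cols)
    rho = pd.DataFrame(np.eye(k), index=cols, columns=cols)
    pval = pd.DataFrame(np.zeros((k, k)), index=cols, columns=cols)
    np.fill_diagonal(pval.values, np.nan)
    for a, b in itertools.combinations(cols, 2):
        sub = frame[[a, b]].dropna()
        if len(sub) < min_pairs:
            rho.loc[a, b] = rho.loc[b, a] = np.nan
            pval.loc[a, b] = pval.loc[b, a] = np.nan
            continue
        r, p = stats.spearmanr(sub[a], sub[b])
        rho.loc[a, b] = rho.loc[b, a] = r
        pval.loc[a, b] = pval.loc[b, a] = p
    return rho, pval


def ordinal_association(score, ordinal) -> tuple[float, float]:
    """Kendall tau-B (tie-corrected) between a score and an ordinal covariate."""
    score = np.asarray(score, dtype=float)
    ordinal = np.asarray(ordinal, dtype=float)
    ok = np.isfinite(score) & np.isfinite(ordinal)
    res = stats.kendalltau(score[ok], ordinal[ok], variant="b")
    return float(res.statistic), float(res.pvalue)


def group_compare(frame: pd.DataFrame, score_col: str, group_col: str) -> pd.DataFrame:
    """Two-sided Mann-Whitney U tests for every pair of category levels."""
    rows = []
    groups = {
        k: sub[score_col].dropna().to_numpy(dtype=float)
        for k, sub in frame.groupby(group_col, sort=True, observed=True)
    }
    for name, vals in groups.items():
        if len(vals) == 0:
            raise ValueError(f"group {name!r} of {group_col!r} is empty")
    for a, b in itertools.combinations(sorted(groups, key=str), 2):
        u, p = stats.mannwhitneyu(groups[a], groups[b], alternative="two-sided")
        rows.append(
            {"group_a": a, "group_b": b, "n_a": len(groups[a]),
             "n_b": len(groups[b]), "U": u, "p": p}
        )
    return pd.DataFrame(rows)


@dataclass
class KMQuartileResult:
    """Quartile-split Kaplan-Meier curves with Wald tests vs the lowest quartile."""

    score: str
    cut_points: np.ndarray  # 25/50/75% quantiles on the full cohort
    curves: pd.DataFrame  # columns: quartile, time, survival, at_risk
    wald_p: dict[int, float]  # quartile (2..4) → Wald p vs Q1
    n_per_quartile: dict[int, int]


def km_quartiles(
    frame: pd.DataFrame,
    score_col: str,
    time_col: str = "ttr_months",
    event_col: str = "ttr_event",
    subset: pd.Series | np.ndarray | None = None,
) -> KMQuartileResult:
    """Quartile-split survival curves, cut on the full cohort.

    Quartile boundaries are linear-interpolation quantiles computed on the
    *full* cohort before any subsetting, so the same patient keeps its
    quartile across subgroup analyses.  Wald p-values come from one
    univariate Cox fit on quartile indicator covariates (Q1 baseline);
    quartiles empty in the subset have their contrast reported as NaN.
    """
    vals = frame[score_col].to_numpy(dtype=float)
    cuts = np.nanquantile(vals, [0.25, 0.5, 0.75])
    if len(np.unique(cuts)) < 3:
        raise ValueError(f"score {score_col!r} has degenerate quartile cut points")
    quart = np.digitize(vals, cuts, right=True) + 1  # 1..4

    work = frame.copy()
    work["_quartile"] = quart
    if subset is not None:
        work = work[np.asarray(subset, dtype=bool)]
    work = work.dropna(subset=[score_col, time_col, event_col])

    kmf = KaplanMeierFitter()
    curve_rows = []
    n_per = {}
    for q in (1, 2, 3, 4):
        sub = work[work["_quartile"] == q]
        n_per[q] = len(sub)
        if len(sub) == 0:
            continue
        kmf.fit(sub[time_col], sub[event_col], label=f"Q{q}")
        surv = kmf.survival_function_
        at_risk = kmf.event_table["at_risk"].reindex(surv.index)
        curve_rows.append(
            pd.DataFrame(
                {
                    "quartile": q,
                    "time": surv.index.to_numpy(dtype=float),
                    "survival": surv.iloc[:, 0].to_numpy(),
                    "at_risk": at_risk.to_numpy(),
                }
            )
        )
    curves = pd.concat(curve_rows, ignore_index=True) if curve_rows else pd.DataFrame()

    wald_p: dict[int, float] = {}
    model = work[[time_col, event_col]].copy()
    present = sorted(q for q in (2, 3, 4) if n_per.get(q, 0) > 0)
    if n_per.get(1, 0) > 0 and present:
        for q in present:
            model[f"Q{q}"] = (work["_quartile"] == q).astype(float)
        cph = CoxPHFitter()
        cph.fit(model, duration_col=time_col, event_col=event_col)
        for q in (2, 3, 4):
            wald_p[q] = (
                float(cph.summary.loc[f"Q{q}", "p"]) if q in present else float("nan")
            )
    else:
        wald_p = {q: float("nan") for q in (2, 3, 4)}
    return KMQuartileResult(score_col, cuts, curves, wald_p, n_per)


def km_table(times, events) -> pd.DataFrame:
    """Product-limit estimate as a tidy table (time, at_risk, survival)."""
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    surv = kmf.survival_function_
    return pd.DataFrame(
        {
            "time": surv.index.to_numpy(dtype=float),
            "at_risk": kmf.event_table["at_risk"].reindex(surv.index).to_numpy(),
            "survival": surv.iloc[:, 0].to_numpy(),
        }
    )


@dataclass
class CoxResult:
    """A fitted Cox proportional-hazards model."""

    summary: pd.DataFrame  # per covariate: hr, ci_low, ci_high, p
    log_likelihood: float
    aic: float
    n: int
    n_events: int
    covariates: tuple[str, ...]
    subset_key: int  # hash of the exact rows modeled; guards AIC comparisons
    ph_test_p: dict[str, float] = field(default_factory=dict)
    n_dropped: int = 0

    def hr(self, covariate: str) -> float:
        return float(self.summary.loc[covariate, "hr"])

    def ci(self, covariate: str) -> tuple[float, float]:
        row = self.summary.loc[covariate]
        return float(row["ci_low"]), float(row["ci_high"])

    def p(self, covariate: str) -> float:
        return float(self.summary.loc[covariate, "p"])

    def to_frame(self, model_name: str = "") -> pd.DataFrame:
        out = self.summary.reset_index(names="covariate")
        out.insert(0, "model", model_name)
        out["n"] = self.n
        out["events"] = self.n_events
        out["aic"] = self.aic
        return out


def cox_fit(
    frame: pd.DataFrame,
    covariates: list[str] | tuple[str, ...],
    time_col: str = "ttr_months",
    event_col: str = "ttr_event",
    check_ph: bool = True,
) -> CoxResult:
    """Fit a Cox PH model (Efron ties) and report HR, 95% CI, p, AIC.

    Rows with missing values in any modeled column are dropped
    (complete-case; the count is logged and recorded).  Fewer than 10
    events triggers a warning; non-convergence and separation raise.
    """
    cols = [time_col, event_col, *covariates]
    data = frame[cols].dropna()
    n_dropped = len(frame) - len(data)
    if n_dropped:
        logger.info("cox_fit: dropped %d rows with missing values", n_dropped)
    n_events = int(data[event_col].sum())
    if n_events < 10:
        logger.warning("cox_fit: only %d events; estimates may be unstable", n_events)
    cph = CoxPHFitter()
    cph.fit(data, duration_col=time_col, event_col=event_col)
    s = cph.summary
    summary = pd.DataFrame(
        {
            "hr": s["exp(coef)"],
            "ci_low": s["exp(coef) lower 95%"],
            "ci_high": s["exp(coef) upper 95%"],
            "p": s["p"],
        }
    )
    ph_p: dict[str, float] = {}
    if check_ph and n_events >= 10:
        try:
            from lifelines.statistics import proportional_hazard_test

            ph = proportional_hazard_test(cph, data, time_transform="rank")
            ph_p = {str(k): float(v) for k, v in ph.summary["p"].items()}
        except Exception as exc:  # diagnostic only; never blocks the fit
            logger.warning("proportional-hazards diagnostic failed: %s", exc)
    subset_key = int(
        pd.util.hash_pandas_object(data[[time_col, event_col]]).sum() % (2**63)
    )
    return CoxResult(
        summary=summary,
        log_likelihood=float(cph.log_likelihood_),
        aic=float(cph.AIC_partial_),
        n=len(data),
        n_events=n_events,
        covariates=tuple(covariates),
        subset_key=subset_key,
        ph_test_p=ph_p,
        n_dropped=n_dropped,
    )


def model_compare(results: dict[str, CoxResult]) -> pd.DataFrame:
    """Rank fitted models by AIC (ascending) with ΔAIC to the best.

    All models must have been fitted on the identical patient subset,
    otherwise partial-likelihood AICs are not comparable.
    """
    if not results:
        raise ValueError("no models to compare")
    keys = {r.subset_key for r in results.values()}
    if len(keys) > 1:
        raise ValueError("models fitted on differing subsets; AIC not comparable")
    rows = [
        {
            "model": name,
            "aic": r.aic,
            "log_likelihood": r.log_likelihood,
            "k": len(r.covariates),
            "n": r.n,
            "events": r.n_events,
        }
        for name, r in results.items()
    ]
    out = pd.DataFrame(rows).sort_values("aic", kind="stable").reset_index(drop=True)
    out["delta_aic"] = out["aic"] - out["aic"].iloc[0]
    return out
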