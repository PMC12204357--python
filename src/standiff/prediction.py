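"""Forward prediction of future tau and longitudinal validation.

A fitted subject model (seed + kinetic rates) is evaluated at follow-up
stages obtained from the baseline stage by a 1:1 mapping between years and
stages, s_l = s_b + delta_t.  Stages beyond the staging grid are allowed:
the flow is defined for all real s, and multi-year follow-ups of
late-stage subjects can exceed the last stage.  Predictions are compared
to observed follow-up tau with Pearson's R and MSE, per visit and
aggregated per subject and over the cohort (both the visit-pooled and the
subject-mean aggregate are reported).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .connectome import Laplacian
from .diffusion import forward
from .inference import FitResult, _pearson

logger = logging.getLogger(__name__)


@dataclass
class LongitudinalRecord:
    """Follow-up tau scans for one subject, intervals in years from baseline."""

    subject_id: str
    baseline_stage: float
    visits: list[tuple[float, np.ndarray]]  # (delta_years, tau vector)

    def __post_init__(self):
        dts = [dt for dt, _ in self.visits]
        if any(dt <= 0 for dt in dts) or any(np.diff(dts) <= 0):
            raise ValueError("visit intervals must be positive and increasing")


@dataclass
class ValidationReport:
    """Per-visit and aggregated prediction accuracy."""

    per_visit: pd.DataFrame   # subject_id, delta_years, stage, pearson_r, mse
    per_subject: pd.DataFrame  # subject_id, mean_r, mean_mse, n_visits
    mean_r_pooled: float
    mean_r_by_subject: float
    mean_mse_pooled: float
    mean_mse_by_subject: float


def stage_at_followup(s_b: float, delta_years: float) -> float:
    """Follow-up stage under the 1:1 years-to-stages mapping."""
    if delta_years < 0:
        raise ValueError("negative follow-up interval")
    return float(s_b) + float(delta_years)


def predict_future(fit: FitResult, s_l: float, lap: Laplacian) -> np.ndarray:
    """Regional tau predicted at stage s_l from a fitted subject model."""
    return forward(fit.seed, fit.params, s_l, lap).x[0]


def validate_longitudinal(
    fits: dict[str, FitResult],
    records: list[LongitudinalRecord],
    lap: Laplacian,
    include_idx: np.ndarray | None = None,
) -> ValidationReport:
    """Score each fitted subject's forecasts against observed follow-ups.

    ``include_idx`` restricts the comparison to the same region set used
    during fitting (exclusion mask applied consistently).  Subjects without
    follow-ups or without a fit are skipped with a log entry.
    """
    if include_idx is None:
        include_idx = np.arange(lap.n_regions)
    rows = []
    for rec in records:
        fit = fits.get(rec.subject_id)
        if fit is None:
            logger.info("PRED_SKIP_NOFIT: %s has no fitted model", rec.subject_id)
            continue
        if not rec.visits:
            logger.info("PRED_SKIP_NOVISITS: %s has no follow-ups", rec.subject_id)
            continue
        for dt, y in rec.visits:
            s_l = stage_at_followup(rec.baseline_stage, dt)
            pred = predict_future(fit, s_l, lap)
            p, o = pred[include_idx], np.asarray(y, dtype=float)[include_idx]
            r = _pearson(p, o)
            rows.append({
                "subject_id": rec.subject_id,
                "delta_years": dt,
                "stage": s_l,
                "pearson_r": r,
                "mse": float(np.mean((o - p) ** 2)),
            })
    per_visit = pd.DataFrame(rows)
    if per_visit.empty:
        raise ValueError("no scorable follow-up visits")
    per_subject = (
        per_visit.groupby("subject_id")
        .agg(mean_r=("pearson_r", "mean"), mean_mse=("mse", "mean"),
             n_visits=("mse", "size"))
        .reset_index()
    )
    return ValidationReport(
        per_visit=per_visit,
        per_subject=per_subject,
        mean_r_pooled=float(per_visit["pearson_r"].mean()),
        mean_r_by_subject=float(per_subject["mean_r"].mean()),
        mean_mse_pooled=float(per_visit["mse"].mean()),
        mean_mse_by_subject=float(per_subject["mean_mse"].mean()),
    )
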