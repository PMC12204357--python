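"""Spatial and cognitive heterogeneity statistics.

Two stage-resolved statistics quantify how heterogeneous tau patterns are
and how they converge over the disease course:

* the coefficient of variation (CoV) of tau across regions within a
  subject — high near seeding, falling as diffusion smooths the pattern;
* the distribution of pairwise inter-subject correlations of (predicted or
  empirical) tau at each stage — rising with stage because all seeds relax
  toward the sqrt(degree) direction of the connectome.

A third analysis relates per-subject kinetic rates to cognition with age
and stage regressed out of the cognitive score (the score only; the rates
are left untouched).
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd
from scipy import stats

from .connectome import Laplacian
from .diffusion import forward
from .inference import FitResult

logger = logging.getLogger(__name__)


def cov_across_regions(x: np.ndarray, ddof: int = 1) -> float:
    """Coefficient of variation SD/mean across regions (sample SD)."""
    x = np.asarray(x, dtype=float).ravel()
    m = x.mean()
    if m == 0:
        raise ValueError("CoV undefined for zero-mean vector")
    return float(x.std(ddof=ddof) / m)


def pairwise_correlations(
    tau_set: np.ndarray, method: str = "pearson"
) -> np.ndarray:
    """Correlations of all unordered subject pairs' regional tau vectors.

    Constant subject vectors make a pair's correlation undefined; such
    pairs are skipped with a log entry.
    """
    X = np.asarray(tau_set, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 3:
        raise ValueError("need >=2 subjects and >=3 regions")
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown method {method!r}")
    if method == "spearman":
        X = np.apply_along_axis(stats.rankdata, 1, X)
    sd = X.std(axis=1)
    vals = []
    for i, j in itertools.combinations(range(X.shape[0]), 2):
        if sd[i] == 0 or sd[j] == 0:
            logger.warning("HET_CONSTANT_SUBJECT: pair (%d, %d) skipped", i, j)
            continue
        vals.append(np.corrcoef(X[i], X[j])[0, 1])
    return np.asarray(vals)


def convergence_curve(
    fits: list[FitResult],
    lap: Laplacian,
    stages: np.ndarray,
    method: str = "pearson",
) -> pd.DataFrame:
    """Stage-resolved mean CoV and mean pairwise correlation of predictions.

    Each fitted subject's forward trajectory is evaluated on the stage
    grid; per stage, the mean across-subject CoV and the mean pairwise
    inter-subject correlation are recorded.
    """
    if len(fits) < 2:
        raise ValueError("need at least 2 fitted subjects")
    stages = np.asarray(stages, dtype=float)
    preds = np.stack([forward(f.seed, f.params, stages, lap).x for f in fits])
    rows = []
    for k, s in enumerate(stages):
        X = preds[:, k, :]
        covs = [cov_across_regions(x) for x in X if x.mean() != 0]
        pr = pairwise_correlations(X, method=method)
        rows.append({
            "stage": float(s),
            "mean_cov": float(np.mean(covs)) if covs else np.nan,
            "mean_pairwise_r": float(pr.mean()) if pr.size else np.nan,
        })
    return pd.DataFrame(rows)


def empirical_cov_by_stage(
    tau: np.ndarray, stages: np.ndarray
) -> pd.DataFrame:
    """CoV of each subject's observed baseline tau, indexed by assigned stage."""
    tau = np.asarray(tau, dtype=float)
    stages = np.asarray(stages)
    rows = [
        {"subject": i, "stage": float(stages[i]),
         "cov": cov_across_regions(tau[i])}
        for i in range(tau.shape[0]) if tau[i].mean() != 0
    ]
    return pd.DataFrame(rows)


def residualize(score: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    """OLS residuals of score on covariates (intercept included)."""
    score = np.asarray(score, dtype=float)
    C = np.atleast_2d(np.asarray(covariates, dtype=float))
    if C.shape[0] != score.shape[0]:
        C = C.T
    X = np.column_stack([np.ones(len(score)), C])
    coef, *_ = np.linalg.lstsq(X, score, rcond=None)
    return score - X @ coef


def param_cognition_assoc(
    params_table: pd.DataFrame,
    scores: pd.DataFrame,
    age: np.ndarray,
    stage: np.ndarray,
) -> pd.DataFrame:
    """Correlate kinetic rates with cognition, age and stage regressed out.

    ``params_table`` has columns like alpha/beta; ``scores`` one column per
    cognitive test.  Each score is residualized on (age, stage); the
    residual is then Pearson-correlated with each raw parameter.  Returns
    a tidy table (parameter, score, r, p, n).
    """
    if len(params_table) < 10:
        raise ValueError("need at least 10 subjects")
    cov = np.column_stack([np.asarray(age, float), np.asarray(stage, float)])
    rows = []
    for score_name in scores.columns:
        resid = residualize(scores[score_name].to_numpy(dtype=float), cov)
        for pname in params_table.columns:
            v = params_table[pname].to_numpy(dtype=float)
            if v.std() == 0:
                raise ValueError(f"constant parameter vector {pname!r}")
            r, p = stats.pearsonr(v, resid)
            rows.append({"parameter": pname, "score": score_name,
                         "r": float(r), "p": float(p), "n": len(v)})
    return pd.DataFrame(rows)
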