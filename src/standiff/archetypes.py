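"""Seed-archetype discovery: covariance SVD, K-means, and covariate tests.

Individually inferred seed vectors are summarized two ways:

* the uncentered second-moment matrix A = sum_i x_i(0) x_i(0)^T is
  decomposed by SVD; its top singular vectors are recurring seeding
  patterns, and each subject is assigned to the top vector most strongly
  Pearson-correlated with their seed;
* K-means clustering of the raw seeds, with K chosen at the elbow of the
  inertia-vs-K curve, yields archetype centroids and hard labels.

Archetype membership is then tested against clinical covariates
(chi-square for categorical, one-way ANOVA for continuous), and
per-archetype total-tau trajectories are computed from the fitted forward
models.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans

from .connectome import Laplacian
from .diffusion import forward
from .inference import FitResult

logger = logging.getLogger(__name__)


def seed_covariance(seeds: np.ndarray, centered: bool = False) -> np.ndarray:
    """Second-moment matrix A = sum_i x_i(0) x_i(0)^T of subject seeds.

    Uncentered by default; ``centered=True`` subtracts the mean seed first
    (the textbook covariance, up to scale).
    """
    S = np.asarray(seeds, dtype=float)
    if S.ndim != 2 or S.shape[0] < 2:
        raise ValueError("need a (subjects, regions) matrix with >=2 subjects")
    if centered:
        S = S - S.mean(axis=0, keepdims=True)
    return S.T @ S


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    """Orient each column so its largest-magnitude entry is positive."""
    V = vectors.copy()
    for k in range(V.shape[1]):
        i = np.argmax(np.abs(V[:, k]))
        if V[i, k] < 0:
            V[:, k] = -V[:, k]
    return V


def svd_archetypes(A: np.ndarray, k: int = 3) -> tuple[np.ndarray, np.ndarray]:
    """Top-k singular vectors/values of the (symmetric PSD) seed matrix A.

    Returns (vectors (n_regions, k), values (k,)), values descending,
    vectors sign-fixed largest-entry-positive.
    """
    A = np.asarray(A, dtype=float)
    U, s, _ = np.linalg.svd(A, hermitian=True)
    if k > np.sum(s > s[0] * 1e-12):
        raise ValueError(f"k={k} exceeds numerical rank of A")
    return _fix_signs(U[:, :k]), s[:k]


def classify_by_svd(seeds: np.ndarray, vectors: np.ndarray) -> np.ndarray:
    """Assign each subject to the singular vector best correlated with
    their seed (Pearson); ties break to the lower-index (more prominent)
    vector."""
    S = np.asarray(seeds, dtype=float)
    labels = np.empty(S.shape[0], dtype=int)
    for i, x in enumerate(S):
        rs = []
        for k in range(vectors.shape[1]):
            v = vectors[:, k]
            if x.std() == 0 or v.std() == 0:
                rs.append(-np.inf)
            else:
                rs.append(np.corrcoef(x, v)[0, 1])
        labels[i] = int(np.argmax(rs))
    return labels


@dataclass
class KMeansArchetypes:
    selected_k: int
    centroids: np.ndarray          # (K, n_regions)
    labels: np.ndarray             # (n_subjects,)
    inertia_curve: pd.DataFrame    # columns k, inertia


def kmeans_archetypes(
    seeds: np.ndarray,
    k_grid: list[int] | np.ndarray = range(1, 7),
    rng_seed: int = 0,
    n_init: int = 10,
) -> KMeansArchetypes:
    """Seeded K-means over a K grid with elbow selection.

    Inertia (sum of squared distances to the closest centroid) is recorded
    per K; the selected K maximizes the discrete curvature of the inertia
    curve.  K-means++ initialization with ``n_init`` restarts, best inertia
    kept.
    """
    S = np.asarray(seeds, dtype=float)
    k_grid = sorted(int(k) for k in k_grid)
    if k_grid[0] < 1 or k_grid[-1] > S.shape[0]:
        raise ValueError("k grid outside [1, n_subjects]")
    fits = {}
    rows = []
    for k in k_grid:
        km = KMeans(n_clusters=k, n_init=n_init, random_state=rng_seed).fit(S)
        fits[k] = km
        rows.append({"k": k, "inertia": float(km.inertia_)})
    curve = pd.DataFrame(rows)
    inertia = curve["inertia"].to_numpy()
    if len(k_grid) >= 3:
        # normalize so curvature is comparable across scales
        span = inertia[0] - inertia[-1]
        norm = (inertia - inertia[-1]) / span if span > 0 else inertia * 0
        curv = norm[:-2] - 2 * norm[1:-1] + norm[2:]
        selected = k_grid[1 + int(np.argmax(curv))]
    else:
        selected = k_grid[int(np.argmin(inertia))]
    km = fits[selected]
    return KMeansArchetypes(
        selected_k=selected,
        centroids=km.cluster_centers_,
        labels=km.labels_.astype(int),
        inertia_curve=curve,
    )


def match_labels(pred: np.ndarray, truth: np.ndarray) -> tuple[np.ndarray, float]:
    """Optimally relabel predicted clusters to maximize overlap with truth.

    Hungarian assignment on the confusion matrix; returns relabeled
    predictions and the resulting accuracy.
    """
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    pv, pi = np.unique(pred, return_inverse=True)
    tv, ti = np.unique(truth, return_inverse=True)
    conf = np.zeros((len(pv), len(tv)), dtype=int)
    np.add.at(conf, (pi, ti), 1)
    rows, cols = linear_sum_assignment(-conf)
    mapping = {pv[r]: tv[c] for r, c in zip(rows, cols)}
    # unmatched predicted clusters (if more clusters than truth groups) map
    # to their plurality truth group
    for r in range(len(pv)):
        if pv[r] not in mapping:
            mapping[pv[r]] = tv[int(np.argmax(conf[r]))]
    remapped = np.array([mapping[p] for p in pred])
    return remapped, float(np.mean(remapped == truth))


def archetype_covariate_tests(
    labels: np.ndarray, covariates: pd.DataFrame
) -> pd.DataFrame:
    """Test archetype membership against each covariate.

    Categorical (object/bool/categorical dtype) columns get a chi-square
    test of independence; numeric columns a one-way ANOVA across
    archetypes.  Returns a tidy table (variable, kind, statistic, df, p).
    """
    labels = np.asarray(labels)
    groups = np.unique(labels)
    sizes = [np.sum(labels == g) for g in groups]
    if len(groups) < 2 or min(sizes) < 2:
        raise ValueError("need >=2 archetypes with >=2 members each")
    rows = []
    for col in covariates.columns:
        v = covariates[col]
        if v.dtype.kind in "OUSb" or isinstance(v.dtype, pd.CategoricalDtype):
            table = pd.crosstab(labels, v)
            chi2, p, df, expected = stats.chi2_contingency(table)
            if (expected < 1).any():
                logger.warning(
                    "ARCH_LOW_EXPECTED: chi-square cells below 1 for %r", col
                )
            rows.append({"variable": col, "kind": "categorical",
                         "statistic": float(chi2), "df": int(df), "p": float(p)})
        else:
            samples = [v.to_numpy(dtype=float)[labels == g] for g in groups]
            F, p = stats.f_oneway(*samples)
            rows.append({"variable": col, "kind": "continuous",
                         "statistic": float(F),
                         "df": int(len(groups) - 1), "p": float(p)})
    return pd.DataFrame(rows)


def archetype_trajectories(
    labels: np.ndarray,
    fits: list[FitResult],
    lap: Laplacian,
    stages: np.ndarray,
) -> pd.DataFrame:
    """Per-archetype mean +/- SD curves of total predicted tau by stage.

    Total tau is the sum of a subject's predicted regional values; SD is
    omitted (NaN) for archetypes with fewer than 2 subjects.
    """
    labels = np.asarray(labels)
    if len(labels) != len(fits):
        raise ValueError("one label per fitted subject required")
    stages = np.asarray(stages, dtype=float)
    totals = np.stack([
        forward(f.seed, f.params, stages, lap).x.sum(axis=1) for f in fits
    ])  # (n_subjects, n_stages)
    rows = []
    for g in np.unique(labels):
        sub = totals[labels == g]
        for k, s in enumerate(stages):
            rows.append({
                "archetype": int(g), "stage": float(s),
                "mean_total_tau": float(sub[:, k].mean()),
                "sd_total_tau": float(sub[:, k].std(ddof=1))
                if sub.shape[0] >= 2 else np.nan,
                "n": int(sub.shape[0]),
            })
    return pd.DataFrame(rows)
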