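"""Inverse problem: fit seeds and kinetic rates of the diffusion model.

The fitting objective combines fit error and spatial-pattern agreement,

    E(x, y) = MSE(y, x) - 0.5 * R(x, y),

with x the model prediction, y empirical tau, and R Pearson's correlation.
The squared-error term is implemented as a mean over included regions so
the two terms stay commensurate across region counts.  Seed optimization
adds a scale-invariant sparsity penalty lambda * ||x0||_1 / ||x0||_2
(equal to 1 for a one-hot seed, sqrt(n) for a uniform one): sparse seeding
is biologically plausible, and the penalty also discourages degenerate
zero-spread solutions.

Four fitting strategies mirror the level at which seed and rates vary:

    cohort_iterative  alternate rate / seed optimization against the
                      stage-resolved cohort trajectory (both cohort-level)
    subject_params    cohort seed, per-subject rates (k = 2)
    subject_seeds     cohort rates, per-subject seed (k = n regions)
    subject_both      per-subject seed, then per-subject rates with that
                      seed fixed (k = n regions + 2)

Rate optimization runs an ensemble of global and local optimizers
(basin hopping, differential evolution, Powell, L-BFGS-B) and keeps the
best minimum; seed optimization is bound-constrained L-BFGS-B with an
analytic gradient from several starts.  Regions on the exclusion mask
(e.g. striatum, where the tracer binds off-target) are dropped from the
cost only; the forward simulation always runs on the full connectome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .connectome import Laplacian
from .diffusion import KineticParams, propagator
from .staging import CohortTrajectory

logger = logging.getLogger(__name__)

STRATEGIES = ("cohort_iterative", "subject_params", "subject_seeds", "subject_both")
DEFAULT_OPTIMIZERS = ("basinhopping", "differential_evolution", "powell", "l-bfgs-b")


@dataclass
class FitConfig:
    """Settings shared by all fitting routines."""

    strategy: str = "subject_both"
    lam: float = 0.03
    optimizer_set: tuple[str, ...] = DEFAULT_OPTIMIZERS
    max_outer_iters: int = 10
    outer_tol: float = 1e-4
    rng_seed: int = 0
    param_bounds: tuple[tuple[float, float], tuple[float, float]] = (
        (0.0, 10.0),
        (0.0, 10.0),
    )
    excluded_region_mask: np.ndarray | None = None  # boolean, True = excluded
    n_random_seed_starts: int = 5
    seed_maxiter: int = 300
    subject_refinements: int = 3  # seed/rate alternations in subject_both

    def __post_init__(self):
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if self.lam < 0:
            raise ValueError("lambda must be nonnegative")

    def include_idx(self, n_regions: int) -> np.ndarray:
        if self.excluded_region_mask is None:
            return np.arange(n_regions)
        mask = np.asarray(self.excluded_region_mask, dtype=bool)
        if mask.shape[0] != n_regions:
            raise ValueError("exclusion mask length mismatch")
        return np.nonzero(~mask)[0]


@dataclass
class FitResult:
    """Outcome of one fit: seed, rates, cost, fit quality, complexity."""

    seed: np.ndarray
    params: KineticParams
    cost: float
    pearson_r: float
    n_inferred: int
    subject_id: str = "cohort"
    stage: float | None = None
    extras: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# cost and penalty
# ---------------------------------------------------------------------------

def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    nx, ny = np.linalg.norm(xc), np.linalg.norm(yc)
    if nx == 0 or ny == 0:
        return np.nan
    return float(np.dot(xc, yc) / (nx * ny))


def cost(x: np.ndarray, y: np.ndarray) -> float:
    """Combined fit cost E(x, y) = MSE(y, x) - 0.5 * PearsonR(x, y).

    Vectors must already have mask-excluded regions removed.  If either
    vector is constant the correlation term is 0 with a logged warning.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("length mismatch in cost")
    if x.size < 3:
        raise ValueError("cost needs at least 3 regions")
    mse = float(np.mean((y - x) ** 2))
    r = _pearson(x, y)
    if np.isnan(r):
        logger.warning("COST_CONSTANT_VECTOR: correlation term set to 0")
        r = 0.0
    return mse - 0.5 * r


def seed_penalty(x0: np.ndarray, lam: float) -> float:
    """Scale-invariant sparsity penalty lambda * ||x0||_1 / ||x0||_2."""
    x0 = np.asarray(x0, dtype=float).ravel()
    l2 = np.linalg.norm(x0)
    if l2 == 0:
        raise ValueError("seed penalty undefined for the zero vector")
    return float(lam * np.abs(x0).sum() / l2)


def seed_energy_regions(x0: np.ndarray, frac: float = 0.9) -> int:
    """Smallest number of regions holding ``frac`` of the seed's total sum."""
    if not 0 < frac <= 1:
        raise ValueError("frac must be in (0, 1]")
    x0 = np.asarray(x0, dtype=float).ravel()
    if np.any(x0 < 0):
        raise ValueError("seed must be nonnegative")
    total = x0.sum()
    if total <= 0:
        raise ValueError("seed energy undefined for the zero vector")
    csum = np.cumsum(np.sort(x0)[::-1])
    return int(np.searchsorted(csum, frac * total - 1e-12 * total) + 1)


def aic(log_likelihood: float, k: int) -> float:
    """Akaike information criterion, 2k - 2 logL."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if not np.isfinite(log_likelihood):
        raise ValueError("non-finite log-likelihood")
    return 2.0 * k - 2.0 * log_likelihood


def gaussian_loglik_from_mse(mse: float, n: int) -> float:
    """Gaussian log-likelihood of n residuals at their fitted variance (MSE)."""
    mse = max(float(mse), 1e-300)
    return -0.5 * n * (np.log(2.0 * np.pi * mse) + 1.0)


# ---------------------------------------------------------------------------
# rate fitting
# ---------------------------------------------------------------------------

def _total_cost_params(
    theta: np.ndarray,
    targets: np.ndarray,
    stages: np.ndarray,
    x0: np.ndarray,
    lap: Laplacian,
    idx: np.ndarray,
) -> float:
    f, _ = _params_fun_grad(theta, targets, stages, x0, lap, idx)
    return f


def _params_fun_grad(
    theta: np.ndarray,
    targets: np.ndarray,
    stages: np.ndarray,
    x0: np.ndarray,
    lap: Laplacian,
    idx: np.ndarray,
) -> tuple[float, np.ndarray]:
    """Mean stage cost and its analytic gradient wrt (alpha, beta)."""
    alpha, beta = theta
    w, V = lap.eig()
    c = V.T @ x0
    Vt = V.T[:, idx]
    # all stages at once: pred[s] = V @ (exp((alpha - beta*w)*s) * c)
    G = np.exp(np.outer(stages, alpha - beta * w)) * c[None, :]
    P = G @ Vt
    # dP/dalpha = (s * G) @ Vt ; dP/dbeta = -(s * w * G) @ Vt
    Pa = (stages[:, None] * G) @ Vt
    Pb = -(stages[:, None] * (G * w[None, :])) @ Vt
    Y = targets[:, idx]
    n = idx.size
    R_ = P - Y
    mse = np.einsum("sr,sr->s", R_, R_) / n
    dmse_dP = 2.0 * R_ / n
    Pc = P - P.mean(axis=1, keepdims=True)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    num = np.einsum("sr,sr->s", Pc, Yc)
    nP = np.linalg.norm(Pc, axis=1)
    nY = np.linalg.norm(Yc, axis=1)
    den = nP * nY
    ok = den > 1e-30
    r = np.where(ok, num / np.maximum(den, 1e-30), 0.0)
    # dR/dP = Yc/(|Pc||Yc|) - R*Pc/|Pc|^2 (already centered)
    dr_dP = np.zeros_like(P)
    dr_dP[ok] = (
        Yc[ok] / np.maximum(den[ok], 1e-30)[:, None]
        - (r[ok] / np.maximum(nP[ok] ** 2, 1e-30))[:, None] * Pc[ok]
    )
    dJ_dP = dmse_dP - 0.5 * dr_dP
    S = len(stages)
    f = float(np.mean(mse - 0.5 * r))
    g = np.array([
        np.einsum("sr,sr->", dJ_dP, Pa) / S,
        np.einsum("sr,sr->", dJ_dP, Pb) / S,
    ])
    return f, g


def fit_params(
    targets: np.ndarray,
    stages: np.ndarray | float,
    seed: np.ndarray,
    lap: Laplacian,
    config: FitConfig,
) -> tuple[KineticParams, float]:
    """Fit (alpha, beta) with the seed fixed; best of the optimizer ensemble.

    ``targets`` is (n_stages, n_regions) (a single vector is promoted);
    the cost is averaged over the supplied stages.  Deterministic given
    ``config.rng_seed``.
    """
    targets = np.atleast_2d(np.asarray(targets, dtype=float))
    stages = np.atleast_1d(np.asarray(stages, dtype=float))
    if targets.shape[0] != stages.shape[0]:
        raise ValueError("one target vector per stage required")
    if np.allclose(stages, 0):
        logger.warning(
            "FIT_DEGENERATE_STAGE0: targets only at s=0 carry no kinetic "
            "information; returning lower-bound rates"
        )
        lo = (config.param_bounds[0][0], config.param_bounds[1][0])
        return KineticParams(*lo), _total_cost_params(
            np.array(lo), targets, stages, seed, lap,
            config.include_idx(lap.n_regions),
        )
    idx = config.include_idx(lap.n_regions)
    bounds = list(config.param_bounds)
    fun = lambda th: _total_cost_params(th, targets, stages, seed, lap, idx)
    fun_grad = lambda th: _params_fun_grad(th, targets, stages, seed, lap, idx)
    rng = np.random.default_rng(config.rng_seed)
    x_init = np.array([np.mean(b) for b in bounds])

    results: list[tuple[float, np.ndarray]] = []

    def record(res):
        if res is not None and np.all(np.isfinite(res.x)):
            x = np.clip(res.x, [b[0] for b in bounds], [b[1] for b in bounds])
            results.append((float(fun(x)), x))

    for method in config.optimizer_set:
        try:
            if method == "differential_evolution":
                record(
                    optimize.differential_evolution(
                        fun, bounds, seed=int(rng.integers(2**31 - 1)),
                        maxiter=60, popsize=12, tol=1e-8, polish=True,
                    )
                )
            elif method == "basinhopping":
                record(
                    optimize.basinhopping(
                        fun_grad, x_init, niter=15,
                        minimizer_kwargs={
                            "method": "L-BFGS-B", "bounds": bounds, "jac": True,
                        },
                        seed=int(rng.integers(2**31 - 1)), stepsize=1.0,
                    ).lowest_optimization_result
                )
            elif method == "powell":
                record(
                    optimize.minimize(fun, x_init, method="Powell", bounds=bounds)
                )
            elif method == "l-bfgs-b":
                record(
                    optimize.minimize(
                        fun_grad, x_init, method="L-BFGS-B", bounds=bounds, jac=True
                    )
                )
            else:
                raise ValueError(f"unknown optimizer {method!r}")
        except ValueError:
            raise
        except Exception as exc:  # pragma: no cover - optimizer hiccup
            logger.warning("FIT_OPTIMIZER_FAIL: %s failed: %s", method, exc)
    if not results:
        raise RuntimeError("all rate optimizers failed")
    best_cost, best_x = min(results, key=lambda t: t[0])
    return KineticParams(alpha=float(best_x[0]), beta=float(best_x[1])), best_cost


# ---------------------------------------------------------------------------
# seed fitting
# ---------------------------------------------------------------------------

def _seed_objective_factory(
    targets: np.ndarray,
    kernels: list[np.ndarray],
    idx: np.ndarray,
    lam: float,
):
    """Objective and analytic gradient for seed optimization.

    For each stage, pred = K @ x0 restricted to included regions; the cost
    is mean over stages of MSE - 0.5 R plus the L1/L2 penalty.
    """
    Ks = [K[idx, :] for K in kernels]
    Ys = [y[idx] for y in targets]
    n = idx.size
    n_stage = len(Ks)

    def fun_grad(x0: np.ndarray) -> tuple[float, np.ndarray]:
        total = 0.0
        grad = np.zeros_like(x0)
        for K, y in zip(Ks, Ys):
            u = K @ x0
            r = u - y
            mse = np.dot(r, r) / n
            g_u = (2.0 / n) * r
            uc = u - u.mean()
            yc = y - y.mean()
            nu, ny = np.linalg.norm(uc), np.linalg.norm(yc)
            if nu > 1e-30 and ny > 1e-30:
                R = np.dot(uc, yc) / (nu * ny)
                dR_du = yc / (nu * ny) - R * uc / (nu * nu)
                g_u = g_u - 0.5 * dR_du
            else:
                R = 0.0
            total += mse - 0.5 * R
            grad += K.T @ g_u
        total /= n_stage
        grad /= n_stage
        l2 = np.linalg.norm(x0)
        if l2 > 1e-30 and lam > 0:
            l1 = np.abs(x0).sum()
            total += lam * l1 / l2
            grad += lam * (np.sign(x0) / l2 - l1 * x0 / l2**3)
        return total, grad

    return fun_grad


def fit_seed(
    targets: np.ndarray,
    stages: np.ndarray | float,
    params: KineticParams,
    lap: Laplacian,
    config: FitConfig,
    cohort_seed: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Fit a nonnegative seed with rates fixed.

    Minimizes mean stage cost plus the L1/L2 penalty with bound-constrained
    L-BFGS-B (analytic gradient) from several starts: the target vector
    itself, the cohort seed when given, and seeded random sparse starts.
    Returns the best seed and its penalized cost.
    """
    targets = np.atleast_2d(np.asarray(targets, dtype=float))
    stages = np.atleast_1d(np.asarray(stages, dtype=float))
    if np.any(stages <= 0) and targets.shape[0] == 1:
        # s=0: no diffusion has happened, the seed IS the target
        x0 = np.clip(targets[0], 0.0, None)
        logger.warning("FIT_SEED_STAGE0: stage 0 target returned as its own seed")
        return x0, np.nan
    n = lap.n_regions
    idx = config.include_idx(n)
    kernels = [propagator(params, float(s), lap) for s in stages]
    fun_grad = _seed_objective_factory(targets, kernels, idx, config.lam)
    rng = np.random.default_rng(config.rng_seed)

    starts = [np.clip(targets.mean(axis=0), 1e-9, None)]
    # "go back in time": least-squares back-propagation of each target
    # through its kernel, clipped to the nonnegative orthant
    bp = np.mean(
        [np.linalg.lstsq(K, y, rcond=1e-8)[0] for K, y in zip(kernels, targets)],
        axis=0,
    )
    if np.all(np.isfinite(bp)) and np.any(bp > 0):
        starts.append(np.clip(bp, 1e-9, None))
    if cohort_seed is not None:
        starts.append(np.clip(np.asarray(cohort_seed, dtype=float), 1e-9, None))
    scale = max(float(np.abs(targets).mean()), 1e-3)
    for _ in range(config.n_random_seed_starts):
        x = np.zeros(n)
        hot = rng.choice(n, size=max(2, n // 20), replace=False)
        x[hot] = rng.uniform(0.5, 1.5, size=hot.size) * scale
        starts.append(x + 1e-9)

    bounds = [(0.0, None)] * n
    best_x, best_f = None, np.inf
    for x_init in starts:
        res = optimize.minimize(
            fun_grad, x_init, jac=True, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": config.seed_maxiter},
        )
        if np.linalg.norm(res.x) < 1e-12:
            continue  # all-zero solutions are infeasible
        if res.fun < best_f:
            best_f, best_x = float(res.fun), res.x
    if best_x is None:
        raise RuntimeError("seed optimization produced only infeasible solutions")
    return np.clip(best_x, 0.0, None), best_f


# ---------------------------------------------------------------------------
# strategies
# ---------------------------------------------------------------------------

def fit_cohort_iterative(
    traj: CohortTrajectory,
    lap: Laplacian,
    config: FitConfig,
) -> tuple[KineticParams, np.ndarray, list[float]]:
    """Strategy 1: alternate rate and seed fits against the cohort trajectory.

    The seed initializes to the stage-0 trajectory row; the returned trace
    of penalized costs is monotone non-increasing (alternating descent).
    Fitting uses stages >= 1 only: the stage-0 row is the initialization,
    and matching it exactly would pin the seed.
    """
    Y = np.asarray(traj.tau, dtype=float)
    stages = np.asarray(traj.stages, dtype=float)
    if Y.shape[0] < 2:
        raise ValueError("cohort trajectory needs at least 2 stages")
    fit_sel = stages > 0
    Yf, sf = Y[fit_sel], stages[fit_sel]

    x0 = np.clip(Y[0], 1e-9, None)
    idx = config.include_idx(lap.n_regions)
    trace: list[float] = []
    params = KineticParams(0.0, 0.0)
    best = (np.inf, params, x0)
    prev = np.inf
    for it in range(config.max_outer_iters):
        params, _ = fit_params(Yf, sf, x0, lap, config)
        x0, c_pen = fit_seed(Yf, sf, params, lap, config, cohort_seed=x0)
        trace.append(c_pen)
        if c_pen < best[0]:
            best = (c_pen, params, x0)
        if it == 0 and c_pen > prev:
            logger.warning("FIT_COHORT_NONDECREASING: first iteration did not improve")
        if prev - c_pen < config.outer_tol * max(abs(prev), 1.0):
            break
        prev = c_pen
    _, params, x0 = best
    return params, x0, trace


def _result_for(
    x0: np.ndarray,
    params: KineticParams,
    y: np.ndarray,
    s: float,
    lap: Laplacian,
    config: FitConfig,
    n_inferred: int,
    subject_id: str,
) -> FitResult:
    idx = config.include_idx(lap.n_regions)
    pred = propagator(params, s, lap) @ x0
    c = cost(pred[idx], y[idx])
    r = _pearson(pred[idx], y[idx])
    mse = float(np.mean((y[idx] - pred[idx]) ** 2))
    return FitResult(
        seed=x0, params=params, cost=c,
        pearson_r=0.0 if np.isnan(r) else r,
        n_inferred=n_inferred, subject_id=subject_id, stage=s,
        extras={"mse": mse, "n_included": int(idx.size)},
    )


def fit_subject(
    y_i: np.ndarray,
    s_i: float,
    strategy: str,
    lap: Laplacian,
    config: FitConfig,
    cohort_fit: tuple[KineticParams, np.ndarray] | None = None,
    subject_id: str = "subject",
) -> FitResult:
    """Strategies 2-4: subject-level fits against baseline tau at stage s_i.

    subject_params : cohort seed fixed, fit (alpha, beta)       k = 2
    subject_seeds  : cohort rates fixed, fit the seed           k = n regions
    subject_both   : fit the seed under cohort rates, then fit
                     (alpha, beta) with that seed fixed         k = n + 2

    Stage-0 subjects are rejected: with no diffusion elapsed, the seed
    would be the data itself and the rates are unidentifiable.
    """
    if s_i < 1:
        raise ValueError("subject fitting requires stage >= 1")
    if strategy not in ("subject_params", "subject_seeds", "subject_both"):
        raise ValueError(f"not a subject-level strategy: {strategy!r}")
    if cohort_fit is None:
        raise ValueError(f"strategy {strategy!r} requires a cohort fit")
    theta_c, x0_c = cohort_fit
    y_i = np.asarray(y_i, dtype=float).ravel()
    n = lap.n_regions

    if strategy == "subject_params":
        params, _ = fit_params(y_i, s_i, x0_c, lap, config)
        return _result_for(x0_c, params, y_i, s_i, lap, config, 2, subject_id)
    if strategy == "subject_seeds":
        x0, _ = fit_seed(y_i, s_i, theta_c, lap, config, cohort_seed=x0_c)
        return _result_for(x0, theta_c, y_i, s_i, lap, config, n, subject_id)
    # subject_both: individually optimized seed under cohort rates first,
    # then subject-specific rates with that seed fixed, followed by a short
    # alternating refinement (the first seed fit is distorted when the
    # subject's true spread rate is far from the cohort's, and one more
    # seed pass under the subject's own rates removes that distortion).
    # The seed is renormalized to unit total mass before each rate refit:
    # at a single timepoint the seed amplitude and alpha are exactly
    # confounded (c*x0 is undone by alpha -> alpha - log(c)/s) and the
    # L1/L2 penalty is scale-invariant, so pinning the scale lets alpha
    # carry all overall growth.
    rates = theta_c
    x0 = x0_c
    best: tuple[float, np.ndarray, KineticParams] | None = None
    prev_cost = np.inf
    for _ in range(max(1, config.subject_refinements)):
        x0, _ = fit_seed(y_i, s_i, rates, lap, config, cohort_seed=x0)
        total = x0.sum()
        if total > 0:
            x0 = x0 / total
        rates, c_now = fit_params(y_i, s_i, x0, lap, config)
        if best is None or c_now < best[0]:
            best = (c_now, x0, rates)
        if prev_cost - c_now < config.outer_tol * max(abs(prev_cost), 1.0):
            break
        prev_cost = c_now
    _, x0, rates = best
    return _result_for(x0, rates, y_i, s_i, lap, config, n + 2, subject_id)


def fit_cohort_subjects(
    tau: pd.DataFrame,
    stages: np.ndarray,
    strategy: str,
    lap: Laplacian,
    config: FitConfig,
    cohort_fit: tuple[KineticParams, np.ndarray],
) -> list[FitResult]:
    """Fit every eligible subject (stage >= 1); stage-0 rows are skipped."""
    out = []
    stages = np.asarray(stages, dtype=float)
    for i, (sid, row) in enumerate(tau.iterrows()):
        if stages[i] < 1:
            logger.info("FIT_SKIP_STAGE0: subject %s at stage 0 skipped", sid)
            continue
        cfg = FitConfig(**{**config.__dict__, "rng_seed": config.rng_seed + i})
        out.append(
            fit_subject(
                row.to_numpy(dtype=float), stages[i], strategy, lap, cfg,
                cohort_fit=cohort_fit, subject_id=str(sid),
            )
        )
    return out


def strategy_aic(results: list[FitResult]) -> float:
    """Cohort AIC for one strategy: Gaussian likelihood of per-subject
    residual MSEs summed over subjects, penalized by total inferred count."""
    logL = sum(
        gaussian_loglik_from_mse(r.extras["mse"], r.extras["n_included"])
        for r in results
    )
    k = sum(r.n_inferred for r in results)
    return aic(logL, k)


# ---------------------------------------------------------------------------
# lambda selection
# ---------------------------------------------------------------------------

def select_lambda(
    targets: np.ndarray,
    stages: np.ndarray | float,
    params: KineticParams,
    lambda_grid: np.ndarray,
    lap: Laplacian,
    config: FitConfig,
) -> tuple[float, pd.DataFrame]:
    """Pick lambda at the elbow of the (MSE, L1/L2-ratio) trade-off curve.

    Seeds are fit at each grid value; both criteria are min-max normalized
    and the grid point of maximum discrete curvature of their sum is
    returned, along with the full diagnostic table for manual override.
    """
    lambda_grid = np.sort(np.asarray(lambda_grid, dtype=float))
    if lambda_grid.size < 3:
        raise ValueError("lambda grid needs at least 3 values")
    targets = np.atleast_2d(np.asarray(targets, dtype=float))
    stages = np.atleast_1d(np.asarray(stages, dtype=float))
    idx = config.include_idx(lap.n_regions)
    rows = []
    for lam in lambda_grid:
        cfg = FitConfig(**{**config.__dict__, "lam": float(lam)})
        x0, _ = fit_seed(targets, stages, params, lap, cfg)
        mses = []
        for s, y in zip(stages, targets):
            pred = propagator(params, float(s), lap) @ x0
            mses.append(np.mean((y[idx] - pred[idx]) ** 2))
        ratio = np.abs(x0).sum() / max(np.linalg.norm(x0), 1e-30)
        rows.append({"lambda": float(lam), "mse": float(np.mean(mses)),
                     "l1_ratio": float(ratio)})
    table = pd.DataFrame(rows)
    lam_star = elbow_lambda(
        table["lambda"].to_numpy(),
        table["mse"].to_numpy(),
        table["l1_ratio"].to_numpy(),
    )
    return lam_star, table


def elbow_lambda(grid: np.ndarray, mse: np.ndarray, ratio: np.ndarray) -> float:
    """Elbow of the joint normalized criterion by maximum discrete curvature."""
    order = np.argsort(grid)
    grid, mse, ratio = grid[order], mse[order], ratio[order]

    def norm(v):
        span = v.max() - v.min()
        return (v - v.min()) / span if span > 0 else np.zeros_like(v)

    joint = norm(mse) + norm(ratio)
    if np.allclose(joint, joint[0]):
        logger.warning("LAMBDA_FLAT_CURVE: trade-off flat; returning smallest lambda")
        return float(grid[0])
    # a grid point minimizing both criteria at once wins outright
    dominant = (mse <= mse.min() + 1e-15) & (ratio <= ratio.min() + 1e-15)
    if dominant.any():
        return float(grid[np.nonzero(dominant)[0][0]])
    curv = np.abs(np.diff(joint, 2))
    return float(grid[1 + int(np.argmax(curv))])
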