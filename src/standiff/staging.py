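"""Probabilistic disease staging from multimodal biomarkers.

A z-score event-based model (EBM) places subjects on a common pseudo-time
axis.  Events are crossings of per-biomarker abnormality thresholds
(z-scores relative to healthy controls); with B biomarkers and T thresholds
each there are E = B*T events and E+1 stages.  The generative model: at
stage s, biomarker b is normally distributed around a piecewise-linear mean
mu_b(s) that rises from 0, reaches threshold z_bj exactly at the sequence
position of event (b, j), and saturates at its top threshold; the standard
deviation is 1 because inputs are control-referenced z-scores.  The event
ordering is inferred by Metropolis-Hastings sampling over valid sequences,
abnormality thresholds are selected by maximizing the sampled likelihood
over a candidate grid, and each subject receives a posterior over stages
under a uniform stage prior.

The staging output feeds the diffusion model: stage-weighted averages of
subject tau maps form a cohort-level pseudo-longitudinal tau trajectory.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

logger = logging.getLogger(__name__)

_LOG_2PI = float(np.log(2.0 * np.pi))


# ---------------------------------------------------------------------------
# biomarker preprocessing
# ---------------------------------------------------------------------------

def suvr_normalize(
    tau_raw: pd.DataFrame, cerebellum_labels: tuple[str, str]
) -> pd.DataFrame:
    """Reference regional tau to the cerebellum and center at zero.

    Each regional value v becomes v / mean(left cerebellum, right
    cerebellum) - 1, per subject.  The cerebellum is used as reference
    because it stays largely tau-free even in late disease.
    """
    left, right = cerebellum_labels
    for lab in (left, right):
        if lab not in tau_raw.columns:
            raise KeyError(f"reference region {lab!r} missing from tau table")
    ref = tau_raw[[left, right]].mean(axis=1)
    if (ref <= 0).any():
        bad = tau_raw.index[ref <= 0].tolist()
        raise ValueError(f"non-positive cerebellar reference for subjects {bad}")
    return tau_raw.div(ref, axis=0) - 1.0


def age_regress(values: pd.DataFrame, ages: np.ndarray) -> pd.DataFrame:
    """Residualize every column on age (OLS with intercept).

    Returns observed minus fitted values.  Sex is deliberately not a
    covariate.
    """
    ages = np.asarray(ages, dtype=float)
    if len(ages) != len(values):
        raise ValueError("ages length does not match table")
    if len(ages) < 3:
        raise ValueError("need at least 3 subjects for age regression")
    if np.var(ages) == 0:
        raise ValueError("constant ages: age regression undefined")
    X = np.column_stack([np.ones_like(ages), ages])
    Y = values.to_numpy(dtype=float)
    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
    return pd.DataFrame(
        Y - X @ coef, index=values.index, columns=values.columns
    )


def zscore_vs_controls(
    values: pd.DataFrame, control_mask: np.ndarray
) -> pd.DataFrame:
    """Standardize each column against the healthy-control subset.

    z = (value - control mean) / control SD (sample SD, ddof=1).
    """
    control_mask = np.asarray(control_mask, dtype=bool)
    if control_mask.sum() < 2:
        raise ValueError("need at least 2 controls for z-scoring")
    ctl = values.loc[control_mask]
    mu = ctl.mean(axis=0)
    sd = ctl.std(axis=0, ddof=1)
    if (sd <= 0).any():
        bad = sd.index[sd <= 0].tolist()
        raise ValueError(f"degenerate control SD for {bad}")
    return (values - mu) / sd


def prepare_biomarkers(
    values: pd.DataFrame,
    ages: np.ndarray,
    control_mask: np.ndarray,
    decreasing: list[str] | None = None,
) -> pd.DataFrame:
    """Age-regress, z-score vs controls, and orient all markers abnormal-up.

    ``decreasing`` lists biomarkers that fall with disease (e.g. regional
    volumes, MMSE); their z-scores are sign-flipped so that larger z always
    means more abnormal.  Rows with missing values are dropped upstream.
    """
    if values.isna().any().any():
        n_before = len(values)
        keep = ~values.isna().any(axis=1)
        values = values.loc[keep]
        ages = np.asarray(ages)[keep.to_numpy()]
        control_mask = np.asarray(control_mask)[keep.to_numpy()]
        logger.warning(
            "STAGE_DROP_INCOMPLETE: dropped %d subjects with missing biomarkers",
            n_before - len(values),
        )
    z = zscore_vs_controls(age_regress(values, ages), control_mask)
    for name in decreasing or []:
        z[name] = -z[name]
    return z


# ---------------------------------------------------------------------------
# event model
# ---------------------------------------------------------------------------

Event = tuple[int, int]  # (biomarker index, threshold index)


@dataclass
class EventModel:
    """A fitted z-score event model.

    ``thresholds`` is (B, T) with strictly increasing rows; ``sequence`` is
    a permutation of all B*T events in which, for every biomarker, lower
    thresholds precede higher ones.
    """

    thresholds: np.ndarray
    sequence: list[Event]
    log_likelihood: float = np.nan
    biomarker_names: list[str] | None = None

    def __post_init__(self):
        self.thresholds = np.atleast_2d(np.asarray(self.thresholds, dtype=float))
        B, T = self.thresholds.shape
        if np.any(np.diff(self.thresholds, axis=1) <= 0):
            raise ValueError("thresholds must be strictly increasing per biomarker")
        if sorted(self.sequence) != [(b, j) for b in range(B) for j in range(T)]:
            raise ValueError("sequence is not a permutation of all events")
        if not sequence_valid(self.sequence):
            raise ValueError("sequence violates within-biomarker threshold order")

    @property
    def n_events(self) -> int:
        return len(self.sequence)

    @property
    def n_stages(self) -> int:
        return len(self.sequence) + 1

    def event_means(self) -> np.ndarray:
        """(n_stages, B) matrix of expected z-scores mu_b(s)."""
        return _event_means(self.thresholds, self.sequence)


def sequence_valid(sequence: list[Event]) -> bool:
    seen: dict[int, int] = {}
    for b, j in sequence:
        if j != seen.get(b, -1) + 1:
            return False
        seen[b] = j
    return True


def _event_means(thresholds: np.ndarray, sequence: list[Event]) -> np.ndarray:
    B, T = thresholds.shape
    E = B * T
    pos = np.empty((B, T))
    for i, (b, j) in enumerate(sequence):
        pos[b, j] = i + 1  # event at sequence slot i completes at stage i+1
    stages = np.arange(E + 1, dtype=float)
    M = np.empty((E + 1, B))
    for b in range(B):
        xp = np.concatenate([[0.0], pos[b], [float(E)]])
        fp = np.concatenate([[0.0], thresholds[b], [thresholds[b, -1]]])
        # guard: if the last event of b is the final event, xp has a repeat
        xp, idx = np.unique(xp, return_index=True)
        M[:, b] = np.interp(stages, xp, fp[idx])
    return M


def _stage_loglik_matrix(Z: np.ndarray, M: np.ndarray) -> np.ndarray:
    """(n_subjects, n_stages) log p(z_i | stage s) under unit-variance Gaussians."""
    B = Z.shape[1]
    z2 = np.einsum("ib,ib->i", Z, Z)
    m2 = np.einsum("sb,sb->s", M, M)
    cross = Z @ M.T
    return -0.5 * (z2[:, None] - 2.0 * cross + m2[None, :]) - 0.5 * B * _LOG_2PI


def ebm_log_likelihood(Z: np.ndarray | pd.DataFrame, model: EventModel) -> float:
    """Marginal log-likelihood of z-scored data under the event model.

    Sum over subjects of log mean over stages (uniform stage prior) of the
    product over biomarkers of N(z_ib; mu_b(s), 1).
    """
    Z = np.asarray(Z, dtype=float)
    if not np.all(np.isfinite(Z)):
        raise ValueError("non-finite z-scores")
    ll = _stage_loglik_matrix(Z, model.event_means())
    return float(np.sum(logsumexp(ll, axis=1) - np.log(model.n_stages)))


def _random_valid_sequence(events: list[Event], rng: np.random.Generator) -> list[Event]:
    perm = [events[i] for i in rng.permutation(len(events))]
    # within each biomarker, reassign threshold indices in order of appearance
    counters: dict[int, int] = {}
    out = []
    for b, _ in perm:
        j = counters.get(b, 0)
        out.append((b, j))
        counters[b] = j + 1
    return out


def _greedy_sequence(Z: np.ndarray, thresholds: np.ndarray) -> list[Event]:
    """Greedy insertion: add events one by one at their best-likelihood slot."""
    B, T = thresholds.shape
    seq: list[Event] = []
    for b in range(B):
        for j in range(T):
            best_ll, best_seq = -np.inf, None
            for pos in range(len(seq) + 1):
                cand = seq[:pos] + [(b, j)] + seq[pos:]
                if not _prefix_valid(cand):
                    continue
                ll = _partial_loglik(Z, thresholds, cand)
                if ll > best_ll:
                    best_ll, best_seq = ll, cand
            seq = best_seq
    return seq


def _prefix_valid(seq: list[Event]) -> bool:
    seen: dict[int, list[int]] = {}
    for b, j in seq:
        seen.setdefault(b, []).append(j)
    return all(v == sorted(v) for v in seen.values())


def _partial_loglik(Z: np.ndarray, thresholds: np.ndarray, seq: list[Event]) -> float:
    """Likelihood of a partial sequence: only inserted biomarkers' events count."""
    B, T = thresholds.shape
    E = len(seq)
    pos: dict[Event, int] = {ev: i + 1 for i, ev in enumerate(seq)}
    stages = np.arange(E + 1, dtype=float)
    cols, Ms = [], []
    done = {b for b in range(B) if (b, T - 1) in pos}
    for b in sorted(done):
        xp = np.concatenate([[0.0], [pos[(b, j)] for j in range(T)], [float(max(E, 1))]])
        fp = np.concatenate([[0.0], thresholds[b], [thresholds[b, -1]]])
        xp_u, idx = np.unique(xp, return_index=True)
        cols.append(b)
        Ms.append(np.interp(stages, xp_u, fp[idx]))
    if not cols:
        return 0.0
    M = np.column_stack(Ms)
    ll = _stage_loglik_matrix(Z[:, cols], M)
    return float(np.sum(logsumexp(ll, axis=1) - np.log(E + 1)))


def ebm_mcmc(
    Z: np.ndarray | pd.DataFrame,
    thresholds: np.ndarray,
    n_iter: int = 20_000,
    rng_seed: int = 0,
    init: list[Event] | None = None,
    n_random_inits: int = 10,
    biomarker_names: list[str] | None = None,
) -> tuple[EventModel, np.ndarray]:
    """Metropolis-Hastings sampling over event sequences.

    Proposal: swap two random sequence slots; proposals that break the
    within-biomarker threshold order are rejected outright.  Returns the
    best-likelihood model visited plus the per-iteration likelihood trace
    of the chain state.  Deterministic given ``rng_seed``.

    Initialization: greedy insertion plus ``n_random_inits`` seeded random
    valid sequences; the chain starts from the best of these.
    """
    if isinstance(Z, pd.DataFrame):
        if biomarker_names is None:
            biomarker_names = list(Z.columns)
        Z = Z.to_numpy(dtype=float)
    Z = np.asarray(Z, dtype=float)
    if not np.all(np.isfinite(Z)):
        raise ValueError("non-finite z-scores")
    thresholds = np.atleast_2d(np.asarray(thresholds, dtype=float))
    B, T = thresholds.shape
    if Z.shape[1] != B:
        raise ValueError(f"{Z.shape[1]} biomarkers in data, {B} threshold rows")
    rng = np.random.default_rng(rng_seed)
    events = [(b, j) for b in range(B) for j in range(T)]
    E = len(events)

    def loglik(seq: list[Event]) -> float:
        M = _event_means(thresholds, seq)
        ll = _stage_loglik_matrix(Z, M)
        return float(np.sum(logsumexp(ll, axis=1) - np.log(E + 1)))

    candidates = [init] if init is not None else [_greedy_sequence(Z, thresholds)]
    candidates += [_random_valid_sequence(events, rng) for _ in range(n_random_inits)]
    cand_ll = [loglik(s) for s in candidates]
    cur = candidates[int(np.argmax(cand_ll))]
    cur_ll = max(cand_ll)
    best, best_ll = list(cur), cur_ll

    trace = np.empty(max(n_iter, 0))
    for it in range(n_iter):
        i, j = rng.integers(0, E, size=2)
        if i != j:
            prop = list(cur)
            prop[i], prop[j] = prop[j], prop[i]
            if sequence_valid(prop):
                prop_ll = loglik(prop)
                if np.log(rng.random()) < prop_ll - cur_ll:
                    cur, cur_ll = prop, prop_ll
                    if cur_ll > best_ll:
                        best, best_ll = list(cur), cur_ll
        trace[it] = cur_ll

    model = EventModel(
        thresholds=thresholds,
        sequence=best,
        log_likelihood=best_ll,
        biomarker_names=biomarker_names,
    )
    return model, trace


def select_thresholds(
    Z: np.ndarray | pd.DataFrame,
    candidate_sets: list[np.ndarray],
    n_iter: int = 20_000,
    rng_seed: int = 0,
) -> tuple[EventModel, pd.DataFrame]:
    """Exhaustive threshold selection by maximum MCMC sampling likelihood.

    Runs :func:`ebm_mcmc` for every candidate (B, T) threshold array and
    returns the best model together with a per-candidate likelihood table.
    """
    if not candidate_sets:
        raise ValueError("empty candidate threshold list")
    rows, models = [], []
    for k, cand in enumerate(candidate_sets):
        model, _ = ebm_mcmc(Z, cand, n_iter=n_iter, rng_seed=rng_seed + k)
        models.append(model)
        rows.append(
            {"candidate": k, "log_likelihood": model.log_likelihood}
        )
    table = pd.DataFrame(rows)
    best = models[int(table["log_likelihood"].idxmax())]
    return best, table


# ---------------------------------------------------------------------------
# stage posteriors and trajectories
# ---------------------------------------------------------------------------

@dataclass
class StagePosterior:
    """Per-subject posterior over stages; rows sum to 1."""

    probs: np.ndarray            # (n_subjects, n_stages)
    most_likely_stage: np.ndarray  # (n_subjects,)
    subject_ids: list | None = None


def stage_posteriors(
    Z: np.ndarray | pd.DataFrame, model: EventModel
) -> StagePosterior:
    """Posterior pr(i = s) under a uniform stage prior.

    Ties in the argmax resolve to the lowest stage (conservative staging).
    """
    subject_ids = list(Z.index) if isinstance(Z, pd.DataFrame) else None
    Z = np.asarray(Z, dtype=float)
    if not np.all(np.isfinite(Z)):
        raise ValueError("non-finite z-scores")
    ll = _stage_loglik_matrix(Z, model.event_means())
    ll -= ll.max(axis=1, keepdims=True)
    probs = np.exp(ll)
    probs /= probs.sum(axis=1, keepdims=True)
    return StagePosterior(
        probs=probs,
        most_likely_stage=np.argmax(probs, axis=1),
        subject_ids=subject_ids,
    )


@dataclass
class CohortTrajectory:
    """Stage-resolved cohort tau maps y(s), one row per stage."""

    tau: np.ndarray      # (n_stages, n_regions)
    stages: np.ndarray
    region_labels: list[str] | None = None


def cohort_trajectory(
    posteriors: StagePosterior, tau: np.ndarray | pd.DataFrame
) -> CohortTrajectory:
    """Posterior-weighted cohort tau map per stage.

    y(s) = sum_i pr(i=s) y_i / sum_i pr(i=s).  Weighting by assignment
    probability smooths over the uneven distribution of subjects across
    stages.  A stage with total weight below 1e-12 is an error.
    """
    labels = list(tau.columns) if isinstance(tau, pd.DataFrame) else None
    Y = np.asarray(tau, dtype=float)
    P = posteriors.probs
    if P.shape[0] != Y.shape[0]:
        raise ValueError("posterior and tau tables have different subject counts")
    totals = P.sum(axis=0)
    empty = np.nonzero(totals < 1e-12)[0]
    if empty.size:
        raise ValueError(f"stages with no posterior mass: {empty.tolist()}")
    traj = (P.T @ Y) / totals[:, None]
    return CohortTrajectory(
        tau=traj, stages=np.arange(P.shape[1], dtype=float), region_labels=labels
    )
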