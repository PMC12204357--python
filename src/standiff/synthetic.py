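"""Synthetic cohorts with known ground truth.

Everything the pipeline consumes can be generated here with planted truth:
a connected symmetric connectome, per-subject seeds drawn from two
archetypes (focal "entorhinal-like" vs diffuse "temporal-like"), kinetic
rates with the diffuse archetype agglomerating faster on average,
discrete disease stages, baseline tau from the forward model plus
truncated Gaussian noise, stage-linked biomarker z-scores from the same
piecewise-linear event model the staging module fits, clinical covariates
with a planted archetype-genotype association and a planted
rate-cognition coupling, and longitudinal follow-up visits.

Default cohort dimensions mirror a realistic single-site tau-PET study:
78 included regions, 165 patients plus 60 healthy controls, 5 biomarkers
with 3 abnormality thresholds each (16 stages), a quarter of patients in
the diffuse archetype, and 5% observation noise.  Generation is
bit-reproducible from (spec, rng_seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .connectome import Connectome, Laplacian, build_laplacian
from .diffusion import KineticParams, forward
from .prediction import LongitudinalRecord
from .staging import EventModel, _event_means

#: default per-biomarker abnormality slopes, z-score units per stage.
#: Distinct slopes interleave the threshold-crossing events into a unique
#: planted ordering, and every biomarker reaches its top threshold within
#: the 16-stage grid.
DEFAULT_SLOPES = (1.0, 0.8, 0.64, 0.52, 0.42)

DEFAULT_BIOMARKERS = (
    "entorhinal_tau", "hippocampal_tau", "amygdala_tau",
    "hippocampal_volume", "adas11",
)


@dataclass
class CohortSpec:
    """Parameters of the synthetic study."""

    n_regions: int = 78
    n_subjects: int = 165           # patients (staged >= 1)
    n_controls: int = 60
    archetype_mix: float = 0.25     # fraction of diffuse-archetype patients
    alpha_range: tuple[float, float] = (0.05, 0.5)
    beta_range: tuple[float, float] = (0.1, 1.0)
    n_thresholds: int = 3
    threshold_step: float = 2.0     # thresholds at step, 2*step, ...
    biomarker_slopes: tuple[float, ...] = DEFAULT_SLOPES
    biomarker_names: tuple[str, ...] = DEFAULT_BIOMARKERS
    stage_distribution: np.ndarray | None = None  # over 1..n_stages-1
    noise_sd_frac: float = 0.05
    apoe4_freq: tuple[float, float] = (0.3, 0.6)  # (focal, diffuse)
    cognition_alpha_coupling: float = 0.3
    connectome_density: float = 0.3
    rng_seed: int = 0

    def __post_init__(self):
        if min(self.n_regions, self.n_subjects, self.n_controls) <= 0:
            raise ValueError("counts must be positive")
        if not 0 <= self.archetype_mix <= 1:
            raise ValueError("archetype_mix must be in [0, 1]")
        if len(self.biomarker_slopes) != len(self.biomarker_names):
            raise ValueError("one slope per biomarker required")

    @property
    def n_biomarkers(self) -> int:
        return len(self.biomarker_slopes)

    @property
    def n_stages(self) -> int:
        return self.n_biomarkers * self.n_thresholds + 1


def well_separated_staging_spec(**overrides) -> CohortSpec:
    """Spec variant for event-sequence recovery studies.

    Five biomarkers with two abnormality thresholds each at z = 4 and 8:
    threshold gaps far above the unit z-score noise, so the maximum-
    likelihood event ordering coincides with the planted one at moderate
    sample sizes.  With gap-1 thresholds adjacent event orderings are only
    weakly identified at n = 200 and exact sequence recovery is not a
    fair expectation of any sampler.
    """
    base = dict(
        threshold_step=4.0,
        n_thresholds=2,
        biomarker_slopes=(1.6, 1.35, 1.15, 0.97, 0.82),
    )
    base.update(overrides)
    return CohortSpec(**base)


@dataclass
class SyntheticCohort:
    """A generated cohort with full ground truth attached."""

    spec: CohortSpec
    connectome: Connectome
    laplacian: Laplacian
    tau_baseline: pd.DataFrame       # patients x regions
    tau_controls: pd.DataFrame       # controls x regions
    biomarkers: pd.DataFrame         # (patients + controls) x biomarkers, z units
    covariates: pd.DataFrame         # diagnosis, age, apoe4, adas11, mmse
    control_mask: np.ndarray         # over biomarker table rows
    true_seeds: np.ndarray           # (patients, regions)
    true_params: pd.DataFrame        # alpha, beta per patient
    true_stages: np.ndarray          # per patient, >= 1
    true_archetypes: np.ndarray      # 0 = focal, 1 = diffuse
    event_model: EventModel          # planted thresholds + sequence
    longitudinal: list[LongitudinalRecord] = field(default_factory=list)


# ---------------------------------------------------------------------------
# pieces
# ---------------------------------------------------------------------------

def make_connectome(
    n_regions: int, density: float = 0.3, rng_seed: int = 0
) -> Connectome:
    """Distance-decayed random geometric connectome, guaranteed connected.

    Regions are points in the unit cube; candidate edge weights decay
    exponentially with distance.  Edges are kept with probability
    ``density``; the Euclidean minimum spanning tree is always added back
    so no region is isolated.
    """
    if n_regions < 4:
        raise ValueError("need at least 4 regions")
    if not 0 < density <= 1:
        raise ValueError("density must be in (0, 1]")
    rng = np.random.default_rng(rng_seed)
    pts = rng.uniform(size=(n_regions, 3))
    diff = pts[:, None, :] - pts[None, :, :]
    dist = np.sqrt((diff**2).sum(-1))
    W = np.exp(-dist / 0.3)
    np.fill_diagonal(W, 0.0)
    keep = rng.random((n_regions, n_regions)) < density
    keep = keep | keep.T
    G = nx.from_numpy_array(dist)
    mst = nx.minimum_spanning_tree(G)
    for i, j in mst.edges:
        keep[i, j] = keep[j, i] = True
    W = W * keep
    labels = [f"R{i:03d}" for i in range(n_regions)]
    return Connectome.from_array(W, labels)


#: index of the focal "entorhinal-like" region and the diffuse
#: "temporal-like" block used by the seed generator
FOCAL_REGION = 0
DIFFUSE_BLOCK = slice(1, 9)


def make_seeds(
    n_subjects: int,
    archetype_mix: float,
    n_regions: int,
    rng_seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw per-subject seeds from the two archetypes.

    Focal: ~85% of mass on the designated entorhinal-like region plus a
    small uniform background.  Diffuse: mass Dirichlet-spread over the
    designated temporal-like block plus background.  Each seed gets
    multiplicative amplitude jitter and is scaled to unit total mass times
    the jitter.  Returns (seeds, labels) with label 1 = diffuse.
    """
    rng = np.random.default_rng(rng_seed)
    labels = (rng.random(n_subjects) < archetype_mix).astype(int)
    seeds = np.empty((n_subjects, n_regions))
    block = np.arange(n_regions)[DIFFUSE_BLOCK]
    for i, lab in enumerate(labels):
        x = np.full(n_regions, 0.1 / n_regions)  # small background
        if lab == 0:
            x[FOCAL_REGION] += 0.9 * rng.uniform(0.95, 1.05)
        else:
            x[block] += 0.9 * rng.dirichlet(np.full(block.size, 2.0))
        x *= rng.uniform(0.8, 1.2)  # amplitude jitter
        seeds[i] = x
    return seeds, labels


def planted_event_model(spec: CohortSpec) -> EventModel:
    """Event model implied by the spec's biomarker slopes.

    Biomarker b crosses threshold j*step at stage j*step/slope_b; the
    planted sequence orders all crossings by that stage.
    """
    B, T = spec.n_biomarkers, spec.n_thresholds
    step = spec.threshold_step
    thresholds = np.outer(np.ones(B), np.arange(1, T + 1) * step)
    crossings = [
        (thresholds[b, j] / spec.biomarker_slopes[b], (b, j))
        for b in range(B) for j in range(T)
    ]
    sequence = [ev for _, ev in sorted(crossings)]
    return EventModel(
        thresholds=thresholds,
        sequence=sequence,
        biomarker_names=list(spec.biomarker_names),
    )


def make_ebm_cohort(
    model: EventModel,
    n_subjects: int,
    rng_seed: int = 0,
    stage_probs: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample z-scores from the event model's own generative process.

    Stages are drawn from ``stage_probs`` (uniform over all stages by
    default); z_ib ~ N(mu_b(stage_i), 1).  Returns (Z, stages).
    """
    rng = np.random.default_rng(rng_seed)
    S = model.n_stages
    p = np.full(S, 1.0 / S) if stage_probs is None else np.asarray(stage_probs)
    stages = rng.choice(S, size=n_subjects, p=p / p.sum())
    M = model.event_means()
    Z = M[stages] + rng.standard_normal((n_subjects, M.shape[1]))
    return Z, stages


# ---------------------------------------------------------------------------
# full cohort
# ---------------------------------------------------------------------------

def make_cohort(spec: CohortSpec, connectome: Connectome | None = None) -> SyntheticCohort:
    """Generate the full synthetic study defined by ``spec``."""
    rng = np.random.default_rng(spec.rng_seed)
    if connectome is None:
        connectome = make_connectome(
            spec.n_regions, spec.connectome_density,
            rng_seed=int(rng.integers(2**31 - 1)),
        )
    lap = build_laplacian(connectome)
    n, n_reg = spec.n_subjects, connectome.n_regions
    labels = connectome.region_labels

    seeds, arch = make_seeds(
        n, spec.archetype_mix, n_reg, rng_seed=int(rng.integers(2**31 - 1))
    )

    # kinetics: diffuse archetype draws alpha from the upper part of the
    # range, focal from the lower part; beta is archetype-independent
    a_lo, a_hi = spec.alpha_range
    a_mid = a_lo + 0.6 * (a_hi - a_lo)
    alpha = np.where(
        arch == 1,
        rng.uniform(a_lo + 0.4 * (a_hi - a_lo), a_hi, size=n),
        rng.uniform(a_lo, a_mid, size=n),
    )
    beta = rng.uniform(*spec.beta_range, size=n)

    # stages: patients uniform over 1..n_stages-1 unless specified
    S = spec.n_stages
    if spec.stage_distribution is None:
        p = np.full(S - 1, 1.0 / (S - 1))
    else:
        p = np.asarray(spec.stage_distribution, dtype=float)
        p = p / p.sum()
    stages = rng.choice(np.arange(1, S), size=n, p=p)

    # baseline tau = forward model + truncated Gaussian noise
    tau = np.empty((n, n_reg))
    noise_sd = np.empty(n)
    for i in range(n):
        clean = forward(
            seeds[i], KineticParams(alpha[i], beta[i]), float(stages[i]), lap
        ).x[0]
        noise_sd[i] = spec.noise_sd_frac * clean.std(ddof=1)
        tau[i] = np.clip(clean + rng.normal(0, noise_sd[i], n_reg), 0.0, None)
    subj_ids = [f"sub-{i:04d}" for i in range(n)]
    tau_baseline = pd.DataFrame(tau, index=subj_ids, columns=labels)

    # controls: stage 0, tau is reference-level noise only
    ctl_ids = [f"ctl-{i:04d}" for i in range(spec.n_controls)]
    ctl_scale = max(float(np.median(noise_sd)), 1e-3)
    tau_controls = pd.DataFrame(
        np.clip(rng.normal(0, ctl_scale, (spec.n_controls, n_reg)), 0.0, None),
        index=ctl_ids, columns=labels,
    )

    # biomarkers from the planted event model (z units, abnormal-up)
    model = planted_event_model(spec)
    M = model.event_means()
    Z_pat = M[stages] + rng.standard_normal((n, spec.n_biomarkers))
    Z_ctl = rng.standard_normal((spec.n_controls, spec.n_biomarkers))
    biomarkers = pd.DataFrame(
        np.vstack([Z_pat, Z_ctl]),
        index=subj_ids + ctl_ids,
        columns=list(spec.biomarker_names),
    )
    control_mask = np.array([False] * n + [True] * spec.n_controls)

    # covariates: age (no planted age effect), APOE4 enriched in the
    # diffuse archetype, cognition coupled to alpha beyond stage
    age = rng.normal(72.0, 5.0, n + spec.n_controls)
    apoe_p = np.where(arch == 1, spec.apoe4_freq[1], spec.apoe4_freq[0])
    apoe4 = np.concatenate([
        (rng.random(n) < apoe_p).astype(int),
        (rng.random(spec.n_controls) < spec.apoe4_freq[0]).astype(int),
    ])
    alpha_z = (alpha - alpha.mean()) / max(alpha.std(), 1e-12)
    c = spec.cognition_alpha_coupling
    adas = 10.0 + 1.5 * np.concatenate([stages, np.zeros(spec.n_controls)])
    adas[:n] += 5.0 * (c * alpha_z + np.sqrt(max(1 - c**2, 0.0)) * rng.standard_normal(n))
    adas[n:] += 5.0 * rng.standard_normal(spec.n_controls)
    mmse = 30.0 - 0.6 * np.concatenate([stages, np.zeros(spec.n_controls)])
    mmse[:n] -= 2.0 * (c * alpha_z + np.sqrt(max(1 - c**2, 0.0)) * rng.standard_normal(n))
    mmse[n:] -= 2.0 * rng.standard_normal(spec.n_controls)
    covariates = pd.DataFrame({
        "diagnosis": ["patient"] * n + ["control"] * spec.n_controls,
        "age": age,
        "apoe4": apoe4,
        "adas11": adas,
        "mmse": np.clip(mmse, 0, 30),
    }, index=subj_ids + ctl_ids)

    # longitudinal visits at +1 and +2 years from the same forward model
    longitudinal = []
    for i in range(n):
        visits = []
        for dt in (1.0, 2.0):
            clean = forward(
                seeds[i], KineticParams(alpha[i], beta[i]),
                float(stages[i]) + dt, lap,
            ).x[0]
            obs = np.clip(clean + rng.normal(0, noise_sd[i], n_reg), 0.0, None)
            visits.append((dt, obs))
        longitudinal.append(
            LongitudinalRecord(
                subject_id=subj_ids[i],
                baseline_stage=float(stages[i]),
                visits=visits,
            )
        )

    return SyntheticCohort(
        spec=spec,
        connectome=connectome,
        laplacian=lap,
        tau_baseline=tau_baseline,
        tau_controls=tau_controls,
        biomarkers=biomarkers,
        covariates=covariates,
        control_mask=control_mask,
        true_seeds=seeds,
        true_params=pd.DataFrame({"alpha": alpha, "beta": beta}, index=subj_ids),
        true_stages=stages,
        true_archetypes=arch,
        event_model=model,
        longitudinal=longitudinal,
    )
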