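# Methods

`standiff` couples two models that are individually standard in
neurodegeneration research — an event-based disease-progression model
(EBM) and a network diffusion model (NDM) — so that a single baseline
tau-PET scan plus multimodal biomarkers suffice to infer a personalized
spatiotemporal model of tau spread and forecast its future course.

## Staging: the z-score event-based model

Biomarkers are oriented so that larger values mean more abnormal
(volumes and MMSE are sign-flipped), age-residualized by per-feature OLS
(sex is deliberately not a covariate), and z-scored against the
healthy-control subset (sample SD).  With B biomarkers and T abnormality
thresholds per biomarker there are E = B·T events — crossings of a
threshold — and E + 1 stages.

The generative model: at stage s, biomarker b is Gaussian with unit SD
around a piecewise-linear mean μ_b(s) that starts at 0, passes through
threshold z_bj exactly at the sequence position of event (b, j), and
saturates at the top threshold.  σ_b = 1 for all biomarkers because
inputs are control-referenced z-scores; no per-biomarker variance model
is attempted.  The marginal likelihood sums over stages with a uniform
stage prior.

The event ordering is sampled by Metropolis–Hastings over valid
sequences (proposal: swap two slots; swaps violating the
lower-before-higher threshold order within a biomarker are rejected).
Initialization is greedy insertion plus 10 seeded random valid
sequences, starting the chain at the best.  Abnormality thresholds are
selected by exhaustively re-running the sampler on a candidate grid and
keeping the maximum sampled likelihood.  Stage posteriors are the
per-stage Gaussian products normalized per subject; ties in the argmax
resolve to the lower stage (conservative staging).

A cohort-level tau trajectory interpolates the cross-section: for every
stage, y(s) is the posterior-weighted average of subject tau maps,
which smooths over the uneven distribution of subjects across stages.

**Identifiability note.**  With unit noise and threshold gaps of 1 z,
the order of adjacent events in a 15-event sequence is only weakly
identified at n = 200: the maximum-likelihood sequence frequently
differs from the generating one (we verified the sampler reaches
likelihoods above the planted sequence's).  Exact-sequence recovery
studies therefore use a well-separated configuration (5 biomarkers × 2
thresholds at z = 4 and 8, `well_separated_staging_spec`), under which
the sampler recovers the planted order essentially always; stage
*assignment* is much more robust and already accurate at gap-2
thresholds.

## Forward model: linear reaction–diffusion on the connectome

Regional tau x evolves as dx/ds = (−βℒ + αI)x on the symmetric
normalized Laplacian ℒ = I − D^(−1/2)CD^(−1/2) of the structural
connectome (asymmetric inputs are averaged; isolated regions are
rejected).  β (per stage) is the inter-region spread rate, α (per
stage) the within-region agglomeration rate; both are constrained to
[0, 10] per stage during fitting — negative rates are unphysical — with
configurable bounds.  The closed form x(s) = e^((−βℒ+αI)s) x(0) is
evaluated through the eigendecomposition of ℒ (computed once per
connectome and reused for every (α, β, s)); agreement with direct
`expm` and with adaptive ODE integration is part of the test suite.

Stage is used as pseudo-time: the affine stage-to-time map is absorbed
into α, β and the seed, so no time constants are estimated.  Useful
identities: √degree spans the null space of ℒ, so ⟨d^{1/2}, x(s)⟩ =
e^{αs}⟨d^{1/2}, x(0)⟩ (conservation when α = 0), and any nonnegative
seed relaxes toward the d^{1/2} direction — the origin of the
stage-wise convergence phenomenon in the heterogeneity analyses.

## Inverse problem

The fit cost is E(x, y) = MSE(y, x) − 0.5·R(x, y) with R Pearson's
correlation.  MSE is a mean over included regions (not a summed norm)
so the two terms stay commensurate across region counts.  Regions on an
exclusion mask (e.g. striatum, off-target tracer binding) are removed
from the cost only; simulation always runs on the full graph.  Seed
optimization adds the scale-invariant sparsity penalty λ‖x(0)‖₁/‖x(0)‖₂
(1 for one-hot, √n for uniform).  Default λ = 0.03, calibrated on
planted-recovery simulations as the best trade-off between seed
sparsity and fit fidelity; λ can also be chosen per dataset at the
elbow (maximum discrete curvature) of the MSE vs L1/L2 trade-off curve.

Rate fits run an ensemble — basin hopping, differential evolution,
Powell, L-BFGS-B (the gradient of the stage-averaged cost in (α, β) is
analytic) — and keep the best minimum; all stochastic optimizers are
seeded.  Seed fits use bound-constrained L-BFGS-B with an analytic
gradient from multiple starts: the target itself, its least-squares
back-propagation through the diffusion kernel ("going back in time"),
the cohort seed, and 5 seeded sparse random starts.  All-zero solutions
are rejected.

Four strategies:

1. **cohort_iterative** — seed initialized to the stage-0 trajectory
   row, then alternating rate/seed minimization against the stage-≥1
   cohort trajectory until relative improvement < 1e−4 or 10 outer
   iterations; the cost trace is non-increasing by construction.
2. **subject_params** (k = 2) — cohort seed, subject rates.
3. **subject_seeds** (k = n regions) — cohort rates, subject seed.
4. **subject_both** (k = n + 2) — subject seed inferred under cohort
   rates, then subject rates with that seed fixed, followed by up to 3
   short seed/rate alternations with early stopping.

Two design choices in strategy 4 deserve comment.  First, at a single
baseline timepoint the seed amplitude and α are exactly confounded
(c·x(0) is undone by α → α − log c/s) and the sparsity penalty is
scale-invariant, so the seed is renormalized to unit total mass before
each rate refit; α then carries all overall growth.  Without this
pinning the refit α simply returns the cohort α.  Second, the extra
alternations matter when a subject's true spread rate is far from the
cohort's: the first seed fit is then shape-distorted, and one more seed
pass under the subject's own rates removes the distortion.

Controls and stage-0 subjects are excluded from subject-level fitting:
at stage 0 the seed equals the data and no diffusion information
exists.

AIC uses logL = −n/2·(log(2π·MSE) + 1) per subject (Gaussian residuals
at the fitted variance), summed over subjects, with k summed likewise.
Seed sparsity is additionally summarized as the number of regions
holding 90% of the seed's total mass ("energy").

**Limitation.**  For late-stage subjects with large β·s the diffusion
kernel is numerically near rank-one: the observed pattern is close to
the d^{1/2} fixed point and the seed is fundamentally unidentifiable
(any seed with the right mass fits).  Recovery statistics are therefore
reported as medians over subjects; α and the predicted pattern remain
accurate even in those cases.

## Prediction

Follow-up stages come from a 1:1 mapping between years and stages,
s_l = s_b + Δt, with s_b the most-likely baseline stage (not the
posterior mean).  Stages beyond the staging grid are allowed — the flow
is defined for all real s.  Validation reports per-visit Pearson R and
MSE against observed follow-up tau, aggregated both by pooling visits
and by averaging per subject first (the two aggregates are reported
side by side since either convention is defensible).

## Heterogeneity and archetypes

Per subject and stage the package computes the coefficient of variation
of tau across regions (sample SD by default; a `ddof` switch gives the
population convention) and, across subjects, the distribution of
pairwise Pearson/Spearman correlations of predicted tau per stage.
Rate–cognition associations residualize the cognitive score on age and
stage (the score only, not the rates) and report Pearson r with
two-sided p.

Seed archetypes are found two ways on the subject-specific seeds: (i)
SVD of the uncentered second-moment matrix A = Σᵢ xᵢ(0)xᵢ(0)ᵀ — A is
implemented uncentered exactly as defined, with a `centered` option
since the centering convention is a genuine ambiguity — classifying
each subject to the top singular vector (sign-fixed
largest-entry-positive) most correlated with their seed; and (ii)
seeded K-means (k-means++ with 10 restarts) with K selected at the
maximum-curvature elbow of the inertia curve.  Label agreement between
methods and against planted truth is evaluated after Hungarian matching
of cluster labels.  Archetype–covariate associations use chi-square
(categorical) and one-way ANOVA (continuous).

## Synthetic cohorts

The generator plants every quantity the pipeline later infers.
Defaults: 78 regions, 165 patients + 60 controls, 16 stages
(5 biomarkers × 3 thresholds), 25% diffuse-archetype mix, α ∈
[0.05, 0.5] and β ∈ [0.1, 1.0] per stage, 5% observation noise.
Specifics:

* **Connectome** — random geometric graph in the unit cube with
  exponentially distance-decayed weights, edges kept with a density
  parameter, minimum-spanning-tree backbone guaranteeing connectivity.
* **Seeds** — focal archetype: ~90% of mass on a designated
  "entorhinal-like" region; diffuse archetype: Dirichlet-weighted mass
  over a contiguous "temporal-like" block; small uniform background and
  ±20% amplitude jitter; unit total mass before jitter.
* **Rates** — diffuse subjects draw α from the upper part of the range,
  focal from the lower (the planted rate–archetype association);
  β is archetype-independent.
* **Tau** — forward model at the planted stage plus Gaussian noise
  (SD = 5% of the per-subject signal SD), truncated at 0.
* **Biomarkers** — z-scores drawn from the event model implied by
  per-biomarker slopes (z per stage); distinct slopes at gap-2
  thresholds give a unique planted event sequence with all crossings
  inside the stage grid.  Controls are standard normal at stage 0.
* **Covariates** — age (no planted age effect), an APOE4-like binary
  enriched in the diffuse archetype (0.6 vs 0.3 carrier frequency),
  and two cognitive scores coupled to α (r ≈ 0.3) beyond a stage trend.
* **Longitudinal** — visits at +1 and +2 years from the same forward
  model plus noise.

What the generator does **not** emulate: off-target binding structure,
scanner/site effects, non-Gaussian PET noise, missing-data patterns,
atypical disease variants, and any nonlinearity in the stage–time
relationship.  Passing recovery tests on these cohorts demonstrates
the correctness and identifiability behavior of the algorithms under
the model's own assumptions; it does not certify performance on real
PET data.

## Problem sizes and numerical choices

Recovery studies use 50 planted subjects at 78 regions with 5% noise;
staging recovery uses 20 replicates of n = 200 with 20,000 MCMC
iterations; archetype recovery uses 160 subjects at mix 0.25; the
AIC comparison uses 30 subjects at 40 regions with rates varying
moderately around the cohort values (spatial heterogeneity dominating,
the regime the strategy comparison addresses); the end-to-end
reproducibility check runs the full pipeline twice on a 20-region,
12-patient cohort.  Symmetry tolerance for connectomes is a relative
1e−8; the alternating cohort loop stops at relative improvement 1e−4;
stage posteriors are normalized to 1e−9; floats are serialized at 17
significant digits and parsed in round-trip mode so pipeline artifacts
are byte-stable across reruns with the same seed.
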