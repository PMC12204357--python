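# standiff — stage-based network diffusion modeling of tau spread

`standiff` infers personalized spatiotemporal models of tau pathology
from a *single baseline* tau-PET scan.  It is aimed at researchers in
neurodegeneration who have cross-sectional regional tau tables,
multimodal biomarkers, and a structural connectome, and want
subject-level estimates of *where* tau seeding began, *how fast* it
accumulates and spreads, and *what the regional pattern will look like*
years later — without longitudinal training data.

## The model

Two standard ingredients are coupled through a pseudo-time axis:

1. **Staging (event-based model).**  Biomarkers z-scored against
   healthy controls cross abnormality thresholds in an unknown order;
   with B biomarkers and T thresholds there are B·T events and B·T + 1
   stages.  The event order is sampled by MCMC, thresholds are selected
   by maximum sampled likelihood, and each subject receives a posterior
   pr(i = s) over stages.  Stage-weighted averages of subject tau maps
   give a cohort trajectory y(s) — a pseudo-longitudinal time series
   built from a cross-section.

2. **Diffusion (network reaction–diffusion model).**  Regional tau
   x evolves on the connectome's symmetric normalized Laplacian
   ℒ = I − D^(−1/2)CD^(−1/2):

       dx/ds = (−βℒ + αI) x,     x(s) = e^((−βℒ+αI)s) x(0)

   with spread rate β and agglomeration rate α per stage, and seed
   x(0) — the regional tau pattern at disease onset.

Fitting minimizes E(x, y) = MSE(y, x) − 0.5·R(x, y) (R = Pearson) plus
a scale-invariant seed-sparsity penalty λ‖x(0)‖₁/‖x(0)‖₂, with an
ensemble of seeded global/local optimizers.  Seed and rates can be
cohort-level or subject-specific (four strategies, compared by AIC);
the fully individualized strategy fits a seed and rates per subject and
forecasts future tau by evaluating the flow at s = s_baseline + Δt
years.  Downstream analyses quantify stage-wise convergence of tau
patterns (CoV across regions, pairwise inter-subject correlations) and
discover seeding archetypes (SVD of the seed second-moment matrix;
K-means with elbow selection).

See `docs/methods.md` for assumptions, parameter defaults, and
limitations.

## Worked example

Everything is testable without external data through the synthetic
cohort generator, which plants seeds, rates, stages, and archetypes and
generates tau with the forward model:

```python
import numpy as np
from standiff import (CohortSpec, make_cohort, stage_posteriors,
                      cohort_trajectory, fit_cohort_iterative,
                      fit_subject, FitConfig, KineticParams)

coh = make_cohort(CohortSpec(n_regions=40, n_subjects=30, n_controls=20,
                             rng_seed=7))
post = stage_posteriors(coh.biomarkers, coh.event_model)
patients = ~coh.control_mask
rho = np.corrcoef(post.most_likely_stage[patients], coh.true_stages)[0, 1]
print(f"stage recovery r = {rho:.3f}")

i = int(np.argmin(np.abs(coh.true_stages - 6)))   # a mid-stage subject
res = fit_subject(coh.tau_baseline.iloc[i].to_numpy(),
                  float(coh.true_stages[i]), "subject_both",
                  coh.laplacian, FitConfig(rng_seed=0),
                  cohort_fit=(KineticParams(0.275, 0.55),
                              coh.true_seeds.mean(axis=0)))
print(f"alpha {res.params.alpha:.3f} (true {coh.true_params.alpha.iloc[i]:.3f}), "
      f"beta {res.params.beta:.3f} (true {coh.true_params.beta.iloc[i]:.3f}), "
      f"fit R {res.pearson_r:.3f}")
```

prints (seed 7):

```
stage recovery r = 0.972
alpha 0.437 (true 0.452), beta 0.209 (true 0.187), fit R 0.994
```

The first line says assigned stages track the planted disease stages
almost perfectly; the second says the individualized fit recovered this
subject's planted kinetic rates to ~0.02 and reproduces their baseline
tau pattern at R = 0.994 despite 5% observation noise.

More narrative walk-throughs live in `examples/` (one script per
capability: simulation, staging, fitting, prediction, heterogeneity,
archetypes); each builds a small synthetic input, runs the method, and
prints what the numbers mean.

A thin CLI wraps the same library:

```bash
stand simulate-cohort --out cohort/ --seed 1 --n-regions 40 --n-subjects 30
stand run --connectome cohort/connectome.csv --tau cohort/tau.csv \
          --biomarkers cohort/biomarkers.csv --longitudinal cohort/longitudinal.csv \
          --out run/ --seed 1
```

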