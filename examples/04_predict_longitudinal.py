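"""Prediction: forecast follow-up tau and validate against observations.

Generates a small synthetic cohort with longitudinal visits, fits each
patient's model to baseline only, and scores forecasts at +1 and +2
years (stage = baseline stage + years).  Printed numbers: mean Pearson R
and MSE between predicted and observed follow-up tau.
"""

import numpy as np

from standiff import CohortSpec, KineticParams, make_cohort
from standiff.inference import FitConfig, fit_cohort_subjects
from standiff.prediction import validate_longitudinal

coh = make_cohort(CohortSpec(n_regions=40, n_subjects=20, n_controls=15,
                             rng_seed=3))
cohort_fit = (KineticParams(0.275, 0.55),
              np.clip(coh.tau_baseline.mean(axis=0).to_numpy(), 1e-6, None))
fits = fit_cohort_subjects(
    coh.tau_baseline, coh.true_stages.astype(float), "subject_both",
    coh.laplacian, FitConfig(rng_seed=0), cohort_fit=cohort_fit,
)
report = validate_longitudinal(
    {f.subject_id: f for f in fits}, coh.longitudinal, coh.laplacian
)
print(report.per_visit.groupby("delta_years")[["pearson_r", "mse"]].mean())
print(f"\nmean R over subjects: {report.mean_r_by_subject:.3f}")
print(f"mean MSE over subjects: {report.mean_mse_by_subject:.5f}")
print("\nForecasts made from baseline alone track the observed follow-up")
print("patterns; accuracy decays gently with horizon as noise accumulates.")
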