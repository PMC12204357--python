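"""Disease staging: recover a planted event sequence and subject stages.

Samples a 200-subject biomarker cohort from a known event model, runs the
MCMC event-sequence sampler, and assigns stage posteriors.  Printed
numbers: whether the planted event ordering was recovered exactly, and
the Spearman correlation between assigned and planted stages.
"""

import numpy as np
from scipy.stats import spearmanr

from standiff import ebm_mcmc, stage_posteriors
from standiff.synthetic import (
    make_ebm_cohort,
    planted_event_model,
    well_separated_staging_spec,
)

spec = well_separated_staging_spec()
model = planted_event_model(spec)
Z, true_stages = make_ebm_cohort(model, 200, rng_seed=0)

fit, trace = ebm_mcmc(Z, model.thresholds, n_iter=20_000, rng_seed=0)
post = stage_posteriors(Z, fit)
rho = spearmanr(post.most_likely_stage, true_stages).statistic

print(f"planted sequence recovered exactly: {fit.sequence == model.sequence}")
print(f"best log-likelihood: {fit.log_likelihood:.1f}")
print(f"assigned vs planted stage Spearman rho: {rho:.3f}")
print("\nA rho near 1 means the cross-sectional staging axis orders")
print("subjects by their true disease progression, which is what the")
print("diffusion module consumes as pseudo-time.")
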