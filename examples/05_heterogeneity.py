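"""Heterogeneity: stage-wise convergence of tau patterns across subjects.

Evolves 20 heterogeneous planted seeds forward and tracks two statistics
per stage: mean CoV of tau across regions (within-subject spatial
heterogeneity) and mean pairwise inter-subject correlation.  Printed
table: convergence — patterns that start diverse end up similar because
every seed relaxes toward the same connectome-determined direction.
"""

import numpy as np

from standiff import KineticParams, build_laplacian
from standiff.heterogeneity import convergence_curve
from standiff.inference import FitResult
from standiff.synthetic import make_connectome, make_seeds

lap = build_laplacian(make_connectome(40, density=0.4, rng_seed=4))
rng = np.random.default_rng(5)
seeds, _ = make_seeds(20, archetype_mix=0.5, n_regions=40, rng_seed=6)
fits = [
    FitResult(seed=seeds[i],
              params=KineticParams(rng.uniform(0.05, 0.5), rng.uniform(0.1, 1.0)),
              cost=0.0, pearson_r=1.0, n_inferred=42, subject_id=f"s{i}")
    for i in range(20)
]
curve = convergence_curve(fits, lap, np.arange(1.0, 16.0, 2.0))
print(curve.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
print("\nmean pairwise R rises and mean CoV falls with stage: inter-subject")
print("and inter-region heterogeneity are largest at seeding and shrink as")
print("pathology spreads — heterogeneity lives at the disease's origin.")
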