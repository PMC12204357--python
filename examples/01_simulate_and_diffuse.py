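"""Forward simulation: evolve a focal seed on a synthetic connectome.

Builds a 40-region connectome, places all initial tau in one region, and
evolves it with the closed-form reaction-diffusion flow.  Printed numbers:
the degree-sqrt-weighted total grows exactly as exp(alpha * s) (the
conservation law of the flow), while the coefficient of variation across
regions falls as diffusion flattens the pattern.
"""

import numpy as np

from standiff import KineticParams, build_laplacian, forward
from standiff.heterogeneity import cov_across_regions
from standiff.synthetic import make_connectome

conn = make_connectome(40, density=0.3, rng_seed=0)
lap = build_laplacian(conn)

seed = np.zeros(40)
seed[0] = 1.0  # all tau starts in region R000
params = KineticParams(alpha=0.2, beta=0.5)
stages = np.array([0.0, 2.0, 5.0, 10.0, 15.0])
pred = forward(seed, params, stages, lap)

d = np.sqrt(lap.degree)
print("stage   weighted total   exp(alpha*s)   CoV across regions")
for s, x in zip(pred.stages, pred.x):
    print(f"{s:5.1f}   {d @ x:14.4f}   {np.exp(params.alpha * s) * (d @ seed):12.4f}"
          f"   {cov_across_regions(x):8.3f}")
print("\nThe weighted total matches exp(alpha*s) exactly (spread moves tau")
print("between regions; only agglomeration changes the total), and the")
print("falling CoV shows the focal pattern flattening toward equilibrium.")
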