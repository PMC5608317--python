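"""Identify a patch's dynamical system and verify subspace recovery.

Generates a noiseless 16x16 RGB patch from a known stable system, fits the
higher-order LDS, and measures how far the identified observability subspace
is from the generator's on the Grassmann manifold.
"""

import numpy as np

from grassvlad import fit_hlds, geodesic_distance, observability_subspace
from grassvlad.synthetic import make_stable_system, synth_patch

spec = make_stable_system(seed=7, sigma_v=0.0, sigma_w=0.0)
patch = synth_patch(spec, size=16, seed=8)
model = fit_hlds(patch)

print("true sigma_1(A): %.4f" % np.linalg.norm(spec.A_true, 2))
print("fitted sigma_1(A): %.4f   stabilized: %s" % (model.sigma1, model.stabilized))
print("fitted C (orthonormal mapping):")
print(np.round(model.C, 3))

d = geodesic_distance(observability_subspace(model, m=3),
                      spec.observability_point(m=3))
print("subspace recovery distance: %.2e" % d)
print("-> with noiseless data the identified span([C; CA; CA^2]) matches the")
print("   generator's to machine precision; this is the per-patch descriptor.")
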