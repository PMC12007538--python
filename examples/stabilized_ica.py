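"""Icasso-stabilized spatial ICA on mixed synthetic sources.

Three sparse spatial sources are mixed into a voxels x time matrix; ICA
is re-run 20 times from random initial conditions, the pooled components
are clustered by absolute spatial correlation, and each cluster reports a
centrotype map with a stability index Iq (1 = perfectly reproducible).
Maps are Z-scaled and thresholded at |Z| > 3 for display.
"""

import numpy as np

from smsfus import icasso

rng = np.random.default_rng(0)
n_vox, n_t = 2000, 40
truth = rng.laplace(size=(n_vox, 3))  # sparse spatial maps
mixing = rng.standard_normal((n_t, 3))
data = truth @ mixing.T + 0.05 * rng.standard_normal((n_vox, n_t))

components = icasso(data, n_components=3, n_runs=20, seed=0)

print(f"{'component':>9} {'Iq':>6} {'members':>8} {'|Z|>3 voxels':>13} {'match to truth':>15}")
for k, comp in enumerate(components):
    match = np.abs(np.corrcoef(comp.map, truth.T)[0, 1:]).max()
    print(f"{k:>9} {comp.iq:6.3f} {comp.n_members:>8} {int(comp.mask.sum()):>13} {match:15.3f}")
print("\nIq near 1 marks components that reappear across randomized runs;")
print("the |Z|>3 mask keeps ~0.27% of voxels on a Gaussian map, more when a real source loads.")
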