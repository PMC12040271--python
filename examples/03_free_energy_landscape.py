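"""Free-energy landscape and cluster analysis over (PC1, PC2).

The first two dPCA projections are histogrammed on a 64×64 grid;
ΔG = −kBT[ln ρ − ln ρmax] anchors the most populated cell at 0.  Grid
basins become conformational clusters, and the hidden two-state labels
should be recovered almost perfectly.
"""

import numpy as np

from dimerscope import dpca, landscape
from dimerscope import synthetic_data as synth

spec = synth.two_state_spec(n_res=20, n_frames=2000, kappa=20.0, seed=3)
series, truth = synth.sample_dihedral_series(spec)
model = dpca.fit_series(series)
v1, v2 = model.projections[:, 0], model.projections[:, 1]

surf = landscape.free_energy(landscape.density(v1, v2, bins=64))
i, j = np.unravel_index(surf.density.argmax(), surf.density.shape)
print(f"Delta G at the densest cell: {surf.delta_g[i, j]:.3f} kBT (the landscape anchor)")
print(f"highest free energy among populated cells: {surf.delta_g.max():.2f} kBT")

cmap = landscape.find_clusters(surf)
labels = landscape.assign_frames(cmap, surf, v1, v2)
print(f"clusters found: {cmap.n_clusters} (ranked by peak density)")
for k, peak in cmap.ranking:
    print(f"  cluster {k}: {np.sum(labels == k)} frames")
acc = max(np.mean((labels == 1) == (truth.state_labels == s)) for s in (0, 1))
print(f"hidden-state recovery (permutation-aligned): {100 * acc:.1f}%")
# Two clusters matching the two Markov states, with recovery near 100%.
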