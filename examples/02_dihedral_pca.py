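"""Dihedral-angle PCA of a metastable trajectory.

The (φ, ψ) series is sin/cos-embedded, the covariance eigendecomposed,
and each frame projected onto the leading eigenvectors.  The per-angle
contribution profile Δn(1) localizes the dominant motion on the sequence.
"""

import numpy as np

from dimerscope import dpca
from dimerscope import synthetic_data as synth

spec = synth.two_state_spec(n_res=20, n_frames=1000, kappa=20.0, seed=2)
series, truth = synth.sample_dihedral_series(spec)
model = dpca.fit_series(series)

print(f"{series.n_angles} dihedrals -> {2 * series.n_angles} embedded coordinates")
print(f"variance captured by PC1+PC2: {dpca.cumulative_variance(model, 2):.3f}")

delta = dpca.contributions(model, 1)
print(f"sum of per-angle contributions to PC1: {delta.sum():.12f}  (unit eigenvector)")
top = np.argsort(delta)[::-1][:3]
for n in top:
    chain, res, kind = series.labels[n]
    print(f"  {kind} of residue {res} (chain {chain}) contributes {100 * delta[n]:.1f}% of PC1")
# With every residue switching basins together, the contribution is spread
# over many angles; in real data a few peaks single out the mobile loops.
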