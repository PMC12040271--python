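"""RMSD, RMSF and hydrogen-bond monitoring on a synthetic dimer.

Cα RMSD to the first frame (after Kabsch superposition), per-residue
RMSF about the mean structure, and the distance trace of the enforced
inter-chain contact with its H-bond occupancy.
"""

import numpy as np

from dimerscope import structure_metrics as sm
from dimerscope import synthetic_data as synth
from dimerscope import trajectory_io as tio

spec = synth.two_state_spec(
    n_res=16,
    n_frames=80,
    seed=4,
    contact_pairs=[synth.ContactSpec("A:8:CA", "B:8:CA", 3.4, noise=0.4)],
)
traj, truth = synth.simulate_dimer(spec)

ca = tio.select(traj, atom_names={"CA"})
rmsd = sm.rmsd_series(traj, reference_frame=0, indices=ca)
print(f"C-alpha RMSD: first frame {rmsd[0]:.2f} Å, mean {rmsd.mean():.2f} Å, max {rmsd.max():.2f} Å")

rmsf = sm.rmsf(traj, indices=ca)
imax = int(np.argmax(rmsf))
a = traj.atoms[ca[imax]]
print(f"most mobile residue: {a.chain_id}:{a.res_seq} with RMSF {rmsf[imax]:.2f} Å")

trace = sm.distance_trace(traj, "A:8:CA", "B:8:CA")
frac = sm.hbond_fraction(trace, cutoff=3.5)
print(f"contact distance: {trace.distances.mean():.2f} ± {trace.distances.std():.2f} Å")
print(f"fraction of frames within 3.5 Å: {frac:.2f}")
# With the pair held at 3.4 ± 0.4 Å, roughly 60% of frames fall under the
# 3.5 Å heavy-atom criterion (the Gaussian tail P(d <= 3.5)).
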