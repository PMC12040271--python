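"""Generate a ground-truthed synthetic two-chain dimer trajectory.

Backbone dihedrals follow a two-state hidden Markov chain (α-helical vs
β-extended basins, von Mises noise); chain B is rigidly placed each frame
so residue 10's Cα atoms sit 4.0 ± 0.2 Å apart.  The ground truth records
the hidden state of every frame and which residues the generator actually
put in the interface.
"""

import numpy as np

from dimerscope import synthetic_data as synth
from dimerscope import trajectory_io as tio

spec = synth.two_state_spec(
    n_res=20,
    n_frames=100,
    kappa=20.0,
    switch=0.05,
    seed=1,
    contact_pairs=[synth.ContactSpec("A:10:CA", "B:10:CA", 4.0, noise=0.2)],
)
traj, truth = synth.simulate_dimer(spec)
tio.write_multimodel_pdb(traj, "synthetic_dimer.pdb")

occupancy = np.bincount(truth.state_labels, minlength=2) / spec.n_frames
print(f"frames: {traj.n_frames}, atoms: {traj.n_atoms} (chains A+B)")
print(f"hidden-state occupancy: state 0 = {occupancy[0]:.2f}, state 1 = {occupancy[1]:.2f}")
print(f"residues in the interface in every frame: {truth.true_interface_residues}")
# The occupancies hover near 0.5 (symmetric switching); the persistent
# interface is residue 10 of each chain — the enforced contact.
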