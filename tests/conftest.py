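import numpy as np
import pytest

from dimerscope import synthetic_data as synth


@pytest.fixture(scope="session")
def two_state_series():
    """Two-state von Mises HMM dihedral series with its hidden labels."""
    spec = synth.two_state_spec(n_res=20, n_frames=2000, kappa=20.0, switch=0.05, seed=42)
    series, truth = synth.sample_dihedral_series(spec)
    return series, truth


@pytest.fixture(scope="session")
def dimer():
    """Small two-chain synthetic dimer with persistent and transient contacts.

    Residue 7 of each chain is held in contact in every frame; residue 12
    only in the first half, so the generator's persistent/transient split
    is known.  A donor/acceptor pseudo-atom pair and one glycan site
    exercise H-bond and glycan contact typing.
    """
    spec = synth.two_state_spec(
        n_res=14,
        n_frames=60,
        seed=5,
        contact_pairs=[
            synth.ContactSpec("A:7:CA", "B:7:CA", 4.0, noise=0.1),
            synth.ContactSpec("A:12:OD1", "B:12:ND2", 3.2, noise=0.1, active_fraction=0.5),
        ],
        pseudo_atoms=[("A", 12, "OD1", "O"), ("B", 12, "ND2", "N")],
        glycan_sites=[("A", 3)],
    )
    traj, truth = synth.simulate_dimer(spec)
    return traj, truth, spec


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
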