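"""Ground-truthed synthetic dimer trajectories.

Real adhesion-dimer trajectories come from long MD runs that are rarely
deposited; to test the analysis chain end-to-end this module generates
trajectories whose answers are known by construction:

* backbone (φ, ψ) dihedrals follow a hidden-state Markov chain over K
  metastable conformational states, with von Mises angular noise of
  concentration κ about each state's mean angles;
* Cartesian backbones (N, CA, C per residue) are rebuilt frame-by-frame
  from the dihedrals by sequential internal-to-Cartesian (NeRF) placement
  with fixed ideal geometry (bond lengths 1.46/1.53/1.33 Å, bond angles
  111°/117°/121°, ω = 180°);
* chain B is rigidly placed each frame so that user-specified inter-chain
  contact pairs sit at target distances (plus optional Gaussian noise),
  giving controlled interfaces, hydrogen-bond traces, and — via transient
  contacts — a known persistent/transient split of interface residues.

Everything is reproducible bit-for-bit from the spec's seed.  The
:class:`GroundTruth` records the hidden state per frame, the interface
residues measured from the generated coordinates, and the frames in which
each contact pair satisfies its hydrogen-bond distance criterion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .dpca import DihedralSeries
from .trajectory_io import AtomRecord, Trajectory, parse_atom_spec, resolve_atom

__all__ = [
    "ContactSpec",
    "SyntheticSpec",
    "GroundTruth",
    "two_state_spec",
    "sample_dihedral_series",
    "build_backbone",
    "assemble_dimer",
    "simulate_dimer",
]

# ideal backbone geometry (Å / degrees)
BOND_N_CA = 1.46
BOND_CA_C = 1.53
BOND_C_N = 1.33
ANGLE_N_CA_C = np.deg2rad(111.0)
ANGLE_CA_C_N = np.deg2rad(117.0)
ANGLE_C_N_CA = np.deg2rad(121.0)
OMEGA = np.pi

# canonical (φ, ψ) basins used by the default state means
ALPHA = (np.deg2rad(-57.0), np.deg2rad(-47.0))
BETA = (np.deg2rad(-120.0), np.deg2rad(130.0))
PPII = (np.deg2rad(-75.0), np.deg2rad(150.0))


@dataclass(frozen=True)
class ContactSpec:
    """One enforced inter-chain contact.

    ``atom_a``/``atom_b`` are ``chain:res:name`` specs on chains A and B.
    The pair is held at ``target`` Å (+ Gaussian noise of sd ``noise``) in
    the first ``active_fraction`` of frames and released to
    ``target + detach_offset`` afterwards — a transient contact when
    ``active_fraction < 1``.
    """

    atom_a: str
    atom_b: str
    target: float
    noise: float = 0.0
    active_fraction: float = 1.0
    detach_offset: float = 10.0


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic dimer generator.

    Defaults describe a desk-scale two-state dimer: 20 residues per chain,
    400 frames, κ = 20 (≈ 13° angular sd), 5% per-frame switching.
    """

    n_res_per_chain: int = 20
    n_frames: int = 400
    n_states: int = 2
    state_means: np.ndarray | None = None  # (K, N) radians
    concentration: float | np.ndarray = 20.0  # von Mises κ, scalar or per-angle
    transition_matrix: np.ndarray | None = None  # (K, K) row-stochastic
    initial_state: int = 0
    contact_pairs: list[ContactSpec] = field(default_factory=list)
    pseudo_atoms: list[tuple[str, int, str, str]] = field(default_factory=list)
    # (chain, res_seq, name, element): donor/acceptor stand-ins off the CA
    glycan_sites: list[tuple[str, int]] = field(default_factory=list)
    interface_cutoff: float = 5.0
    hbond_cutoff: float = 3.5
    frame_spacing_ns: float = 1.0
    seed: int = 0

    @property
    def n_angles(self) -> int:
        return 2 * self.n_res_per_chain - 2

    def resolved_means(self) -> np.ndarray:
        if self.state_means is not None:
            means = np.asarray(self.state_means, dtype=float)
        else:
            basins = [ALPHA, BETA, PPII][: self.n_states]
            if len(basins) < self.n_states:
                raise ValueError("provide state_means for more than 3 states")
            means = np.stack(
                [_uniform_chain_angles(self.n_res_per_chain, b) for b in basins]
            )
        if means.shape != (self.n_states, self.n_angles):
            raise ValueError(
                f"state_means must have shape ({self.n_states}, {self.n_angles})"
            )
        return means

    def resolved_transitions(self) -> np.ndarray:
        if self.transition_matrix is not None:
            P = np.asarray(self.transition_matrix, dtype=float)
        else:
            K = self.n_states
            P = np.full((K, K), 0.05 / max(K - 1, 1))
            np.fill_diagonal(P, 0.95 if K > 1 else 1.0)
        if P.shape != (self.n_states, self.n_states):
            raise ValueError("transition matrix shape must be (K, K)")
        if np.any(P < 0) or np.any(np.abs(P.sum(axis=1) - 1.0) > 1e-12):
            raise ValueError("transition matrix rows must be nonnegative and sum to 1")
        return P

    def validate(self) -> None:
        if self.n_states < 1:
            raise ValueError("need at least one state")
        if np.any(np.asarray(self.concentration) <= 0):
            raise ValueError("von Mises concentration must be positive")
        if self.n_res_per_chain < 2:
            raise ValueError("a chain needs at least 2 residues to define dihedrals")
        self.resolved_means()
        self.resolved_transitions()


@dataclass
class GroundTruth:
    """What the generator knows that the analyses must recover."""

    state_labels: np.ndarray  # (T,) hidden state per frame
    interface_residues_per_frame: list[dict[str, set[int]]] = field(default_factory=list)
    true_hbond_frames: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def true_interface_residues(self) -> dict[str, set[int]]:
        """Residues inside the interface cutoff in *every* frame (persistent)."""
        if not self.interface_residues_per_frame:
            return {}
        out: dict[str, set[int]] = {}
        chains = self.interface_residues_per_frame[0].keys()
        for c in chains:
            sets = [f[c] for f in self.interface_residues_per_frame]
            out[c] = set.intersection(*sets) if sets else set()
        return out


def _uniform_chain_angles(n_res: int, basin: tuple[float, float]) -> np.ndarray:
    """Angle vector (ψ1, φ2, ψ2, ..., φn) with every residue in one basin."""
    phi, psi = basin
    out = []
    for r in range(1, n_res + 1):
        if r > 1:
            out.append(phi)
        if r < n_res:
            out.append(psi)
    return np.asarray(out)


def dihedral_labels(chain_id: str, n_res: int, res_start: int = 1) -> list[tuple[str, int, str]]:
    """Column labels matching the layout of :func:`~dimerscope.dpca.compute_dihedrals`."""
    labels: list[tuple[str, int, str]] = []
    for i in range(n_res):
        r = res_start + i
        if i > 0:
            labels.append((chain_id, r, "phi"))
        if i < n_res - 1:
            labels.append((chain_id, r, "psi"))
    return labels


def two_state_spec(
    n_res: int = 20,
    n_frames: int = 400,
    kappa: float = 20.0,
    switch: float = 0.05,
    seed: int = 0,
    **kwargs,
) -> SyntheticSpec:
    """A ready-made two-state spec (α-helical vs β-extended basins)."""
    P = np.array([[1 - switch, switch], [switch, 1 - switch]])
    return SyntheticSpec(
        n_res_per_chain=n_res,
        n_frames=n_frames,
        n_states=2,
        concentration=kappa,
        transition_matrix=P,
        seed=seed,
        **kwargs,
    )


def sample_dihedral_series(
    spec: SyntheticSpec, chain_id: str = "A", rng: np.random.Generator | None = None
) -> tuple[DihedralSeries, GroundTruth]:
    """Sample the hidden-state Markov chain and the per-frame dihedrals.

    Reproducible bit-for-bit from ``spec.seed`` (or a caller-supplied
    generator, for independent chains sharing one stream).
    """
    spec.validate()
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    P = spec.resolved_transitions()
    means = spec.resolved_means()
    T, K = spec.n_frames, spec.n_states

    labels = np.empty(T, dtype=int)
    state = spec.initial_state
    for t in range(T):
        labels[t] = state
        state = rng.choice(K, p=P[state])

    angles = np.asarray(rng.vonmises(means[labels], np.asarray(spec.concentration)))
    series = DihedralSeries(
        angles=angles, labels=dihedral_labels(chain_id, spec.n_res_per_chain)
    )
    return series, GroundTruth(state_labels=labels)


def _nerf(a: np.ndarray, b: np.ndarray, c: np.ndarray, r: float, theta: float, chi) -> np.ndarray:
    """Place atom D from A, B, C with bond r, angle θ at C, torsion χ (A-B-C-D).

    Vectorized over leading dimensions; ``chi`` may be scalar or (T,).
    """
    bc = c - b
    bc = bc / np.linalg.norm(bc, axis=-1, keepdims=True)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n, axis=-1, keepdims=True)
    m = np.cross(n, bc)
    cos_chi = np.cos(np.asarray(chi))[..., None]
    sin_chi = np.sin(np.asarray(chi))[..., None]
    # minus on the out-of-plane term gives the IUPAC (right-handed) torsion sign
    return c + (
        -r * np.cos(theta) * bc
        + r * np.sin(theta) * cos_chi * m
        - r * np.sin(theta) * sin_chi * n
    )


def build_backbone(
    dihedrals: DihedralSeries, chain_id: str, res_start: int = 1, res_name: str = "ALA"
) -> Trajectory:
    """Rebuild an ideal-geometry backbone trajectory from (φ, ψ) series.

    Atom order is N, CA, C per residue.  The reconstruction is exact in the
    sense that recomputing the dihedrals from the built coordinates returns
    the inputs (to numerical precision).
    """
    N_angles = dihedrals.n_angles
    if N_angles < 2 or N_angles % 2 != 0:
        raise ValueError(
            "need 2·n_res − 2 angles (ψ of first, φ/ψ of middle, φ of last residue); "
            "a single residue defines no φ/ψ"
        )
    n_res = N_angles // 2 + 1
    col = {lab[1:]: k for k, lab in enumerate(dihedrals.labels)}
    if len(col) != N_angles:
        raise ValueError("duplicate (res, kind) labels in dihedral series")

    T = dihedrals.n_frames
    ang = dihedrals.angles

    def angle_of(res_i: int, kind: str) -> np.ndarray:  # res_i 0-based
        key = (res_start + res_i, kind)
        if key not in col:
            raise ValueError(f"missing {kind} angle for residue {key[0]}")
        return ang[:, col[key]]

    coords = np.empty((T, 3 * n_res, 3))
    # first residue in a fixed frame, identical across frames
    n0 = np.zeros(3)
    ca0 = np.array([BOND_N_CA, 0.0, 0.0])
    c0 = ca0 + BOND_CA_C * np.array(
        [np.cos(np.pi - ANGLE_N_CA_C), np.sin(np.pi - ANGLE_N_CA_C), 0.0]
    )
    coords[:, 0] = n0
    coords[:, 1] = ca0
    coords[:, 2] = c0
    for i in range(1, n_res):
        Np, CAp, Cp = coords[:, 3 * i - 3], coords[:, 3 * i - 2], coords[:, 3 * i - 1]
        Ni = _nerf(Np, CAp, Cp, BOND_C_N, ANGLE_CA_C_N, angle_of(i - 1, "psi"))
        CAi = _nerf(CAp, Cp, Ni, BOND_N_CA, ANGLE_C_N_CA, np.full(T, OMEGA))
        Ci = _nerf(Cp, Ni, CAi, BOND_CA_C, ANGLE_N_CA_C, angle_of(i, "phi"))
        coords[:, 3 * i] = Ni
        coords[:, 3 * i + 1] = CAi
        coords[:, 3 * i + 2] = Ci

    atoms = []
    serial = 1
    for i in range(n_res):
        for name, elem in (("N", "N"), ("CA", "C"), ("C", "C")):
            atoms.append(
                AtomRecord(
                    serial=serial,
                    name=name,
                    element=elem,
                    res_name=res_name,
                    res_seq=res_start + i,
                    chain_id=chain_id,
                )
            )
            serial += 1
    return Trajectory(atoms=atoms, frames=coords)


def add_pseudo_atoms(traj: Trajectory, entries: list[tuple[str, int, str, str]]) -> Trajectory:
    """Attach named donor/acceptor stand-in atoms 1.5 Å off a residue's CA.

    Each entry is ``(chain, res_seq, atom_name, element)``; the atom is
    placed along the outward bisector of the N–CA–C angle (a Cβ-like
    direction), rigidly following the residue in every frame.
    """
    atoms = list(traj.atoms)
    new_cols = []
    for chain, res, name, elem in entries:
        idx = {a.name: k for k, a in enumerate(traj.atoms)
               if a.chain_id == chain and a.res_seq == res}
        if not {"N", "CA", "C"} <= idx.keys():
            raise KeyError(f"residue {chain}:{res} lacks backbone atoms")
        ca = traj.frames[:, idx["CA"]]
        out_dir = ca - 0.5 * (traj.frames[:, idx["N"]] + traj.frames[:, idx["C"]])
        out_dir = out_dir / np.linalg.norm(out_dir, axis=-1, keepdims=True)
        pos = ca + 1.5 * out_dir
        atoms.append(
            AtomRecord(
                serial=len(atoms) + 1, name=name, element=elem,
                res_name=traj.atoms[idx["CA"]].res_name, res_seq=res, chain_id=chain,
            )
        )
        new_cols.append(pos[:, None, :])
    frames = np.concatenate([traj.frames] + new_cols, axis=1) if new_cols else traj.frames
    return Trajectory(atoms=atoms, frames=frames, times=traj.times.copy())


#: GlcNAc-like stand-in: 5 heavy atoms in a local frame (Å), attached to an Asn.
_GLYCAN_TEMPLATE = [
    ("C1", "C", np.array([0.0, 0.0, 0.0])),
    ("O5", "O", np.array([1.2, 0.8, 0.0])),
    ("C2", "C", np.array([1.3, -0.9, 0.3])),
    ("N2", "N", np.array([2.6, -0.9, -0.4])),
    ("O3", "O", np.array([0.9, -2.1, -0.5])),
]


def add_glycans(traj: Trajectory, sites: list[tuple[str, int]], res_seq_base: int = 500) -> Trajectory:
    """Attach a single GlcNAc-like pseudo-residue (``NAG``) to each site.

    The sugar sits 2.9 Å off the anchor residue's CA along the outward
    direction, on the same chain as the glycosylated residue (N-glycans are
    covalently part of their chain).  Glycan residues are numbered
    ``res_seq_base``, ``res_seq_base + 1``, ... in site order.
    """
    atoms = list(traj.atoms)
    new_cols = []
    for k, (chain, res) in enumerate(sites):
        idx = {a.name: i for i, a in enumerate(traj.atoms)
               if a.chain_id == chain and a.res_seq == res}
        if not {"N", "CA", "C"} <= idx.keys():
            raise KeyError(f"glycan anchor {chain}:{res} lacks backbone atoms")
        ca = traj.frames[:, idx["CA"]]
        u = ca - 0.5 * (traj.frames[:, idx["N"]] + traj.frames[:, idx["C"]])
        u = u / np.linalg.norm(u, axis=-1, keepdims=True)
        # local orthonormal frame per frame
        helper = np.where(np.abs(u[..., :1]) < 0.9, [1.0, 0, 0], [0, 1.0, 0])
        v = np.cross(u, helper)
        v = v / np.linalg.norm(v, axis=-1, keepdims=True)
        w = np.cross(u, v)
        origin = ca + 2.9 * u
        for name, elem, local in _GLYCAN_TEMPLATE:
            pos = origin + local[0] * v + local[1] * w + local[2] * u
            atoms.append(
                AtomRecord(
                    serial=len(atoms) + 1, name=name, element=elem,
                    res_name="NAG", res_seq=res_seq_base + k, chain_id=chain,
                )
            )
            new_cols.append(pos[:, None, :])
    frames = np.concatenate([traj.frames] + new_cols, axis=1) if new_cols else traj.frames
    return Trajectory(atoms=atoms, frames=frames, times=traj.times.copy())


def _place_multi_contact(
    A: np.ndarray,
    B: np.ndarray,
    ia: list[int],
    ib: list[int],
    want: np.ndarray,
    cent_a: np.ndarray,
    tol: float,
    frame: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Rigidly place B so each contact atom sits ``want[k]`` Å from its partner.

    Seed: pseudo-targets along one common outward direction, matched by a
    correspondence Kabsch (plus a centroid pseudo-point keeping B on the far
    side of the interface); refine: least squares over rotation+translation
    on the *distance* residuals.  Random rotational restarts guard against
    local minima; persistent residuals above ``tol`` mean the targets are
    not simultaneously realizable.
    """
    pa = A[ia]
    u = pa.mean(axis=0) - cent_a
    nu = np.linalg.norm(u)
    u = u / nu if nu > 1e-9 else np.array([1.0, 0.0, 0.0])
    pseudo_targets = pa + u * want[:, None]

    b_contacts_0 = B[ib]
    cb = B.mean(axis=0)
    src = np.vstack([b_contacts_0, cb])
    dst = np.vstack(
        [pseudo_targets, pseudo_targets.mean(axis=0) + u * np.linalg.norm(cb - b_contacts_0.mean(axis=0))]
    )
    wts = np.concatenate([np.ones(len(ib)), [0.3]])
    wmean_s = (wts[:, None] * src).sum(axis=0) / wts.sum()
    wmean_d = (wts[:, None] * dst).sum(axis=0) / wts.sum()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rot0, _ = Rotation.align_vectors(dst - wmean_d, src - wmean_s, weights=wts)
    B0 = (B - wmean_s) @ rot0.as_matrix().T + wmean_d
    b_contacts = B0[ib]

    def residuals(p: np.ndarray) -> np.ndarray:
        R = Rotation.from_rotvec(p[:3]).as_matrix()
        moved = b_contacts @ R.T + p[3:]
        return np.linalg.norm(moved - pa, axis=1) - want

    x0 = np.zeros(6)
    best = None
    for attempt in range(8):
        sol = least_squares(residuals, x0, max_nfev=400)
        err = np.max(np.abs(sol.fun))
        if best is None or err < best[0]:
            best = (err, sol.x)
        if err <= tol:
            break
        x0 = np.concatenate([rng.normal(scale=0.8, size=3), rng.normal(scale=2.0, size=3)])
    err, x = best
    if err > tol:
        R = Rotation.from_rotvec(x[:3]).as_matrix()
        achieved = np.linalg.norm((b_contacts @ R.T + x[3:]) - pa, axis=1)
        raise ValueError(
            f"infeasible simultaneous contact targets at frame {frame}: "
            f"requested {want}, achieved {achieved}"
        )
    R = Rotation.from_rotvec(x[:3]).as_matrix()
    return B0 @ R.T + x[3:]


def assemble_dimer(
    chain_a: Trajectory,
    chain_b: Trajectory,
    spec: SyntheticSpec,
    rng: np.random.Generator | None = None,
    feasibility_tol: float = 0.5,
) -> tuple[Trajectory, GroundTruth]:
    """Rigidly place chain B each frame to realize the contact targets.

    A single contact pair is solved exactly (the measured distance equals
    target + noise to machine precision); multiple pairs are solved by
    weighted least squares over rotation + translation, with a feasibility
    check on the residual distances.  Ground truth (interface residues per
    frame, H-bond frames per pair) is *measured* from the final coordinates,
    so it is consistent with the generated geometry by construction.
    """
    if chain_a.n_frames != chain_b.n_frames:
        raise ValueError("chain trajectories must have equal frame counts")
    if not spec.contact_pairs:
        raise ValueError("assemble_dimer needs at least one contact pair")
    if rng is None:
        rng = np.random.default_rng(spec.seed + 1)
    T = chain_a.n_frames

    def local_index(traj: Trajectory, spec_str: str) -> int:
        c, r, n = parse_atom_spec(spec_str)
        for i, a in enumerate(traj.atoms):
            if a.chain_id == c and a.res_seq == r and a.name == n:
                return i
        raise KeyError(f"contact atom {spec_str!r} not in chain topology")

    ia = [local_index(chain_a, cp.atom_a) for cp in spec.contact_pairs]
    ib = [local_index(chain_b, cp.atom_b) for cp in spec.contact_pairs]
    n_pairs = len(spec.contact_pairs)
    noise = np.stack(
        [cp.noise * rng.standard_normal(T) for cp in spec.contact_pairs], axis=1
    )

    b_frames = np.empty_like(chain_b.frames)
    for t in range(T):
        A = chain_a.frames[t]
        B = chain_b.frames[t]
        cent_a = A.mean(axis=0)
        targets = np.empty((n_pairs, 3))
        dists = np.empty(n_pairs)
        units = np.empty((n_pairs, 3))
        for k, cp in enumerate(spec.contact_pairs):
            pa = A[ia[k]]
            u = pa - cent_a
            nu = np.linalg.norm(u)
            u = u / nu if nu > 1e-9 else np.array([1.0, 0, 0])
            d = cp.target + noise[t, k]
            if t >= cp.active_fraction * T:
                d += cp.detach_offset
            targets[k] = pa + u * d
            dists[k] = d
            units[k] = u

        if n_pairs == 1:
            # exact: orient B's centroid away from A, then translate
            pb = B[ib[0]]
            cb = B.mean(axis=0)
            vec = cb - pb
            nv = np.linalg.norm(vec)
            if nv > 1e-9:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    rot, _ = Rotation.align_vectors(units[0][None], (vec / nv)[None])
                B2 = (B - pb) @ rot.as_matrix().T
            else:
                B2 = B - pb
            b_frames[t] = B2 + targets[0]
        else:
            placed = _place_multi_contact(
                A, B, ia, ib, np.abs(dists), cent_a, feasibility_tol, t, rng
            )
            b_frames[t] = placed

    placed_b = Trajectory(atoms=chain_b.atoms, frames=b_frames, times=chain_b.times.copy())
    merged = Trajectory(
        atoms=[replace(a, serial=i + 1) for i, a in enumerate(chain_a.atoms + placed_b.atoms)],
        frames=np.concatenate([chain_a.frames, b_frames], axis=1),
        times=chain_a.times.copy(),
    )

    truth = GroundTruth(state_labels=np.zeros(T, dtype=int))
    _measure_ground_truth(merged, spec, truth)
    return merged, truth


def _measure_ground_truth(traj: Trajectory, spec: SyntheticSpec, truth: GroundTruth) -> None:
    chains = traj.chain_ids
    if len(chains) != 2:
        raise ValueError("ground truth expects exactly two chains")
    ca, cb = chains
    heavy = [i for i, a in enumerate(traj.atoms) if not a.is_hydrogen]
    idx_a = [i for i in heavy if traj.atoms[i].chain_id == ca]
    idx_b = [i for i in heavy if traj.atoms[i].chain_id == cb]
    truth.interface_residues_per_frame = []
    for t in range(traj.n_frames):
        tree_b = cKDTree(traj.frames[t, idx_b])
        pairs = tree_b.query_ball_point(traj.frames[t, idx_a], spec.interface_cutoff)
        res_a: set[int] = set()
        res_b: set[int] = set()
        for qi, hits in enumerate(pairs):
            if hits:
                res_a.add(traj.atoms[idx_a[qi]].res_seq)
                for h in hits:
                    res_b.add(traj.atoms[idx_b[h]].res_seq)
        truth.interface_residues_per_frame.append({ca: res_a, cb: res_b})

    for cp in spec.contact_pairs:
        i = resolve_atom(traj, cp.atom_a)
        j = resolve_atom(traj, cp.atom_b)
        d = np.linalg.norm(traj.frames[:, i] - traj.frames[:, j], axis=1)
        truth.true_hbond_frames[f"{cp.atom_a}-{cp.atom_b}"] = np.nonzero(
            d <= spec.hbond_cutoff
        )[0]


def simulate_dimer(
    spec: SyntheticSpec, shared_states: bool = True
) -> tuple[Trajectory, GroundTruth]:
    """Full pipeline: sample dihedrals, build both chains, assemble the dimer.

    With ``shared_states`` both chains visit the same hidden state each
    frame (a concerted conformational change); their angular noise is
    always independent.  The returned ground truth carries chain A's state
    labels plus the measured interface/H-bond truth.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    series_a, truth_a = sample_dihedral_series(spec, chain_id="A", rng=rng)
    if shared_states:
        means = spec.resolved_means()
        angles_b = rng.vonmises(means[truth_a.state_labels], np.asarray(spec.concentration))
        series_b = DihedralSeries(
            angles=np.asarray(angles_b),
            labels=dihedral_labels("B", spec.n_res_per_chain),
        )
    else:
        series_b, _ = sample_dihedral_series(spec, chain_id="B", rng=rng)

    traj_a = build_backbone(series_a, "A")
    traj_b = build_backbone(series_b, "B")
    pa = [p for p in spec.pseudo_atoms if p[0] == "A"]
    pb = [p for p in spec.pseudo_atoms if p[0] == "B"]
    if pa:
        traj_a = add_pseudo_atoms(traj_a, pa)
    if pb:
        traj_b = add_pseudo_atoms(traj_b, pb)
    ga = [g for g in spec.glycan_sites if g[0] == "A"]
    gb = [g for g in spec.glycan_sites if g[0] == "B"]
    if ga:
        traj_a = add_glycans(traj_a, ga)
    if gb:
        traj_b = add_glycans(traj_b, gb, res_seq_base=600)

    traj_a.times = np.arange(spec.n_frames) * spec.frame_spacing_ns
    traj_b.times = traj_a.times.copy()
    merged, truth = assemble_dimer(traj_a, traj_b, spec, rng=rng)
    truth.state_labels = truth_a.state_labels
    return merged, truth
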