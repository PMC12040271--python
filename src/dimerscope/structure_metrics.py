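"""Superposition, RMSD/RMSF, atom-pair distance traces and Shrake–Rupley SASA.

RMSD series are computed against a reference frame after least-squares
rigid superposition (Kabsch; proper rotations only, so a reflection is
never returned).  RMSF is the per-atom root-mean-square fluctuation about
the mean structure after iterated alignment to that mean.

Hydrogen-bond monitoring follows the distance-only criterion used when
inspecting donor–acceptor pairs along a trajectory: 2.5 Å for an explicit
hydrogen–acceptor pair, 3.5 Å for a heavy-atom donor–acceptor pair.

SASA is the Shrake–Rupley quadrature with a deterministic golden-spiral
point layout (no RNG, bit-reproducible): each atom's sphere of radius
r_vdw + probe is sampled at quasi-uniform points; a point is accessible iff
it lies outside every neighbor's inflated sphere, and the atom's SASA is
the accessible fraction times its sphere area.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .trajectory_io import AtomRecord, Trajectory, resolve_atom, select

__all__ = [
    "DistanceTrace",
    "SasaResult",
    "superpose",
    "rmsd_series",
    "rmsf",
    "distance_trace",
    "hbond_fraction",
    "sasa",
    "sphere_points",
    "HBOND_CUTOFF_HYDROGEN",
    "HBOND_CUTOFF_HEAVY",
]

#: Default H-bond cutoffs (Å): explicit H–acceptor vs heavy donor–acceptor.
HBOND_CUTOFF_HYDROGEN = 2.5
HBOND_CUTOFF_HEAVY = 3.5


@dataclass
class DistanceTrace:
    """Distance between two named atoms along the trajectory."""

    pair: tuple[str, str]  # chain:res:name specs
    distances: np.ndarray  # (T,) Å
    times: np.ndarray  # (T,) ns
    criterion_cutoff: float  # Å, default H-bond criterion for this pair


@dataclass
class SasaResult:
    """Per-atom solvent-accessible surface areas (Å²)."""

    per_atom: np.ndarray
    probe_radius: float
    n_sphere_points: int

    @property
    def total(self) -> float:
        return float(self.per_atom.sum())


def superpose(
    reference: np.ndarray,
    mobile: np.ndarray,
    indices: Sequence[int] | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` best fits the reference over the
    selected atoms.  The rotation is always proper (det = +1).

    Raises
    ------
    ValueError
        For fewer than 3 selected atoms or a collinear selection.
    """
    reference = np.asarray(reference, dtype=float)
    mobile = np.asarray(mobile, dtype=float)
    idx = np.arange(reference.shape[0]) if indices is None else np.asarray(list(indices))
    if idx.size < 3:
        raise ValueError("superposition needs at least 3 atoms")
    ref_sel = reference[idx]
    mob_sel = mobile[idx]
    ref_mean = ref_sel.mean(axis=0)
    mob_mean = mob_sel.mean(axis=0)
    a = ref_sel - ref_mean
    b = mob_sel - mob_mean
    if np.linalg.matrix_rank(b, tol=1e-8) < 2:
        raise ValueError("selected atoms are collinear; rotation underdetermined")
    rot, _ = Rotation.align_vectors(a, b)
    R = rot.as_matrix()
    t = ref_mean - mob_mean @ R.T
    moved = mob_sel @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - ref_sel) ** 2, axis=1))))
    return R, t, rmsd


def rmsd_series(
    traj: Trajectory,
    reference_frame: int = 0,
    indices: Sequence[int] | None = None,
) -> np.ndarray:
    """Per-frame RMSD (Å) to a reference frame after superposition.

    The selection defaults to the Cα atoms; the same selection is used for
    fitting and for the RMSD value.  The entry at the reference frame is 0.
    """
    if indices is None:
        indices = select(traj, atom_names={"CA"})
    ref = traj.frames[reference_frame]
    out = np.empty(traj.n_frames)
    for t in range(traj.n_frames):
        _, _, out[t] = superpose(ref, traj.frames[t], indices)
    return out


def rmsf(traj: Trajectory, indices: Sequence[int] | None = None) -> np.ndarray:
    """Per-atom RMSF (Å) about the mean structure over the selection.

    Frames are first aligned to frame 0, a mean structure is computed, and
    the alignment is repeated against that mean (two passes) before taking
    RMSF_i = sqrt(⟨|x_i − ⟨x_i⟩|²⟩).
    """
    if traj.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")
    if indices is None:
        indices = select(traj, atom_names={"CA"})
    idx = np.asarray(list(indices))
    coords = traj.frames[:, idx, :].copy()

    def align_all(target: np.ndarray) -> None:
        for t in range(coords.shape[0]):
            R, tr, _ = superpose(target, coords[t], None)
            coords[t] = coords[t] @ R.T + tr

    align_all(coords[0].copy())
    align_all(coords.mean(axis=0))
    mean = coords.mean(axis=0)
    return np.sqrt(np.mean(np.sum((coords - mean) ** 2, axis=2), axis=0))


def distance_trace(traj: Trajectory, a: str, b: str) -> DistanceTrace:
    """Euclidean distance between two ``chain:res:name`` atoms per frame."""
    ia = resolve_atom(traj, a)
    ib = resolve_atom(traj, b)
    d = np.linalg.norm(traj.frames[:, ia] - traj.frames[:, ib], axis=1)
    involves_h = traj.atoms[ia].is_hydrogen or traj.atoms[ib].is_hydrogen
    cutoff = HBOND_CUTOFF_HYDROGEN if involves_h else HBOND_CUTOFF_HEAVY
    return DistanceTrace(pair=(a, b), distances=d, times=traj.times, criterion_cutoff=cutoff)


def hbond_fraction(trace: DistanceTrace, cutoff: float | None = None) -> float:
    """Fraction of frames where the pair satisfies the distance criterion."""
    c = trace.criterion_cutoff if cutoff is None else cutoff
    return float(np.mean(trace.distances <= c))


def _local_frame(center: np.ndarray, neighbors: np.ndarray) -> np.ndarray:
    """Orthonormal frame anchored in an atom's local neighbor geometry.

    Expressing the quadrature sphere points in this frame makes SASA
    exactly covariant under rigid motion (the points rotate with the
    molecule), and — because only *nearby* atoms define the frame — the
    per-atom SASA of two far-apart groups is bitwise unchanged when they
    are combined, so interface ΔSASA vanishes exactly for non-interacting
    chains.  Neighbors are taken in distance order.
    """
    e1 = None
    for x in neighbors:
        v = x - center
        if np.linalg.norm(v) > 1e-6:
            e1 = v / np.linalg.norm(v)
            break
    if e1 is None:
        return np.eye(3)
    e2 = None
    for x in neighbors:
        v = x - center
        u = v - (v @ e1) * e1
        if np.linalg.norm(u) > 1e-6:
            e2 = u / np.linalg.norm(u)
            break
    if e2 is None:
        return np.eye(3)
    return np.column_stack([e1, e2, np.cross(e1, e2)])


def sphere_points(n: int) -> np.ndarray:
    """``n`` quasi-uniform unit-sphere points on the golden spiral (deterministic)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * k
    return np.column_stack(
        (np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi))
    )


def sasa(
    coords: np.ndarray,
    atoms: Sequence[AtomRecord],
    probe: float = 1.4,
    n_points: int = 960,
    subset: Sequence[int] | None = None,
) -> SasaResult:
    """Shrake–Rupley SASA of one frame (heavy atoms and hydrogens alike).

    ``subset`` restricts which atoms are *reported* (all atoms still
    occlude).  Radii come from the Bondi table via ``AtomRecord.vdw_radius``;
    an unknown element raises before any computation.
    """
    coords = np.asarray(coords, dtype=float)
    radii = np.array([a.vdw_radius for a in atoms]) + probe
    base_pts = sphere_points(n_points)
    tree = cKDTree(coords)
    report = range(len(atoms)) if subset is None else subset
    out = np.zeros(len(atoms))
    max_r = radii.max()
    k_nn = min(4, len(atoms))
    for i in report:
        _, nn = tree.query(coords[i], k=k_nn)
        nn = np.atleast_1d(nn)
        frame = _local_frame(coords[i], coords[nn[1:]])
        pts = base_pts @ frame.T
        sphere = coords[i] + radii[i] * pts
        accessible = np.ones(n_points, dtype=bool)
        for j in tree.query_ball_point(coords[i], radii[i] + max_r):
            if j == i:
                continue
            d2 = np.sum((sphere - coords[j]) ** 2, axis=1)
            accessible &= d2 > radii[j] ** 2
            if not accessible.any():
                break
        out[i] = accessible.mean() * 4.0 * np.pi * radii[i] ** 2
    return SasaResult(per_atom=out, probe_radius=probe, n_sphere_points=n_points)
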