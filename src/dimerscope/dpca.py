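"""Dihedral-angle principal component analysis (dPCA).

Backbone torsions are periodic, so PCA is performed not on the angles
γ_n themselves but on their sin/cos embedding

    q = (cos γ1, sin γ1, ..., cos γN, sin γN),

which removes the 2π wrap-around.  The k-th principal component of a frame
is the projection V_k = v(k) · (q − ⟨q⟩) onto the k-th eigenvector v(k) of
the covariance matrix of q.  Because each eigenvector has unit length, the
quantity

    Δ_n(k) = v_{2n-1}(k)² + v_{2n}(k)²

sums to 1 over the angles n and measures the fractional contribution of
dihedral γ_n to component k — the per-angle "participation" profile used to
localize a concerted motion on the sequence.

No mass weighting enters: the embedded coordinates are dimensionless.
Covariance (not correlation) with unbiased 1/(T−1) normalization is used,
and each eigenvector's sign is fixed so its largest-magnitude entry is
positive, making projections reproducible across linear-algebra backends.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .trajectory_io import Trajectory, select

__all__ = [
    "DihedralSeries",
    "DPCAModel",
    "dihedral_angle",
    "compute_dihedrals",
    "embed",
    "fit",
    "contributions",
    "cumulative_variance",
]

logger = logging.getLogger(__name__)

#: Maximum C(i-1)–N(i) distance (Å) for two residues to count as bonded.
CHAIN_BREAK_CUTOFF = 2.0


@dataclass
class DihedralSeries:
    """T×N matrix of backbone dihedrals in radians, with per-column labels.

    Labels are ``(chain_id, res_seq, kind)`` with ``kind`` in {"phi","psi"};
    angles follow the IUPAC sign convention and lie in (−π, π].
    """

    angles: np.ndarray  # (T, N) radians
    labels: list[tuple[str, int, str]]

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=float)
        if self.angles.ndim != 2:
            raise ValueError("angles must be a T×N matrix")
        if self.angles.shape[1] != len(self.labels):
            raise ValueError("one label per angle column required")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("angle labels must be unique")
        if not np.all(np.isfinite(self.angles)):
            raise ValueError("angles contain undefined entries")

    @property
    def n_frames(self) -> int:
        return self.angles.shape[0]

    @property
    def n_angles(self) -> int:
        return self.angles.shape[1]


@dataclass
class DPCAModel:
    """Eigendecomposition of the sin/cos-embedded dihedral covariance."""

    mean_q: np.ndarray  # (2N,)
    eigenvectors: np.ndarray  # (2N, 2N), columns v(k), orthonormal
    eigenvalues: np.ndarray  # (2N,), nonincreasing, >= 0
    projections: np.ndarray  # (T, 2N), V_k per frame
    labels: list[tuple[str, int, str]]

    @property
    def variance_fraction(self) -> np.ndarray:
        total = self.eigenvalues.sum()
        if total <= 0:
            return np.zeros_like(self.eigenvalues)
        return self.eigenvalues / total


def dihedral_angle(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray, p4: np.ndarray) -> np.ndarray:
    """Signed dihedral of four points (IUPAC convention), in (−π, π].

    Accepts arrays of shape ``(..., 3)`` and is vectorized over leading
    dimensions.  A perfectly planar trans arrangement returns +π (never −π).
    """
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = b2 / np.linalg.norm(b2, axis=-1, keepdims=True)
    m = np.cross(n1, b2n)
    x = np.sum(n1 * n2, axis=-1)
    y = np.sum(m * n2, axis=-1)
    ang = np.arctan2(y, x)
    return np.where(ang <= -np.pi + 1e-12, np.pi, ang)


def compute_dihedrals(
    traj: Trajectory, chain_filter: Iterable[str] | None = None
) -> DihedralSeries:
    """Backbone φ/ψ time series for every residue with N, CA, C atoms.

    φ_i is the torsion C(i−1)–N(i)–CA(i)–C(i) and ψ_i the torsion
    N(i)–CA(i)–C(i)–N(i+1); terminal residues contribute only their defined
    angle.  A spanning angle is excluded (with a warning) where consecutive
    residues are not bonded, i.e. the C(i−1)–N(i) distance exceeds
    ``CHAIN_BREAK_CUTOFF`` in the first frame.
    """
    chains = list(chain_filter) if chain_filter is not None else traj.chain_ids
    # residue -> backbone atom indices, per chain, ordered by res_seq
    backbone: dict[str, dict[int, dict[str, int]]] = {}
    for i, a in enumerate(traj.atoms):
        if a.chain_id in chains and a.name in ("N", "CA", "C"):
            backbone.setdefault(a.chain_id, {}).setdefault(a.res_seq, {})[a.name] = i

    quads: list[tuple[int, int, int, int]] = []
    labels: list[tuple[str, int, str]] = []
    ref = traj.frames[0]
    for chain in chains:
        residues = backbone.get(chain, {})
        res_ids = sorted(r for r, atoms in residues.items() if len(atoms) == 3)
        for j, r in enumerate(res_ids):
            cur = residues[r]
            prev = residues.get(res_ids[j - 1]) if j > 0 else None
            nxt = residues.get(res_ids[j + 1]) if j + 1 < len(res_ids) else None

            if prev is not None:
                d = np.linalg.norm(ref[cur["N"]] - ref[prev["C"]])
                if d > CHAIN_BREAK_CUTOFF:
                    logger.warning(
                        "chain break before %s:%d (C–N %.2f Å); phi excluded", chain, r, d
                    )
                else:
                    quads.append((prev["C"], cur["N"], cur["CA"], cur["C"]))
                    labels.append((chain, r, "phi"))
            if nxt is not None:
                d = np.linalg.norm(ref[nxt["N"]] - ref[cur["C"]])
                if d > CHAIN_BREAK_CUTOFF:
                    logger.warning(
                        "chain break after %s:%d (C–N %.2f Å); psi excluded", chain, r, d
                    )
                else:
                    quads.append((cur["N"], cur["CA"], cur["C"], nxt["N"]))
                    labels.append((chain, r, "psi"))

    if not quads:
        raise ValueError("no defined backbone dihedrals in the selection")
    q = np.asarray(quads)
    angles = dihedral_angle(
        traj.frames[:, q[:, 0]], traj.frames[:, q[:, 1]],
        traj.frames[:, q[:, 2]], traj.frames[:, q[:, 3]],
    )
    return DihedralSeries(angles=angles, labels=labels)


def embed(series: DihedralSeries) -> np.ndarray:
    """Sin/cos embedding: T×2N matrix (cos γ1, sin γ1, ..., cos γN, sin γN)."""
    T, N = series.angles.shape
    q = np.empty((T, 2 * N))
    q[:, 0::2] = np.cos(series.angles)
    q[:, 1::2] = np.sin(series.angles)
    return q


def fit(q: np.ndarray, labels: Sequence[tuple[str, int, str]] | None = None) -> DPCAModel:
    """PCA of the embedded coordinates: center, covariance, eigendecompose.

    Eigenpairs are sorted by descending eigenvalue; projections are the
    centered data times the eigenvectors.  Requires at least two frames.
    """
    q = np.asarray(q, dtype=float)
    if q.ndim != 2 or q.shape[0] < 2:
        raise ValueError("need a T×2N matrix with T >= 2")
    T = q.shape[0]
    mean_q = q.mean(axis=0)
    qc = q - mean_q
    cov = (qc.T @ qc) / (T - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    # sign convention: largest-magnitude entry of each eigenvector positive
    flip = evecs[np.abs(evecs).argmax(axis=0), np.arange(evecs.shape[1])] < 0
    evecs[:, flip] *= -1.0
    if labels is None:
        labels = [("?", n + 1, "angle") for n in range(q.shape[1] // 2)]
    return DPCAModel(
        mean_q=mean_q,
        eigenvectors=evecs,
        eigenvalues=evals,
        projections=qc @ evecs,
        labels=list(labels),
    )


def fit_series(series: DihedralSeries) -> DPCAModel:
    """Convenience: :func:`embed` then :func:`fit`, carrying the labels."""
    return fit(embed(series), labels=series.labels)


def contributions(model: DPCAModel, k: int) -> np.ndarray:
    """Per-angle contributions Δ_n(k) to component ``k`` (1-based).

    Δ_n(k) = v_{2n−1}(k)² + v_{2n}(k)²; the values sum to 1 because each
    eigenvector has unit length.
    """
    n_comp = model.eigenvectors.shape[1]
    if not 1 <= k <= n_comp:
        raise IndexError(f"component index {k} out of range 1..{n_comp}")
    v = model.eigenvectors[:, k - 1]
    return v[0::2] ** 2 + v[1::2] ** 2


def cumulative_variance(model: DPCAModel, m: int) -> float:
    """Fraction of total variance captured by the first ``m`` components."""
    n_comp = model.eigenvalues.shape[0]
    if not 1 <= m <= n_comp:
        raise IndexError(f"m={m} out of range 1..{n_comp}")
    total = model.eigenvalues.sum()
    if total <= 0:
        logger.warning("all eigenvalues are zero; cumulative variance undefined, returning 0")
        return 0.0
    return float(model.eigenvalues[:m].sum() / total)
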