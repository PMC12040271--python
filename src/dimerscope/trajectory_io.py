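"""Multi-model PDB trajectories for two-chain complexes.

A :class:`Trajectory` is the package's canonical container: a fixed atom
topology (:class:`AtomRecord` list) plus a ``(T, M, 3)`` coordinate array in
Å and a strictly increasing time axis in ns.  Parsing and writing of the
multi-model PDB format are delegated to :mod:`biotite.structure.io.pdb`;
this module adds the trajectory contract on top (identical atom order in
every model, element → van der Waals radius resolution, atom selection).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

__all__ = [
    "AtomRecord",
    "Trajectory",
    "TrajectoryFormatError",
    "VDW_RADII",
    "read_multimodel_pdb",
    "write_multimodel_pdb",
    "select",
    "parse_atom_spec",
    "resolve_atom",
]

logger = logging.getLogger(__name__)

#: Bondi van der Waals radii in Å (NACCESS-comparable set).
VDW_RADII: dict[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "H": 1.20,
    "P": 1.80,
    "SE": 1.90,
}


class TrajectoryFormatError(ValueError):
    """Raised for malformed multi-model PDB input (e.g. atom-count mismatch)."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom of the (frame-invariant) topology.

    ``res_seq`` is the author numbering of the source PDB; it is never
    renumbered, so residue labels like Asn226 refer to the author numbers.
    """

    serial: int
    name: str
    element: str
    res_name: str
    res_seq: int
    chain_id: str

    @property
    def vdw_radius(self) -> float:
        try:
            return VDW_RADII[self.element.upper()]
        except KeyError:
            raise KeyError(
                f"no van der Waals radius for element {self.element!r} "
                f"(atom {self.chain_id}:{self.res_seq}:{self.name})"
            ) from None

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() == "H"

    def spec(self) -> str:
        """``chain:res_seq:name`` atom spec, e.g. ``A:226:ND2``."""
        return f"{self.chain_id}:{self.res_seq}:{self.name}"


@dataclass
class Trajectory:
    """Atom topology plus T coordinate frames (Å) and frame times (ns)."""

    atoms: list[AtomRecord]
    frames: np.ndarray  # (T, M, 3) float64, Å
    times: np.ndarray = field(default=None)  # (T,) ns

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (T, M, 3)")
        if self.frames.shape[0] < 1:
            raise ValueError("trajectory must contain at least one frame")
        if self.frames.shape[1] != len(self.atoms):
            raise ValueError(
                f"frame atom count {self.frames.shape[1]} does not match "
                f"topology size {len(self.atoms)}"
            )
        if self.times is None:
            self.times = np.arange(self.n_frames, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.times.shape != (self.n_frames,):
            raise ValueError("times must have one entry per frame")
        if self.n_frames > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]

    @property
    def chain_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain_id, None)
        return list(seen)

    def subset(self, indices: Sequence[int]) -> "Trajectory":
        idx = list(indices)
        return Trajectory(
            atoms=[self.atoms[i] for i in idx],
            frames=self.frames[:, idx, :],
            times=self.times.copy(),
        )


def _scan_model_atom_counts(path: Path) -> list[int]:
    """Per-MODEL ATOM/HETATM line counts, used only to name a bad model."""
    counts: list[int] = []
    current = 0
    in_model = False
    with open(path) as fh:
        for line in fh:
            rec = line[:6]
            if rec.startswith("MODEL"):
                in_model = True
                current = 0
            elif rec.startswith("ENDMDL"):
                counts.append(current)
                in_model = False
            elif rec.startswith(("ATOM", "HETATM")):
                current += 1
    if not counts and current > 0:  # single implicit model
        counts.append(current)
    elif in_model:  # MODEL without ENDMDL
        counts.append(current)
    return counts


def read_multimodel_pdb(path: str | Path, times: np.ndarray | None = None) -> Trajectory:
    """Read a multi-model PDB file into a :class:`Trajectory`.

    One frame per ``MODEL`` block (a file without MODEL records is a
    single-frame trajectory).  Frame times come from, in order of priority:
    the ``times`` argument, a ``<path>.times`` sidecar file (one ns value
    per line), or the frame index.  Alternate locations other than ''/'A'
    are dropped.

    Raises
    ------
    TrajectoryFormatError
        If models disagree in atom count (the offending model is named).
    KeyError
        If an atom's element cannot be resolved to a van der Waals radius.
    """
    path = Path(path)
    pdb_file = PDBFile.read(str(path))
    try:
        stack = pdb_file.get_structure(model=None, altloc="first")
    except Exception as exc:
        counts = _scan_model_atom_counts(path)
        if len(set(counts)) > 1:
            ref = counts[0]
            bad = next(i + 1 for i, c in enumerate(counts) if c != ref)
            raise TrajectoryFormatError(
                f"model {bad} has {counts[bad - 1]} atoms, expected {ref} "
                f"(from model 1) in {path.name}"
            ) from None
        raise TrajectoryFormatError(f"could not parse {path.name}: {exc}") from exc

    if isinstance(stack, struc.AtomArray):  # single model
        stack = struc.stack([stack])

    elements = [e.upper() for e in stack.element]
    for i, e in enumerate(elements):
        if e not in VDW_RADII:
            raise KeyError(
                f"unknown element {e!r} for atom "
                f"{stack.chain_id[i]}:{int(stack.res_id[i])}:{stack.atom_name[i]}"
            )

    atoms = [
        AtomRecord(
            serial=i + 1,
            name=str(stack.atom_name[i]),
            element=elements[i],
            res_name=str(stack.res_name[i]),
            res_seq=int(stack.res_id[i]),
            chain_id=str(stack.chain_id[i]),
        )
        for i in range(stack.array_length())
    ]

    if times is None:
        sidecar = path.with_suffix(path.suffix + ".times")
        if sidecar.exists():
            times = np.loadtxt(sidecar, ndmin=1)
    return Trajectory(atoms=atoms, frames=np.asarray(stack.coord, dtype=float), times=times)


def write_multimodel_pdb(traj: Trajectory, path: str | Path) -> None:
    """Write a :class:`Trajectory` as a standard multi-model PDB file.

    Raises
    ------
    ValueError
        If the trajectory is empty or a coordinate exceeds the fixed
        ``%8.3f`` PDB column width.
    """
    if traj.n_frames < 1 or traj.n_atoms < 1:
        raise ValueError("cannot write an empty trajectory")
    if np.any(np.abs(traj.frames) >= 10000.0):
        raise ValueError("coordinate magnitude >= 10000 Å exceeds PDB field width")

    n = traj.n_atoms
    template = struc.AtomArray(n)
    template.coord = traj.frames[0]
    template.chain_id = np.array([a.chain_id for a in traj.atoms], dtype="U4")
    template.res_id = np.array([a.res_seq for a in traj.atoms], dtype=int)
    template.res_name = np.array([a.res_name for a in traj.atoms], dtype="U5")
    template.atom_name = np.array([a.name for a in traj.atoms], dtype="U6")
    template.element = np.array([a.element for a in traj.atoms], dtype="U2")
    template.hetero = np.array(
        [a.res_name in ("NAG", "HOH") for a in traj.atoms], dtype=bool
    )
    stack = struc.stack([template] * traj.n_frames)
    stack.coord = traj.frames.copy()

    pdb_file = PDBFile()
    pdb_file.set_structure(stack)
    pdb_file.write(str(path))

    sidecar = Path(path).with_suffix(Path(path).suffix + ".times")
    np.savetxt(sidecar, traj.times, fmt="%.6f")


def select(
    traj: Trajectory,
    chain: str | None = None,
    res_range: tuple[int, int] | None = None,
    atom_names: Iterable[str] | None = None,
) -> list[int]:
    """Indices of atoms matching *all* given criteria, in topology order.

    An empty result is valid (e.g. a residue range outside the chain).
    """
    names = set(atom_names) if atom_names is not None else None
    out: list[int] = []
    for i, a in enumerate(traj.atoms):
        if chain is not None and a.chain_id != chain:
            continue
        if res_range is not None and not (res_range[0] <= a.res_seq <= res_range[1]):
            continue
        if names is not None and a.name not in names:
            continue
        out.append(i)
    return out


def parse_atom_spec(spec: str) -> tuple[str, int, str]:
    """Parse ``chain:res_seq:atom_name`` (e.g. ``A:226:HD21``)."""
    parts = spec.split(":")
    if len(parts) != 3:
        raise ValueError(f"atom spec {spec!r} is not of the form chain:res:name")
    return parts[0], int(parts[1]), parts[2]


def resolve_atom(traj: Trajectory, spec: str) -> int:
    """Topology index of the atom named by a ``chain:res:name`` spec."""
    chain, res, name = parse_atom_spec(spec)
    for i, a in enumerate(traj.atoms):
        if a.chain_id == chain and a.res_seq == res and a.name == name:
            return i
    raise KeyError(f"atom {spec!r} not found in topology")
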