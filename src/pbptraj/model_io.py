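"""Domain types and PDB readers/writers for structures and trajectories.

The in-memory model is deliberately flat: a :class:`Structure` is an ordered
list of :class:`Atom` records, a :class:`Trajectory` is a shared atom roster
plus an ``(n_frames, n_atoms, 3)`` coordinate block.  Multi-model PDB is the
only trajectory format; binary MD formats (DCD/XTC) are out of scope — use
``mdconvert`` or ``cpptraj`` to produce a multi-model PDB first.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from Bio.PDB import PDBParser

from .constants import WATER_NAMES, atomic_mass

__all__ = [
    "Atom",
    "Structure",
    "Trajectory",
    "DomainPartition",
    "read_pdb",
    "read_trajectory",
    "write_pdb",
    "write_trajectory",
]


@dataclass(eq=False)
class Atom:
    """One atom: residue bookkeeping, element, position and mass.

    ``residue_index`` is the 1-based mature-chain number taken verbatim from
    the PDB residue sequence field (no renumbering is ever applied).
    """

    residue_index: int
    residue_name: str
    atom_name: str
    element: str
    position: np.ndarray
    mass: float = 0.0

    def __post_init__(self) -> None:
        if self.residue_index < 1:
            raise ValueError(f"residue_index must be >= 1, got {self.residue_index}")
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError("position must be a 3-vector")
        if not np.all(np.isfinite(self.position)):
            raise ValueError("position must be finite")
        if self.mass == 0.0:
            self.mass = atomic_mass(self.element)
        if self.mass <= 0:
            raise ValueError(f"mass must be positive, got {self.mass}")

    @property
    def key(self) -> tuple[int, str]:
        """Roster identity: (residue_index, atom_name)."""
        return (self.residue_index, self.atom_name)


class Structure:
    """One conformation: an ordered atom list with cached coordinate arrays."""

    def __init__(self, atoms: Sequence[Atom], label: str = "", model_number: int = 1):
        atoms = list(atoms)
        if not atoms:
            raise ValueError("a Structure needs at least one atom")
        idx = [a.residue_index for a in atoms]
        if any(b < a for a, b in zip(idx, idx[1:])):
            raise ValueError("residue indices must be non-decreasing along the atom list")
        self.atoms: list[Atom] = atoms
        self.label = label
        self.model_number = model_number
        self._coords: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.atoms)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Structure({self.label!r}, {len(self.atoms)} atoms, model {self.model_number})"

    # -- cached array views -------------------------------------------------

    @property
    def coords(self) -> np.ndarray:
        """``(n_atoms, 3)`` float array of positions (read-only view)."""
        if self._coords is None:
            c = np.array([a.position for a in self.atoms], dtype=float)
            c.setflags(write=False)
            self._coords = c
        return self._coords

    @property
    def residue_indices(self) -> np.ndarray:
        return np.array([a.residue_index for a in self.atoms], dtype=int)

    @property
    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms], dtype=float)

    @property
    def roster(self) -> tuple[tuple[int, str], ...]:
        return tuple(a.key for a in self.atoms)

    # -- selections ---------------------------------------------------------

    def select(self, residue_set: Iterable[int] | None = None,
               atom_filter: str = "heavy") -> np.ndarray:
        """Indices of atoms matching a residue set and an atom filter.

        ``atom_filter`` is ``"heavy"`` (non-hydrogen), ``"ca"`` (CA atoms) or
        ``"all"``.
        """
        if atom_filter not in ("heavy", "ca", "all"):
            raise ValueError(f"unknown atom_filter {atom_filter!r}")
        rset = None if residue_set is None else frozenset(residue_set)
        out = []
        for i, a in enumerate(self.atoms):
            if rset is not None and a.residue_index not in rset:
                continue
            if atom_filter == "ca" and a.atom_name != "CA":
                continue
            if atom_filter == "heavy" and a.element.upper() == "H":
                continue
            out.append(i)
        return np.array(out, dtype=int)

    def ca_by_residue(self) -> dict[int, int]:
        """Map residue_index -> atom index of its CA (first CA wins)."""
        out: dict[int, int] = {}
        for i, a in enumerate(self.atoms):
            if a.atom_name == "CA" and a.residue_index not in out:
                out[a.residue_index] = i
        return out

    def with_coords(self, coords: np.ndarray, label: str | None = None,
                    model_number: int | None = None) -> "Structure":
        """New Structure sharing atom metadata but with replaced positions."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError("coords shape mismatch")
        atoms = [dataclasses.replace(a, position=coords[i]) for i, a in enumerate(self.atoms)]
        return Structure(atoms,
                         label=self.label if label is None else label,
                         model_number=self.model_number if model_number is None else model_number)


class Trajectory:
    """Ordered frames sharing one atom roster, with a frame interval in ps."""

    def __init__(self, atoms: Sequence[Atom], coords: np.ndarray,
                 frame_interval_ps: float, run_id: str = ""):
        if frame_interval_ps <= 0:
            raise ValueError("frame_interval_ps must be positive")
        coords = np.asarray(coords, dtype=float)
        if coords.ndim != 3 or coords.shape[1:] != (len(atoms), 3):
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if coords.shape[0] == 0:
            raise ValueError("a Trajectory needs at least one frame")
        self.atoms = list(atoms)
        self.coords = coords
        self.frame_interval_ps = float(frame_interval_ps)
        self.run_id = run_id
        # template structure used for selections / roster checks
        self._template = Structure(self.atoms, label=run_id)

    @classmethod
    def from_structures(cls, frames: Sequence[Structure], frame_interval_ps: float,
                        run_id: str = "") -> "Trajectory":
        if not frames:
            raise ValueError("a Trajectory needs at least one frame")
        roster = frames[0].roster
        for k, fr in enumerate(frames[1:], start=2):
            if fr.roster != roster:
                raise ValueError(
                    f"atom roster of frame {k} does not match frame 1 "
                    f"({len(fr.roster)} vs {len(roster)} atoms or differing identities)")
        coords = np.stack([fr.coords for fr in frames])
        return cls(frames[0].atoms, coords, frame_interval_ps, run_id=run_id)

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def __len__(self) -> int:
        return self.n_frames

    @property
    def template(self) -> Structure:
        """Roster-bearing Structure (positions are those of frame 1)."""
        return self._template

    @property
    def times_ps(self) -> np.ndarray:
        """Simulation time of each frame; the first frame sits at one interval."""
        return self.frame_interval_ps * np.arange(1, self.n_frames + 1)

    def frame(self, i: int) -> Structure:
        return self._template.with_coords(self.coords[i],
                                          label=f"{self.run_id}[{i}]",
                                          model_number=i + 1)

    def __iter__(self) -> Iterator[Structure]:
        for i in range(self.n_frames):
            yield self.frame(i)


@dataclass(frozen=True)
class DomainPartition:
    """Residue-index sets for the two domains and the two hinge linkers."""

    domain1: frozenset[int]
    domain2: frozenset[int]
    linker1: frozenset[int]
    linker2: frozenset[int]

    def __post_init__(self) -> None:
        sets = {"domain1": self.domain1, "domain2": self.domain2,
                "linker1": self.linker1, "linker2": self.linker2}
        for name, s in sets.items():
            object.__setattr__(self, name, frozenset(s))
        sets = {n: getattr(self, n) for n in sets}
        for name, s in sets.items():
            if not s:
                raise ValueError(f"{name} must not be empty")
        names = list(sets)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                if sets[a] & sets[b]:
                    raise ValueError(f"{a} and {b} overlap: {sorted(sets[a] & sets[b])[:5]}")

    @property
    def hinge(self) -> frozenset[int]:
        return self.linker1 | self.linker2

    @classmethod
    def default_pbp(cls) -> "DomainPartition":
        """The canonical two-domain split of the 238-residue PBP chain."""
        return cls(
            domain1=frozenset(range(1, 87)) | frozenset(range(197, 239)),
            domain2=frozenset(range(90, 193)),
            linker1=frozenset(range(87, 90)),
            linker2=frozenset(range(193, 197)),
        )


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _biopdb_models(path: str | Path):
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"PDB file not found: {path}")
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure(path.stem, str(path))
    return list(structure.get_models())


def _model_to_structure(model, label: str, model_number: int,
                        keep_hetero: bool, keep_hydrogens: bool) -> Structure | None:
    atoms: list[Atom] = []
    for chain in model:
        for residue in chain:
            hetfield, resseq, _icode = residue.id
            resname = residue.get_resname().strip()
            if resname in WATER_NAMES or hetfield == "W":
                continue
            if hetfield.strip() and not keep_hetero:
                continue
            for at in residue:
                altloc = at.get_altloc()
                if altloc not in (" ", "", "A"):
                    continue
                element = (at.element or "").strip() or at.get_name()[0]
                if element.upper() in ("H", "D") and not keep_hydrogens:
                    continue
                atoms.append(Atom(
                    residue_index=int(resseq),
                    residue_name=resname,
                    atom_name=at.get_name().strip(),
                    element=element.upper(),
                    position=np.asarray(at.get_coord(), dtype=float),
                ))
    if not atoms:
        return None
    atoms.sort(key=lambda a: a.residue_index)  # chains may restart numbering; keep it monotone
    return Structure(atoms, label=label, model_number=model_number)


def read_pdb(path: str | Path, model_selector: int | str = "first", *,
             keep_hetero: bool = False, keep_hydrogens: bool = False) -> Structure:
    """Read one model of a PDB file into a :class:`Structure`.

    Waters are always discarded; other heteroatoms and hydrogens are dropped
    unless explicitly kept.  ``model_selector`` is ``"first"`` or a MODEL
    serial number (NMR ensembles default to model 1).
    """
    models = _biopdb_models(path)
    if not models:
        raise ValueError(f"{path}: no models found")
    if model_selector == "first":
        model = models[0]
    else:
        wanted = int(model_selector)
        by_serial = {m.serial_num: m for m in models}
        if wanted in by_serial:
            model = by_serial[wanted]
        elif 1 <= wanted <= len(models):
            model = models[wanted - 1]
        else:
            raise ValueError(f"{path}: model {wanted} not found ({len(models)} models present)")
    st = _model_to_structure(model, Path(path).stem, model.serial_num or 1,
                             keep_hetero, keep_hydrogens)
    if st is None:
        raise ValueError(f"{path}: zero protein atoms after filtering")
    return st


def read_trajectory(path: str | Path, frame_interval_ps: float, *,
                    run_id: str | None = None,
                    keep_hetero: bool = False) -> Trajectory:
    """Read a multi-model PDB as a trajectory; all models must share a roster."""
    models = _biopdb_models(path)
    frames: list[Structure] = []
    for k, model in enumerate(models, start=1):
        st = _model_to_structure(model, f"{Path(path).stem}[{k}]", k, keep_hetero, False)
        if st is None:
            raise ValueError(f"{path}: frame {k} contains zero protein atoms")
        frames.append(st)
    if not frames:
        raise ValueError(f"{path}: no models found")
    roster = frames[0].roster
    for k, fr in enumerate(frames[1:], start=2):
        if fr.roster != roster:
            raise ValueError(f"{path}: atom roster of frame {k} differs from frame 1")
    return Trajectory.from_structures(frames, frame_interval_ps,
                                      run_id=run_id if run_id is not None else Path(path).stem)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def _format_atom_name(name: str, element: str) -> str:
    # PDB columns 13-16: element right-justified in 13-14 for 1-char elements
    if len(name) >= 4:
        return name[:4]
    if len(element) == 1:
        return f" {name:<3s}"
    return f"{name:<4s}"


def _atom_record(serial: int, atom: Atom, pos: np.ndarray) -> str:
    name = _format_atom_name(atom.atom_name, atom.element)
    return (f"ATOM  {serial:5d} {name} {atom.residue_name:<3.3s} A"
            f"{atom.residue_index:4d}    "
            f"{pos[0]:8.3f}{pos[1]:8.3f}{pos[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
            f"          {atom.element:>2.2s}")


def write_pdb(structure: Structure, path: str | Path) -> None:
    """Write a single-model PDB file."""
    lines = [_atom_record(i + 1, a, structure.coords[i]) for i, a in enumerate(structure.atoms)]
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def write_trajectory(trajectory: Trajectory, path: str | Path) -> None:
    """Write a trajectory as a multi-model PDB, one MODEL block per frame."""
    if trajectory.n_frames == 0:
        raise ValueError("cannot write an empty trajectory")
    chunks: list[str] = []
    atoms = trajectory.atoms
    for f in range(trajectory.n_frames):
        chunks.append(f"MODEL     {f + 1:4d}")
        pos = trajectory.coords[f]
        chunks.extend(_atom_record(i + 1, a, pos[i]) for i, a in enumerate(atoms))
        chunks.append("ENDMDL")
    chunks.append("END")
    Path(path).write_text("\n".join(chunks) + "\n")
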