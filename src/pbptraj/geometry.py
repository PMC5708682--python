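"""Rigid-body superposition and the inter-domain hinge metrics.

All angles are returned in degrees.  Superposition is the classic Kabsch
least-squares fit (proper rotations only); batched variants operating on
``(n_frames, n_atoms, 3)`` blocks back the trajectory pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .model_io import DomainPartition, Structure, Trajectory

__all__ = [
    "SuperpositionResult",
    "center_of_mass",
    "superpose",
    "rmsd",
    "interdomain_distance",
    "interdomain_angle",
    "interdomain_dihedral",
    "torsion_deg",
]


@dataclass(frozen=True)
class SuperpositionResult:
    """Optimal rigid map ``x -> rotation @ x + translation`` (mobile onto reference)."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd_fit_atoms: float

    def __post_init__(self) -> None:
        if not np.isclose(np.linalg.det(self.rotation), 1.0, atol=1e-6):
            raise ValueError("rotation must be proper (det +1)")
        if self.rmsd_fit_atoms < 0:
            raise ValueError("rmsd must be non-negative")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation


def center_of_mass(structure: Structure, residue_set: Iterable[int] | None = None,
                   atom_filter: str = "heavy") -> np.ndarray:
    """Mass-weighted mean position of the selected atoms."""
    idx = structure.select(residue_set, atom_filter)
    if idx.size == 0:
        raise ValueError("empty atom selection for center of mass")
    w = structure.masses[idx]
    return w @ structure.coords[idx] / w.sum()


def paired_indices(mobile: Structure, reference: Structure,
                   atom_filter: str = "ca",
                   residue_set: Iterable[int] | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Pair atoms 1:1 by (residue_index, atom_name); order follows the mobile."""
    sel_m = mobile.select(residue_set, atom_filter)
    sel_r = reference.select(residue_set, atom_filter)
    ref_map = {reference.atoms[i].key: i for i in sel_r}
    im, ir = [], []
    for i in sel_m:
        j = ref_map.get(mobile.atoms[i].key)
        if j is not None:
            im.append(i)
            ir.append(j)
    return np.array(im, dtype=int), np.array(ir, dtype=int)


def _kabsch(mob: np.ndarray, ref: np.ndarray) -> tuple[np.ndarray, float]:
    """Optimal proper rotation aligning centered ``mob`` to centered ``ref``.

    Returns (rotation, rmsd over the fit atoms).  Supports a leading batch
    dimension on ``mob``.
    """
    mob = np.asarray(mob, dtype=float)
    ref = np.asarray(ref, dtype=float)
    batched = mob.ndim == 3
    if not batched:
        mob = mob[None]
    n = mob.shape[1]
    mc = mob - mob.mean(axis=1, keepdims=True)
    rc = ref - ref.mean(axis=0)
    h = np.einsum("fni,nj->fij", mc, rc)
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(np.einsum("fij,fjk->fik", u, vt)))
    # flip the smallest singular direction when the raw solution is improper
    u_fixed = u.copy()
    u_fixed[..., :, 2] *= d[..., None]
    rot = np.einsum("fja,fbj->fab", vt, u_fixed)  # R = V diag(1,1,d) U^T
    resid = np.einsum("fij,fnj->fni", rot, mc) - rc
    r = np.sqrt((resid ** 2).sum(axis=2).mean(axis=1))
    if not batched:
        return rot[0], float(r[0])
    return rot, r


def superpose(mobile: Structure, reference: Structure,
              fit_atoms: str = "heavy",
              residue_set: Iterable[int] | None = None) -> SuperpositionResult:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``."""
    im, ir = paired_indices(mobile, reference, fit_atoms, residue_set)
    if im.size < 3:
        raise ValueError(f"need at least 3 paired fit atoms, got {im.size}")
    mob = mobile.coords[im]
    ref = reference.coords[ir]
    rot, fit_rmsd = _kabsch(mob, ref)
    t = ref.mean(axis=0) - rot @ mob.mean(axis=0)
    return SuperpositionResult(rotation=rot, translation=t, rmsd_fit_atoms=fit_rmsd)


def rmsd(mobile: Structure, reference: Structure,
         fit_atoms: str = "ca", measure_atoms: str = "ca",
         residue_set: Iterable[int] | None = None) -> float:
    """Superpose on ``fit_atoms`` then measure RMSD over ``measure_atoms``."""
    sup = superpose(mobile, reference, fit_atoms, residue_set)
    if fit_atoms == measure_atoms:
        return sup.rmsd_fit_atoms
    im, ir = paired_indices(mobile, reference, measure_atoms, residue_set)
    if im.size == 0:
        raise ValueError("no paired measure atoms")
    moved = sup.apply(mobile.coords[im])
    return float(np.sqrt(((moved - reference.coords[ir]) ** 2).sum(axis=1).mean()))


def rmsd_series(traj: Trajectory, reference: Structure,
                fit_atoms: str = "heavy", measure_atoms: str = "ca") -> np.ndarray:
    """Per-frame RMSD of a trajectory against one reference (batched Kabsch)."""
    tpl = traj.template
    fm, fr = paired_indices(tpl, reference, fit_atoms)
    if fm.size < 3:
        raise ValueError("need at least 3 paired fit atoms")
    mob = traj.coords[:, fm]
    ref = reference.coords[fr]
    rot, fit_rmsd = _kabsch(mob, ref)
    if fit_atoms == measure_atoms:
        return fit_rmsd
    mm, mr = paired_indices(tpl, reference, measure_atoms)
    if mm.size == 0:
        raise ValueError("no paired measure atoms")
    mob_c = traj.coords[:, fm].mean(axis=1)
    ref_c = ref.mean(axis=0)
    moved = np.einsum("fij,fnj->fni", rot, traj.coords[:, mm] - mob_c[:, None, :]) + ref_c
    diff = moved - reference.coords[mr]
    return np.sqrt((diff ** 2).sum(axis=2).mean(axis=1))


# ---------------------------------------------------------------------------
# inter-domain metrics
# ---------------------------------------------------------------------------

def _com_from_arrays(coords: np.ndarray, masses: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """COM over ``idx``; ``coords`` may carry a leading frame axis."""
    w = masses[idx]
    return np.tensordot(coords[..., idx, :], w, axes=([-2], [0])) / w.sum()


def _partition_indices(structure: Structure, partition: DomainPartition,
                       atom_filter: str = "heavy") -> dict[str, np.ndarray]:
    out = {}
    for name in ("domain1", "domain2", "linker1", "linker2"):
        idx = structure.select(getattr(partition, name), atom_filter)
        if idx.size == 0:
            raise ValueError(f"partition set {name} selects no atoms")
        out[name] = idx
    out["hinge"] = structure.select(partition.hinge, atom_filter)
    return out


def _angle_deg(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    na = np.linalg.norm(a, axis=-1)
    nb = np.linalg.norm(b, axis=-1)
    if np.any(na < 1e-9) or np.any(nb < 1e-9):
        raise ValueError("degenerate (collocated) centers: angle undefined")
    cosang = np.clip((a * b).sum(axis=-1) / (na * nb), -1.0, 1.0)
    return np.degrees(np.arccos(cosang))


def torsion_deg(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray, p4: np.ndarray) -> np.ndarray:
    """Signed dihedral over four points, in (-180, 180]; accepts batches."""
    b1 = np.asarray(p2) - p1
    b2 = np.asarray(p3) - p2
    b3 = np.asarray(p4) - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.any(np.linalg.norm(n1, axis=-1) < 1e-9) or np.any(np.linalg.norm(n2, axis=-1) < 1e-9):
        raise ValueError("degenerate (collinear) centers: dihedral undefined")
    m1 = np.cross(n1, b2 / np.linalg.norm(b2, axis=-1, keepdims=True))
    x = (n1 * n2).sum(axis=-1)
    y = (m1 * n2).sum(axis=-1)
    ang = np.degrees(np.arctan2(y, x))
    # map -180 -> 180 to keep the (−180, 180] contract
    return np.where(np.isclose(ang, -180.0), 180.0, ang)


def interdomain_distance(structure: Structure, partition: DomainPartition) -> float:
    """Distance between the heavy-atom COMs of the two domains."""
    c1 = center_of_mass(structure, partition.domain1)
    c2 = center_of_mass(structure, partition.domain2)
    return float(np.linalg.norm(c1 - c2))


def interdomain_angle(structure: Structure, partition: DomainPartition) -> float:
    """Angle at the hinge COM subtended by the two domain COMs, degrees."""
    c1 = center_of_mass(structure, partition.domain1)
    c2 = center_of_mass(structure, partition.domain2)
    h = center_of_mass(structure, partition.hinge)
    return float(_angle_deg(c1 - h, c2 - h))


def interdomain_dihedral(structure: Structure, partition: DomainPartition) -> float:
    """Torsion over COM(domain1)-COM(linker1)-COM(linker2)-COM(domain2), degrees."""
    pts = [center_of_mass(structure, getattr(partition, n))
           for n in ("domain1", "linker1", "linker2", "domain2")]
    return float(torsion_deg(*pts))


def interdomain_series(traj: Trajectory, partition: DomainPartition) -> dict[str, np.ndarray]:
    """Per-frame distance/angle/dihedral for a whole trajectory."""
    tpl = traj.template
    idx = _partition_indices(tpl, partition)
    masses = tpl.masses
    c1 = _com_from_arrays(traj.coords, masses, idx["domain1"])
    c2 = _com_from_arrays(traj.coords, masses, idx["domain2"])
    l1 = _com_from_arrays(traj.coords, masses, idx["linker1"])
    l2 = _com_from_arrays(traj.coords, masses, idx["linker2"])
    h = _com_from_arrays(traj.coords, masses, idx["hinge"])
    return {
        "distance": np.linalg.norm(c1 - c2, axis=-1),
        "angle": _angle_deg(c1 - h, c2 - h),
        "dihedral": torsion_deg(c1, l1, l2, c2),
    }
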