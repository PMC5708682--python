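"""Radius of gyration, accessible surface area and omega-angle isomers.

The accessible-surface routine is a deterministic Shrake-Rupley: a fixed
golden-spiral point set is placed on every expanded atom sphere and points
buried inside any neighbour are discarded.  Identical coordinates therefore
give bitwise-identical areas.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .constants import PROBE_RADIUS, vdw_radius
from .model_io import Structure, Trajectory

logger = logging.getLogger(__name__)

__all__ = [
    "OmegaRecord",
    "ProlineIsomerSeries",
    "radius_of_gyration",
    "sasa",
    "omega_angles",
    "classify_omega",
    "check_proline_isomer",
]

#: classification bands, degrees; |omega| <= CIS_MAX -> cis, >= TRANS_MIN -> trans
CIS_MAX_DEG = 30.0
TRANS_MIN_DEG = 150.0


@dataclass(frozen=True)
class OmegaRecord:
    """Peptide-bond torsion for the bond ending at ``residue_index``."""

    residue_index: int
    omega_deg: float
    isomer: str

    def __post_init__(self) -> None:
        if self.isomer != classify_omega(self.omega_deg):
            raise ValueError("isomer label inconsistent with omega_deg")


@dataclass(frozen=True)
class ProlineIsomerSeries:
    residue_index: int
    labels: tuple[str, ...]
    stable: bool
    flip_frames: tuple[int, ...]


def classify_omega(omega_deg: float, cis_max: float = CIS_MAX_DEG,
                   trans_min: float = TRANS_MIN_DEG) -> str:
    a = abs(float(omega_deg))
    if a <= cis_max:
        return "cis"
    if a >= trans_min:
        return "trans"
    return "twisted"


def radius_of_gyration(structure: Structure, atom_filter: str = "heavy") -> float:
    """Mass-weighted radius of gyration about the centre of mass."""
    idx = structure.select(atom_filter=atom_filter)
    if idx.size == 0:
        raise ValueError("empty atom selection for radius of gyration")
    w = structure.masses[idx]
    x = structure.coords[idx]
    com = w @ x / w.sum()
    return float(np.sqrt((w * ((x - com) ** 2).sum(axis=1)).sum() / w.sum()))


def rg_series(traj: Trajectory, atom_filter: str = "heavy") -> np.ndarray:
    tpl = traj.template
    idx = tpl.select(atom_filter=atom_filter)
    if idx.size == 0:
        raise ValueError("empty atom selection for radius of gyration")
    w = tpl.masses[idx]
    x = traj.coords[:, idx]
    com = np.tensordot(x, w, axes=([1], [0])) / w.sum()
    sq = ((x - com[:, None, :]) ** 2).sum(axis=2)
    return np.sqrt((sq * w).sum(axis=1) / w.sum())


@lru_cache(maxsize=8)
def sphere_points(n: int) -> np.ndarray:
    """Deterministic golden-spiral point set on the unit sphere."""
    if n < 1:
        raise ValueError("need at least one sphere point")
    k = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * k + 1.0) / n
    phi = k * np.pi * (3.0 - np.sqrt(5.0))
    r = np.sqrt(np.maximum(1.0 - z * z, 0.0))
    pts = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    pts.setflags(write=False)
    return pts


def _sasa_coords(coords: np.ndarray, radii: np.ndarray,
                 probe_radius: float, n_points: int) -> float:
    pts = sphere_points(n_points)
    expanded = radii + probe_radius
    # pairwise neighbour lists once per frame
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    n = len(coords)
    area = 0.0
    for i in range(n):
        ri = expanded[i]
        nbr = np.flatnonzero((d[i] < ri + expanded) & (np.arange(n) != i))
        sphere = coords[i] + ri * pts
        if nbr.size:
            dist2 = ((sphere[:, None, :] - coords[nbr][None, :, :]) ** 2).sum(axis=-1)
            buried = (dist2 < (expanded[nbr] ** 2)[None, :]).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        area += 4.0 * np.pi * ri * ri * frac
    return float(area)


def sasa(structure: Structure, probe_radius: float = PROBE_RADIUS,
         n_points: int = 960, radii: dict[str, float] | None = None) -> float:
    """Total solvent-accessible surface over heavy atoms, Angstrom^2."""
    idx = structure.select(atom_filter="heavy")
    if idx.size == 0:
        raise ValueError("no heavy atoms for SASA")
    elements = [structure.atoms[i].element for i in idx]
    if radii is None:
        r = np.array([vdw_radius(e) for e in elements])
    else:
        r = np.array([radii[e.upper()] if e.upper() in radii else vdw_radius(e)
                      for e in elements])
    return _sasa_coords(structure.coords[idx], r, probe_radius, n_points)


def sasa_series(traj: Trajectory, probe_radius: float = PROBE_RADIUS,
                n_points: int = 960) -> np.ndarray:
    tpl = traj.template
    idx = tpl.select(atom_filter="heavy")
    if idx.size == 0:
        raise ValueError("no heavy atoms for SASA")
    r = np.array([vdw_radius(tpl.atoms[i].element) for i in idx])
    return np.array([_sasa_coords(traj.coords[f][idx], r, probe_radius, n_points)
                     for f in range(traj.n_frames)])


# ---------------------------------------------------------------------------
# omega angles
# ---------------------------------------------------------------------------

def _backbone_map(structure: Structure) -> dict[int, dict[str, np.ndarray]]:
    out: dict[int, dict[str, np.ndarray]] = {}
    for a in structure.atoms:
        if a.atom_name in ("N", "CA", "C"):
            out.setdefault(a.residue_index, {})[a.atom_name] = a.position
    return out


def omega_angles(structure: Structure) -> list[OmegaRecord]:
    """Omega torsion CA(i-1)-C(i-1)-N(i)-CA(i) for every scoreable bond.

    Bonds with missing backbone atoms are skipped with a warning rather than
    raising: partial backbones are the norm in pseudo-atom models.
    """
    from .geometry import torsion_deg

    bb = _backbone_map(structure)
    residues = sorted(bb)
    records: list[OmegaRecord] = []
    for prev, cur in zip(residues, residues[1:]):
        if cur != prev + 1:
            continue
        a, b = bb[prev], bb[cur]
        if not ({"CA", "C"} <= a.keys() and {"N", "CA"} <= b.keys()):
            # warn only when a partial backbone exists; pure CA traces are
            # expected (pseudo-atom models) and would flood the log
            if "C" in a or "N" in b:
                logger.warning("omega bond %d-%d skipped: missing backbone atoms", prev, cur)
            continue
        omega = float(torsion_deg(a["CA"], a["C"], b["N"], b["CA"]))
        records.append(OmegaRecord(cur, omega, classify_omega(omega)))
    return records


def check_proline_isomer(traj: Trajectory, residue_index: int = 16) -> ProlineIsomerSeries:
    """Per-frame cis/trans label of one peptide bond across a trajectory."""
    from .geometry import torsion_deg

    if traj.n_frames == 0:
        raise ValueError("empty trajectory")
    tpl = traj.template
    pos: dict[tuple[int, str], int] = {}
    for i, a in enumerate(tpl.atoms):
        pos.setdefault(a.key, i)
    needed = [(residue_index - 1, "CA"), (residue_index - 1, "C"),
              (residue_index, "N"), (residue_index, "CA")]
    try:
        ia, ib, ic, id_ = (pos[k] for k in needed)
    except KeyError as exc:
        raise ValueError(
            f"residue {residue_index}: backbone atoms for the omega bond are absent "
            f"(missing {exc.args[0]})") from None
    om = torsion_deg(traj.coords[:, ia], traj.coords[:, ib],
                     traj.coords[:, ic], traj.coords[:, id_])
    labels = tuple(classify_omega(o) for o in np.atleast_1d(om))
    flips = tuple(i for i in range(1, len(labels)) if labels[i] != labels[i - 1])
    return ProlineIsomerSeries(residue_index, labels, stable=len(set(labels)) == 1,
                               flip_frames=flips)
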