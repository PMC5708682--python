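"""Synthetic two-domain hinge trajectories with ground-truth events.

A pseudo-CA chain (3.8 A spacing) is folded into two compact globular
domains joined by two short linkers.  The closed reference is the open one
with domain 2 rigidly rotated about the hinge; trajectories interpolate the
hinge angle along a schedule of logistic transitions and add isotropic
Gaussian noise.  Everything is reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .model_io import Atom, DomainPartition, Structure, Trajectory

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "scaled_partition",
    "make_toy_protein",
    "generate_trajectory",
    "benchmark_suite",
    "default_benchmark_config",
]


def scaled_partition(n_residues: int) -> DomainPartition:
    """The canonical 238-residue partition rescaled to ``n_residues``."""
    if n_residues == 238:
        return DomainPartition.default_pbp()
    if n_residues < 20:
        raise ValueError("need at least 20 residues for a sensible partition")
    b1 = max(int(round(86 / 238 * n_residues)), 4)       # end of domain1 head
    l1 = 3                                               # linker1 length
    b2 = int(round(192 / 238 * n_residues))              # end of domain2
    l2 = 4                                               # linker2 length
    d2_start = b1 + l1 + 1
    return DomainPartition(
        domain1=frozenset(range(1, b1 + 1)) | frozenset(range(b2 + l2 + 1, n_residues + 1)),
        linker1=frozenset(range(b1 + 1, d2_start)),
        domain2=frozenset(range(d2_start, b2 + 1)),
        linker2=frozenset(range(b2 + 1, b2 + l2 + 1)),
    )


@dataclass(frozen=True)
class SyntheticConfig:
    """Full description of one synthetic data set."""

    n_residues: int = 238
    partition: DomainPartition | None = None
    theta_open: float = 130.0
    theta_closed: float = 95.0
    start_state: str = "closed"
    #: entries are (time_ps, direction) applied to every run, or
    #: (run_index, time_ps, direction) for a single run
    event_schedule: tuple = ()
    noise_sigma: float = 0.3
    n_runs: int = 1
    run_length_ns: float = 10.0
    frame_interval_ps: float = 20.0
    transition_width_ps: float = 500.0
    seed: int = 0
    omega16: str = "cis"
    ligand: bool = False
    label: str = "synthetic"

    def __post_init__(self) -> None:
        if self.theta_open == self.theta_closed:
            raise ValueError("theta_open must differ from theta_closed")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if self.run_length_ns <= 0 or self.frame_interval_ps <= 0:
            raise ValueError("run length and frame interval must be positive")
        if self.start_state not in ("open", "closed"):
            raise ValueError("start_state must be 'open' or 'closed'")
        if self.omega16 not in ("cis", "trans"):
            raise ValueError("omega16 must be 'cis' or 'trans'")
        part = self.partition if self.partition is not None else scaled_partition(self.n_residues)
        covered = part.domain1 | part.domain2 | part.hinge
        if max(covered) > self.n_residues:
            raise ValueError("partition references residues beyond n_residues")
        object.__setattr__(self, "partition", part)
        # normalize and validate the schedule
        self.per_run_schedule()  # raises on malformed entries

    @property
    def run_length_ps(self) -> float:
        return self.run_length_ns * 1000.0

    @property
    def n_frames_per_run(self) -> int:
        return int(round(self.run_length_ps / self.frame_interval_ps))

    def per_run_schedule(self) -> list[list[tuple[float, str]]]:
        """Schedule normalised to one sorted (time_ps, direction) list per run."""
        runs: list[list[tuple[float, str]]] = [[] for _ in range(self.n_runs)]
        for entry in self.event_schedule:
            if len(entry) == 2:
                t, direction = entry
                targets = range(self.n_runs)
            elif len(entry) == 3:
                r, t, direction = entry
                if not 0 <= int(r) < self.n_runs:
                    raise ValueError(f"schedule entry references run {r} of {self.n_runs}")
                targets = [int(r)]
            else:
                raise ValueError(f"malformed schedule entry {entry!r}")
            if direction not in ("opening", "closing"):
                raise ValueError(f"unknown event direction {direction!r}")
            if not 0 < float(t) < self.run_length_ps:
                raise ValueError(f"event time {t} ps outside run (0, {self.run_length_ps})")
            for r in targets:
                runs[r].append((float(t), direction))
        for r, sched in enumerate(runs):
            sched.sort()
            state = self.start_state
            for t, direction in sched:
                want = "closed" if direction == "opening" else "open"
                if state != want:
                    raise ValueError(
                        f"run {r}: {direction} event at {t} ps but state is already "
                        f"{'open' if direction == 'opening' else 'closed'}")
                state = "open" if direction == "opening" else "closed"
        return runs


@dataclass(frozen=True)
class GroundTruth:
    """What the generator actually did, for scoring detectors against."""

    events: tuple[tuple[tuple[int, str], ...], ...]  # per run: (frame, direction)
    true_angles: tuple[np.ndarray, ...]              # per run, per frame, degrees
    theta_open: float
    theta_closed: float

    @property
    def all_events(self) -> list[tuple[int, int, str]]:
        """Flattened (run, frame, direction) triples."""
        return [(r, f, d) for r, evs in enumerate(self.events) for f, d in evs]


# ---------------------------------------------------------------------------
# toy protein construction
# ---------------------------------------------------------------------------

_REGION_CENTERS = {
    "domain1": np.array([0.0, 0.0, 0.0]),
    "linker1": np.array([13.0, 2.0, 0.0]),
    "linker2": np.array([13.0, -2.0, 0.0]),
    "domain2": np.array([24.0, 10.0, 0.0]),
}
_DOMAIN_RADIUS = 11.0
_CA_SPACING = 3.8


def _region_of(residue: int, part: DomainPartition) -> str:
    for name in ("domain1", "domain2", "linker1", "linker2"):
        if residue in getattr(part, name):
            return name
    raise ValueError(f"residue {residue} not covered by the partition")


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _walk_chain(n: int, part: DomainPartition, rng: np.random.Generator) -> np.ndarray:
    """Compact biased random walk with fixed 3.8 A steps."""
    pos = np.empty((n, 3))
    pos[0] = _REGION_CENTERS[_region_of(1, part)] + rng.normal(scale=2.0, size=3)
    for i in range(1, n):
        center = _REGION_CENTERS[_region_of(i + 1, part)]
        cur = pos[i - 1]
        off = center - cur
        dist = np.linalg.norm(off)
        pull = off / dist if dist > 1e-9 else _random_unit(rng)
        weight = 3.0 if dist > _DOMAIN_RADIUS else 0.8
        step = weight * pull + _random_unit(rng)
        pos[i] = cur + _CA_SPACING * step / np.linalg.norm(step)
    return pos


def _place_by_internal(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                       bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """NeRF placement of the atom bonded to ``c`` with given internal coordinates."""
    theta = np.radians(angle_deg)
    tau = np.radians(torsion_deg)
    bc = c - b
    bc_u = bc / np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc_u)
    n_u = n / np.linalg.norm(n)
    m_u = np.cross(n_u, bc_u)
    d_local = np.array([-bond * np.cos(theta),
                        bond * np.sin(theta) * np.cos(tau),
                        -bond * np.sin(theta) * np.sin(tau)])
    return c + d_local[0] * bc_u + d_local[1] * m_u + d_local[2] * n_u


def _rodrigues(axis: np.ndarray, angle_rad: np.ndarray) -> np.ndarray:
    """Rotation matrices about ``axis`` for each angle; shape (..., 3, 3)."""
    a = np.asarray(angle_rad, dtype=float)
    k = axis / np.linalg.norm(axis)
    kx = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    eye = np.eye(3)
    c = np.cos(a)[..., None, None]
    s = np.sin(a)[..., None, None]
    return c * eye + s * kx + (1 - np.cos(a))[..., None, None] * np.outer(k, k)


def _hinge_frame(structure: Structure, part: DomainPartition
                 ) -> tuple[np.ndarray, np.ndarray, float]:
    """(hinge COM, rotation axis, current hinge angle in degrees)."""
    from .geometry import center_of_mass, interdomain_angle

    h = center_of_mass(structure, part.hinge)
    u = center_of_mass(structure, part.domain1) - h
    v = center_of_mass(structure, part.domain2) - h
    axis = np.cross(u, v)
    norm = np.linalg.norm(axis)
    if norm < 1e-9:
        raise ValueError("degenerate hinge geometry: domain arms are collinear")
    return h, axis / norm, interdomain_angle(structure, part)


def _rotate_domain2(coords: np.ndarray, idx: np.ndarray, hinge: np.ndarray,
                    axis: np.ndarray, angle_deg: np.ndarray | float) -> np.ndarray:
    """Rotating domain 2 by +phi about cross(u, v) grows the hinge angle by phi."""
    rot = _rodrigues(axis, np.radians(angle_deg))
    out = np.broadcast_to(coords, rot.shape[:-2] + coords.shape).copy() \
        if np.ndim(angle_deg) else coords.copy()
    moved = np.einsum("...ij,nj->...ni", rot, coords[idx] - hinge) + hinge
    out[..., idx, :] = moved
    return out


# omega-bond local geometry; bonds are scaled up ~2x so the torsion is
# robust to the generator's coordinate noise (the toy chain is not physical)
_OMEGA_BONDS = {"ca_c": 3.0, "c_n": 2.6, "n_ca": 2.9}


def make_toy_protein(config: SyntheticConfig) -> tuple[Structure, Structure]:
    """Build the open and closed reference structures for a config."""
    part = config.partition
    rng = np.random.default_rng([int(config.seed), 7])
    chain = _walk_chain(config.n_residues, part, rng)

    omega = 0.0 if config.omega16 == "cis" else 180.0
    special = {15: ("CA", "C"), 16: ("N", "CA", "C")}
    w15, w16 = chain[14], chain[15]
    e1 = (w16 - w15) / np.linalg.norm(w16 - w15)
    ca15 = w15
    c15 = ca15 + _OMEGA_BONDS["ca_c"] * e1
    # dummy previous atom fixes the plane for the first NeRF placement
    dummy = ca15 + np.array([0.0, 0.0, 5.0])
    n16 = _place_by_internal(dummy, ca15, c15, _OMEGA_BONDS["c_n"], 116.0, 150.0)
    ca16 = _place_by_internal(ca15, c15, n16, _OMEGA_BONDS["n_ca"], 122.0, omega)
    c16 = _place_by_internal(c15, n16, ca16, _OMEGA_BONDS["ca_c"], 111.0, 180.0)
    special_pos = {(15, "CA"): ca15, (15, "C"): c15,
                   (16, "N"): n16, (16, "CA"): ca16, (16, "C"): c16}

    atoms: list[Atom] = []
    coords: list[np.ndarray] = []
    for r in range(1, config.n_residues + 1):
        resname = "PRO" if r == 16 else "ALA"
        for name in special.get(r, ("CA",)):
            element = "N" if name == "N" else "C"
            p = special_pos.get((r, name), chain[r - 1])
            atoms.append(Atom(r, resname, name, element, p))
            coords.append(p)
    if config.ligand:
        d1 = np.mean([chain[r - 1] for r in sorted(part.domain1)], axis=0)
        d2 = np.mean([chain[r - 1] for r in sorted(part.domain2)], axis=0)
        p = 0.5 * (d1 + d2)
        atoms.append(Atom(config.n_residues + 1, "LIG", "LIG", "C", p))
        coords.append(p)

    base = Structure(atoms, label=f"{config.label}-base")
    h, axis, theta0 = _hinge_frame(base, part)
    idx2 = base.select(part.domain2, "all")
    xyz = base.coords

    open_xyz = _rotate_domain2(xyz, idx2, h, axis, config.theta_open - theta0)
    closed_xyz = _rotate_domain2(xyz, idx2, h, axis, config.theta_closed - theta0)
    open_ref = base.with_coords(open_xyz, label=f"{config.label}-open")
    closed_ref = base.with_coords(closed_xyz, label=f"{config.label}-closed")
    return open_ref, closed_ref


# ---------------------------------------------------------------------------
# trajectory generation
# ---------------------------------------------------------------------------

def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))


def _angle_profile(times_ps: np.ndarray, start_theta: float,
                   schedule: Sequence[tuple[float, str]],
                   theta_open: float, theta_closed: float,
                   width_ps: float) -> np.ndarray:
    theta = np.full_like(times_ps, start_theta, dtype=float)
    prev = start_theta
    scale = width_ps / 6.0  # logistic ~95% complete across one width
    for t_event, direction in schedule:
        target = theta_open if direction == "opening" else theta_closed
        theta = theta + (target - prev) * _logistic((times_ps - t_event) / scale)
        prev = target
    return theta


def generate_trajectory(config: SyntheticConfig
                        ) -> tuple[list[Trajectory], GroundTruth]:
    """Generate all runs of a config plus the ground truth that produced them."""
    open_ref, closed_ref = make_toy_protein(config)
    part = config.partition
    h, axis, _ = _hinge_frame(open_ref, part)
    idx2 = open_ref.select(part.domain2, "all")
    base = open_ref.coords
    n_frames = config.n_frames_per_run
    times = config.frame_interval_ps * np.arange(1, n_frames + 1)
    start_theta = config.theta_open if config.start_state == "open" else config.theta_closed

    runs: list[Trajectory] = []
    truth_events: list[tuple[tuple[int, str], ...]] = []
    truth_angles: list[np.ndarray] = []
    for r, schedule in enumerate(config.per_run_schedule()):
        theta = _angle_profile(times, start_theta, schedule,
                               config.theta_open, config.theta_closed,
                               config.transition_width_ps)
        coords = _rotate_domain2(base, idx2, h, axis, theta - config.theta_open)
        if config.noise_sigma > 0:
            rng = np.random.default_rng([int(config.seed), 1000 + r])
            coords = coords + rng.normal(scale=config.noise_sigma, size=coords.shape)
        runs.append(Trajectory(open_ref.atoms, coords, config.frame_interval_ps,
                               run_id=f"{config.label}-run{r:02d}"))
        truth_events.append(tuple(
            (int(np.argmin(np.abs(times - t))), d) for t, d in schedule))
        truth_angles.append(theta)
    truth = GroundTruth(events=tuple(truth_events), true_angles=tuple(truth_angles),
                        theta_open=config.theta_open, theta_closed=config.theta_closed)
    return runs, truth


# ---------------------------------------------------------------------------
# canonical fixtures
# ---------------------------------------------------------------------------

def default_benchmark_config(seed: int = 0) -> SyntheticConfig:
    """The standard event-recovery benchmark: 10 runs, 4 scheduled openings.

    Runs are 10 ns (500 frames at 20 ps) rather than 50 ns so the benchmark
    fits a CI budget; detector thresholds are expressed in frames and are
    unaffected by the shortening.
    """
    return SyntheticConfig(
        start_state="closed",
        omega16="trans",
        n_runs=10,
        run_length_ns=10.0,
        event_schedule=(
            (1, 4000.0, "opening"),
            (3, 5000.0, "opening"),
            (5, 6000.0, "opening"),
            (8, 3000.0, "opening"),
        ),
        seed=seed,
        label="benchmark",
    )


def benchmark_suite(seed: int = 0) -> dict[str, SyntheticConfig]:
    """Eight canonical fixtures: four starting conditions x {cis, trans}.

    Mirroring the observation that the trans isomer moves more, trans
    configs carry scheduled transitions while cis configs carry none.
    """
    conditions = {
        "open_empty": ("open", False),
        "open_holo": ("open", True),
        "closed_holo": ("closed", True),
        "closed_empty": ("closed", False),
    }
    out: dict[str, SyntheticConfig] = {}
    for name, (start, ligand) in conditions.items():
        for isomer in ("cis", "trans"):
            if isomer == "trans":
                direction = "opening" if start == "closed" else "closing"
                schedule = ((0, 2000.0, direction), (2, 2500.0, direction))
            else:
                schedule = ()
            out[f"{name}_{isomer}"] = SyntheticConfig(
                start_state=start,
                ligand=ligand,
                omega16=isomer,
                n_runs=3,
                run_length_ns=4.0,
                event_schedule=schedule,
                seed=seed,
                label=f"{name}_{isomer}",
            )
    return out
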