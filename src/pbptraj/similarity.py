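"""Native-contact and all-pair Gaussian similarity scores against references.

Two related per-frame scores over CA-CA distances:

* ``q_nc`` — restricted to the reference's contact set (pairs within a
  distance cutoff at sequence separation >= 2); Gaussian term
  ``exp(-(r_ref - r)^2 / (2 sigma_ij^2))``.
* ``q_similarity`` — over *all* pairs at separation >= 2, no distance
  cutoff; Gaussian term ``exp(-(r_ref - r)^2 / sigma_ij^2)``.

``sigma_ij = |i - j| ** 0.15`` in residue-index units for both.

Normalisation: ``unit_identity`` (default) divides by the number of summed
terms so a frame identical to the reference scores exactly 1.0.  ``printed``
divides by ``(N - 1) * (N - 2)`` where N is the contact count (q_nc) or the
residue count (q_similarity); that convention does NOT score 1 at identity
and is provided only for comparison with legacy outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .model_io import Structure, Trajectory

logger = logging.getLogger(__name__)

__all__ = [
    "ContactSet",
    "SimilaritySeries",
    "DensityMap",
    "build_contacts",
    "q_nc",
    "q_similarity",
    "similarity_series",
    "density_map",
]

SIGMA_EXPONENT = 0.15


def _sigma(i: np.ndarray, j: np.ndarray) -> np.ndarray:
    return np.abs(i - j).astype(float) ** SIGMA_EXPONENT


@dataclass(frozen=True)
class ContactSet:
    """Residue pairs in contact in a reference structure, with native distances."""

    pairs: tuple[tuple[int, int], ...]
    native_distances: np.ndarray
    reference_label: str
    cutoff: float
    separation: int

    def __post_init__(self) -> None:
        nd = np.asarray(self.native_distances, dtype=float)
        object.__setattr__(self, "native_distances", nd)
        if len(self.pairs) != nd.size:
            raise ValueError("pairs and native_distances length mismatch")
        if len(set(self.pairs)) != len(self.pairs):
            raise ValueError("duplicate contact pairs")
        for i, j in self.pairs:
            if j - i < self.separation:
                raise ValueError(f"pair ({i},{j}) violates separation {self.separation}")
        if np.any(nd > self.cutoff + 1e-9):
            raise ValueError("native distance exceeds cutoff")

    def __len__(self) -> int:
        return len(self.pairs)

    def to_tsv(self, path: str | Path) -> None:
        lines = ["i\tj\tnative_distance"]
        lines += [f"{i}\t{j}\t{d:.4f}"
                  for (i, j), d in zip(self.pairs, self.native_distances)]
        Path(path).write_text("\n".join(lines) + "\n")


@dataclass(frozen=True)
class SimilaritySeries:
    """Per-frame similarity to the open and closed references."""

    q_open: np.ndarray
    q_closed: np.ndarray
    metric_kind: str  # "Q_NC" | "q_similarity"
    normalization: str

    def __post_init__(self) -> None:
        qo = np.asarray(self.q_open, dtype=float)
        qc = np.asarray(self.q_closed, dtype=float)
        if qo.shape != qc.shape:
            raise ValueError("q_open and q_closed must have equal length")
        if self.normalization == "unit_identity":
            for arr in (qo, qc):
                if np.any(arr < -1e-12) or np.any(arr > 1 + 1e-12):
                    raise ValueError("unit_identity scores must lie in [0, 1]")
        object.__setattr__(self, "q_open", qo)
        object.__setattr__(self, "q_closed", qc)


def _ca_positions(structure: Structure, residues: np.ndarray | None = None
                  ) -> tuple[np.ndarray, np.ndarray]:
    """(residue indices, CA coordinates) for a structure, sorted by residue."""
    ca = structure.ca_by_residue()
    if not ca:
        raise ValueError("structure has no CA atoms")
    if residues is None:
        res = np.array(sorted(ca), dtype=int)
    else:
        missing = [r for r in residues if r not in ca]
        if missing:
            raise ValueError(f"missing CA for residue {missing[0]}")
        res = np.asarray(residues, dtype=int)
    xyz = structure.coords[[ca[r] for r in res]]
    return res, xyz


def build_contacts(reference: Structure, cutoff: float = 8.0, separation: int = 2,
                   reference_label: str = "") -> ContactSet:
    """All CA-CA pairs within ``cutoff`` (inclusive) at sequence separation >= ``separation``."""
    res, xyz = _ca_positions(reference)
    d = np.linalg.norm(xyz[:, None, :] - xyz[None, :, :], axis=-1)
    sep = np.abs(res[:, None] - res[None, :])
    iu, ju = np.triu_indices(len(res))
    mask = (sep[iu, ju] >= separation) & (d[iu, ju] <= cutoff)
    iu, ju = iu[mask], ju[mask]
    if iu.size == 0:
        raise ValueError(f"no contacts found at cutoff {cutoff} A, separation {separation}")
    pairs = tuple((int(res[a]), int(res[b])) for a, b in zip(iu, ju))
    return ContactSet(pairs=pairs, native_distances=d[iu, ju],
                      reference_label=reference_label or reference.label,
                      cutoff=cutoff, separation=separation)


def _gauss_score(r_ref: np.ndarray, r_comp: np.ndarray, sigma: np.ndarray,
                 denom_factor: float, normalization: str, n_for_printed: int) -> float:
    terms = np.exp(-((r_ref - r_comp) ** 2) / (denom_factor * sigma ** 2))
    if normalization == "unit_identity":
        return float(terms.sum() / terms.size)
    if normalization == "printed":
        n = n_for_printed
        if n < 3:
            raise ValueError("printed normalization needs N >= 3")
        return float(terms.sum() / ((n - 1) * (n - 2)))
    raise ValueError(f"unknown normalization {normalization!r}")


def q_nc(frame: Structure, contacts: ContactSet,
         normalization: str = "unit_identity") -> float:
    """Gaussian native-contact score of ``frame`` against a contact set."""
    ca = frame.ca_by_residue()
    i_idx = np.array([p[0] for p in contacts.pairs])
    j_idx = np.array([p[1] for p in contacts.pairs])
    try:
        xi = frame.coords[[ca[int(r)] for r in i_idx]]
        xj = frame.coords[[ca[int(r)] for r in j_idx]]
    except KeyError as exc:
        raise ValueError(f"frame is missing CA for residue {exc.args[0]}") from None
    r_comp = np.linalg.norm(xi - xj, axis=-1)
    return _gauss_score(contacts.native_distances, r_comp, _sigma(i_idx, j_idx),
                        2.0, normalization, len(contacts))


def _allpair_arrays(res: np.ndarray, separation: int) -> tuple[np.ndarray, np.ndarray]:
    iu, ju = np.triu_indices(len(res))
    mask = (res[ju] - res[iu]) >= separation
    return iu[mask], ju[mask]


def q_similarity(frame: Structure, reference: Structure,
                 normalization: str = "unit_identity", separation: int = 2) -> float:
    """All-pair Gaussian similarity (separation >= 2, no distance cutoff)."""
    res_r, xyz_r = _ca_positions(reference)
    res_f, xyz_f = _ca_positions(frame, residues=res_r)
    iu, ju = _allpair_arrays(res_r, separation)
    if iu.size == 0:
        raise ValueError("too few residues for any pair at the requested separation")
    r_ref = np.linalg.norm(xyz_r[iu] - xyz_r[ju], axis=-1)
    r_comp = np.linalg.norm(xyz_f[iu] - xyz_f[ju], axis=-1)
    return _gauss_score(r_ref, r_comp, _sigma(res_r[iu], res_r[ju]),
                        1.0, normalization, len(res_r))


# ---------------------------------------------------------------------------
# trajectory series
# ---------------------------------------------------------------------------

def _pair_distance_series(coords: np.ndarray, atom_idx: np.ndarray,
                          iu: np.ndarray, ju: np.ndarray,
                          chunk: int = 64) -> np.ndarray:
    """Distances between CA pairs (iu, ju) for every frame.

    Uses the Gram-matrix identity d2 = |x|^2 + |y|^2 - 2 x.y per chunk of
    frames, which is much faster than per-pair differencing when the pair
    list is dense.
    """
    out = np.empty((coords.shape[0], iu.size))
    for s in range(0, coords.shape[0], chunk):
        block = np.ascontiguousarray(coords[s:s + chunk, atom_idx])
        sq = (block ** 2).sum(axis=2)
        gram = np.einsum("fni,fmi->fnm", block, block)
        d2 = sq[:, :, None] + sq[:, None, :] - 2.0 * gram
        out[s:s + chunk] = np.sqrt(np.maximum(d2[:, iu, ju], 0.0))
    return out


def _series_against(traj: Trajectory, reference: Structure, metric_kind: str,
                    normalization: str, cutoff: float, separation: int) -> np.ndarray:
    res_r, xyz_r = _ca_positions(reference)
    ca_f = traj.template.ca_by_residue()
    missing = [r for r in res_r if r not in ca_f]
    if missing:
        raise ValueError(f"trajectory is missing CA for residue {missing[0]}")
    atom_idx = np.array([ca_f[int(r)] for r in res_r])

    iu, ju = _allpair_arrays(res_r, separation)
    r_ref = np.linalg.norm(xyz_r[iu] - xyz_r[ju], axis=-1)
    if metric_kind == "Q_NC":
        keep = r_ref <= cutoff
        iu, ju, r_ref = iu[keep], ju[keep], r_ref[keep]
        if iu.size == 0:
            raise ValueError("no native contacts in reference")
        denom_factor, n_printed = 2.0, iu.size
    elif metric_kind == "q_similarity":
        denom_factor, n_printed = 1.0, len(res_r)
    else:
        raise ValueError(f"unknown metric_kind {metric_kind!r}")

    sigma = _sigma(res_r[iu], res_r[ju])
    inv = 1.0 / (denom_factor * sigma ** 2)
    terms = _pair_distance_series(traj.coords, atom_idx, iu, ju)
    terms -= r_ref
    np.multiply(terms, terms, out=terms)
    terms *= -inv
    np.exp(terms, out=terms)
    if normalization == "unit_identity":
        return terms.mean(axis=1)
    if normalization == "printed":
        return terms.sum(axis=1) / ((n_printed - 1) * (n_printed - 2))
    raise ValueError(f"unknown normalization {normalization!r}")


def similarity_series(traj: Trajectory, open_ref: Structure, closed_ref: Structure,
                      metric_kind: str = "q_similarity",
                      normalization: str = "unit_identity",
                      cutoff: float = 8.0, separation: int = 2) -> SimilaritySeries:
    """Per-frame similarity of every trajectory frame to both references."""
    if traj.n_frames == 0:
        raise ValueError("empty trajectory")
    qo = _series_against(traj, open_ref, metric_kind, normalization, cutoff, separation)
    qc = _series_against(traj, closed_ref, metric_kind, normalization, cutoff, separation)
    return SimilaritySeries(q_open=qo, q_closed=qc,
                            metric_kind=metric_kind, normalization=normalization)


# ---------------------------------------------------------------------------
# density maps
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DensityMap:
    counts: np.ndarray
    log10_counts: np.ndarray
    x_edges: np.ndarray
    y_edges: np.ndarray
    n_dropped: int

    def to_tsv(self, path: str | Path) -> None:
        header = "\t".join(f"{c:.6f}" for c in 0.5 * (self.x_edges[:-1] + self.x_edges[1:]))
        rows = ["# log10(1+count) matrix; rows = y bins, columns = x bins",
                "# x_centers\t" + header]
        for row in self.log10_counts.T[::-1]:
            rows.append("\t".join(f"{v:.6f}" for v in row))
        Path(path).write_text("\n".join(rows) + "\n")


def density_map(series_x: np.ndarray, series_y: np.ndarray, bins: int = 100,
                value_range: tuple[float, float] = (0.4, 1.0)) -> DensityMap:
    """2-D histogram over ``value_range`` squared with log10(1+count) cells."""
    x = np.asarray(series_x, dtype=float)
    y = np.asarray(series_y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("series length mismatch")
    lo, hi = value_range
    keep = (x >= lo) & (x <= hi) & (y >= lo) & (y <= hi)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("density_map dropped %d of %d points outside %s", dropped, x.size, value_range)
    counts, xe, ye = np.histogram2d(x[keep], y[keep], bins=bins, range=[[lo, hi], [lo, hi]])
    return DensityMap(counts=counts, log10_counts=np.log10(1.0 + counts),
                      x_edges=xe, y_edges=ye, n_dropped=dropped)
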