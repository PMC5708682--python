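"""Element tables shared across modules.

Masses are standard atomic weights (IUPAC 2021, rounded); van der Waals
radii follow the common Bondi-style set used for accessible-surface work.
Both tables are deliberately small: structures handled here are proteins
plus the occasional pseudo-atom, and an unknown element is an error the
caller must see rather than a silent default.
"""

from __future__ import annotations

ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "P": 30.974,
    "SE": 78.971,
    "FE": 55.845,
    "ZN": 65.38,
    "MG": 24.305,
    "CA": 40.078,
    "NA": 22.990,
    "K": 39.098,
    "CL": 35.45,
}

#: Van der Waals radii in Angstrom used by the accessible-surface routine.
VDW_RADII: dict[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "H": 1.20,
    "SE": 1.90,
}

#: Default probe radius (water) in Angstrom.
PROBE_RADIUS: float = 1.4

#: Residue names treated as solvent and always discarded on read.
WATER_NAMES: frozenset[str] = frozenset({"HOH", "WAT", "DOD", "H2O", "TIP3"})


def atomic_mass(element: str) -> float:
    """Return the standard atomic mass for ``element`` (case-insensitive)."""
    try:
        return ATOMIC_MASSES[element.upper()]
    except KeyError:
        raise KeyError(f"no atomic mass tabulated for element {element!r}") from None


def vdw_radius(element: str) -> float:
    """Return the van der Waals radius for ``element`` (case-insensitive)."""
    try:
        return VDW_RADII[element.upper()]
    except KeyError:
        raise KeyError(f"unknown element {element!r}: no van der Waals radius tabulated") from None
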