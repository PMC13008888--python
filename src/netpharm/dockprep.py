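"""Docking search-box geometry.

The two computable pieces of a docking setup that do not require the docking
engine itself: the ligand radius of gyration and the cubic search-box sizing
rule (a fixed 22.5 Å floor, or 2.9 times the radius of gyration when the
ligand is large enough that the floor would clip it).

Coordinates are read from simple whitespace/tab XYZ-style tables; no PDB or
PDBQT parsing happens here — receptor preparation and the docking run itself
are out of scope. For reference, the docking protocol these boxes feed uses
exhaustiveness 16 and an energy range of 4 kcal/mol.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

BOX_FLOOR_ANGSTROM = 22.5
BOX_RG_MULTIPLIER = 2.9


@dataclass(frozen=True)
class LigandCoordinates:
    """Atom positions in Å, with optional per-atom masses.

    ``masses`` enables the mass-weighted radius of gyration; when omitted the
    geometric (unweighted) form is used.
    """

    positions: np.ndarray  # (n_atoms, 3)
    masses: np.ndarray | None = None

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 3 or pos.shape[0] < 1:
            raise ValueError("positions must be a non-empty (n, 3) array")
        if not np.all(np.isfinite(pos)):
            raise ValueError("coordinates must be finite")
        object.__setattr__(self, "positions", pos)
        if self.masses is not None:
            m = np.asarray(self.masses, dtype=float)
            if m.shape != (pos.shape[0],):
                raise ValueError("masses must match the number of atoms")
            if not np.all(np.isfinite(m)) or np.any(m <= 0):
                raise ValueError("masses must be finite and positive")
            object.__setattr__(self, "masses", m)

    @classmethod
    def from_xyz_table(cls, path: str | Path) -> "LigandCoordinates":
        """Read an XYZ-style table: columns x, y, z and optionally mass.

        Lines starting with '#' are comments; an optional leading element
        symbol column is tolerated and ignored.
        """
        rows = []
        masses = []
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if fields and not _is_number(fields[0]):
                fields = fields[1:]
            vals = [float(f) for f in fields]
            if len(vals) < 3:
                raise ValueError(f"expected at least x y z columns, got: {line!r}")
            rows.append(vals[:3])
            if len(vals) >= 4:
                masses.append(vals[3])
        if masses and len(masses) != len(rows):
            raise ValueError("mass column present on some lines but not all")
        return cls(np.array(rows), np.array(masses) if masses else None)


def _is_number(token: str) -> bool:
    try:
        float(token)
    except ValueError:
        return False
    return True


def radius_of_gyration(coords: LigandCoordinates, mass_weighted: bool = False) -> float:
    """Radius of gyration in Å: sqrt(mean squared distance to the centroid).

    With ``mass_weighted=True`` (requires ``coords.masses``) both the centroid
    and the average are mass-weighted. A single atom has Rg = 0.
    """
    pos = coords.positions
    if mass_weighted:
        if coords.masses is None:
            raise ValueError("mass-weighted Rg requested but no masses supplied")
        w = coords.masses / coords.masses.sum()
    else:
        w = np.full(pos.shape[0], 1.0 / pos.shape[0])
    centroid = w @ pos
    sq = ((pos - centroid) ** 2).sum(axis=1)
    return float(np.sqrt(w @ sq))


def box_length(rg: float) -> float:
    """Cubic search-box edge in Å: max(22.5, 2.9 × Rg).

    The floor keeps small ligands in a box large enough for pose sampling;
    the 2.9×Rg branch takes over for extended ligands.
    """
    if not np.isfinite(rg) or rg < 0:
        raise ValueError(f"radius of gyration must be finite and >= 0, got {rg}")
    return max(BOX_FLOOR_ANGSTROM, BOX_RG_MULTIPLIER * rg)
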