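"""Dihedral angles and periodic minimum-image distances.

All coordinates are Cartesian, in Angstrom, inside an orthorhombic periodic
box.  Dihedrals follow the IUPAC right-handed sign convention and are
reported on [0, 360) (a negative IUPAC angle maps up by 360), which is the
domain the torsion-binning rule in :mod:`diolconf.conformation_space`
expects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .conformation_space import TorsionQuad

__all__ = [
    "SITE_NAMES",
    "DegenerateGeometryError",
    "SiteCoords",
    "minimum_image",
    "minimum_image_distance",
    "dihedral",
    "torsion_quad",
    "intra_OO",
    "pair_distances_OO",
]

#: The seven named sites of a 1,3-diol, in bonded-chain order.
SITE_NAMES = ("H1", "O1", "C1", "C2", "C3", "O2", "H2")

# Cross-product norms below this (Angstrom^2) mean a collinear bond triple:
# the dihedral is undefined.  Far below any thermal geometry noise.
_COLLINEAR_TOL = 1e-10


class DegenerateGeometryError(ValueError):
    """Raised when a dihedral is undefined (collinear bond triple)."""


def minimum_image(vec: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    """Wrap displacement vector(s) to the nearest periodic image.

    ``box`` is the three orthorhombic edge lengths, or None for a
    non-periodic system (vectors returned unchanged).
    """
    vec = np.asarray(vec, dtype=float)
    if box is None:
        return vec
    box = np.asarray(box, dtype=float)
    return vec - box * np.round(vec / box)


def minimum_image_distance(a: np.ndarray, b: np.ndarray, box: np.ndarray | None) -> float:
    """Minimum-image distance between two points."""
    d = minimum_image(np.asarray(b, float) - np.asarray(a, float), box)
    return float(np.linalg.norm(d))


def dihedral(p1, p2, p3, p4) -> float:
    """Right-handed dihedral of four points, in degrees on [0, 360).

    Computed with the atan2 formulation: for bond vectors b1 = p2-p1,
    b2 = p3-p2, b3 = p4-p3,

        phi = atan2((b1 x b2) x (b2 x b3) . b2/|b2|, (b1 x b2).(b2 x b3))

    which is numerically stable for near-planar geometries.  A positive
    IUPAC angle (clockwise far bond viewed from atom 1) lands in (0, 180);
    negative angles are shifted up by 360.  Coordinate inversion maps
    phi -> 360 - phi.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < _COLLINEAR_TOL or np.linalg.norm(n2) < _COLLINEAR_TOL:
        raise DegenerateGeometryError("collinear bond triple; dihedral undefined")
    b2n = np.linalg.norm(b2)
    if b2n == 0.0:
        raise DegenerateGeometryError("coincident central atoms")
    y = np.dot(np.cross(n1, n2), b2 / b2n)
    x = np.dot(n1, n2)
    phi = np.degrees(np.arctan2(y, x))
    return float(phi % 360.0)


@dataclass
class SiteCoords:
    """Positions of the seven named sites of one molecule in one frame.

    ``positions`` is a (7, 3) array in :data:`SITE_NAMES` order.  On
    construction the chain is unwrapped: each site is moved to the periodic
    image nearest its bonded predecessor, so downstream geometry never sees
    a molecule split across the box boundary.  Consecutive bonded sites
    farther apart than ``bond_sanity`` Angstrom (after unwrapping) indicate
    a mis-assigned topology and are rejected.
    """

    positions: np.ndarray
    box: np.ndarray | None = None
    bond_sanity: float = 2.0
    _unwrapped: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.shape != (7, 3):
            raise ValueError(f"expected (7, 3) site coordinates, got {pos.shape}")
        if not np.all(np.isfinite(pos)):
            raise ValueError("non-finite site coordinates")
        box = None if self.box is None else np.asarray(self.box, dtype=float)
        unwrapped = pos.copy()
        for i in range(1, 7):
            step = minimum_image(pos[i] - unwrapped[i - 1], box)
            unwrapped[i] = unwrapped[i - 1] + step
            bond = float(np.linalg.norm(step))
            if bond > self.bond_sanity:
                raise ValueError(
                    f"bond {SITE_NAMES[i - 1]}-{SITE_NAMES[i]} is {bond:.2f} A "
                    f"(> {self.bond_sanity} A sanity bound); check the topology"
                )
        self._unwrapped = unwrapped

    def site(self, name: str) -> np.ndarray:
        return self._unwrapped[SITE_NAMES.index(name)]


def torsion_quad(mol: SiteCoords, box=None) -> TorsionQuad:
    """The four named diol torsions of one molecule.

    Order: H1-O1-C1-C2, O1-C1-C2-C3, C1-C2-C3-O2, C2-C3-O2-H2.  ``box`` is
    accepted for interface symmetry; the molecule is already unwrapped by
    :class:`SiteCoords`, so the value is not used again.
    """
    p = mol._unwrapped
    return TorsionQuad(
        dihedral(p[0], p[1], p[2], p[3]),
        dihedral(p[1], p[2], p[3], p[4]),
        dihedral(p[2], p[3], p[4], p[5]),
        dihedral(p[3], p[4], p[5], p[6]),
    )


def intra_OO(mol: SiteCoords, box=None) -> float:
    """Minimum-image intramolecular O1...O2 distance in Angstrom."""
    box = mol.box if box is None else box
    return minimum_image_distance(mol.site("O1"), mol.site("O2"), box)


def pair_distances_OO(frame, topology) -> np.ndarray:
    """All hydroxyl-oxygen pair distances in one frame, under minimum image.

    For N molecules there are 2N oxygens and C(2N, 2) pairs; both the
    intra- and intermolecular pairs are included.  Returns a flat array of
    distances in Angstrom (unordered).
    """
    oxy = []
    for mol in topology.molecules:
        oxy.append(frame.position(mol["O1"]))
        oxy.append(frame.position(mol["O2"]))
    pos = np.asarray(oxy, dtype=float)
    i, j = np.triu_indices(len(pos), k=1)
    d = minimum_image(pos[j] - pos[i], frame.box)
    return np.linalg.norm(d, axis=1)
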