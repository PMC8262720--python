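"""Covalent-bond perception from CONECT records and covalent radii.

Produces the atom adjacency the feature rules need: hydrophobic carbons
(all heavy neighbours carbon), halogen donors (C-X), donor hydrogen
attachment, and the graph used for ligand ring/functional-group perception.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

__all__ = ["COVALENT_RADII", "perceive_bonds", "heavy_neighbors"]

# single-bond covalent radii in Å (Cordero et al. consensus values, rounded)
COVALENT_RADII = {
    "H": 0.31, "B": 0.84, "C": 0.76, "N": 0.71, "O": 0.66, "F": 0.57,
    "P": 1.07, "S": 1.05, "CL": 1.02, "BR": 1.20, "I": 1.39, "SE": 1.20,
    "SI": 1.11, "NA": 1.66, "K": 2.03, "MG": 1.41, "CA": 1.76, "MN": 1.39,
    "FE": 1.32, "CO": 1.26, "NI": 1.24, "CU": 1.32, "ZN": 1.22, "CD": 1.44,
    "LI": 1.28, "AL": 1.21, "AS": 1.19,
}
_DEFAULT_RADIUS = 1.5
#: slack added to the radii sum when deciding whether two atoms are bonded
_BOND_TOLERANCE = 0.45
_MIN_BOND = 0.4


def _radius(element: str) -> float:
    return COVALENT_RADII.get(element.upper(), _DEFAULT_RADIUS)


def perceive_bonds(atoms, conect=None, use_distances=True):
    """Adjacency mapping ``Atom -> set of bonded Atoms``.

    CONECT record pairs (by serial) are always honoured; when
    ``use_distances`` is true, pairs whose separation is below the sum of
    covalent radii plus tolerance are added. Metals are never given
    distance-based covalent bonds (their contacts are coordination, handled
    by the metal-complex detector).
    """
    atoms = list(atoms)
    adjacency = {a: set() for a in atoms}
    by_serial = {a.serial: a for a in atoms}

    if conect:
        for serial, partners in conect.items():
            a = by_serial.get(serial)
            if a is None:
                continue
            for p in partners:
                b = by_serial.get(p)
                if b is not None and b is not a:
                    adjacency[a].add(b)
                    adjacency[b].add(a)

    if use_distances and len(atoms) > 1:
        from .structure import METAL_SYMBOLS
        coords = np.array([a.coords for a in atoms])
        tree = cKDTree(coords)
        max_r = 2 * max(COVALENT_RADII.values()) + _BOND_TOLERANCE
        for i, j in tree.query_pairs(r=max_r):
            a, b = atoms[i], atoms[j]
            if a.element in METAL_SYMBOLS or b.element in METAL_SYMBOLS:
                continue
            cutoff = _radius(a.element) + _radius(b.element) + _BOND_TOLERANCE
            d = np.linalg.norm(coords[i] - coords[j])
            if _MIN_BOND <= d <= cutoff:
                adjacency[a].add(b)
                adjacency[b].add(a)
    return adjacency


def heavy_neighbors(atom, adjacency):
    return [n for n in adjacency.get(atom, ()) if n.is_heavy]
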