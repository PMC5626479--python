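"""Small internal-coordinate geometry kernel.

Everything downstream (ideal-helix generation, rotamer construction,
dihedral self-checks) is built on three primitives: bond angles, torsion
angles, and NeRF-style placement of a new atom from three reference atoms
plus (bond, angle, torsion) internal coordinates.
"""

from __future__ import annotations

import numpy as np

__all__ = ["bond_angle", "dihedral", "place_atom"]


def bond_angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a-b-c in degrees."""
    v1 = np.asarray(a, float) - b
    v2 = np.asarray(c, float) - b
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed torsion p0-p1-p2-p3 in degrees, IUPAC sign convention."""
    p0, p1, p2, p3 = (np.asarray(p, float) for p in (p0, p1, p2, p3))
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return float(np.degrees(np.arctan2(y, x)))


def place_atom(
    a3: np.ndarray,
    a2: np.ndarray,
    a1: np.ndarray,
    bond: float,
    angle_deg: float,
    torsion_deg: float,
) -> np.ndarray:
    """Place atom X from internal coordinates relative to a chain a3-a2-a1.

    Returns X such that |X - a1| = bond, angle(X, a1, a2) = angle_deg and
    torsion(X, a1, a2, a3) = torsion_deg (equivalently torsion(a3, a2, a1, X);
    a torsion is invariant under reversal of the atom order).
    """
    a1, a2, a3 = np.asarray(a1, float), np.asarray(a2, float), np.asarray(a3, float)
    theta = np.radians(angle_deg)
    phi = np.radians(torsion_deg)
    # local displacement in the a3-a2-a1 frame
    d = np.array(
        [
            -bond * np.cos(theta),
            bond * np.sin(theta) * np.cos(phi),
            bond * np.sin(theta) * np.sin(phi),
        ]
    )
    bc = a1 - a2
    bc /= np.linalg.norm(bc)
    ab = a2 - a3
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    rot = np.column_stack([bc, m, n])
    return a1 + rot @ d
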