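"""Low-level 3D geometry: dihedral measurement, internal-coordinate atom
placement (NeRF), and rigid transforms.

Conventions: coordinates in Å, angles in degrees. Dihedrals follow the
IUPAC sign convention: for atoms a-b-c-d the torsion is the angle between
the (a,b,c) and (b,c,d) planes, positive for a clockwise rotation of d
relative to a when viewed from b toward c, reported on (-180, 180].
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "measure_dihedral",
    "measure_angle",
    "place_atom",
    "rotation_about_axis",
    "random_rotation",
]


def measure_dihedral(p0, p1, p2, p3) -> float:
    """Torsion angle a-b-c-d in degrees on (-180, 180]."""
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b1 = p1 - p0
    b2 = p2 - p1
    b3 = p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = np.linalg.norm(b2)
    if b2n == 0 or np.linalg.norm(n1) == 0 or np.linalg.norm(n2) == 0:
        raise ValueError("collinear atoms: dihedral undefined")
    ang = np.degrees(np.arctan2(np.dot(np.cross(n1, n2), b2 / b2n), np.dot(n1, n2)))
    # map -180 -> +180 so the range is (-180, 180]
    if ang <= -180.0:
        ang += 360.0
    return float(ang)


def measure_angle(p0, p1, p2) -> float:
    """Bond angle a-b-c in degrees on [0, 180]."""
    p0, p1, p2 = (np.asarray(p, dtype=float) for p in (p0, p1, p2))
    u = p0 - p1
    v = p2 - p1
    c = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def place_atom(a, b, c, bond_length: float, bond_angle_deg: float,
               torsion_deg: float) -> np.ndarray:
    """Position atom d so that |cd| = bond_length, angle(b,c,d) =
    bond_angle_deg and dihedral(a,b,c,d) = torsion_deg (NeRF placement)."""
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    theta = np.radians(bond_angle_deg)
    chi = np.radians(torsion_deg)
    # local displacement in the (bc, m, n) frame
    d2 = bond_length * np.array(
        [-np.cos(theta), np.sin(theta) * np.cos(chi), np.sin(theta) * np.sin(chi)]
    )
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-12:
        raise ValueError("collinear reference atoms: frame undefined")
    n /= nn
    m = np.cross(n, bc)
    frame = np.column_stack([bc, m, n])
    return c + frame @ d2


def rotation_about_axis(axis, angle_deg: float) -> np.ndarray:
    """Rotation matrix for a right-handed rotation about ``axis``."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    t = np.radians(angle_deg)
    x, y, z = axis
    c, s = np.cos(t), np.sin(t)
    C = 1.0 - c
    return np.array(
        [
            [c + x * x * C, x * y * C - z * s, x * z * C + y * s],
            [y * x * C + z * s, c + y * y * C, y * z * C - x * s],
            [z * x * C - y * s, z * y * C + x * s, c + z * z * C],
        ]
    )


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian matrix)."""
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
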