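"""Small internal-coordinate geometry kernel: dihedrals and NeRF placement."""

from __future__ import annotations

import numpy as np

__all__ = ["dihedral", "nerf_place", "wrap_angle"]


def wrap_angle(deg: float) -> float:
    """Wrap to the half-open interval [-180, 180); +180 maps to -180."""
    return float(((deg + 180.0) % 360.0) - 180.0)


def dihedral(p1, p2, p3, p4) -> float:
    """Torsion angle p1-p2-p3-p4 in degrees, IUPAC sign convention.

    Positive means clockwise rotation of p4 relative to p1 when looking from
    p2 toward p3.  Returns a value in [-180, 180).  Raises on degenerate
    geometry (coincident consecutive points or three collinear points).
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    for b in (b1, b2, b3):
        if np.linalg.norm(b) < 1e-9:
            raise ValueError("dihedral: coincident consecutive points")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-9 or np.linalg.norm(n2) < 1e-9:
        raise ValueError("dihedral: three collinear points")
    b2n = b2 / np.linalg.norm(b2)
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2n))
    return wrap_angle(np.degrees(np.arctan2(y, x)))


def nerf_place(a, b, c, bond: float, angle: float, torsion: float) -> np.ndarray:
    """Place atom D from three reference atoms by internal coordinates.

    Natural extension reference frame: |CD| = bond, angle(B,C,D) = ``angle``
    degrees, dihedral(A,B,C,D) = ``torsion`` degrees.
    """
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    theta = np.radians(angle)
    phi = np.radians(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-9:
        raise ValueError("nerf_place: reference atoms are collinear")
    n /= nn
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * np.cos(theta),
            bond * np.sin(theta) * np.cos(phi),
            bond * np.sin(theta) * np.sin(phi),
        ]
    )
    rot = np.column_stack([bc, m, n])
    return c + rot @ d_local
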