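"""Small vector-geometry utilities shared by feature perception and detectors.

All angles are unsigned degrees; ring-plane angles are folded into [0, 90].
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "distance", "centroid", "angle_deg", "vector_angle_deg",
    "fit_plane", "plane_angle_deg", "ring_offset",
]


def distance(a, b) -> float:
    return float(np.linalg.norm(np.asarray(a, float) - np.asarray(b, float)))


def centroid(points) -> np.ndarray:
    """Unweighted mean of coordinates."""
    return np.mean(np.asarray(points, float), axis=0)


def vector_angle_deg(u, v) -> float:
    """Unsigned angle between two vectors in degrees, in [0, 180]."""
    u = np.asarray(u, float)
    v = np.asarray(v, float)
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0 or nv == 0:
        return 0.0
    cosang = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def angle_deg(a, b, c) -> float:
    """Angle at vertex b of the triangle a-b-c, degrees."""
    a, b, c = (np.asarray(p, float) for p in (a, b, c))
    return vector_angle_deg(a - b, c - b)


def fit_plane(points):
    """Best-fit plane through points.

    Returns ``(center, unit_normal, rmsd)`` where rmsd is the RMS
    out-of-plane deviation in Å. The normal's sign is arbitrary; consumers
    must use unsigned angles.
    """
    pts = np.asarray(points, float)
    center = pts.mean(axis=0)
    _, s, vt = np.linalg.svd(pts - center)
    normal = vt[-1]
    rmsd = float(s[-1] / np.sqrt(len(pts)))
    return center, normal / np.linalg.norm(normal), rmsd


def plane_angle_deg(n1, n2) -> float:
    """Angle between two planes via their normals, folded into [0, 90]."""
    ang = vector_angle_deg(n1, n2)
    return min(ang, 180.0 - ang)


def ring_offset(center1, normal1, center2) -> float:
    """Lateral offset: distance from center1 to center2's projection onto
    the plane through center1 with normal normal1."""
    d = np.asarray(center2, float) - np.asarray(center1, float)
    n = np.asarray(normal1, float)
    n = n / np.linalg.norm(n)
    proj = d - np.dot(d, n) * n
    return float(np.linalg.norm(proj))
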