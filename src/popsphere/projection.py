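"""Equal Earth projection of the spherical embedding, with optional rotation.

The encoder places samples on the unit sphere in 3D; for 2-D visualization
the sphere is mapped to the plane with the Equal Earth pseudocylindrical
projection, which preserves relative areas (shape distortion grows toward the
poles). The sphere carries no preferred orientation, so it may be rotated
arbitrarily before projecting; rotation changes the 2-D picture but never the
3-D geometry the quality metrics are computed on.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation

# Equal Earth polynomial coefficients (published closed form)
_A1 = 1.340264
_A2 = -0.081106
_A3 = 0.000893
_A4 = 0.003796
_SQRT3 = np.sqrt(3.0)


def to_lonlat(xyz: np.ndarray) -> np.ndarray:
    """Unit vectors (..., 3) -> (longitude, latitude) in radians.

    Latitude is arcsin of the third component; longitude is atan2 of the
    second over the first. Raises on vectors that are not unit length.
    """
    xyz = np.asarray(xyz, dtype=float)
    norms = np.linalg.norm(xyz, axis=-1)
    if np.any(norms < 1e-9):
        raise ValueError("zero vector has no spherical coordinates")
    if np.any(np.abs(norms - 1.0) > 1e-6):
        raise ValueError("input vectors must lie on the unit sphere")
    lon = np.arctan2(xyz[..., 1], xyz[..., 0])
    lat = np.arcsin(np.clip(xyz[..., 2], -1.0, 1.0))
    return np.stack([lon, lat], axis=-1)


def lonlat_to_xyz(lonlat: np.ndarray) -> np.ndarray:
    lonlat = np.asarray(lonlat, dtype=float)
    lon, lat = lonlat[..., 0], lonlat[..., 1]
    return np.stack([np.cos(lat) * np.cos(lon),
                     np.cos(lat) * np.sin(lon),
                     np.sin(lat)], axis=-1)


def rotation_from_euler(angles_deg) -> np.ndarray:
    """Proper rotation matrix from intrinsic z-y-x Euler angles in degrees."""
    return Rotation.from_euler("zyx", np.asarray(angles_deg, dtype=float),
                               degrees=True).as_matrix()


def rotate_sphere(xyz: np.ndarray, rotation: np.ndarray) -> np.ndarray:
    """Apply a validated proper rotation to (..., 3) coordinates."""
    rotation = np.asarray(rotation, dtype=float)
    if rotation.shape != (3, 3):
        raise ValueError("rotation must be a 3x3 matrix")
    if not np.allclose(rotation @ rotation.T, np.eye(3), atol=1e-8):
        raise ValueError("rotation matrix is not orthogonal")
    if not np.isclose(np.linalg.det(rotation), 1.0, atol=1e-8):
        raise ValueError("rotation matrix must have determinant +1")
    return np.asarray(xyz, dtype=float) @ rotation.T


def equal_earth(lonlat: np.ndarray) -> np.ndarray:
    """Equal Earth forward projection of (..., 2) (lon, lat) radians.

    theta = arcsin((sqrt(3)/2) sin(lat));
    y = A1 t + A2 t^3 + A3 t^7 + A4 t^9;
    x = (2 sqrt(3) / 3) lon cos(t) / (A1 + 3 A2 t^2 + 7 A3 t^6 + 9 A4 t^8).
    """
    lonlat = np.asarray(lonlat, dtype=float)
    lon, lat = lonlat[..., 0], lonlat[..., 1]
    theta = np.arcsin(np.clip(_SQRT3 / 2.0 * np.sin(lat), -1.0, 1.0))
    t2 = theta * theta
    t6 = t2 * t2 * t2
    y = theta * (_A1 + _A2 * t2 + _A3 * t6 + _A4 * t6 * t2)
    dy_dtheta = _A1 + 3.0 * _A2 * t2 + 7.0 * _A3 * t6 + 9.0 * _A4 * t6 * t2
    x = (2.0 * _SQRT3 / 3.0) * lon * np.cos(theta) / dy_dtheta
    return np.stack([x, y], axis=-1)


def project_points(xyz: np.ndarray,
                   rotation: np.ndarray | None = None) -> np.ndarray:
    """Rotate (optional), convert to lon/lat, and apply Equal Earth."""
    if rotation is not None:
        xyz = rotate_sphere(xyz, rotation)
    return equal_earth(to_lonlat(xyz))


def projection_boundary(n_points: int = 361) -> np.ndarray:
    """Closed outline of the projected sphere (the lon = +/-pi meridians),
    for drawing the envelope around all samples in 2-D plots."""
    lat = np.linspace(-np.pi / 2.0, np.pi / 2.0, n_points)
    east = equal_earth(np.stack([np.full_like(lat, np.pi), lat], axis=-1))
    west = equal_earth(np.stack([np.full_like(lat, -np.pi), lat[::-1]],
                                axis=-1))
    return np.vstack([east, west, east[:1]])


def project_embedding(coords3: np.ndarray,
                      rotation: np.ndarray | None = None) -> np.ndarray:
    """2-D Equal Earth coordinates for an (n, 3) spherical embedding."""
    coords3 = np.asarray(coords3, dtype=float)
    if coords3.ndim != 2 or coords3.shape[1] != 3:
        raise ValueError("expected an (n, 3) embedding")
    if len(coords3) == 0:
        return np.empty((0, 2))
    return project_points(coords3, rotation)
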