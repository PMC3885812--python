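"""View-vector sensing: which gaze sectors of a 120-degree fan hit the doorway.

The agent's state is a binary vector phi of length 50.  A fan of 50 rays is
spread symmetrically about the gaze direction; each ray is extended to the
door line y = y_door and phi_i = 1 iff its intersection falls inside the
opening [-d_pos, d_pos].  Rays that do not point toward the door line
(forward component <= 0) cannot hit the opening and score 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .environment import TrackGeometry

__all__ = ["Orientation", "RayFan", "build_ray_fan", "view_vector", "view_vectors_batch"]

N_SECTORS = 50
FOV_DEG = 120.0


def sector_angles_deg(n_sectors: int = N_SECTORS, fov: float = FOV_DEG) -> np.ndarray:
    """Centers of ``n_sectors`` equal sectors tiling [-fov/2, +fov/2] (degrees)."""
    width = fov / n_sectors
    return -fov / 2.0 + width * (np.arange(n_sectors) + 0.5)


@dataclass(frozen=True)
class Orientation:
    """Unit gaze direction (v_x, v_y)."""

    v_x: float
    v_y: float

    def __post_init__(self) -> None:
        n = np.hypot(self.v_x, self.v_y)
        if n == 0.0:
            raise ValueError("orientation vector must be nonzero")
        object.__setattr__(self, "v_x", self.v_x / n)
        object.__setattr__(self, "v_y", self.v_y / n)

    @property
    def vector(self) -> np.ndarray:
        return np.array([self.v_x, self.v_y])

    @classmethod
    def toward(cls, position: np.ndarray, target: np.ndarray) -> "Orientation":
        d = np.asarray(target, dtype=float) - np.asarray(position, dtype=float)
        return cls(d[0], d[1])


def _rotate_fan(orientation_xy: np.ndarray, angles_deg: np.ndarray) -> np.ndarray:
    """Apply the orientation matrix [[cos, sin], [-sin, cos]] to the gaze vector.

    Positive sector angles rotate the gaze clockwise (toward +x when facing +y).
    Returns an (n, 2) array of unit sector vectors.
    """
    th = np.deg2rad(angles_deg)
    vx, vy = orientation_xy
    rx = np.cos(th) * vx + np.sin(th) * vy
    ry = -np.sin(th) * vx + np.cos(th) * vy
    return np.stack([rx, ry], axis=1)


@dataclass(frozen=True)
class RayFan:
    """Sector geometry for one pose: angles, unit vectors, slopes, door hits."""

    position: np.ndarray
    angles_deg: np.ndarray
    vectors: np.ndarray            # (n, 2) unit sector vectors
    slopes: np.ndarray             # dy/dx per sector (inf for vertical rays)
    door_intersections: np.ndarray  # x at y = y_door (nan for non-forward rays)


def build_ray_fan(
    position: np.ndarray,
    orientation: Orientation,
    geometry: TrackGeometry,
    n_sectors: int = N_SECTORS,
    fov: float = FOV_DEG,
) -> RayFan:
    if not (0.0 < fov < 180.0):
        raise ValueError("fov must lie in (0, 180) degrees")
    if n_sectors < 2:
        raise ValueError("need at least 2 sectors")
    angles = sector_angles_deg(n_sectors, fov)
    vecs = _rotate_fan(orientation.vector, angles)
    with np.errstate(divide="ignore", invalid="ignore"):
        slopes = vecs[:, 1] / vecs[:, 0]
    pos = np.asarray(position, dtype=float)
    dy = geometry.y_door - pos[1]
    x_door = np.full(n_sectors, np.nan)
    fwd = vecs[:, 1] > 0.0
    x_door[fwd] = pos[0] + dy * vecs[fwd, 0] / vecs[fwd, 1]
    return RayFan(pos, angles, vecs, slopes, x_door)


def view_vector(ray_fan: RayFan, geometry: TrackGeometry) -> np.ndarray:
    """Binary phi: 1 where the ray meets the door line inside the opening."""
    if ray_fan.position[1] >= geometry.y_door:
        raise ValueError("agent must be before the door line")
    x = ray_fan.door_intersections
    with np.errstate(invalid="ignore"):
        phi = (x >= -geometry.d_pos) & (x <= geometry.d_pos)
    return phi.astype(float)


def view_vectors_batch(
    positions: np.ndarray,
    orientations: np.ndarray,
    geometry: TrackGeometry,
    n_sectors: int = N_SECTORS,
    fov: float = FOV_DEG,
) -> np.ndarray:
    """phi for a batch of poses: positions (B, 2), unit orientations (B, 2) -> (B, n).

    Vectorized equivalent of build_ray_fan + view_vector, used by the
    lock-step episode runner.  Poses at or beyond the door line return all
    zeros (their passes are already terminal).
    """
    th = np.deg2rad(sector_angles_deg(n_sectors, fov))
    cos_t, sin_t = np.cos(th), np.sin(th)
    vx = orientations[:, 0:1]
    vy = orientations[:, 1:2]
    rx = cos_t * vx + sin_t * vy          # (B, n)
    ry = -sin_t * vx + cos_t * vy
    dy = geometry.y_door - positions[:, 1:2]
    ok = (ry > 0.0) & (dy > 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        x_door = positions[:, 0:1] + dy * rx / ry
    phi = ok & (np.abs(x_door) <= geometry.d_pos)
    return phi.astype(float)
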