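"""Pinhole camera model with radial–tangential distortion.

The pose maps camera coordinates to scene (screen) coordinates.  The camera
frame follows the usual computer-vision convention: +z along the optical
axis into the scene, +x right and +y down in the image.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import Ray, RigidTransform, as_vec3, normalize


@dataclass
class CameraModel:
    pose: RigidTransform  # camera-to-scene
    focal: float  # px (square pixels)
    principal_point: tuple[float, float]  # px
    resolution: tuple[int, int] = (1420, 1420)  # (width, height) px
    distortion: np.ndarray = field(default_factory=lambda: np.zeros(5))  # k1 k2 p1 p2 k3

    def __post_init__(self):
        if self.focal <= 0:
            raise ValueError("focal length must be positive")
        if min(self.resolution) <= 0:
            raise ValueError("resolution must be positive")
        self.distortion = np.asarray(self.distortion, dtype=float).reshape(5)

    # -- intrinsics ---------------------------------------------------------
    @property
    def K(self) -> np.ndarray:
        cx, cy = self.principal_point
        return np.array([[self.focal, 0, cx], [0, self.focal, cy], [0, 0, 1.0]])

    @property
    def origin(self) -> np.ndarray:
        """Camera centre in scene coordinates (mm)."""
        return self.pose.translation

    def _distort(self, xn: float, yn: float) -> tuple[float, float]:
        if not self.distortion.any():
            return xn, yn
        k1, k2, p1, p2, k3 = self.distortion
        r2 = xn * xn + yn * yn
        radial = 1 + k1 * r2 + k2 * r2 * r2 + k3 * r2 * r2 * r2
        xd = xn * radial + 2 * p1 * xn * yn + p2 * (r2 + 2 * xn * xn)
        yd = yn * radial + p1 * (r2 + 2 * yn * yn) + 2 * p2 * xn * yn
        return xd, yd

    def _undistort(self, xd: float, yd: float) -> tuple[float, float]:
        if not self.distortion.any():
            return xd, yd
        # fixed-point iteration
        xn, yn = xd, yd
        for _ in range(20):
            xe, ye = self._distort(xn, yn)
            xn += xd - xe
            yn += yd - ye
        return xn, yn

    # -- projection ---------------------------------------------------------
    def project(self, p_scene) -> np.ndarray:
        """Project a scene point to pixel coordinates ``(u, v)``.

        Returns NaNs when the point is behind the camera or lands outside
        the sensor.
        """
        pc = self.pose.inverse().apply(as_vec3(p_scene))
        if pc[2] <= 0:
            return np.array([np.nan, np.nan])
        xn, yn = pc[0] / pc[2], pc[1] / pc[2]
        xd, yd = self._distort(xn, yn)
        u = self.focal * xd + self.principal_point[0]
        v = self.focal * yd + self.principal_point[1]
        w, h = self.resolution
        if not (0 <= u <= w and 0 <= v <= h):
            return np.array([np.nan, np.nan])
        return np.array([u, v])

    def back_project(self, pixel) -> Ray:
        """Ray in scene coordinates through the given pixel."""
        u, v = float(pixel[0]), float(pixel[1])
        xd = (u - self.principal_point[0]) / self.focal
        yd = (v - self.principal_point[1]) / self.focal
        xn, yn = self._undistort(xd, yd)
        d_cam = normalize([xn, yn, 1.0])
        return Ray(self.origin, self.pose.apply_direction(d_cam))


def look_at_pose(position, target, up=(0.0, -1.0, 0.0)) -> RigidTransform:
    """Camera-to-scene pose for a camera at ``position`` looking at ``target``.

    ``up`` is the scene direction that should map to image-up (-y in camera
    coordinates).  The default keeps the image upright in the screen frame,
    where +y points down.
    """
    position = as_vec3(position)
    z = normalize(as_vec3(target) - position)
    up = as_vec3(up)
    x = np.cross(-up, z)  # camera +y is image-down
    x = normalize(x - z * np.dot(x, z))
    y = np.cross(z, x)
    R = np.column_stack([x, y, z])
    return RigidTransform(R, position)
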