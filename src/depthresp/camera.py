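"""Pinhole camera geometry for depth frames.

A depth frame stores, per pixel, the distance from the camera plane to the
scene along the optical axis, in millimetres, with 0 marking an invalid
measurement.  This module unprojects pixels into camera-centred 3D points and
estimates the 3D surface area subtended by each pixel from its immediate
neighbours, which is the geometric core of the pixel-wise volume method: the
area each pixel "sees" on the chest wall scales with depth squared and with
surface obliquity, and both effects are captured by unprojecting the
neighbouring pixels at their own measured depths and taking the cross product
of the two central-difference tangent vectors.

Conventions
-----------
* Pixel coordinates are ``(u, v) = (column, row)``, 0-based, with the pixel
  centre at integer coordinates.
* Depth ``d`` is the z-coordinate (not the ray length); the camera is an ideal
  pinhole with no lens distortion.
* Units: depth mm, area mm².
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .errors import BoundsError, ConfigError, EmptyROIError, InvalidDepthError

__all__ = [
    "CameraIntrinsics",
    "Point3D",
    "unproject",
    "project",
    "pixel_area",
    "area_map",
]


@dataclass(frozen=True)
class CameraIntrinsics:
    """Pinhole parameters mapping depth pixels to 3D points (mm).

    Attributes
    ----------
    fx, fy : float
        Focal lengths in pixels.
    cx, cy : float
        Principal point in pixels.
    width, height : int
        Sensor resolution in pixels.
    """

    fx: float
    fy: float
    cx: float
    cy: float
    width: int
    height: int

    def __post_init__(self):
        if not (self.fx > 0 and self.fy > 0):
            raise ConfigError(f"focal lengths must be positive, got fx={self.fx}, fy={self.fy}")
        if not (self.width >= 3 and self.height >= 3):
            raise ConfigError(f"sensor must be at least 3x3 pixels, got {self.width}x{self.height}")
        if not (0 <= self.cx < self.width and 0 <= self.cy < self.height):
            raise ConfigError(
                f"principal point ({self.cx}, {self.cy}) outside sensor {self.width}x{self.height}"
            )

    @classmethod
    def from_fov(cls, width: int, height: int, hfov_deg: float = 75.0, vfov_deg: float = 65.0):
        """Intrinsics of an ideal pinhole with the given field of view.

        Defaults match a narrow-field-of-view depth sensor (75° x 65°) such as
        the Azure Kinect NFOV unbinned mode; the principal point is placed at
        the geometric centre of the pixel grid.
        """
        fx = (width / 2.0) / math.tan(math.radians(hfov_deg) / 2.0)
        fy = (height / 2.0) / math.tan(math.radians(vfov_deg) / 2.0)
        return cls(fx=fx, fy=fy, cx=(width - 1) / 2.0, cy=(height - 1) / 2.0,
                   width=width, height=height)

    def to_dict(self) -> dict:
        return {
            "fx": self.fx, "fy": self.fy, "cx": self.cx, "cy": self.cy,
            "width": self.width, "height": self.height, "depth_unit": "mm",
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CameraIntrinsics":
        return cls(fx=d["fx"], fy=d["fy"], cx=d["cx"], cy=d["cy"],
                   width=int(d["width"]), height=int(d["height"]))


class Point3D(NamedTuple):
    """Camera-centred 3D point in mm; z along the optical axis."""

    x: float
    y: float
    z: float


def unproject(intr: CameraIntrinsics, u, v, d) -> Point3D:
    """Unproject pixel ``(u, v)`` at depth ``d`` mm into a 3D point.

    ``x = (u - cx) * d / fx``, ``y = (v - cy) * d / fy``, ``z = d``.

    Raises
    ------
    BoundsError
        If the pixel lies outside the sensor.
    InvalidDepthError
        If ``d <= 0`` (0 is the sensor's invalid-measurement marker).
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    d = np.asarray(d, dtype=float)
    if np.any(u < 0) or np.any(u >= intr.width) or np.any(v < 0) or np.any(v >= intr.height):
        raise BoundsError(f"pixel ({u}, {v}) outside sensor {intr.width}x{intr.height}")
    if np.any(d <= 0):
        raise InvalidDepthError("non-positive depth is invalid")
    x = (u - intr.cx) * d / intr.fx
    y = (v - intr.cy) * d / intr.fy
    if x.ndim == 0:
        return Point3D(float(x), float(y), float(d))
    return Point3D(x, y, d)


def project(intr: CameraIntrinsics, point: Point3D):
    """Project a 3D point back to pixel coordinates ``(u, v)``.

    Inverse of :func:`unproject` for points with ``z > 0``.
    """
    x, y, z = point
    z = np.asarray(z, dtype=float)
    if np.any(z <= 0):
        raise InvalidDepthError("cannot project a point with non-positive z")
    return np.asarray(x) * intr.fx / z + intr.cx, np.asarray(y) * intr.fy / z + intr.cy


def _neighbor_tangent(intr, frame, u, v, du, dv):
    """Half tangent toward neighbour (u+du, v+dv), or None if unavailable."""
    un, vn = u + du, v + dv
    if not (0 <= un < intr.width and 0 <= vn < intr.height):
        return None
    dn = frame[vn, un]
    if dn <= 0:
        return None
    p = unproject(intr, un, vn, dn)
    p0 = unproject(intr, u, v, frame[v, u])
    return np.array([p.x - p0.x, p.y - p0.y, p.z - p0.z])


def pixel_area(intr: CameraIntrinsics, frame: np.ndarray, u: int, v: int) -> float:
    """3D surface area (mm²) subtended by pixel ``(u, v)``.

    Neighbours at ``(u±1, v)`` and ``(u, v±1)`` are unprojected at their own
    measured depths; the area is the magnitude of the cross product of the two
    central-difference tangents.  At frame borders or next to invalid pixels a
    one-sided difference is used.  For a fronto-parallel plane at depth ``d``
    this reduces to the closed form ``d² / (fx·fy)``.

    Raises
    ------
    InvalidDepthError
        If the centre pixel is invalid, or a direction has no valid neighbour.
    BoundsError
        If ``(u, v)`` lies outside the frame.
    """
    frame = np.asarray(frame, dtype=float)
    if not (0 <= u < intr.width and 0 <= v < intr.height):
        raise BoundsError(f"pixel ({u}, {v}) outside sensor")
    if frame[v, u] <= 0:
        raise InvalidDepthError(f"centre pixel ({u}, {v}) has invalid depth")

    tu_p = _neighbor_tangent(intr, frame, u, v, +1, 0)
    tu_m = _neighbor_tangent(intr, frame, u, v, -1, 0)
    tv_p = _neighbor_tangent(intr, frame, u, v, 0, +1)
    tv_m = _neighbor_tangent(intr, frame, u, v, 0, -1)

    if tu_p is not None and tu_m is not None:
        tu = (tu_p - tu_m) / 2.0
    elif tu_p is not None:
        tu = tu_p
    elif tu_m is not None:
        tu = -tu_m
    else:
        raise InvalidDepthError(f"pixel ({u}, {v}) has no valid horizontal neighbour")

    if tv_p is not None and tv_m is not None:
        tv = (tv_p - tv_m) / 2.0
    elif tv_p is not None:
        tv = tv_p
    elif tv_m is not None:
        tv = -tv_m
    else:
        raise InvalidDepthError(f"pixel ({u}, {v}) has no valid vertical neighbour")

    return float(np.linalg.norm(np.cross(tu, tv)))


def _shifted(arr: np.ndarray, dv: int, du: int) -> np.ndarray:
    """Array shifted so out[v, u] = arr[v+dv, u+du], NaN-padded at borders."""
    out = np.full_like(arr, np.nan)
    h, w = arr.shape[-2:]
    src_v = slice(max(dv, 0), h + min(dv, 0))
    src_u = slice(max(du, 0), w + min(du, 0))
    dst_v = slice(max(-dv, 0), h + min(-dv, 0))
    dst_u = slice(max(-du, 0), w + min(-du, 0))
    out[..., dst_v, dst_u] = arr[..., src_v, src_u]
    return out


def area_map(intr: CameraIntrinsics, reference_frame: np.ndarray, roi_mask: np.ndarray):
    """Per-pixel 3D area grid (mm²) for all ROI pixels of a reference frame.

    The area of every ROI pixel that is valid in the reference frame is
    computed once and frozen for the whole acquisition.  ROI pixels whose
    reference depth is invalid (or that have no valid neighbour in one of the
    two directions) are removed from the mask; areas outside the ROI are zero.

    Parameters
    ----------
    intr : CameraIntrinsics
    reference_frame : (H, W) array of depth mm, 0 = invalid
    roi_mask : (H, W) boolean array

    Returns
    -------
    areas : (H, W) float array, mm²; zero outside the effective mask
    effective_mask : (H, W) boolean array, the ROI mask minus removed pixels

    Raises
    ------
    EmptyROIError
        If no ROI pixel survives.
    """
    frame = np.asarray(reference_frame, dtype=float)
    mask = np.asarray(roi_mask, dtype=bool)
    if frame.shape != mask.shape:
        raise ConfigError(f"mask shape {mask.shape} != frame shape {frame.shape}")
    if frame.shape != (intr.height, intr.width):
        raise ConfigError(
            f"frame shape {frame.shape} != sensor ({intr.height}, {intr.width})"
        )
    if not mask.any():
        raise EmptyROIError("ROI mask is empty")

    valid = frame > 0
    h, w = frame.shape
    uu, vv = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
    z = np.where(valid, frame, np.nan)
    p = np.stack([(uu - intr.cx) * z / intr.fx, (vv - intr.cy) * z / intr.fy, z])

    def tangent(dv, du):
        pp = _shifted(p, dv, du)            # neighbour at +step
        pm = _shifted(p, -dv, -du)          # neighbour at -step
        has_p = np.isfinite(pp[2])
        has_m = np.isfinite(pm[2])
        both = has_p & has_m
        t = np.where(both, (pp - pm) / 2.0,
                     np.where(has_p, pp - p, p - pm))
        return t, (has_p | has_m)

    tu, oku = tangent(0, 1)
    tv, okv = tangent(1, 0)
    effective = mask & valid & oku & okv
    if not effective.any():
        raise EmptyROIError("no ROI pixel has a valid depth in the reference frame")

    cross = np.cross(tu, tv, axisa=0, axisb=0, axisc=0)
    areas = np.where(effective, np.linalg.norm(np.where(np.isfinite(cross), cross, 0.0), axis=0), 0.0)
    return areas, effective
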