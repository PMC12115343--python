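"""Oriented-bounding-box ROI geometry and detection.

The region of interest over which volume is integrated is an oriented
bounding box (OBB): a rectangle that can rotate to fit the patient's torso.
This module provides the box geometry (point membership, rasterisation into a
pixel mask) and two ways of obtaining a box:

* :func:`fixed_roi` — a box supplied by configuration;
* :func:`detect_roi_variance` — a motion-variance heuristic that finds the
  region whose depth fluctuates coherently over time.

The detector implements a generic contract — sequence in, confidence-bearing
``OrientedBBox`` out — so a learned detector (e.g. one trained on infrared
frames) can be plugged in behind the same interface.  When several candidate
regions exist the highest-confidence box wins.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
import shapely
from scipy import ndimage

from .container import DepthSequence
from .errors import ConfigError, DetectionFailureError, EmptyROIError

__all__ = [
    "OrientedBBox",
    "point_in_obb",
    "rasterize_obb",
    "expand_obb",
    "fixed_roi",
    "detect_roi_variance",
]

log = logging.getLogger(__name__)

_EPS = 1e-9


def _normalize_angle(angle: float) -> float:
    """Fold an angle into (-pi/2, pi/2]; a box is symmetric under pi."""
    a = (angle + math.pi / 2.0) % math.pi - math.pi / 2.0
    if a <= -math.pi / 2.0 + 0.0:  # exactly -pi/2 folds to +pi/2
        a += math.pi
    return a


@dataclass(frozen=True)
class OrientedBBox:
    """Rotated rectangular ROI in pixel coordinates.

    ``angle`` is counter-clockwise about the centre, radians, normalised to
    (-pi/2, pi/2]; ``confidence`` expresses the detector's certainty in
    [0, 1] (1.0 for configured boxes).
    """

    center_u: float
    center_v: float
    width_box: float
    height_box: float
    angle: float = 0.0
    confidence: float = 1.0

    def __post_init__(self):
        if self.width_box <= 0 or self.height_box <= 0:
            raise ConfigError("box width and height must be positive")
        if not (0.0 <= self.confidence <= 1.0):
            raise ConfigError("confidence must lie in [0, 1]")
        object.__setattr__(self, "angle", _normalize_angle(self.angle))

    def corners(self) -> np.ndarray:
        """The four corners as (4, 2) array of (u, v), counter-clockwise."""
        c, s = math.cos(self.angle), math.sin(self.angle)
        hw, hh = self.width_box / 2.0, self.height_box / 2.0
        local = np.array([[-hw, -hh], [hw, -hh], [hw, hh], [-hw, hh]])
        rot = np.array([[c, -s], [s, c]])
        return local @ rot.T + np.array([self.center_u, self.center_v])


def point_in_obb(obb: OrientedBBox, u, v):
    """True iff the point lies inside the box, boundary inclusive.

    The point is rotated by ``-angle`` about the centre and compared against
    the half-extents.  Accepts scalars or arrays.
    """
    du = np.asarray(u, dtype=float) - obb.center_u
    dv = np.asarray(v, dtype=float) - obb.center_v
    c, s = math.cos(obb.angle), math.sin(obb.angle)
    x = du * c + dv * s
    y = -du * s + dv * c
    inside = (np.abs(x) <= obb.width_box / 2.0 + _EPS) & \
             (np.abs(y) <= obb.height_box / 2.0 + _EPS)
    return inside if inside.ndim else bool(inside)


def rasterize_obb(obb: OrientedBBox, width: int, height: int) -> np.ndarray:
    """Binary mask of pixels whose centres fall inside the box.

    Pixel centres are at integer coordinates; the mask is clipped to the
    frame.  Raises :class:`EmptyROIError` if no pixel centre is covered.
    """
    if width <= 0 or height <= 0:
        raise ConfigError("frame dimensions must be positive")
    uu, vv = np.meshgrid(np.arange(width, dtype=float),
                         np.arange(height, dtype=float))
    mask = point_in_obb(obb, uu, vv)
    if not mask.any():
        raise EmptyROIError("oriented box covers no pixel centre inside the frame")
    return mask


def expand_obb(obb: OrientedBBox, factor: float) -> OrientedBBox:
    """Scale the box extents about its centre by ``factor`` (> 0).

    Used by the pipeline to widen a detected motion core so the integration
    region covers the full breathing surface; surrounding static scene adds
    no volume variation.
    """
    if factor <= 0:
        raise ConfigError("expansion factor must be positive")
    return replace(obb, width_box=obb.width_box * factor,
                   height_box=obb.height_box * factor)


def fixed_roi(config) -> OrientedBBox:
    """Build the configured box with confidence 1.0.

    ``config`` may be an :class:`OrientedBBox`, a mapping with keys
    ``center_u, center_v, width_box, height_box, angle_deg`` or a string
    ``"cu,cv,w,h,angle_deg"``.
    """
    if isinstance(config, OrientedBBox):
        return replace(config, confidence=1.0)
    if isinstance(config, str):
        parts = config.split(",")
        if len(parts) != 5:
            raise ConfigError(f"fixed ROI string must be 'cu,cv,w,h,angle_deg', got {config!r}")
        cu, cv, w, h, angle_deg = (float(p) for p in parts)
    else:
        try:
            cu = float(config["center_u"])
            cv = float(config["center_v"])
            w = float(config["width_box"])
            h = float(config["height_box"])
            angle_deg = float(config.get("angle_deg", 0.0))
        except (KeyError, TypeError) as exc:
            raise ConfigError(f"invalid fixed ROI config: {config!r}") from exc
    return OrientedBBox(center_u=cu, center_v=cv, width_box=w, height_box=h,
                        angle=math.radians(angle_deg), confidence=1.0)


def detect_roi_variance(sequence: DepthSequence, n_frames: int = 300,
                        quantile: float = 0.98) -> OrientedBBox:
    """Detect the breathing region from temporal depth variance.

    The per-pixel standard deviation of depth over the first ``n_frames``
    frames is thresholded at the given quantile; the minimum-area rotated
    rectangle around the largest 8-connected component of supra-threshold
    pixels is returned, with confidence the fraction of all candidate pixels
    it contains.  Deterministic: no randomness is involved.

    Raises
    ------
    DetectionFailureError
        If fewer than 50 candidate pixels are found, or the component is
        degenerate (no coherent motion region) — callers fall back to a fixed
        ROI.
    """
    if n_frames < 10:
        raise ConfigError("variance detection needs at least 10 frames")
    if not (0.0 < quantile < 1.0):
        raise ConfigError("quantile must lie in (0, 1)")
    n = min(n_frames, sequence.n_frames)
    if n < 10:
        raise ConfigError(f"sequence has only {sequence.n_frames} frames; need >= 10")

    window = sequence.data[:n].astype(np.float32) * np.float32(0.1)
    valid = (sequence.data[:n] > 0).all(axis=0)
    std = window.std(axis=0, dtype=np.float64)
    if not valid.any():
        raise DetectionFailureError("no pixel is valid across the detection window")
    threshold = np.quantile(std[valid], quantile)
    candidates = valid & (std > threshold)
    n_cand = int(candidates.sum())
    if n_cand < 50:
        raise DetectionFailureError(
            f"only {n_cand} pixels above the {quantile:.2f} variance quantile; "
            "no coherent motion region"
        )

    labels, n_comp = ndimage.label(candidates, structure=np.ones((3, 3), dtype=int))
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    biggest = int(sizes.argmax())
    if sizes[biggest] < 50:
        raise DetectionFailureError(
            f"largest connected motion component has only {sizes[biggest]} pixels"
        )
    vs, us = np.nonzero(labels == biggest)
    rect = shapely.minimum_rotated_rectangle(shapely.multipoints(np.column_stack([us, vs])))
    if rect.geom_type != "Polygon":
        raise DetectionFailureError("motion component is degenerate (collinear pixels)")
    corners = np.asarray(rect.exterior.coords)[:4]
    center = corners.mean(axis=0)
    e1 = corners[1] - corners[0]
    e2 = corners[2] - corners[1]
    w = float(np.hypot(*e1))
    h = float(np.hypot(*e2))
    if w < _EPS or h < _EPS:
        raise DetectionFailureError("motion component is degenerate (zero-extent box)")
    angle = math.atan2(e1[1], e1[0])

    box = OrientedBBox(center_u=float(center[0]), center_v=float(center[1]),
                       width_box=w, height_box=h, angle=angle, confidence=1.0)
    cand_v, cand_u = np.nonzero(candidates)
    conf = float(np.mean(point_in_obb(box, cand_u, cand_v)))
    box = replace(box, confidence=conf)
    log.info("variance ROI: %d candidates, component %d px, box %.1fx%.1f px at "
             "(%.1f, %.1f), angle %.1f deg, confidence %.3f",
             n_cand, sizes[biggest], w, h, box.center_u, box.center_v,
             math.degrees(box.angle), conf)
    return box
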