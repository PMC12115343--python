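"""Depth sequence + ROI -> thoracic volume time series (mL).

Two estimators are provided.  The pixel-wise method multiplies each ROI
pixel's depth by its own frozen 3D area and sums — robust to depth-dependent
and obliquity-dependent pixel footprints.  The spatial-average baseline
multiplies the mean ROI depth change by the total ROI area, the classic
``V(k) = D(k) x S`` estimate, kept for comparison.

Sign convention: as the lungs fill, the chest wall rises toward the camera
and the camera-to-thorax volume *shrinks*, so the raw series is inverted (and
zeroed to its first value) before any respiratory analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .camera import CameraIntrinsics, area_map
from .container import DepthSequence
from .errors import EmptyROIError

__all__ = [
    "VolumeSeries",
    "compute_volume_series",
    "invert_and_zero",
    "compute_volume_baseline",
    "HELD_PIXEL_WARN_FRACTION",
]

log = logging.getLogger(__name__)

HELD_PIXEL_WARN_FRACTION = 0.2


@dataclass
class VolumeSeries:
    """A volume signal sampled at the camera frame rate.

    ``meta`` records provenance: zeroing reference, inversion flag, held-pixel
    statistics, filter edge region, quality warnings.
    """

    time: np.ndarray
    volume: np.ndarray
    fps: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.volume = np.asarray(self.volume, dtype=float)
        if self.time.shape != self.volume.shape:
            raise ValueError("time and volume must have the same length")

    def __len__(self) -> int:
        return len(self.volume)


def compute_volume_series(sequence: DepthSequence, areas: np.ndarray,
                          roi_mask: np.ndarray,
                          reference_frame: np.ndarray | None = None) -> VolumeSeries:
    """Raw camera-to-thorax volume per frame (mL), before inversion/zeroing.

    Per frame, ``V_raw = sum over ROI of depth(p) * area(p) / 1000`` (mm³ to
    mL), with the area map frozen from the reference frame.  A pixel that
    drops out (depth 0) in a later frame holds its most recent valid depth so
    the fixed-area assumption is preserved; the held fraction per frame is
    reported in ``meta['held_fraction']`` and a quality warning is attached
    when any frame holds more than 20% of the ROI.

    ``reference_frame`` (mm), when given, initialises the hold values for
    pixels already invalid in the first frame.
    """
    mask = np.asarray(roi_mask, dtype=bool)
    if not mask.any():
        raise EmptyROIError("ROI mask is empty")
    flat_idx = np.flatnonzero(mask.ravel())
    a = np.asarray(areas, dtype=float).ravel()[flat_idx]

    n = sequence.n_frames
    vol = np.empty(n, dtype=float)
    held_fraction = np.empty(n, dtype=float)

    if reference_frame is not None:
        last_valid = np.asarray(reference_frame, dtype=float).ravel()[flat_idx].copy()
    else:
        last_valid = sequence.depth_mm(0).ravel()[flat_idx]

    for k in range(n):
        d = sequence.depth_mm(k).ravel()[flat_idx]
        invalid = d <= 0
        if invalid.any():
            d = np.where(invalid, last_valid, d)
        held_fraction[k] = invalid.mean()
        last_valid = d
        vol[k] = float(d @ a) / 1000.0

    meta = {
        "method": "pixelwise",
        "inverted": False,
        "zeroed": False,
        "roi_pixels": int(mask.sum()),
        "held_fraction": held_fraction,
        "held_fraction_max": float(held_fraction.max()),
    }
    warnings = []
    if held_fraction.max() > HELD_PIXEL_WARN_FRACTION:
        warnings.append(
            f"held pixel fraction reached {held_fraction.max():.1%} "
            f"(> {HELD_PIXEL_WARN_FRACTION:.0%}) — volume quality degraded"
        )
        log.warning(warnings[-1])
    meta["quality_warnings"] = warnings
    return VolumeSeries(time=sequence.time, volume=vol, fps=sequence.fps, meta=meta)


def invert_and_zero(raw: VolumeSeries) -> VolumeSeries:
    """Flip the sign of deviations from the first sample.

    ``v'(k) = -(v(k) - v(0))`` so that lung filling appears as a rising
    signal starting at zero.  Applying it twice restores the original shape
    (zeroed); it is not idempotent.
    """
    if len(raw) == 0:
        raise ValueError("cannot invert an empty series")
    v = -(raw.volume - raw.volume[0])
    meta = dict(raw.meta)
    meta.update(inverted=not meta.get("inverted", False), zeroed=True,
                zero_reference=float(raw.volume[0]))
    return VolumeSeries(time=raw.time.copy(), volume=v, fps=raw.fps, meta=meta)


def compute_volume_baseline(sequence: DepthSequence, roi_mask: np.ndarray,
                            intr: CameraIntrinsics,
                            reference_frame: np.ndarray | None = None) -> VolumeSeries:
    """Spatial-average volume estimate ``V(k) = D(k) x S``, inverted and zeroed.

    ``D(k)`` is the mean ROI depth change from frame 0 and ``S`` the total 3D
    ROI area from the reference frame.  Dropped-out pixels hold their last
    valid depth exactly as in :func:`compute_volume_series`.
    """
    ref = np.asarray(reference_frame, dtype=float) if reference_frame is not None \
        else sequence.depth_mm(0)
    areas, eff_mask = area_map(intr, ref, np.asarray(roi_mask, dtype=bool))
    total_area = float(areas.sum())
    flat_idx = np.flatnonzero(eff_mask.ravel())

    n = sequence.n_frames
    mean_depth = np.empty(n, dtype=float)
    last_valid = ref.ravel()[flat_idx].copy()
    for k in range(n):
        d = sequence.depth_mm(k).ravel()[flat_idx]
        invalid = d <= 0
        if invalid.any():
            d = np.where(invalid, last_valid, d)
        last_valid = d
        mean_depth[k] = d.mean()

    raw = (mean_depth - mean_depth[0]) * total_area / 1000.0
    series = VolumeSeries(time=sequence.time, volume=raw, fps=sequence.fps,
                          meta={"method": "baseline", "inverted": False,
                                "zeroed": False, "roi_pixels": int(eff_mask.sum()),
                                "total_area_mm2": total_area})
    return invert_and_zero(series)
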