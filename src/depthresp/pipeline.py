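"""End-to-end analysis: depth sequence -> respiratory report.

Chains the stages in their canonical order: build a reference frame, obtain
the ROI (fixed box or variance detection, with fallback), freeze the
per-pixel area map, integrate the per-frame volume, invert/zero, low-pass
filter, detect cycles, differentiate to flow, and assemble the report.

The reference frame is the per-pixel temporal mean of the first
``reference_frames`` frames (default 30, i.e. 1 s at 30 FPS).  Averaging
suppresses single-frame sensor noise before the area map is computed from
depth differences of neighbouring pixels — the cross-product area estimate is
convex in that noise, so a single noisy frame would bias every pixel's area
(hence every volume) upward.  The area map stays frozen for the whole
acquisition, and detection runs once, on the reference frame window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .camera import area_map
from .container import DepthSequence
from .errors import ConfigError, DetectionFailureError
from .respparams import RespiratoryReport, assemble_report
from .respsignal import (FilterSpec, FlowSeries, compute_flow, detect_cycles,
                         filter_volume)
from .roi import (OrientedBBox, detect_roi_variance, expand_obb, fixed_roi,
                  rasterize_obb)
from .volume import (VolumeSeries, compute_volume_baseline,
                     compute_volume_series, invert_and_zero)

__all__ = ["AnalysisConfig", "AnalysisResult", "analyze_sequence", "reference_frame"]

log = logging.getLogger(__name__)


@dataclass
class AnalysisConfig:
    """Tunable parameters of the analysis pipeline (defaults as used in the
    reference setup: 2 Hz / order-10 filter, 120 breaths/min ceiling)."""

    roi_mode: str = "variance"            # "variance" | "fixed"
    fixed_box: object = None              # OrientedBBox | "cu,cv,w,h,angle_deg" | dict
    roi_margin: float = 1.5               # linear expansion of detected boxes
    detector_frames: int = 300
    detector_quantile: float = 0.98
    reference_frames: int = 30
    filter_order: int = 10
    filter_cutoff_hz: float = 2.0
    causal_filter: bool = False
    prominence_fraction: float = 0.2
    max_rr: float = 120.0
    method: str = "pixelwise"             # "pixelwise" | "baseline"
    vt_convention: str = "expiratory"
    vt_source: str = "unfiltered"         # "unfiltered" | "filtered"
    flow_convention: str = "paper"


@dataclass
class AnalysisResult:
    """Everything the pipeline produced, for reporting and inspection."""

    report: RespiratoryReport
    volume: VolumeSeries          # zeroed, inverted, filtered
    raw_volume: VolumeSeries      # camera-to-thorax, unprocessed
    flow: FlowSeries
    roi: OrientedBBox
    roi_effective: OrientedBBox   # after margin expansion (equals roi when fixed)
    mask: np.ndarray
    reference: np.ndarray


def reference_frame(sequence: DepthSequence, n_frames: int = 15) -> np.ndarray:
    """Per-pixel temporal mean of the first ``n_frames`` valid depths (mm).

    Pixels with no valid sample in the window come out 0 (invalid).
    """
    n = max(1, min(n_frames, sequence.n_frames))
    window = sequence.data[:n].astype(np.float64) * 0.1
    valid = window > 0
    counts = valid.sum(axis=0)
    sums = np.where(valid, window, 0.0).sum(axis=0)
    with np.errstate(invalid="ignore"):
        ref = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    return ref


def _obtain_roi(sequence: DepthSequence, config: AnalysisConfig):
    """Returns (box, detected): detected is False for configured boxes."""
    if config.roi_mode == "fixed":
        if config.fixed_box is None:
            raise ConfigError("roi_mode='fixed' requires fixed_box")
        return fixed_roi(config.fixed_box), False
    if config.roi_mode != "variance":
        raise ConfigError(f"unknown roi_mode {config.roi_mode!r}")
    try:
        box = detect_roi_variance(sequence,
                                  n_frames=min(config.detector_frames,
                                               sequence.n_frames),
                                  quantile=config.detector_quantile)
        return box, True
    except DetectionFailureError:
        if config.fixed_box is not None:
            log.warning("variance ROI detection failed; falling back to fixed ROI")
            return fixed_roi(config.fixed_box), False
        raise


def analyze_sequence(sequence: DepthSequence,
                     config: AnalysisConfig | None = None) -> AnalysisResult:
    """Run the full pipeline on a depth sequence.

    Raises the stage-specific errors (:class:`DetectionFailureError`,
    :class:`EmptyROIError`, :class:`NoCycleError`, ...) unchanged so callers
    can react; the CLI maps them to machine-readable exits.
    """
    config = config or AnalysisConfig()
    ref = reference_frame(sequence, config.reference_frames)

    box, detected = _obtain_roi(sequence, config)
    if detected and config.roi_margin != 1.0:
        box_eff = expand_obb(box, config.roi_margin)
    else:
        box_eff = box
    mask = rasterize_obb(box_eff, sequence.intrinsics.width,
                         sequence.intrinsics.height)
    log.info("ROI: %s box %.0fx%.0f px, confidence %.3f; mask %d px",
             config.roi_mode, box_eff.width_box, box_eff.height_box,
             box.confidence, int(mask.sum()))

    if config.method == "baseline":
        processed_src = compute_volume_baseline(sequence, mask,
                                                sequence.intrinsics,
                                                reference_frame=ref)
        raw = processed_src  # baseline estimator returns processed directly
        processed = processed_src
        areas, eff_mask = area_map(sequence.intrinsics, ref, mask)
    elif config.method == "pixelwise":
        areas, eff_mask = area_map(sequence.intrinsics, ref, mask)
        removed = int(mask.sum() - eff_mask.sum())
        if removed:
            log.info("area map: %d ROI pixels removed (invalid reference depth)",
                     removed)
        raw = compute_volume_series(sequence, areas, eff_mask,
                                    reference_frame=ref)
        processed = invert_and_zero(raw)
    else:
        raise ConfigError(f"unknown method {config.method!r}")

    spec = FilterSpec(fps=sequence.fps, order=config.filter_order,
                      cutoff_hz=config.filter_cutoff_hz)
    filtered = filter_volume(processed, spec, causal=config.causal_filter)
    markers = detect_cycles(filtered, prominence_fraction=config.prominence_fraction,
                            max_rr=config.max_rr)
    flow = compute_flow(filtered)
    quality = {"roi_confidence": box.confidence,
               "roi_mode": config.roi_mode,
               "roi_pixels": int(eff_mask.sum())}
    if config.vt_source == "unfiltered" and not config.causal_filter:
        amplitude_series = processed
    elif config.vt_source in ("filtered", "unfiltered"):
        amplitude_series = None  # read amplitudes from the filtered series
    else:
        raise ConfigError(f"unknown vt_source {config.vt_source!r}")
    report = assemble_report(filtered, flow, markers,
                             amplitude_series=amplitude_series,
                             flow_convention=config.flow_convention,
                             vt_convention=config.vt_convention,
                             quality=quality)
    log.info("cycles detected: %d", report.n_cycles)
    return AnalysisResult(report=report, volume=filtered, raw_volume=raw,
                          flow=flow, roi=box, roi_effective=box_eff, mask=eff_mask,
                          reference=ref)
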