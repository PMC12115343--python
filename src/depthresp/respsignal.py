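"""Filtering, respiratory-cycle detection and flow derivation.

The volume signal is low-pass filtered with a linear-phase FIR filter
(windowed-sinc, Hamming window; default order 10, cutoff 2 Hz — 2 Hz being
120 breaths/min, the physiological maximum respiratory rate).  In offline
mode the constant group delay of ``order/2`` samples is compensated so the
filtered series stays aligned with its timestamps; a causal mode without
compensation is available for streaming use.

Cycle detection finds local maxima and minima subject to a minimum inter-peak
distance (derived from the same 120 breaths/min bound: 15 frames at 30 FPS)
and a minimum prominence expressed as a fraction of the observed signal
range, then pairs the extrema into complete trough -> peak -> trough cycles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy.integrate import cumulative_trapezoid

from .errors import ConfigError, NoCycleError
from .volume import VolumeSeries

__all__ = [
    "FilterSpec",
    "CycleMarkers",
    "FlowSeries",
    "design_fir",
    "filter_volume",
    "min_distance_frames",
    "detect_cycles",
    "compute_flow",
    "integrate_flow",
    "MAX_RESPIRATORY_RATE",
]

log = logging.getLogger(__name__)

#: Physiological maximum respiratory rate (breaths/min) used for the filter
#: cutoff (120/60 = 2 Hz) and the minimum peak distance.
MAX_RESPIRATORY_RATE = 120.0


@dataclass(frozen=True)
class FilterSpec:
    """Low-pass FIR specification: ``order`` is taps - 1 and must be even so
    the group delay (order/2 samples) is an integer."""

    fps: float
    order: int = 10
    cutoff_hz: float = 2.0

    def __post_init__(self):
        if self.order <= 0 or self.order % 2 != 0:
            raise ConfigError(f"filter order must be a positive even integer, got {self.order}")
        if not (0 < self.cutoff_hz < self.fps / 2.0):
            raise ConfigError(
                f"cutoff {self.cutoff_hz} Hz must lie in (0, Nyquist={self.fps / 2.0} Hz)"
            )


def design_fir(spec: FilterSpec) -> np.ndarray:
    """Symmetric windowed-sinc low-pass taps with unit DC gain.

    ``order + 1`` Hamming-windowed taps; linear phase by symmetry
    (c[k] = c[order-k]) and sum exactly 1 so a constant signal passes
    unchanged.
    """
    return sps.firwin(spec.order + 1, spec.cutoff_hz, window="hamming", fs=spec.fps)


def filter_volume(series: VolumeSeries, spec: FilterSpec,
                  causal: bool = False) -> VolumeSeries:
    """Low-pass the volume series.

    Offline (default): convolution with edge-value padding and group-delay
    compensation of ``order/2`` samples, so the output is aligned to the
    input timestamps; the first and last ``order/2`` samples are flagged as
    the edge region in ``meta['edge_region']``.  Causal: plain streaming
    convolution, delay uncompensated (``meta['causal'] = True``).
    """
    if spec.fps != series.fps:
        raise ConfigError(f"filter fps {spec.fps} != series fps {series.fps}")
    n = len(series)
    if n <= spec.order:
        raise ConfigError(f"series length {n} must exceed filter order {spec.order}")
    taps = design_fir(spec)
    half = spec.order // 2
    if causal:
        filtered = sps.lfilter(taps, 1.0, series.volume)
    else:
        padded = np.pad(series.volume, half, mode="edge")
        filtered = np.convolve(padded, taps, mode="valid")
    meta = dict(series.meta)
    meta.update(filtered=True, filter_order=spec.order,
                filter_cutoff_hz=spec.cutoff_hz, causal=causal,
                edge_region=half)
    return VolumeSeries(time=series.time.copy(), volume=filtered,
                        fps=series.fps, meta=meta)


def min_distance_frames(fps: float, max_rr: float = MAX_RESPIRATORY_RATE) -> int:
    """Minimum frames between consecutive peaks for a given maximum rate.

    ``round(fps * 60 / max_rr)`` with round-half-up: at 30 FPS and 120
    breaths/min — one breath every 0.5 s — this is 15 frames.
    """
    if fps <= 0:
        raise ConfigError("fps must be positive")
    if max_rr <= 0:
        raise ConfigError("max_rr must be positive")
    return int(np.floor(fps * 60.0 / max_rr + 0.5))


@dataclass
class CycleMarkers:
    """Peak/trough frame indices and their pairing into complete cycles.

    ``pairing`` lists ``(trough, peak, next_trough)`` index triples;
    consecutive cycles share their boundary trough.  Within the paired
    region peaks and troughs strictly alternate.
    """

    peak_indices: np.ndarray
    trough_indices: np.ndarray
    pairing: list = field(default_factory=list)

    @property
    def n_cycles(self) -> int:
        return len(self.pairing)


def _alternate(peaks: np.ndarray, troughs: np.ndarray, values: np.ndarray):
    """Merge extrema into a strictly alternating sequence.

    When two extrema of the same kind are adjacent (possible on noisy data
    after independent peak/trough scans), the more extreme one is kept —
    higher for peaks, lower for troughs, leftmost on ties — which keeps the
    procedure exactly symmetric under signal negation.
    """
    events = [(int(i), +1) for i in peaks] + [(int(i), -1) for i in troughs]
    events.sort()
    merged: list[tuple[int, int]] = []
    for idx, kind in events:
        if merged and merged[-1][1] == kind:
            prev_idx = merged[-1][0]
            better = values[idx] * kind > values[prev_idx] * kind
            if better:
                merged[-1] = (idx, kind)
        else:
            merged.append((idx, kind))
    return merged


def detect_cycles(filtered: VolumeSeries, fps: float | None = None,
                  prominence_fraction: float = 0.2,
                  max_rr: float = MAX_RESPIRATORY_RATE) -> CycleMarkers:
    """Detect respiratory peaks/troughs and pair them into complete cycles.

    Local maxima (and minima, via the negated series) are found with the
    minimum inter-peak distance from :func:`min_distance_frames` and a
    minimum prominence of ``prominence_fraction`` times the global signal
    range (default 0.2 — rejects ripple without suppressing shallow
    breaths).  Flat extrema resolve to their leftmost sample.  Unpaired
    leading/trailing extrema are dropped.

    Raises
    ------
    NoCycleError
        If no complete trough -> peak -> trough cycle exists; the exception
        carries a structured diagnostic.
    """
    fps = fps if fps is not None else filtered.fps
    v = filtered.volume
    mind = min_distance_frames(fps, max_rr)
    if len(v) < 2 * mind:
        raise NoCycleError(
            f"series of {len(v)} samples is shorter than two minimum peak distances "
            f"({2 * mind} frames)",
            diagnostic={"n_samples": int(len(v)), "min_distance_frames": mind},
        )
    vrange = float(v.max() - v.min())
    if vrange <= 0:
        raise NoCycleError("signal is constant; no respiratory cycles",
                           diagnostic={"signal_range": 0.0})
    prom = prominence_fraction * vrange

    peaks, pprops = sps.find_peaks(v, distance=mind, prominence=prom,
                                   plateau_size=(1, None))
    troughs, tprops = sps.find_peaks(-v, distance=mind, prominence=prom,
                                     plateau_size=(1, None))
    # leftmost sample of a flat extremum, for determinism
    peaks = pprops["left_edges"]
    troughs = tprops["left_edges"]

    merged = _alternate(peaks, troughs, v)
    pairing = []
    for i in range(len(merged) - 2):
        a, b, c = merged[i], merged[i + 1], merged[i + 2]
        if a[1] == -1 and b[1] == +1 and c[1] == -1:
            pairing.append((a[0], b[0], c[0]))
    if not pairing:
        raise NoCycleError(
            "no complete trough-peak-trough cycle found",
            diagnostic={"n_peaks": int(len(peaks)), "n_troughs": int(len(troughs)),
                        "signal_range": vrange,
                        "min_distance_frames": mind,
                        "prominence_threshold": prom},
        )
    return CycleMarkers(peak_indices=np.asarray(peaks, dtype=int),
                        trough_indices=np.asarray(troughs, dtype=int),
                        pairing=pairing)


@dataclass
class FlowSeries:
    """Respiratory flow (mL/s) on the same time base as its volume series."""

    time: np.ndarray
    flow: np.ndarray
    fps: float
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.flow)


def compute_flow(filtered: VolumeSeries) -> FlowSeries:
    """Flow = time derivative of volume: central differences, one-sided ends."""
    if len(filtered) < 3:
        raise ConfigError("need at least 3 samples to differentiate")
    flow = np.gradient(filtered.volume, 1.0 / filtered.fps, edge_order=1)
    return FlowSeries(time=filtered.time.copy(), flow=flow, fps=filtered.fps,
                      meta={"source": "filtered" if filtered.meta.get("filtered")
                            else "raw"})


def integrate_flow(flow: FlowSeries, v0: float = 0.0) -> np.ndarray:
    """Trapezoidal integral of flow back to a volume trace (mL).

    Second-order consistent with the central-difference derivative, so
    integrating :func:`compute_flow` output reconstructs the filtered volume
    series to well within 1% RMS at respiratory frequencies.
    """
    return v0 + cumulative_trapezoid(flow.flow, dx=1.0 / flow.fps, initial=0.0)
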