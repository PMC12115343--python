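"""Ventilator-equivalent respiratory parameters from cycle markers.

Given the filtered volume series, its flow derivative and the paired cycle
markers, this module derives the quantities a ventilator would display:
respiratory rate (RR), per-cycle and mean tidal volume (Vt), minute
ventilation (MEV), inspiratory/expiratory times (Ti, Te), the I:E ratio
(written 1 : Te/Ti), and peak inspiratory/expiratory flows (PIF, PEF).

Definitions
-----------
* Vt uses the expiratory reading by default — filtered volume at the cycle
  peak minus at the cycle-ending trough, i.e. the air exhaled during the
  cycle; the inspiratory variant (peak minus starting trough) is available.
* RR and MEV share the same denominator: the span from the start of the
  first complete cycle to the end of the last, which makes the identity
  ``MEV = mean(Vt) * RR`` exact.
* PIF/PEF come in two conventions: ``standard`` reads the flow extremum
  itself (comparable with ventilator readouts); ``paper`` reads the
  peak-to-following-trough flow *difference* (and the trough-to-peak
  difference for PIF), which is about twice the standard value on a
  symmetric breath.  Both are computed; reports record which one they carry.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .errors import AlignmentError, ConfigError, NoCycleError
from .respsignal import (CycleMarkers, FlowSeries, MAX_RESPIRATORY_RATE,
                         min_distance_frames)
from .volume import VolumeSeries

__all__ = [
    "RespiratoryCycle",
    "RespiratoryReport",
    "respiratory_rate",
    "tidal_volumes",
    "minute_ventilation",
    "phase_times",
    "peak_flows",
    "assemble_report",
    "evaluate_against_truth",
]

log = logging.getLogger(__name__)


@dataclass
class RespiratoryCycle:
    """One complete trough -> peak -> trough respiratory cycle."""

    t_start: float
    t_peak: float
    t_end: float
    vt: float
    ti: float
    te: float
    pif: float | None = None
    pef: float | None = None

    def to_dict(self) -> dict:
        return {"t_start": self.t_start, "t_peak": self.t_peak, "t_end": self.t_end,
                "vt": self.vt, "ti": self.ti, "te": self.te,
                "pif": self.pif, "pef": self.pef}

    @classmethod
    def from_dict(cls, d: dict) -> "RespiratoryCycle":
        return cls(**d)


@dataclass
class RespiratoryReport:
    """Aggregated respiratory parameters with per-cycle detail.

    ``ie_ratio`` stores the x of "1 : x", i.e. mean_te / mean_ti.
    """

    rr: float
    mean_vt: float
    minute_ventilation: float
    mean_ti: float
    mean_te: float
    ie_ratio: float
    mean_pif: float | None
    mean_pef: float | None
    n_cycles: int
    cycles: list = field(default_factory=list)
    quality: dict = field(default_factory=dict)
    flow_convention: str = "paper"
    vt_convention: str = "expiratory"

    def to_dict(self) -> dict:
        return {
            "rr": self.rr,
            "mean_vt": self.mean_vt,
            "minute_ventilation": self.minute_ventilation,
            "mean_ti": self.mean_ti,
            "mean_te": self.mean_te,
            "ie_ratio": self.ie_ratio,
            "mean_pif": self.mean_pif,
            "mean_pef": self.mean_pef,
            "n_cycles": self.n_cycles,
            "cycles": [c.to_dict() for c in self.cycles],
            "quality": self.quality,
            "flow_convention": self.flow_convention,
            "vt_convention": self.vt_convention,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=1, sort_keys=True) + "\n"
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "RespiratoryReport":
        d = dict(d)
        d["cycles"] = [RespiratoryCycle.from_dict(c) for c in d.get("cycles", [])]
        return cls(**d)

    @classmethod
    def from_json(cls, source) -> "RespiratoryReport":
        if isinstance(source, (str, bytes)) and not str(source).lstrip().startswith("{"):
            with open(source) as fh:
                return cls.from_dict(json.load(fh))
        if isinstance(source, (str, bytes)):
            return cls.from_dict(json.loads(source))
        return cls.from_dict(json.load(source))


def _cycle_span_s(markers: CycleMarkers, fps: float) -> float:
    first = markers.pairing[0][0]
    last = markers.pairing[-1][2]
    return (last - first) / fps


def _require_cycles(markers: CycleMarkers):
    if markers.n_cycles < 1:
        raise NoCycleError("no complete respiratory cycle available")


def respiratory_rate(markers: CycleMarkers, fps: float) -> float:
    """Breaths/min: complete cycles over the span they cover.

    ``n_cycles / (end of last cycle - start of first cycle) * 60``.
    """
    _require_cycles(markers)
    span = _cycle_span_s(markers, fps)
    if span <= 0:
        raise NoCycleError("degenerate cycle span")
    return markers.n_cycles / span * 60.0


def tidal_volumes(filtered: VolumeSeries, markers: CycleMarkers,
                  convention: str = "expiratory") -> np.ndarray:
    """Per-cycle tidal volume (mL).

    ``expiratory`` (default): volume at the peak minus at the cycle-ending
    trough — the air exhaled.  ``inspiratory``: peak minus the starting
    trough.  Positive by construction of the markers.
    """
    _require_cycles(markers)
    v = filtered.volume
    if convention == "expiratory":
        return np.array([v[p] - v[t2] for (_, p, t2) in markers.pairing])
    if convention == "inspiratory":
        return np.array([v[p] - v[t1] for (t1, p, _) in markers.pairing])
    raise ConfigError(f"unknown tidal volume convention {convention!r}")


def minute_ventilation(vts, markers: CycleMarkers, fps: float) -> float:
    """Expired volume per minute: sum of Vt over the cycle span, per 60 s."""
    _require_cycles(markers)
    vts = np.asarray(vts, dtype=float)
    span = _cycle_span_s(markers, fps)
    return float(vts.sum()) / span * 60.0


def phase_times(markers: CycleMarkers, fps: float):
    """Mean inspiratory/expiratory times (s) and the I:E ratio as 1 : x.

    Per cycle, Ti runs start trough -> peak and Te peak -> end trough;
    x = mean_te / mean_ti.
    """
    _require_cycles(markers)
    ti = np.array([(p - t1) / fps for (t1, p, _) in markers.pairing])
    te = np.array([(t2 - p) / fps for (_, p, t2) in markers.pairing])
    mean_ti = float(ti.mean())
    mean_te = float(te.mean())
    return mean_ti, mean_te, mean_te / mean_ti


def peak_flows(flow: FlowSeries, markers: CycleMarkers,
               convention: str = "paper",
               max_rr: float = MAX_RESPIRATORY_RATE,
               prominence_fraction: float = 0.2):
    """Per-cycle (PIF, PEF) in mL/s under the chosen convention.

    ``standard``: PIF is the maximum flow during inspiration (start trough to
    volume peak), PEF the maximum flow magnitude during expiration.

    ``paper``: flow extrema are detected on the flow signal with the same
    minimum-distance rule used for volume peaks; PEF is the difference
    between a flow peak and the following flow trough, PIF the difference
    between the preceding flow trough and that peak.  A cycle with no flow
    extremum yields ``(None, None)`` and is reported, not raised.
    """
    _require_cycles(markers)
    f = flow.flow
    out = []
    if convention == "standard":
        for (t1, p, t2) in markers.pairing:
            insp = f[t1:p + 1]
            exp = f[p:t2 + 1]
            if len(insp) == 0 or len(exp) == 0:
                out.append((None, None))
                continue
            out.append((float(insp.max()), float(-exp.min())))
        return out
    if convention != "paper":
        raise ConfigError(f"unknown peak flow convention {convention!r}")

    mind = min_distance_frames(flow.fps, max_rr)
    frange = float(f.max() - f.min())
    if frange <= 0:
        log.info("flow signal is constant; peak flows unavailable")
        return [(None, None) for _ in markers.pairing]
    prom = prominence_fraction * frange
    fpeaks, _ = sps.find_peaks(f, distance=mind, prominence=prom)
    ftroughs, _ = sps.find_peaks(-f, distance=mind, prominence=prom)
    for (t1, p, t2) in markers.pairing:
        in_cycle = fpeaks[(fpeaks >= t1) & (fpeaks <= t2)]
        if len(in_cycle) == 0:
            out.append((None, None))
            continue
        fp = int(in_cycle[np.argmax(f[in_cycle])])
        after = ftroughs[ftroughs > fp]
        before = ftroughs[ftroughs < fp]
        pef = float(f[fp] - f[after[0]]) if len(after) else None
        pif = float(f[fp] - f[before[-1]]) if len(before) else None
        out.append((pif, pef))
    return out


def _mean_or_none(values) -> float | None:
    vals = [v for v in values if v is not None]
    return float(np.mean(vals)) if vals else None


def assemble_report(filtered: VolumeSeries, flow: FlowSeries,
                    markers: CycleMarkers, fps: float | None = None,
                    amplitude_series: VolumeSeries | None = None,
                    flow_convention: str = "paper",
                    vt_convention: str = "expiratory",
                    quality: dict | None = None) -> RespiratoryReport:
    """Aggregate all parameters over the complete cycles into a report.

    ``amplitude_series``, when given, is the series from which per-cycle Vt
    amplitudes are read at the detected markers (typically the unfiltered
    inverted/zeroed volume, so the low-pass gain at the breathing frequency
    does not shave the amplitudes); timing-derived quantities always come
    from the markers on the filtered series.

    Quality flags carried along: held-pixel statistics from the volume stage
    (if present in the series metadata), and the indices of cycles touching
    the filter edge region.
    """
    fps = fps if fps is not None else filtered.fps
    _require_cycles(markers)
    amp = amplitude_series if amplitude_series is not None else filtered
    vts = tidal_volumes(amp, markers, convention=vt_convention)
    rr = respiratory_rate(markers, fps)
    mev = minute_ventilation(vts, markers, fps)
    mean_ti, mean_te, ie = phase_times(markers, fps)
    flows = peak_flows(flow, markers, convention=flow_convention)

    cycles = []
    for (t1, p, t2), vt, (pif, pef) in zip(markers.pairing, vts, flows):
        cycles.append(RespiratoryCycle(
            t_start=t1 / fps, t_peak=p / fps, t_end=t2 / fps,
            vt=float(vt), ti=(p - t1) / fps, te=(t2 - p) / fps,
            pif=pif, pef=pef))

    q = dict(quality or {})
    edge = int(filtered.meta.get("edge_region", 0))
    n = len(filtered)
    q.setdefault("edge_region_samples", edge)
    q.setdefault("edge_region_cycles", [
        i for i, (t1, _, t2) in enumerate(markers.pairing)
        if t1 < edge or t2 >= n - edge
    ])
    if "held_fraction_max" in filtered.meta:
        q.setdefault("held_fraction_max", filtered.meta["held_fraction_max"])
    if filtered.meta.get("quality_warnings"):
        q.setdefault("warnings", list(filtered.meta["quality_warnings"]))

    report = RespiratoryReport(
        rr=rr, mean_vt=float(vts.mean()), minute_ventilation=mev,
        mean_ti=mean_ti, mean_te=mean_te, ie_ratio=ie,
        mean_pif=_mean_or_none(p for p, _ in flows),
        mean_pef=_mean_or_none(p for _, p in flows),
        n_cycles=markers.n_cycles, cycles=cycles, quality=q,
        flow_convention=flow_convention, vt_convention=vt_convention)
    log.info("report: rr=%.2f /min, vt=%.1f mL, mev=%.0f mL/min, ie=1:%.2f, "
             "%d cycles", report.rr, report.mean_vt, report.minute_ventilation,
             report.ie_ratio, report.n_cycles)
    return report


def evaluate_against_truth(report: RespiratoryReport, series: VolumeSeries,
                           truth, exclude_edge: bool = True) -> dict:
    """Error metrics of an analysis against phantom ground truth.

    Returns Pearson correlation between estimated and true volume waveforms
    (edge region excluded by default), the mean absolute percentage error of
    per-cycle Vt, the RR error (breaths/min and %), and the MEV percentage
    error.  Correlation is invariant to constant offsets, so differing zero
    levels between the two series are harmless.
    """
    est = np.asarray(series.volume, dtype=float)
    ref = np.asarray(truth.true_volume, dtype=float)
    if est.shape != ref.shape:
        raise AlignmentError(
            f"estimated series has {est.shape[0]} samples, truth {ref.shape[0]}"
        )
    lo = int(series.meta.get("edge_region", 0)) if exclude_edge else 0
    hi = len(est) - lo if lo else len(est)
    e, r = est[lo:hi], ref[lo:hi]
    if np.std(e) == 0 or np.std(r) == 0:
        pearson = float("nan")
    else:
        pearson = float(np.corrcoef(e, r)[0, 1])

    vts = np.array([c.vt for c in report.cycles])
    vt_mape = float(np.mean(np.abs(vts - truth.true_vt) / truth.true_vt) * 100.0)
    rr_error = report.rr - truth.true_rr
    true_mev = truth.true_vt * truth.true_rr
    return {
        "pearson_r": pearson,
        "vt_mape_pct": vt_mape,
        "vt_mean_error_pct": float((vts.mean() - truth.true_vt) / truth.true_vt * 100.0),
        "rr_error_bpm": float(rr_error),
        "rr_error_pct": float(rr_error / truth.true_rr * 100.0),
        "mev_error_pct": float((report.minute_ventilation - true_mev) / true_mev * 100.0),
        "n_cycles": report.n_cycles,
    }
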