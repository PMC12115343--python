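"""Synthetic breathing-torso phantom with analytic ground truth.

The phantom renders what a ceiling-mounted depth camera sees when pointed
straight down at a bed: a flat bed plane at ``bed_distance`` mm, with a smooth
elliptical chest-wall dome that inflates and deflates following a periodic
breathing waveform.  The dome is a height field ``h(x, y, t) =
(baseline_height + A(t)) * b(x, y)`` over the bed plane, where ``b`` is a
``cos²`` bump with compact elliptical support and ``A(t)`` is scaled so the
peak-to-trough *added volume* equals the requested tidal volume exactly.

Because the deformation is analytic, every quantity the analysis pipeline
estimates (volume waveform, flow, respiratory rate, tidal volume, phase times,
peak flows) has an exact closed-form ground truth, computed here without ever
touching the camera model — so recovery tests exercise the full pipeline
against an independent oracle.

Sensor effects modelled: per-pixel i.i.d. Gaussian depth noise (default
1.1 mm, a depth camera's typical accuracy at ~1 m) and quantisation of depths
to 0.1 mm.  Not modelled: lens distortion, occlusions, gross patient motion,
self-occlusion (the dome is viewed near-perpendicular, so none occurs).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.integrate import quad

from .camera import CameraIntrinsics
from .container import DepthSequence
from .errors import ConfigError

__all__ = [
    "PhantomConfig",
    "GroundTruth",
    "breathing_waveform",
    "breathing_waveform_rate",
    "dome_height_field",
    "dome_unit_volume",
    "render_frame",
    "render_intensity",
    "generate_sequence",
]


@dataclass
class PhantomConfig:
    """Study conditions for one synthetic acquisition.

    Parameters
    ----------
    bed_distance : float
        Camera-to-bed distance, mm.  1100 matches an adult bedside setup,
        800 a child's.
    torso_center : (float, float)
        Dome centre on the bed plane, mm, relative to the optical axis.
    torso_semi_axes : (float, float)
        Semi-axes (a, b) of the elliptical dome support, mm.
    baseline_height : float
        Static dome height at its centre, mm.  Kept gentle by default so the
        chest surface stays in the small-slope regime assumed by single-axis
        depth plethysmography.
    vt_true : float
        Tidal volume, mL: exact peak-to-trough added dome volume.
    rr_true : float
        Respiratory rate, breaths/min.
    insp_fraction : float
        Fraction of each cycle spent in inspiration, in (0, 1).
    duration : float
        Acquisition length, s.
    fps : float
        Frame rate, frames/s.
    noise_sigma : float
        Per-pixel Gaussian depth noise, mm.
    resolution : (int, int)
        Sensor (width, height) in pixels.
    seed : int
        Seed for the noise generator; identical seeds give bit-identical
        sequences.
    plane_tilt_deg : float
        Optional tilt of the bed plane about the row axis, degrees; used to
        study surface-obliquity error.  Dome height stays along the optical
        axis so the ground truth remains exact.
    """

    bed_distance: float = 1100.0
    torso_center: tuple = (0.0, 0.0)
    torso_semi_axes: tuple = (240.0, 170.0)
    baseline_height: float = 5.0
    vt_true: float = 400.0
    rr_true: float = 15.0
    insp_fraction: float = 0.4
    duration: float = 30.0
    fps: float = 30.0
    noise_sigma: float = 1.1
    resolution: tuple = (640, 576)
    seed: int = 0
    hfov_deg: float = 75.0
    vfov_deg: float = 65.0
    plane_tilt_deg: float = 0.0

    def __post_init__(self):
        if self.vt_true <= 0:
            raise ConfigError("vt_true must be positive")
        if not (0 < self.rr_true <= 120):
            raise ConfigError("rr_true must lie in (0, 120] breaths/min")
        if not (0 < self.insp_fraction < 1):
            raise ConfigError("insp_fraction must lie in (0, 1)")
        if self.fps <= 0 or self.duration <= 0:
            raise ConfigError("fps and duration must be positive")
        if self.noise_sigma < 0:
            raise ConfigError("noise_sigma must be non-negative")
        if self.baseline_height < 0:
            raise ConfigError("baseline_height must be non-negative")
        a, b = self.torso_semi_axes
        if a <= 0 or b <= 0:
            raise ConfigError("torso_semi_axes must be positive")
        if self.bed_distance <= self.baseline_height + self.peak_amplitude:
            raise ConfigError("camera would be inside the dome")
        self._check_in_fov()

    # -- derived quantities ------------------------------------------------

    @property
    def intrinsics(self) -> CameraIntrinsics:
        w, h = self.resolution
        return CameraIntrinsics.from_fov(w, h, self.hfov_deg, self.vfov_deg)

    @property
    def unit_volume(self) -> float:
        """Volume (mm³) of the dome at unit centre amplitude."""
        a, b = self.torso_semi_axes
        return dome_unit_volume(float(a), float(b))

    @property
    def peak_amplitude(self) -> float:
        """Waveform amplitude A_max (mm) producing vt_true mL peak-to-trough."""
        return self.vt_true * 1000.0 / self.unit_volume

    def _check_in_fov(self):
        intr = self.intrinsics
        xc, yc = self.torso_center
        a, b = self.torso_semi_axes
        # nearest surface point gives the widest projection
        d_near = self.bed_distance - self.baseline_height - self.peak_amplitude
        d_near -= abs(math.tan(math.radians(self.plane_tilt_deg))) * (abs(yc) + b)
        if d_near <= 0:
            raise ConfigError("dome reaches the camera plane")
        for x in (xc - a, xc + a):
            u = intr.cx + x * intr.fx / d_near
            if not (0 <= u < intr.width):
                raise ConfigError("dome projects outside the camera field of view (u)")
        for y in (yc - b, yc + b):
            v = intr.cy + y * intr.fy / d_near
            if not (0 <= v < intr.height):
                raise ConfigError("dome projects outside the camera field of view (v)")

    # -- presets -----------------------------------------------------------

    @classmethod
    def adult(cls, **overrides) -> "PhantomConfig":
        """Adult bedside setup: camera 1.10 m above the bed, Vt 400 mL."""
        return cls(**overrides)

    @classmethod
    def child(cls, **overrides) -> "PhantomConfig":
        """Child setup: camera 0.80 m above the bed, Vt 50 mL, RR 40."""
        params = dict(
            bed_distance=800.0,
            torso_semi_axes=(120.0, 95.0),
            baseline_height=5.0,
            vt_true=50.0,
            rr_true=40.0,
            duration=60.0,
        )
        params.update(overrides)
        return cls(**params)

    def to_dict(self) -> dict:
        return {
            "bed_distance": self.bed_distance,
            "torso_center": list(self.torso_center),
            "torso_semi_axes": list(self.torso_semi_axes),
            "baseline_height": self.baseline_height,
            "vt_true": self.vt_true,
            "rr_true": self.rr_true,
            "insp_fraction": self.insp_fraction,
            "duration": self.duration,
            "fps": self.fps,
            "noise_sigma": self.noise_sigma,
            "resolution": list(self.resolution),
            "seed": self.seed,
            "hfov_deg": self.hfov_deg,
            "vfov_deg": self.vfov_deg,
            "plane_tilt_deg": self.plane_tilt_deg,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomConfig":
        d = dict(d)
        preset = d.pop("preset", None)
        for key in ("torso_center", "torso_semi_axes", "resolution"):
            if key in d:
                d[key] = tuple(d[key])
        if preset == "child":
            return cls.child(**d)
        if preset in (None, "adult"):
            return cls.adult(**d)
        raise ConfigError(f"unknown phantom preset {preset!r}")


@dataclass
class GroundTruth:
    """Exact per-frame and per-cycle truth for a phantom sequence.

    ``true_volume`` is the added dome volume above the end-expiratory baseline
    (mL, minimum 0), ``true_flow`` its analytic time derivative (mL/s).  Peak
    flows are given under both conventions (see :mod:`depthresp.respparams`):
    ``standard`` is the flow extremum itself, ``paper`` the peak-to-trough
    flow difference.
    """

    time: np.ndarray
    true_volume: np.ndarray
    true_flow: np.ndarray
    true_rr: float
    true_vt: float
    true_ti: float
    true_te: float
    true_ie: float
    true_pif_standard: float
    true_pef_standard: float
    true_pif_paper: float
    true_pef_paper: float

    def scalars(self) -> dict:
        return {
            "true_rr": self.true_rr,
            "true_vt": self.true_vt,
            "true_ti": self.true_ti,
            "true_te": self.true_te,
            "true_ie": self.true_ie,
            "true_pif_standard": self.true_pif_standard,
            "true_pef_standard": self.true_pef_standard,
            "true_pif_paper": self.true_pif_paper,
            "true_pef_paper": self.true_pef_paper,
        }

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"time_s": self.time, "true_volume_ml": self.true_volume,
             "true_flow_ml_s": self.true_flow}
        ).to_csv(path, index=False)

    @classmethod
    def from_files(cls, csv_path, scalars: dict | None = None) -> "GroundTruth":
        df = pd.read_csv(csv_path)
        s = scalars or {}
        vol = df["true_volume_ml"].to_numpy()
        t = df["time_s"].to_numpy()
        vt = s.get("true_vt", float(vol.max() - vol.min()))
        rr = s.get("true_rr", float("nan"))
        return cls(
            time=t, true_volume=vol, true_flow=df["true_flow_ml_s"].to_numpy(),
            true_rr=rr, true_vt=vt,
            true_ti=s.get("true_ti", float("nan")),
            true_te=s.get("true_te", float("nan")),
            true_ie=s.get("true_ie", float("nan")),
            true_pif_standard=s.get("true_pif_standard", float("nan")),
            true_pef_standard=s.get("true_pef_standard", float("nan")),
            true_pif_paper=s.get("true_pif_paper", float("nan")),
            true_pef_paper=s.get("true_pef_paper", float("nan")),
        )


# ---------------------------------------------------------------------------
# waveform


def breathing_waveform(t, rr: float, insp_fraction: float):
    """Normalised breathing amplitude in [0, 1] at time(s) ``t`` (s).

    Each cycle of period ``T = 60/rr`` starts at end-expiration (0), rises as
    a raised cosine to 1 over ``insp_fraction * T`` (inspiration), then falls
    as a raised cosine back to 0 over the remainder (expiration).  Continuous,
    periodic, with continuous first derivative.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ConfigError("time must be non-negative")
    period = 60.0 / rr
    ti = insp_fraction * period
    tau = np.mod(t, period)
    rising = tau < ti
    w = np.where(
        rising,
        0.5 * (1.0 - np.cos(np.pi * tau / ti)),
        0.5 * (1.0 + np.cos(np.pi * (tau - ti) / (period - ti))),
    )
    return w if w.ndim else float(w)


def breathing_waveform_rate(t, rr: float, insp_fraction: float):
    """Analytic time derivative of :func:`breathing_waveform`, 1/s."""
    t = np.asarray(t, dtype=float)
    period = 60.0 / rr
    ti = insp_fraction * period
    te = period - ti
    tau = np.mod(t, period)
    rising = tau < ti
    w = np.where(
        rising,
        0.5 * np.pi / ti * np.sin(np.pi * tau / ti),
        -0.5 * np.pi / te * np.sin(np.pi * (tau - ti) / te),
    )
    return w if w.ndim else float(w)


# ---------------------------------------------------------------------------
# dome geometry


def dome_height_field(x, y, config: PhantomConfig):
    """Dome height per unit centre amplitude at bed-plane coordinates (mm).

    ``b(x, y) = cos²(π r / 2)`` for normalised elliptical radius ``r <= 1``,
    zero outside: a smooth bump with compact support.
    """
    xc, yc = config.torso_center
    a, b = config.torso_semi_axes
    r = np.sqrt(((np.asarray(x, float) - xc) / a) ** 2
                + ((np.asarray(y, float) - yc) / b) ** 2)
    out = np.where(r <= 1.0, np.cos(np.pi * np.minimum(r, 1.0) / 2.0) ** 2, 0.0)
    return out if out.ndim else float(out)


@lru_cache(maxsize=64)
def dome_unit_volume(a: float, b: float) -> float:
    """Volume (mm³) under the unit-amplitude dome with semi-axes a, b (mm).

    Integrated numerically once per (a, b) and cached.  In polar form the
    integral separates: V = a·b · 2π ∫₀¹ cos²(πr/2) r dr.
    """
    radial, _ = quad(lambda r: math.cos(math.pi * r / 2.0) ** 2 * r, 0.0, 1.0,
                     epsabs=1e-12, epsrel=1e-12)
    return a * b * 2.0 * math.pi * radial


# ---------------------------------------------------------------------------
# rendering


def _bed_depth(config: PhantomConfig) -> np.ndarray:
    """Depth grid (mm) of the bare (possibly tilted) bed plane."""
    intr = config.intrinsics
    w, h = config.resolution
    tilt = math.tan(math.radians(config.plane_tilt_deg))
    if tilt == 0.0:
        return np.full((h, w), config.bed_distance, dtype=float)
    v = np.arange(h, dtype=float)[:, None]
    denom = 1.0 - tilt * (v - intr.cy) / intr.fy
    if np.any(denom <= 0):
        raise ConfigError("bed tilt too steep for the field of view")
    return np.broadcast_to(config.bed_distance / denom, (h, w)).copy()


def _dome_window(config: PhantomConfig):
    """Conservative pixel window (u0, u1, v0, v1) containing the dome."""
    intr = config.intrinsics
    xc, yc = config.torso_center
    a, b = config.torso_semi_axes
    tilt = abs(math.tan(math.radians(config.plane_tilt_deg)))
    h_max = config.baseline_height + config.peak_amplitude
    d_lo = config.bed_distance - h_max - tilt * (abs(yc) + b) - 5.0
    d_hi = config.bed_distance + tilt * (abs(yc) + b) + 5.0

    def bound(coord, f, c, lim):
        lo = min(c + coord * f / d_lo, c + coord * f / d_hi)
        hi = max(c + coord * f / d_lo, c + coord * f / d_hi)
        return lo, hi

    u_lo = min(bound(xc - a, intr.fx, intr.cx, intr.width))
    u_hi = max(bound(xc + a, intr.fx, intr.cx, intr.width))
    v_lo = min(bound(yc - b, intr.fy, intr.cy, intr.height))
    v_hi = max(bound(yc + b, intr.fy, intr.cy, intr.height))
    u0 = max(0, int(math.floor(u_lo)) - 2)
    u1 = min(intr.width, int(math.ceil(u_hi)) + 3)
    v0 = max(0, int(math.floor(v_lo)) - 2)
    v1 = min(intr.height, int(math.ceil(v_hi)) + 3)
    return u0, u1, v0, v1


def _surface_depth(config: PhantomConfig, t: float) -> np.ndarray:
    """Noise-free, unquantised depth grid of bed + dome at time t."""
    intr = config.intrinsics
    bed = _bed_depth(config)
    u0, u1, v0, v1 = _dome_window(config)
    amp = config.baseline_height + config.peak_amplitude * breathing_waveform(
        t, config.rr_true, config.insp_fraction)
    uu, vv = np.meshgrid(np.arange(u0, u1, dtype=float),
                         np.arange(v0, v1, dtype=float))
    bed_w = bed[v0:v1, u0:u1]
    d = bed_w.copy()
    # Depth along a ray satisfies d = bed(y(d)) - amp*b(x(d), y(d)); the dome
    # is far shallower than the camera distance, so 3 fixed-point sweeps
    # converge to well below the 0.1 mm quantisation step.
    for _ in range(3):
        x = (uu - intr.cx) * d / intr.fx
        y = (vv - intr.cy) * d / intr.fy
        d = bed_w - amp * dome_height_field(x, y, config)
    out = bed
    out[v0:v1, u0:u1] = d
    return out


def render_frame(config: PhantomConfig, t: float, rng: np.random.Generator) -> np.ndarray:
    """Depth frame (mm) at time ``t``: surface + Gaussian noise, 0.1 mm steps.

    Noise is added before quantisation; quantisation rounds half to even,
    mimicking a discrete sensor.  Pixels whose ray misses the dome see the
    bare bed plane.
    """
    if not (0 <= t):
        raise ConfigError("t must be non-negative")
    frame = _surface_depth(config, t)
    if config.noise_sigma > 0:
        frame = frame + rng.normal(0.0, config.noise_sigma, frame.shape)
    return np.round(frame * 10.0) / 10.0


def render_intensity(config: PhantomConfig, t: float) -> np.ndarray:
    """IR-like intensity frame in [0, 1]: Lambertian shading of the surface.

    Emitted to exercise detector interfaces that consume an intensity image;
    the built-in variance detector works on depth alone.
    """
    intr = config.intrinsics
    d = _surface_depth(config, t)
    # surface normal z-component from depth gradients in metric units
    gy, gx = np.gradient(-d)
    sx = gx * intr.fx / d
    sy = gy * intr.fy / d
    return 1.0 / np.sqrt(1.0 + sx ** 2 + sy ** 2)


def generate_sequence(config: PhantomConfig):
    """Render a full phantom acquisition.

    Returns
    -------
    sequence : DepthSequence
        ``round(duration * fps)`` quantised depth frames.
    truth : GroundTruth
        Analytic ground truth on the same time base, computed from the
        waveform and the cached dome volume integral only — never through the
        camera pipeline.
    """
    rng = np.random.default_rng(config.seed)
    n = int(round(config.duration * config.fps))
    w, h = config.resolution
    data = np.empty((n, h, w), dtype=np.uint16)
    for k in range(n):
        frame = render_frame(config, k / config.fps, rng)
        data[k] = np.rint(frame * 10.0).astype(np.uint16)

    t = np.arange(n, dtype=float) / config.fps
    vol = config.vt_true * breathing_waveform(t, config.rr_true, config.insp_fraction)
    flow = config.vt_true * breathing_waveform_rate(t, config.rr_true, config.insp_fraction)
    period = 60.0 / config.rr_true
    ti = config.insp_fraction * period
    te = period - ti
    pif_std = config.vt_true * math.pi / (2.0 * ti)
    pef_std = config.vt_true * math.pi / (2.0 * te)
    truth = GroundTruth(
        time=t, true_volume=vol, true_flow=flow,
        true_rr=config.rr_true, true_vt=config.vt_true,
        true_ti=ti, true_te=te, true_ie=te / ti,
        true_pif_standard=pif_std, true_pef_standard=pef_std,
        true_pif_paper=pif_std + pef_std, true_pef_paper=pif_std + pef_std,
    )
    meta = {"synthetic": True, "phantom_config": config.to_dict()}
    seq = DepthSequence(data=data, fps=config.fps, intrinsics=config.intrinsics,
                        meta=meta)
    return seq, truth
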