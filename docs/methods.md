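# Methods

## Problem and approach

`depthresp` estimates respiratory parameters from depth video of a patient
lying supine under a downward-facing depth camera.  Under the standard
single-axis assumption — the patient is motionless apart from breathing, the
camera is roughly perpendicular to the chest, and no occlusion covers the
torso — chest-wall displacement along the optical axis tracks lung volume
change.  The pipeline is:

1. **ROI.** An oriented bounding box (a rotatable rectangle) selects the
   thorax region.  It comes either from configuration or from a
   motion-variance heuristic (below).  Including static bed inside the box is
   harmless: static pixels contribute no volume *variation*.
2. **Per-pixel area.** Each ROI pixel's 3D surface area is computed once,
   from a reference frame, by unprojecting its four immediate neighbours at
   their own depths through the ideal pinhole model and taking the magnitude
   of the cross product of the two central-difference tangent vectors.  For a
   fronto-parallel surface at depth d this is exactly `d²/(fx·fy)`; on tilted
   surfaces the cross product supplies the obliquity factor that a naive
   `Δx·Δy` product misses.  One-sided differences are used at frame borders
   and next to invalid pixels.  The area map is frozen for the whole
   acquisition, which keeps the signal free of frame-to-frame area noise.
3. **Volume series.** Per frame, `V_raw = Σ depth·area / 1000` (mm³ → mL)
   over the ROI.  Pixels that drop out hold their last valid depth (the
   held fraction is reported; above 20% in any frame a quality warning is
   attached).  Because the camera-to-thorax volume shrinks as the lungs
   fill, the series is inverted and zeroed to its first value:
   `v(k) = −(V_raw(k) − V_raw(0))`.
4. **Filtering.** Linear-phase FIR low-pass, windowed-sinc with a Hamming
   window, order 10 (11 taps), cutoff 2 Hz.  2 Hz corresponds to 120
   breaths/min, the physiological ceiling; the same ceiling gives the
   minimum peak distance `round(fps·60/120)` = 15 frames at 30 FPS.  Offline,
   the constant group delay of order/2 = 5 samples is compensated so the
   filtered series is aligned with its timestamps; the first/last 5 samples
   are flagged as the edge region.  A causal streaming mode skips the
   compensation.
5. **Cycles.** Local maxima and minima of the filtered series (minimum
   distance 15 frames; minimum prominence 0.2 of the observed signal range;
   flat extrema resolve to their leftmost sample), paired into complete
   trough→peak→trough cycles.  Consecutive cycles share their boundary
   trough.
6. **Parameters.** RR = cycles / span of complete cycles × 60.  Per-cycle
   Vt = volume at peak minus volume at the cycle-ending trough (the air
   exhaled); the inspiratory variant is available.  Minute ventilation
   = ΣVt / same span × 60, so MEV ≡ mean(Vt)·RR exactly.  Ti, Te and
   I:E = 1 : (mean Te / mean Ti) come from the marker times.  Flow is the
   central-difference derivative of the filtered volume; PIF/PEF are
   reported under two conventions (below).
7. **Comparison (V(k) = D(k)·S).** The classical spatial-average estimate —
   mean ROI depth change times total ROI area — is implemented alongside for
   comparison; it matches the pixel-wise method on near-fronto-parallel
   scenes and degrades when pixel areas vary across the ROI.

## Where the amplitude is read

Cycle markers always come from the filtered series — that is what the filter
is for.  Per-cycle Vt amplitudes, however, are read by default from the
*unfiltered* inverted/zeroed series at those marker positions
(`AnalysisConfig.vt_source`).  The reason is quantitative: the order-10 /
2 Hz filter's passband is not flat at breathing frequencies — measured on
the clean analytic waveform it shaves 0.5% off Vt at 15 breaths/min, 3.5%
at 40 and 6.5% at 55.  Timing-derived quantities (RR, Ti, Te, I:E) are
unaffected by gain, and the unfiltered read costs only the per-sample noise
of the ROI sum (≈0.5–1 mL at the default study conditions), which is
negligible against the attenuation it avoids.  Setting
`vt_source="filtered"` restores the all-filtered behaviour.

## Variance-based ROI detection

The per-pixel standard deviation of depth over the first `detector_frames`
frames (default 300, i.e. 10 s — at least one full cycle down to 6
breaths/min) is thresholded at the 0.98 quantile of its distribution over
valid pixels; the minimum-area rotated rectangle around the largest
8-connected supra-threshold component is returned, with confidence the
fraction of all candidate pixels inside the box.  The detector is
deterministic and defines the generic contract — sequence in,
confidence-bearing box out — behind which a learned detector (e.g. one
trained on infrared frames) can be substituted.

A quantile threshold on a smoothly vanishing motion field necessarily
returns the high-motion *core*: whenever the breathing region covers more
than 2% of the frame, the 0.98 quantile falls inside the region's own
variance distribution.  The pipeline therefore expands the detected box by a
linear margin (`roi_margin`, default 1.5) before rasterising it, recovering
the low-amplitude flanks; the surrounding static scene it also includes adds
no volume variation.  Fixed boxes are used as configured, without expansion.
If detection fails (fewer than 50 candidate pixels — e.g. a static scene)
the pipeline falls back to the fixed box when one is configured, otherwise
raises a detection failure.

Limitation: with a *forced* fixed ROI on a completely static but noisy
scene, the cycle detector will happily segment smoothed sensor noise, since
its prominence threshold is relative to the observed signal range.  The
variance detector is the guard against analysing motion-free scenes.

## Reference frame

The reference frame used for the area map (and for initialising dropout
holds) is the per-pixel temporal mean of the first `reference_frames` frames
(default 30; 1 s at 30 FPS), not a single frame.  The cross-product area is
convex in the neighbour depths, so i.i.d. depth noise of standard deviation
σ on a single frame biases every area upward by roughly
`(σ·fx/(d·√2))² + (σ·fy/(d·√2))²` — about +8% at 640×576, 1.1 mm noise and
1.1 m range, which would propagate directly into every volume.  Averaging K
frames divides the bias by K: below 0.4% at the default 30.  The window is
far shorter than any breathing period and the area map is insensitive to
the phase at which it is taken.

## PIF/PEF conventions

`standard`: PIF is the maximum flow during inspiration, PEF the maximum flow
magnitude during expiration — directly comparable with ventilator readouts.
`paper` (default): flow extrema are detected on the flow signal with the
same minimum-distance rule, and PEF is the *difference* between a flow peak
and the following flow trough, PIF the difference between the preceding
trough and that peak.  On a symmetric breath the difference convention reads
about twice the extremum convention; both are computed, and reports record
which convention they carry.

## The phantom

The synthetic generator renders what the camera sees: a flat bed plane at
`bed_distance` (default 1100 mm; 800 mm for the child preset) and an
elliptical chest dome `h(x,y,t) = (baseline_height + A(t))·b(x,y)` with
`b = cos²(π r/2)` on the normalised elliptical radius r ≤ 1 — a smooth bump
with compact support.  The breathing waveform is a raised-cosine rise over
`insp_fraction` of each cycle (default 0.4, i.e. I:E = 1:1.5) and a
raised-cosine fall over the remainder; `A(t)` is scaled so the peak-to-trough
added volume equals `vt_true` exactly, using the dome's unit-amplitude
volume `a·b·(π/2 − 2/π)` (integrated numerically once and cached).  Per-pixel
depth along each ray solves `d = bed − h(x(d), y(d), t)` by three fixed-point
sweeps (the dome is far shallower than the camera distance, so convergence
is far below the quantisation step).  Gaussian noise (default σ = 1.1 mm, a
depth camera's typical accuracy at ~1 m) is added per pixel, then depths are
quantised to 0.1 mm (round half to even).  Intrinsics follow the 75°×65°
narrow field of view at 640×576 (reduced resolutions keep the same field of
view).  An IR-like Lambertian intensity frame is available to exercise
intensity-based detector plug-ins.

Ground truth (volume and flow waveforms, RR, Vt, Ti/Te, I:E, peak flows
under both conventions) is computed analytically from the waveform and the
cached dome integral — never through the camera model — so recovery tests
compare against an independent oracle.

**Geometry defaults.**  The phantom is required, by design, to recover its
added volume through the noise-free camera path to within 1%
(discretisation only).  Two systematic effects constrain the geometry: the
surface/projected area ratio grows quadratically with the static dome's
slope (the depth×area sum integrates *surface* area, while the true added
volume is a *projected* integral), and the sampling point of each ray slides
toward the dome centre as the surface approaches the camera, contributing
roughly `π·A/(2·bed_distance)` weighted toward the flanks.  Keeping the
static relief gentle — adult semi-axes (240, 170) mm with 5 mm baseline
height, child (120, 95) mm with 5 mm — keeps the combined noise-free bias
below 0.9% at both scales.  This models the breathing-active chest
prominence relative to the surrounding static surface, consistent with the
perpendicular-camera assumption; steeper relief (and a tilted bed, via
`plane_tilt_deg`) is available to study obliquity error, which is exactly
where the spatial-average baseline method falls behind the pixel-wise one.

**What the phantom does not emulate:** occlusions (sheets, cables), gross
patient motion, several people in frame, lateral rib-cage expansion, lens
distortion, and spatially correlated sensor noise.  Passing recovery tests
therefore demonstrates the correctness of the geometry/signal chain under
the method's stated assumptions, not robustness to clinical confounders.

## Numerical choices

- Depths are stored as 16-bit integers in 0.1 mm units; write→read round
  trips are bit-identical, and identical configuration + seed reproduces
  reports byte for byte.
- Pixel coordinates are (column, row), 0-based, pixel centres at integer
  coordinates; box rasterisation is boundary-inclusive on pixel centres.
- Box angles are normalised to (−π/2, π/2]; a box is invariant under a
  quarter turn with swapped extents, which rasterisation tests exploit.
- Filtering pads with edge values before convolving, avoiding the zero-pad
  droop that would distort the first/last cycles; those samples are still
  flagged as the edge region and excluded from waveform-correlation scoring.
- When two extrema of the same kind meet during alternation enforcement,
  the more extreme one wins (leftmost on ties) — exactly symmetric under
  signal negation.
- Flow→volume reconstruction uses trapezoidal integration, the second-order
  companion of the central-difference derivative; a plain cumulative sum
  carries an inherent half-sample shift (≈2.6% RMS at 0.25 Hz) that no
  implementation could avoid.
- Sinusoid-at-sample-rate effects: peak sampling at 30 FPS underestimates a
  raised-cosine peak by <0.05% at the default rates; no interpolation is
  performed.

## Problem sizes used in validation

Recovery experiments run at the reference conditions: 640×576 at 30 FPS,
30 s adult runs (Vt 400 mL) and a 60 s child run (Vt 50 mL), 1.1 mm noise,
variance ROI detection.  Module-level property tests use 160×144 or 320×288
renders of the same phantom, where the geometry invariants (linearity,
distance and off-centre invariance, noise-free recovery) hold identically.

## Known limitations

- Vt is systematically high by ~1% at default conditions (residual
  obliquity + ray-sampling bias); steep chest relief or a tilted camera
  increases it — the `plane_tilt_deg` experiments quantify this.
- Rates near the 120 breaths/min ceiling leave the filter passband; RR
  remains accurate but filtered-amplitude quantities (flows) attenuate.
- The trough-anchored cycle definition drops the boundary cycles of a
  recording that starts or ends exactly at end-expiration; RR is unaffected
  (it uses the span of complete cycles) but short recordings yield one to
  two fewer cycles than `duration·RR/60`.
- A forced fixed ROI on a motion-free noisy scene yields spurious cycles
  (see the ROI section).
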