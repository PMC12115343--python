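# depthresp

Contactless respirometry from depth video.  `depthresp` turns a sequence of
depth frames of a patient's chest — as produced by a ceiling-mounted depth
camera such as an Azure Kinect in NFOV unbinned mode (640×576, 30 FPS) —
into the parameter set a ventilator would display: tidal volume (Vt),
respiratory rate (RR), minute ventilation (MEV), inspiratory/expiratory
times (Ti, Te), I:E ratio, and peak inspiratory/expiratory flows (PIF, PEF).
It is aimed at researchers prototyping non-contact respiratory monitoring
for intensive-care settings, where bedside Vt measurement of spontaneously
breathing patients is otherwise impractical.

## Method

With the patient supine and the camera perpendicular to the chest, lung
volume change appears as chest-wall displacement along the optical axis.
Within an oriented-bounding-box region of interest, every pixel is assigned
a 3D surface area from the pinhole model — neighbours unprojected at their
own depths, cross product of the central-difference tangents; exactly
`d²/(fx·fy)` on a fronto-parallel surface — frozen from a reference frame.
Per frame

    V_raw(k) = Σ_ROI depth(p) · area(p) / 1000        [mL]

and the signal is inverted and zeroed (`v(k) = −(V_raw(k) − V_raw(0))`) so
inspiration rises.  A linear-phase FIR low-pass (order 10, cutoff 2 Hz —
120 breaths/min) with group-delay compensation cleans the series; peaks and
troughs (minimum distance 15 frames at 30 FPS, prominence 0.2 of the signal
range) are paired into trough→peak→trough cycles, from which

    RR  = n_cycles / span · 60
    Vt  = v(peak) − v(end trough)       (per cycle; the air exhaled)
    MEV = Σ Vt / span · 60  ≡  mean(Vt) · RR
    I:E = 1 : (mean Te / mean Ti)

and flow = dv/dt gives PIF/PEF.  The classical spatial-average estimate
`V(k) = D(k)·S` (mean depth change × total ROI area) is included for
comparison.  See `docs/methods.md` for the model details, conventions, and
error analysis.

A synthetic breathing-torso phantom — a bed plane plus a cos² chest dome
driven by a raised-cosine breathing waveform, with per-pixel Gaussian depth
noise (1.1 mm) and 0.1 mm quantisation — provides sequences whose volume,
flow and parameter ground truth is known analytically, so the whole pipeline
is validated by parameter recovery without any camera or patient data.

## Worked example

```sh
depthresp simulate --config adult.json --out run/          # adult.json: {"seed": 1}
depthresp analyze --in run/ --out run/report.json
depthresp evaluate --report run/report.json --truth run/truth.csv
```

which prints:

```
{"frames": 900, "out": "run"}
{"n_cycles": 6, "report": "run/report.json"}
{
 "mev_error_pct": 1.1603230237924436,
 "n_cycles": 6,
 "pearson_r": 0.9999935039195046,
 "rr_error_bpm": 0.0,
 "rr_error_pct": 0.0,
 "vt_mape_pct": 1.1603230237924436,
 "vt_mean_error_pct": 1.1603230237924436
}
```

Reading: on a default adult phantom (Vt 400 mL, RR 15, 30 s), the pipeline
found 6 complete breathing cycles, recovered the respiratory rate exactly,
matched the true volume waveform with Pearson r > 0.999, and estimated
per-cycle tidal volume within about 1.2% of the true 400 mL.  The same
commands with `{"preset": "child", "seed": 1}` exercise the child-scale
setup (Vt 50 mL, RR 40, camera at 800 mm).

The library API mirrors the CLI:

```python
from depthresp import PhantomConfig, generate_sequence, analyze_sequence

sequence, truth = generate_sequence(PhantomConfig.adult(seed=1))
result = analyze_sequence(sequence)
print(result.report.rr, result.report.mean_vt)
```

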