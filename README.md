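# glucolens

Noninvasive glucose sensing with a swelling hydrogel contact lens, modelled
end to end — from binding chemistry to smartphone pixels and back.

A phenylboronic-acid (PBA) functionalised HEMA contact lens binds tear
glucose through reversible boronate–diol complexation. Binding changes the
gel's osmotic pressure, so the lens swells: its thickness tracks the ambient
glucose concentration. On a fixed imaging platform, a red LED shines through
the lens and a smartphone photographs the scene; as the lens thickens its
optical power changes and the red-light spot grows. The measurable signal is
an **area ratio** — red-light disc area over the area of the sample's outer
circle — which increases monotonically with thickness, hence with glucose.

`glucolens` implements that full chain as a tested Python library:

- **Forward model** (`glucolens.sensor_model`) — equilibrium swelling as a
  Hill isotherm `t(G) = t_base + Δt_max · Gⁿ / (K½ⁿ + Gⁿ)` fitted to
  measured lens cross-sections (78, 105, 114 µm at 0, 0.1, 0.6 mM);
  first-order kinetics `1 − e^(−t/τ)` with τ = 15/ln 10 min so a step
  reaches 90 % in 15 min; thick-lens optics via Gullstrand's equation
  `P = P₁ + P₂ − (t/n)·P₁·P₂`; and a strictly monotone thickness → ratio
  map anchored to the platform's three-point calibration
  (0.135, 2.247, 5.343 mm → 0.418, 0.462, 0.549).
- **Synthetic imaging** (`glucolens.synthetic`) — seeded rendering of
  smartphone-like photographs (bright sample rim, central red disc,
  background clutter, illumination gradient, CMOS noise) with pixel-exact
  ground truth, and forward-model-driven monitoring sequences.
- **Segmentation** (`glucolens.segmentation`) — the six-step measurement:
  gray conversion + multi-level (3-class) threshold, morphological cleanup
  (erosion, small-object removal, closing), algebraic least-squares circle
  fit of the sample's outer edge, excess-red (`R − (G+B)/2`) extraction of
  the light disc, and the red-area / outer-circle ratio with QC flags.
- **Calibration & inference** (`glucolens.calibration`) — monotone
  ratio ↔ thickness calibration with exact anchor interpolation and
  bracketed inversion, plus analytic inversion of the Hill isotherm to
  glucose with clinical classification (normal tear glucose 0.1–0.6 mM,
  diabetic > 0.61 mM).
- **Monitoring** (`glucolens.monitoring`) — per-frame ratio traces, robust
  step detection, 90 %-response-time (t90) estimation and soak-cycle
  reversibility statistics.

A thin CLI (`glucolens simulate | segment | calibrate | monitor`) wraps the
library for batch work; `examples/` holds short narrative scripts, one per
capability.

## Worked example

```python
from glucolens import SceneSpec, compute_ratio, render_frame

spec = SceneSpec(red_area_fraction=0.462, noise_sigma=4.0, seed=2)
frame, truth = render_frame(spec)
result = compute_ratio(frame)
print(truth["ratio_pixel"], result.ratio)
```

Running `python examples/render_and_segment.py` prints:

```
scene: 512x512 px, sample radius 200 px, read noise sigma 4.0
ground truth : red radius 135.9 px, pixel ratio 0.4618
measured     : red area 57989 px, reference area 124478 px^2
               fitted sample radius 199.1 px, ratio 0.4659
error        : 0.0040 (qc flags: none)
```

The scene encodes a ground-truth area ratio of 0.462 (the platform's
middle calibration point); the pipeline — which sees only pixels, never the
scene parameters — recovers 0.4659, within the calibration's own
experimental spread. `examples/continuous_monitoring.py` simulates a
0 → 20 mM step and reports the estimated response time:

```
detected step at t = 20 min
baseline ratio 0.4243, plateau ratio 0.5570
estimated t90 = 15.28 min (kinetics were calibrated for 90% response in 15 min)
```

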