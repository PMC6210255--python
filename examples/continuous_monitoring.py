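"""Continuous monitoring: simulate a glucose step and estimate t90.

Renders a short timestamped image sequence for a 0 -> 20 mM step, runs the
per-frame segmentation and the trace analysis, and reports the estimated
90 % response time and phase levels.
"""

from glucolens import (
    GlucoseSchedule,
    SceneSpec,
    analyze_trace,
    default_swelling_params,
    lens_optical_map,
    render_sequence,
)

params = default_swelling_params()
lens = lens_optical_map(params)
schedule = GlucoseSchedule.step(20.0, 0.0, 20.0)
scene = SceneSpec(height=256, width=256, sample_center=(128.0, 128.0),
                  sample_radius=100.0, noise_sigma=4.0, seed=1)

frames, truth = render_sequence(schedule, params, lens, scene,
                                frame_interval=2.0, duration=120.0)
trace = analyze_trace(frames)

print(f"simulated {len(frames)} frames (one every 2 min) for a 0->20 mM "
      f"step at t = 20 min")
print(f"detected step at t = {trace.step_time:.0f} min")
print(f"baseline ratio {trace.baseline:.4f}, plateau ratio {trace.plateau:.4f}")
print(f"estimated t90 = {trace.t90:.2f} min "
      f"(kinetics were calibrated for 90% response in 15 min)")
print(f"flags: {trace.flags or 'none'}")
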