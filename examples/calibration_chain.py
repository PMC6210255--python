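"""Calibration and inference: measured ratio -> thickness -> glucose class.

Fits the demonstration calibration, then runs the full inference chain with
a lens-regime calibration spanning the physiological swelling range.
"""

import numpy as np

from glucolens import (
    default_swelling_params,
    equilibrium_thickness,
    fit_calibration,
    lens_optical_map,
    ratio_to_thickness,
)
from glucolens.calibration import estimate_from_ratio
from glucolens.sensor_model import PDMS_CALIBRATION_PAIRS

fit = fit_calibration(PDMS_CALIBRATION_PAIRS)
print("Demonstration calibration (thickness mm -> ratio):")
for t, r in PDMS_CALIBRATION_PAIRS:
    print(f"  {t:5.3f} mm -> {fit.predict(t):.3f} (measured {r})")
print(f"inverting ratio 0.50 -> {ratio_to_thickness(0.50, fit):.3f} mm")

params = default_swelling_params()
lens = lens_optical_map(params)
coeffs = np.asarray(lens.ratio_coeffs)[::-1]
lens_pairs = [(t, float(np.polyval(coeffs, t)))
              for t in np.linspace(*lens.thickness_range, 3)]
lens_fit = fit_calibration(lens_pairs)

print("\nFull chain on lens-regime measurements "
      "(ratio -> thickness -> glucose):")
for glucose in (0.05, 0.3, 0.45, 0.8):
    t_um = equilibrium_thickness(glucose, params)
    ratio = lens_fit.predict(t_um / 1000.0)
    est = estimate_from_ratio(ratio, lens_fit, params)
    print(f"  true {glucose:4.2f} mM -> ratio {ratio:.4f} -> "
          f"{est.glucose:6.4f} mM [{est.class_label}]")
print("\nNormal tear glucose spans 0.1-0.6 mM; levels above 0.61 mM are "
      "classified diabetic.")
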