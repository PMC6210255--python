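"""Forward model: glucose -> lens thickness -> optical power and ratio.

Evaluates the fitted swelling isotherm, the first-order response kinetics
and the thick-lens optics for a few tear-relevant glucose levels.
"""

from glucolens import (
    default_optical_map,
    default_swelling_params,
    equilibrium_thickness,
    gullstrand_power,
    lens_optical_map,
    response_fraction,
    thickness_to_ratio,
)

params = default_swelling_params()
print("Swelling isotherm fitted to the measured thickness midpoints:")
print(f"  t_base = {params.t_base:.1f} um, dt_max = {params.dt_max:.2f} um, "
      f"k_half = {params.k_half:.4f} mM, tau = {params.tau:.3f} min")

print("\nEquilibrium thickness vs glucose (um):")
for glucose in (0.0, 0.1, 0.3, 0.6, 1.0, 20.0):
    t = equilibrium_thickness(glucose, params)
    print(f"  {glucose:5.1f} mM -> {t:7.2f} um")

print("\nStep-response completion (fraction of the thickness change):")
for minutes in (5, 10, 15, 30):
    print(f"  {minutes:3d} min -> {response_fraction(minutes, params):.3f}")
print("  (the default time constant places 90% completion at 15 min)")

lens = lens_optical_map(params)
print("\nThick-lens (Gullstrand) power and red-area ratio across the "
      "swelling range:")
for glucose in (0.0, 0.3, 20.0):
    t_mm = equilibrium_thickness(glucose, params) / 1000.0
    power = gullstrand_power(lens, t_mm)
    ratio = thickness_to_ratio(lens, t_mm)
    print(f"  {glucose:5.1f} mM: t = {t_mm*1000:6.1f} um, "
          f"P = {power:.3f} D, ratio = {ratio:.4f}")
print("(thicker lens -> lower total power -> larger red-light spot)")

pdms = default_optical_map()
print("\nDemonstration calibration (mm-scale samples):")
for t_mm in (0.135, 2.247, 5.343):
    print(f"  {t_mm:5.3f} mm -> ratio {thickness_to_ratio(pdms, t_mm):.3f}")
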