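# Methods

This note records the scientific model behind `glucolens`, the choices made
where the underlying experiment leaves the design open, and what the
synthetic benchmark does and does not establish.

## Sensing model

**Swelling isotherm.** Reversible 1:1 boronate–diol binding motivates a
Hill (default n = 1, i.e. Langmuir) form for the equilibrium lens
thickness:

    t(G) = t_base + Δt_max · Gⁿ / (K½ⁿ + Gⁿ)

The three parameters are fitted to the midpoints of the measured lens
cross-section ranges — 78 µm at 0 mM (range 70–86), 105 µm at 0.1 mM
(98–112), 114 µm at 0.6 mM (91–137). With G₁ = 0 and x = Gⁿ the fit is
closed-form (two linear equations in K½ⁿ and Δt_max), giving
t_base = 78 µm, Δt_max = 38.57 µm, K½ = 0.0429 mM. The small K½ means the
lens is already near saturation at the top of the normal tear range, which
is what the bench data show: most of the swelling happens below 0.1 mM.

**Kinetics.** Swelling and shrinking share a single first-order time
constant, τ = 15/ln 10 ≈ 6.514 min, chosen so that a concentration step
completes 90 % of its thickness change in exactly 15 min — the one kinetic
datum available. Traces under piecewise-constant glucose schedules are
evaluated analytically per interval (no ODE integration error), and are
continuous across schedule breakpoints.

**Optics.** Total optical power follows Gullstrand's thick-lens equation
P = P₁ + P₂ − (t/n)·P₁·P₂ (t in metres). Surface powers default to
P₁ = P₂ = 50 D and the refractive index to 1.43 (typical HEMA hydrogel);
these are configurable and, deliberately, do not drive the pipeline — the
quantitative link from power to spot size on this platform is not known, so
an **empirical monotone thickness → ratio map** stands in:

- *Demonstration regime* (`default_optical_map`): the quadratic through the
  platform's three calibration pairs (0.135, 2.247, 5.343 mm →
  0.418, 0.462, 0.549), valid on 0.05–6 mm. The parabola's vertex lies far
  outside this range, so the interpolant is strictly increasing; a
  shape-preserving (PCHIP) fallback exists for anchor sets where the
  quadratic is not monotone.
- *Lens regime* (`lens_optical_map`): the calibration spans millimetre-thick
  samples, while the lens itself swells over ~0.078–0.117 mm, where the
  quadratic is essentially flat (Δratio ≈ 7·10⁻⁴ — far below what any image
  measurement resolves). Monitoring simulations therefore use a **linear**
  map over [t_base, t_base + Δt_max] spanning the same ratio interval
  (0.418–0.549). Linearity is the physically natural thin-sample limit:
  Gullstrand power is exactly linear in t. It also makes the ratio response
  to a glucose step exactly first-order, so the simulated t90 is the
  kinetic τ's, not an artefact of map curvature.

## Synthetic scene

The generator emulates the fixed imaging platform: a dark stage with a
linear illumination gradient (amplitude 30 of 255 across the frame),
a circular sample whose outer edge appears as a bright neutral rim
(12 px wide, intensity 210), a concentric red-light disc whose area
fraction is the ground-truth ratio (peak red 250, luminance chosen close to
the rim's so both land in the brightest histogram class), a handful of
mid-brightness reddish clutter blobs outside the sample (the "scatter"
that the multi-level threshold is meant to reject), and sensor noise —
additive Gaussian read noise (default σ = 4), optional Poisson shot noise —
applied last and clipped to 8 bits.

Geometry is pixel-centre based (a pixel belongs to a disc if its centre is
inside), so ground-truth areas are exact integer censuses. Layer edges are
softened by a 2 px Gaussian; the rim and red disc are composited jointly
with the locally brighter layer winning, because sequentially alpha-blending
two coincident soft edges (rim and disc at full coverage) would shift the
apparent luminance edge outward by about a pixel. Noise is driven entirely
by the scene seed; clutter placement has its own fixed sub-seed so
noise-free renders are bit-identical across seeds. Sequence rendering
derives per-frame seeds by splitting the master seed.

What the scene does **not** emulate: perspective and lens blur, RAW sensor
response, specular highlights, non-circular samples, motion, and the true
radial profile of the red spot (a soft-edged top-hat is an idealisation).
Passing the benchmark therefore shows the pipeline is correct and robust on
this geometry and noise model — not that it handles arbitrary bench photos.

## Segmentation

The six-step measurement, with the open details fixed as follows (all in
`SegmentationConfig`):

1. Luminance grayscale; **two-threshold (3-class) Otsu**; foreground = the
   brightest class. Rasters with < 3 distinct values fall back to single
   Otsu, which makes binarisation idempotent. A constant image raises
   "no foreground".
2. Erosion with a radius-2 disc, removal of components below 64 px,
   closing with a radius-2 disc.
3. Reference circle: holes are filled so a closed rim counts as the whole
   sample, the largest region wins (ties: centroid nearest frame centre),
   and its outer edge pixels are fitted by algebraic least squares
   (scikit-image's `CircleModel`). The fitted radius gets +0.5 px (edge
   pixel centres sit about half a pixel inside the true circle) plus the
   erosion radius (erosion shifts the outer boundary inward by the
   structuring-element radius). Relative RMS residual above 2 % flags
   "non-circular reference". The denominator is the fitted circle's area
   πr², which is robust to rim gaps.
4. Red area: excess-red R − (G+B)/2 clipped at zero, single-level Otsu over
   the nonzero values, 1 px closing to consolidate the rasterisation
   speckle ring at the disc's soft edge, restriction to the reference
   interior, largest component's pixel count.

Failures at any stage yield a flagged result (NaN ratio) rather than an
exception, so one bad frame does not abort a monitoring run. The pipeline
never reads generator metadata — it accepts pixel arrays only.

Accuracy, measured against generator ground truth: ≤ 0.015 absolute ratio
error over ratios 0.1–1.0 and radii 100–200 px (noise-free), and ratio
scatter σ ≈ 2·10⁻⁴ at read noise σ = 8 — comfortably inside the bench
calibration's own ±0.007–0.030 spread.

## Calibration and inference

Up to three (thickness, ratio) pairs are interpolated exactly (quadratic,
PCHIP fallback); more are fitted by isotonic regression followed by a PCHIP
through the fitted values. Inversion brackets the root on the calibrated
range and solves to machine tolerance; ratios within 0.01 outside the
calibrated ratio range clamp to the nearer end, farther ones raise
"outside calibration". The Hill isotherm inverts analytically; thickness at
or below baseline maps to 0 mM (flagged), at or above saturation is
rejected. Classification: diabetic strictly above 0.61 mM, normal within
0.1–0.6 mM, below-range under 0.1 mM; the published gap (0.6, 0.61] is
labelled `indeterminate` rather than silently assigned.

The chain ratio → thickness → glucose is this package's composition; the
bench work calibrated ratio vs (PDMS) thickness and thickness vs glucose
separately, and the mm-scale demonstration pairs ship as a demonstration
fixture, not as a lens-regime calibration.

## Monitoring

Per-frame ratios are median-filtered (window 3). Steps are runs of
same-sign frame-to-frame increments exceeding 3× the robust (MAD-based)
increment spread. For the first up-step: baseline = median of pre-step
frames, plateau = median of the last quarter of the phase, and t90 = the
linearly interpolated first crossing of baseline + 0.9·(plateau − baseline),
measured from step onset. Cycles pair each up-step with the next down-step;
reversibility is the absolute difference between the end-of-cycle level and
the initial baseline. Default simulation cadence is one frame per 2 min
(≥ 7 points on a 15 min rise); the three-cycle protocol (2 h per soak
phase) is sampled at 5 min in the acceptance checks to keep runtimes in
seconds-to-minutes on one CPU.

Because 20 mM lies far beyond the isotherm's dynamic range, monitoring
statistics stay in ratio units; mapping a saturated trace to glucose would
be meaningless and is only done on request through the calibration module.

## Numerical choices and limitations

- Tolerances: anchors interpolate to < 10⁻⁹; calibration round trips hold
  to 10⁻⁶ mm; isotherm inversion to 10⁻⁶ mM; circle-fit residual flag at
  2 % relative RMS.
- Degenerate inputs (constant images, empty masks, gray frames, < 3 edge
  points, non-monotone calibrations, empty schedules) raise typed errors or
  set QC flags; they are covered by tests.
- The shared swelling/shrinking τ is an assumption; the bench cycles look
  symmetric but no shrink-time constant was published.
- The lens-regime ratio span (0.418–0.549) is a modelling convention tied
  to the demonstration calibration, not a lens measurement; absolute ratio
  levels in monitoring simulations carry that convention.
- Boundary classifications at exactly 0.6/0.61 mM are floating-point
  sensitive by nature; the indeterminate band exists to make that explicit.
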