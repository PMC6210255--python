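"""Ratio ↔ thickness calibration and thickness → glucose inference.

The imaging platform is calibrated with samples of known thickness: each
yields a red-area/reference ratio, and a strictly increasing interpolant
through the (thickness, ratio) pairs becomes the instrument function.  Up to
three pairs are interpolated exactly (quadratic, with a shape-preserving
PCHIP fallback if the parabola is not monotone on the range); more pairs are
fitted by monotone least squares (isotonic regression followed by a PCHIP
through the fitted values).  Measured ratios are inverted to thickness by
bracketed root finding on the interpolant.

The second link — thickness to glucose — inverts the Hill swelling isotherm
analytically and classifies the estimate against tear-fluid boundaries:
normal tear glucose spans 0.1–0.6 mM and diabetic levels exceed 0.61 mM;
the printed gap (0.6, 0.61] is labelled ``indeterminate``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq
from sklearn.isotonic import IsotonicRegression

from .sensor_model import SwellingParams

__all__ = [
    "NORMAL_TEAR_GLUCOSE_MM",
    "DIABETIC_TEAR_GLUCOSE_MM",
    "CalibrationFit",
    "GlucoseEstimate",
    "fit_calibration",
    "ratio_to_thickness",
    "thickness_to_glucose",
    "estimate_from_ratio",
]

#: Normal tear glucose range (mM).
NORMAL_TEAR_GLUCOSE_MM = (0.1, 0.6)
#: Tear glucose strictly above this is classified diabetic (mM).
DIABETIC_TEAR_GLUCOSE_MM = 0.61


@dataclass
class CalibrationFit:
    """Strictly increasing thickness (mm) → ratio interpolant."""

    anchor_pairs: tuple  # ((thickness mm, ratio), ...)
    kind: str  # "quadratic" | "pchip" | "monotone-lsq"
    coefficients: tuple  # poly coeffs (ascending) or fitted node ratios
    residuals: tuple  # per-anchor fit error
    valid_range: tuple  # (min, max) thickness (mm)
    _predict: object = field(default=None, repr=False, compare=False)

    def predict(self, thickness_mm):
        """Ratio predicted at a thickness (mm) inside ``valid_range``."""
        fn = self._ensure_predictor()
        out = fn(np.asarray(thickness_mm, dtype=float))
        return float(out) if np.isscalar(thickness_mm) else np.asarray(out)

    def _ensure_predictor(self):
        if self._predict is None:
            object.__setattr__(self, "_predict", _build_predictor(self))
        return self._predict

    @property
    def ratio_range(self) -> tuple:
        lo, hi = self.valid_range
        return self.predict(lo), self.predict(hi)

    def to_dict(self) -> dict:
        return {
            "anchor_pairs": [list(p) for p in self.anchor_pairs],
            "kind": self.kind,
            "coefficients": list(self.coefficients),
            "residuals": list(self.residuals),
            "valid_range": list(self.valid_range),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationFit":
        return cls(anchor_pairs=tuple(tuple(p) for p in d["anchor_pairs"]),
                   kind=d["kind"], coefficients=tuple(d["coefficients"]),
                   residuals=tuple(d["residuals"]),
                   valid_range=tuple(d["valid_range"]))


def _build_predictor(fit: CalibrationFit):
    if fit.kind == "quadratic":
        coeffs = np.asarray(fit.coefficients)[::-1]
        return lambda t: np.polyval(coeffs, t)
    t = np.array([p[0] for p in fit.anchor_pairs])
    y = np.asarray(fit.coefficients, dtype=float)
    interp = PchipInterpolator(t, y)
    return interp


def _strictly_increasing(fn, lo, hi, n=1024) -> bool:
    v = fn(np.linspace(lo, hi, n))
    return bool(np.all(np.diff(v) > 0))


def fit_calibration(pairs) -> CalibrationFit:
    """Fit the monotone calibration interpolant to (thickness mm, ratio) pairs.

    Two or three pairs are interpolated exactly; with three pairs a quadratic
    is tried first and replaced by a shape-preserving (PCHIP) interpolant if
    it is not strictly increasing between the anchors.  More than three pairs
    are fitted by monotone least squares.  Ratios that do not increase
    strictly with thickness are rejected.
    """
    pts = sorted((float(t), float(r)) for t, r in pairs)
    if len(pts) < 2:
        raise ValueError("need at least two calibration pairs")
    t = np.array([p[0] for p in pts])
    r = np.array([p[1] for p in pts])
    if np.any(np.diff(t) <= 0):
        raise ValueError("thickness values must be distinct")
    if np.any(np.diff(r) <= 0):
        raise ValueError("calibration not monotone")
    valid_range = (t[0], t[-1])

    if len(pts) <= 3:
        coeffs = np.polyfit(t, r, len(pts) - 1)[::-1]
        fit = CalibrationFit(anchor_pairs=tuple(pts), kind="quadratic",
                             coefficients=tuple(coeffs), residuals=(),
                             valid_range=valid_range)
        if _strictly_increasing(fit._ensure_predictor(), *valid_range):
            resid = fit.predict(t) - r
            fit.residuals = tuple(resid)
            return fit
        # monotone shape-preserving fallback through the same anchors
        fit = CalibrationFit(anchor_pairs=tuple(pts), kind="pchip",
                             coefficients=tuple(r), residuals=(),
                             valid_range=valid_range)
        fit.residuals = tuple(fit.predict(t) - r)
        return fit

    iso = IsotonicRegression(increasing=True)
    y = iso.fit_transform(t, r)
    # PCHIP needs strictly increasing nodes; nudge exact ties apart
    y = np.maximum.accumulate(y + np.arange(len(y)) * 1e-12)
    fit = CalibrationFit(anchor_pairs=tuple(pts), kind="monotone-lsq",
                         coefficients=tuple(y), residuals=(),
                         valid_range=valid_range)
    fit.residuals = tuple(fit.predict(t) - r)
    return fit


def ratio_to_thickness(ratio: float, fit: CalibrationFit,
                       outside_tol: float = 0.01) -> float:
    """Invert the calibration: thickness (mm) whose predicted ratio matches.

    Ratios within ``outside_tol`` outside the fitted ratio range are clamped
    to the nearer range end; ratios farther outside raise
    ``ValueError("outside calibration")``.  The root is bracketed and solved
    to |Δratio| < 1e-8.
    """
    lo_r, hi_r = fit.ratio_range
    if ratio < lo_r - outside_tol or ratio > hi_r + outside_tol:
        raise ValueError("outside calibration")
    ratio = min(max(ratio, lo_r), hi_r)
    lo_t, hi_t = fit.valid_range
    if ratio <= lo_r:
        return float(lo_t)
    if ratio >= hi_r:
        return float(hi_t)
    return float(brentq(lambda t: fit.predict(t) - ratio, lo_t, hi_t,
                        xtol=1e-12, rtol=8.9e-16))


@dataclass(frozen=True)
class GlucoseEstimate:
    """Inverted glucose estimate with its clinical classification."""

    thickness: float  # µm
    glucose: float  # mM
    class_label: str  # below-range | normal | indeterminate | diabetic
    inversion_flags: tuple = ()


def _classify(glucose: float):
    lo, hi = NORMAL_TEAR_GLUCOSE_MM
    if glucose > DIABETIC_TEAR_GLUCOSE_MM:
        return "diabetic", ()
    if glucose > hi:
        return "indeterminate", ("between-normal-and-diabetic-bounds",)
    if glucose >= lo:
        return "normal", ()
    return "below-range", ()


def thickness_to_glucose(thickness_um: float, params: SwellingParams,
                         tolerance_um: float = 1.0) -> GlucoseEstimate:
    """Invert the swelling isotherm: glucose (mM) from lens thickness (µm).

    The Hill isotherm inverts analytically:
    ``G = k_half · (x / (1 - x))^(1/n)`` with ``x = (t - t_base)/dt_max``.
    Thickness at or below the zero-glucose baseline maps to 0 mM (flagged);
    thickness at or beyond full saturation is rejected.
    """
    flags = []
    if thickness_um < params.t_base - tolerance_um:
        raise ValueError("thickness below isotherm baseline")
    if thickness_um >= params.t_base + params.dt_max:
        raise ValueError("beyond isotherm saturation")
    if thickness_um <= params.t_base:
        glucose = 0.0
        flags.append("at-or-below-baseline")
    else:
        x = (thickness_um - params.t_base) / params.dt_max
        glucose = params.k_half * (x / (1.0 - x)) ** (1.0 / params.hill_n)
    label, extra = _classify(glucose)
    return GlucoseEstimate(thickness=float(thickness_um), glucose=float(glucose),
                           class_label=label,
                           inversion_flags=tuple(flags) + extra)


def estimate_from_ratio(ratio: float, fit: CalibrationFit,
                        params: SwellingParams) -> GlucoseEstimate:
    """Full chain: measured ratio → thickness (via the calibration fit,
    mm → µm) → glucose and class."""
    thickness_mm = ratio_to_thickness(ratio, fit)
    return thickness_to_glucose(thickness_mm * 1000.0, params)
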