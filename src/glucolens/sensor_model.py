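"""Forward model: glucose → lens thickness → optical power and red-area ratio.

The sensing lens is a phenylboronic-acid (PBA) HEMA hydrogel whose volume
increases with glucose through reversible 1:1 boronate–diol binding.  The
model has three layers:

1. A Hill isotherm (default ``hill_n = 1``, i.e. Langmuir) for the
   *equilibrium* thickness as a function of glucose concentration, fitted to
   the midpoints of the measured thickness ranges at 0, 0.1 and 0.6 mM.
2. First-order kinetics with a single time constant ``tau`` shared between
   swelling and shrinking; the default ``tau = 15 / ln 10`` min places the
   90 % response exactly at 15 min.
3. Optics: the thick-lens (Gullstrand) power ``P = P1 + P2 - (t/n)·P1·P2``
   and an empirical strictly-monotone map from thickness to the red-area /
   reference area ratio that the image pipeline measures.  The default map is
   a quadratic interpolant through the three measured PDMS calibration pairs;
   :func:`lens_optical_map` provides a linear map rescaled onto the contact
   lens swelling span (Gullstrand power is exactly linear in thickness, so a
   linear ratio map is the natural thin-sample limit).

Units: thickness in µm inside :class:`SwellingParams`, in mm for the optical
operations (converted to metres inside the Gullstrand formula); times in
minutes; glucose in mM.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "DEFAULT_TAU_MIN",
    "SWELLING_CALIBRATION_POINTS",
    "PDMS_CALIBRATION_PAIRS",
    "ExtrapolationWarning",
    "SwellingParams",
    "OpticalMap",
    "GlucoseSchedule",
    "equilibrium_thickness",
    "response_fraction",
    "thickness_trace",
    "gullstrand_power",
    "thickness_to_ratio",
    "fit_swelling_params",
    "default_swelling_params",
    "default_optical_map",
    "lens_optical_map",
]

#: Time constant (min) such that the step response reaches 90 % at 15 min.
DEFAULT_TAU_MIN = 15.0 / math.log(10.0)

#: (glucose mM, equilibrium thickness µm) — midpoints of the measured
#: cross-section ranges 70–86, 98–112 and 91–137 µm of the PBA-HEMA lens.
SWELLING_CALIBRATION_POINTS = ((0.0, 78.0), (0.1, 105.0), (0.6, 114.0))

#: (thickness mm, red-area/reference ratio) measured on PDMS slabs of known
#: thickness; the demonstration calibration of the imaging platform.
PDMS_CALIBRATION_PAIRS = ((0.135, 0.418), (2.247, 0.462), (5.343, 0.549))


class ExtrapolationWarning(UserWarning):
    """Raised when a thickness falls outside the calibrated map range."""


@dataclass(frozen=True)
class SwellingParams:
    """Isotherm and kinetics constants of the swelling hydrogel.

    Equilibrium thickness: ``t_base + dt_max * G**n / (k_half**n + G**n)``.
    """

    t_base: float  # thickness at 0 mM glucose (µm)
    dt_max: float  # maximal additional swelling (µm)
    k_half: float  # glucose at half-maximal swelling (mM)
    hill_n: float = 1.0  # Hill cooperativity
    tau: float = DEFAULT_TAU_MIN  # first-order response time constant (min)

    def __post_init__(self) -> None:
        if self.t_base <= 0:
            raise ValueError("t_base must be positive")
        if self.dt_max < 0:
            raise ValueError("dt_max must be non-negative")
        if self.k_half <= 0:
            raise ValueError("k_half must be positive")
        if self.hill_n <= 0:
            raise ValueError("hill_n must be positive")
        if self.tau <= 0:
            raise ValueError("tau must be positive")

    def to_dict(self) -> dict:
        return {
            "t_base": self.t_base,
            "dt_max": self.dt_max,
            "k_half": self.k_half,
            "hill_n": self.hill_n,
            "tau": self.tau,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SwellingParams":
        return cls(**d)


def _poly_strictly_increasing(coeffs: np.ndarray, lo: float, hi: float, n: int = 1024) -> bool:
    t = np.linspace(lo, hi, n)
    v = np.polyval(coeffs[::-1], t)
    return bool(np.all(np.diff(v) > 0))


@dataclass(frozen=True)
class OpticalMap:
    """Thickness → optical power and thickness → red-area-ratio maps.

    ``ratio_coeffs`` are ascending polynomial coefficients ``c0 + c1·t + …``
    with thickness ``t`` in mm; the polynomial must be strictly increasing and
    map ``thickness_range`` into (0, 1].
    """

    p1: float = 50.0  # front-surface power (D)
    p2: float = 50.0  # back-surface power (D)
    n_lens: float = 1.43  # refractive index (HEMA hydrogel)
    ratio_coeffs: tuple = ()
    thickness_range: tuple = (0.05, 6.0)  # supported thickness (mm)

    def __post_init__(self) -> None:
        if self.n_lens <= 1:
            raise ValueError("n_lens must exceed 1")
        lo, hi = self.thickness_range
        if not lo < hi:
            raise ValueError("thickness_range must be increasing")
        c = np.asarray(self.ratio_coeffs, dtype=float)
        if c.size == 0:
            raise ValueError("ratio_coeffs must be non-empty")
        if not _poly_strictly_increasing(c, lo, hi):
            raise ValueError("thickness→ratio map must be strictly increasing "
                             "on the supported range")
        ends = np.polyval(c[::-1], [lo, hi])
        if ends[0] <= 0 or ends[1] > 1:
            raise ValueError("thickness→ratio map must map into (0, 1]")

    @property
    def ratio_range(self) -> tuple:
        lo, hi = self.thickness_range
        c = np.asarray(self.ratio_coeffs, dtype=float)[::-1]
        return float(np.polyval(c, lo)), float(np.polyval(c, hi))

    def to_dict(self) -> dict:
        return {
            "p1": self.p1,
            "p2": self.p2,
            "n_lens": self.n_lens,
            "ratio_coeffs": list(self.ratio_coeffs),
            "thickness_range": list(self.thickness_range),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "OpticalMap":
        d = dict(d)
        d["ratio_coeffs"] = tuple(d.get("ratio_coeffs", ()))
        d["thickness_range"] = tuple(d.get("thickness_range", (0.05, 6.0)))
        return cls(**d)


@dataclass(frozen=True)
class GlucoseSchedule:
    """Piecewise-constant glucose programme.

    ``levels[i]`` holds on ``[breakpoints[i], breakpoints[i+1])``; the last
    level extends indefinitely.
    """

    breakpoints: tuple  # ordered times (min)
    levels: tuple  # glucose per interval (mM)

    def __post_init__(self) -> None:
        bp = np.asarray(self.breakpoints, dtype=float)
        lv = np.asarray(self.levels, dtype=float)
        if bp.size == 0:
            raise ValueError("schedule must be non-empty")
        if bp.size != lv.size:
            raise ValueError("breakpoints and levels must have equal length")
        if bp.size > 1 and not np.all(np.diff(bp) > 0):
            raise ValueError("breakpoints must be strictly increasing")
        if np.any(lv < 0):
            raise ValueError("glucose levels must be non-negative")
        object.__setattr__(self, "breakpoints", tuple(float(t) for t in bp))
        object.__setattr__(self, "levels", tuple(float(g) for g in lv))

    def level_at(self, time_min: float) -> float:
        """Glucose level at a given time (min)."""
        bp = np.asarray(self.breakpoints)
        if time_min < bp[0]:
            raise ValueError("time precedes schedule start")
        idx = int(np.searchsorted(bp, time_min, side="right") - 1)
        return self.levels[idx]

    @classmethod
    def step(cls, t_step: float, low: float, high: float,
             t_start: float = 0.0) -> "GlucoseSchedule":
        """Single step from ``low`` to ``high`` at ``t_step``."""
        return cls((t_start, t_step), (low, high))

    @classmethod
    def cycles(cls, n_cycles: int, phase_min: float, low: float, high: float,
               lead_in_min: float = 0.0) -> "GlucoseSchedule":
        """``n_cycles`` alternating low→high→low soak cycles.

        Each phase lasts ``phase_min`` minutes (the bench protocol soaked the
        lens 2 h per phase); an optional low lead-in precedes the first cycle.
        """
        times = [0.0]
        levels = [low]
        t = lead_in_min
        for _ in range(n_cycles):
            times.extend([t, t + phase_min])
            levels.extend([high, low])
            t += 2 * phase_min
        if lead_in_min == 0.0:
            times, levels = times[1:], levels[1:]
        return cls(tuple(times), tuple(levels))

    @property
    def end_time(self) -> float:
        return self.breakpoints[-1]

    def to_csv(self, path) -> None:
        pd.DataFrame({"time_min": self.breakpoints,
                      "glucose_mM": self.levels}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "GlucoseSchedule":
        df = pd.read_csv(path)
        missing = {"time_min", "glucose_mM"} - set(df.columns)
        if missing:
            raise ValueError(f"schedule CSV missing columns: {sorted(missing)}")
        return cls(tuple(df["time_min"]), tuple(df["glucose_mM"]))


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def equilibrium_thickness(glucose, params: SwellingParams):
    """Equilibrium lens thickness (µm) at a glucose concentration (mM).

    Hill isotherm ``t_base + dt_max · G^n / (k_half^n + G^n)``; strictly
    increasing in glucose whenever ``dt_max > 0``.
    """
    g = np.asarray(glucose, dtype=float)
    if np.any(g < 0):
        raise ValueError("glucose must be non-negative")
    gn = np.power(g, params.hill_n)
    t = params.t_base + params.dt_max * gn / (params.k_half ** params.hill_n + gn)
    return float(t) if np.isscalar(glucose) else t


def response_fraction(elapsed, params: SwellingParams):
    """Fraction of a step change completed after ``elapsed`` minutes.

    First-order kinetics: ``1 - exp(-elapsed / tau)``, in [0, 1).
    """
    e = np.asarray(elapsed, dtype=float)
    if np.any(e < 0):
        raise ValueError("elapsed time must be non-negative")
    f = 1.0 - np.exp(-e / params.tau)
    return float(f) if np.isscalar(elapsed) else f


def thickness_trace(schedule: GlucoseSchedule, params: SwellingParams,
                    dt: float, duration: float | None = None,
                    t0: float | None = None):
    """Thickness time series under a piecewise-constant glucose programme.

    Within each constant-glucose interval the thickness relaxes exponentially
    (time constant ``tau``) from its value at the interval start toward the
    equilibrium thickness of that level; the trace is continuous across
    breakpoints.  Evaluation is exact (analytic per interval), not an ODE
    integration.

    Parameters
    ----------
    dt : sampling interval (min), > 0.
    duration : total trace length (min) from the schedule start; default
        extends 120 min past the last breakpoint.
    t0 : initial thickness (µm); default is the equilibrium thickness of the
        first level.

    Returns
    -------
    (times, thickness) : two 1-D arrays (min, µm).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    bp = np.asarray(schedule.breakpoints)
    eq = equilibrium_thickness(np.asarray(schedule.levels), params)
    eq = np.atleast_1d(eq)
    if duration is None:
        duration = (bp[-1] - bp[0]) + 120.0
    # thickness at each breakpoint, propagated analytically
    v = np.empty(bp.size)
    v[0] = eq[0] if t0 is None else float(t0)
    for i in range(bp.size - 1):
        span = bp[i + 1] - bp[i]
        v[i + 1] = eq[i] + (v[i] - eq[i]) * math.exp(-span / params.tau)
    times = bp[0] + np.arange(0.0, duration + dt * 0.5, dt)
    idx = np.clip(np.searchsorted(bp, times, side="right") - 1, 0, bp.size - 1)
    thick = eq[idx] + (v[idx] - eq[idx]) * np.exp(-(times - bp[idx]) / params.tau)
    return times, thick


def gullstrand_power(optical_map: OpticalMap, thickness_mm: float) -> float:
    """Total optical power (diopter) of a thick lens.

    ``P = P1 + P2 - (t/n)·P1·P2`` with the thickness converted to metres.
    """
    if thickness_mm < 0:
        raise ValueError("thickness must be non-negative")
    t_m = thickness_mm / 1000.0
    return optical_map.p1 + optical_map.p2 - (t_m / optical_map.n_lens) * optical_map.p1 * optical_map.p2


def thickness_to_ratio(optical_map: OpticalMap, thickness_mm):
    """Red-area / reference ratio predicted for a sample thickness (mm).

    Evaluates the map's strictly increasing polynomial.  Thicknesses outside
    ``thickness_range`` raise :class:`ExtrapolationWarning` and are clamped to
    the range ends.
    """
    t = np.asarray(thickness_mm, dtype=float)
    lo, hi = optical_map.thickness_range
    if np.any(t < lo) or np.any(t > hi):
        warnings.warn(
            f"thickness outside calibrated range [{lo}, {hi}] mm; clamped",
            ExtrapolationWarning, stacklevel=2)
        t = np.clip(t, lo, hi)
    r = np.polyval(np.asarray(optical_map.ratio_coeffs)[::-1], t)
    return float(r) if np.isscalar(thickness_mm) else r


# ---------------------------------------------------------------------------
# fitting and defaults
# ---------------------------------------------------------------------------

def fit_swelling_params(points=SWELLING_CALIBRATION_POINTS, hill_n: float = 1.0,
                        tau: float = DEFAULT_TAU_MIN) -> SwellingParams:
    """Fit the Hill isotherm to (glucose mM, thickness µm) points.

    With exactly three points whose first glucose value is 0 the solution is
    closed-form: ``t_base`` is the zero-glucose thickness, and with
    ``x = G^n`` the two remaining equations are linear in ``k_half^n`` and
    ``dt_max``.  Other inputs are fitted by nonlinear least squares.
    """
    pts = sorted((float(g), float(t)) for g, t in points)
    if len(pts) < 3:
        raise ValueError("need at least three calibration points")
    g = np.array([p[0] for p in pts])
    t = np.array([p[1] for p in pts])
    if len(pts) == 3 and g[0] == 0.0:
        t_base = t[0]
        a2, a3 = t[1] - t_base, t[2] - t_base
        x2, x3 = g[1] ** hill_n, g[2] ** hill_n
        denom = a2 * x3 - a3 * x2
        if denom <= 0 or a3 <= a2 or a2 <= 0:
            raise ValueError("points are not consistent with a saturating "
                             "increasing isotherm")
        kn = x2 * x3 * (a3 - a2) / denom
        dt_max = a2 * (kn + x2) / x2
        return SwellingParams(t_base=t_base, dt_max=dt_max,
                              k_half=kn ** (1.0 / hill_n), hill_n=hill_n, tau=tau)

    def residuals(p):
        t_base, dt_max, k_half = p
        gn = np.power(g, hill_n)
        return t_base + dt_max * gn / (k_half ** hill_n + gn) - t

    x0 = (t[0], t[-1] - t[0], max(np.median(g), 1e-3))
    sol = least_squares(residuals, x0,
                        bounds=([1e-6, 0.0, 1e-9], [np.inf] * 3))
    return SwellingParams(t_base=sol.x[0], dt_max=sol.x[1], k_half=sol.x[2],
                          hill_n=hill_n, tau=tau)


def default_swelling_params() -> SwellingParams:
    """Isotherm fitted to the measured thickness-range midpoints, default tau."""
    return fit_swelling_params(SWELLING_CALIBRATION_POINTS)


def _quadratic_through(pairs) -> tuple:
    """Ascending coefficients of the parabola through three (x, y) pairs."""
    x = np.array([p[0] for p in pairs])
    y = np.array([p[1] for p in pairs])
    c = np.polyfit(x, y, 2)  # descending
    return tuple(c[::-1])


def default_optical_map() -> OpticalMap:
    """Quadratic ratio map interpolating the three PDMS calibration pairs."""
    return OpticalMap(ratio_coeffs=_quadratic_through(PDMS_CALIBRATION_PAIRS),
                      thickness_range=(0.05, 6.0))


def lens_optical_map(params: SwellingParams,
                     ratio_span: tuple = (0.418, 0.549)) -> OpticalMap:
    """Linear ratio map over the contact-lens swelling span.

    The PDMS demonstration calibration spans millimetre thicknesses; the lens
    itself swells over ~0.08–0.12 mm, where that quadratic is essentially
    flat.  In the thin-sample regime the Gullstrand power is exactly linear in
    thickness, so this map is a straight line from ``t_base`` to
    ``t_base + dt_max`` (converted to mm) covering ``ratio_span`` — by default
    the same ratio interval as the PDMS demonstration.
    """
    lo_t = params.t_base / 1000.0
    hi_t = (params.t_base + params.dt_max) / 1000.0
    r0, r1 = ratio_span
    slope = (r1 - r0) / (hi_t - lo_t)
    return OpticalMap(ratio_coeffs=(r0 - slope * lo_t, slope),
                      thickness_range=(lo_t, hi_t))
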