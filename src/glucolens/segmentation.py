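"""Six-step segmentation extracting the red-area / reference ratio.

The measurement chain mirrors the bench image-processing procedure: the RGB
photograph is (I) converted to gray and binarised with a multi-level
(three-class) histogram threshold whose brightest class is foreground,
(II–IV) cleaned by erosion, small-object removal and morphological closing,
(V) the outer circle of the sample is recovered by an algebraic least-squares
circle fit to the edge of the largest region, and the red-light disc by an
excess-red (``R - (G+B)/2``) threshold restricted to that circle, and (VI)
the red area is divided by the fitted outer-circle area to yield the ratio
that tracks sample thickness.

Design points the bench procedure leaves open (threshold variant, structuring
element sizes, the red-enhancement formula, fitted-circle versus raw-pixel
reference area) are fixed here and isolated in :class:`SegmentationConfig`.
Holes are filled before the largest region is selected, so a closed bright
rim stands for the whole sample and its *outer* edge is fitted; because
erosion shifts that edge inward by the structuring-element radius,
:func:`compute_ratio` passes the radius back as ``boundary_offset`` to
de-bias the fitted reference circle.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import binary_fill_holes
from skimage.color import rgb2gray
from skimage.filters import threshold_multiotsu, threshold_otsu
from skimage.measure import CircleModel, label, regionprops
from skimage.morphology import closing, disk, erosion, remove_small_objects

from .synthetic import ImageFrame

__all__ = [
    "SegmentationConfig",
    "SegmentationError",
    "ReferenceCircle",
    "SegmentationResult",
    "fit_circle",
    "to_gray_binary",
    "clean_binary",
    "find_reference_circle",
    "find_red_area",
    "compute_ratio",
    "segment_images",
]


class SegmentationError(RuntimeError):
    """A pipeline stage could not produce a usable result."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"{stage}: {message}")


@dataclass(frozen=True)
class SegmentationConfig:
    """Tunable parameters of the segmentation pipeline."""

    erosion_radius: int = 2  # disc structuring element for erosion (px)
    closing_radius: int = 2  # disc structuring element for closing (px)
    min_object_px: int = 64  # connected components smaller than this are dropped
    circle_residual_tol: float = 0.02  # relative RMS residual flag threshold
    ratio_hard_max: float = 1.05  # ratios above this are flagged out of bounds

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SegmentationConfig":
        return cls(**d)


@dataclass(frozen=True)
class ReferenceCircle:
    """Fitted outer circle of the sample: the ratio denominator."""

    center: tuple  # (row, col), px
    radius: float  # px
    area: float  # π·radius², px²
    rms_residual: float  # relative RMS of |distance − radius| / radius
    flags: tuple = ()


@dataclass
class SegmentationResult:
    """Red area, reference area, their ratio and diagnostics for one frame."""

    red_area: float
    reference_area: float
    ratio: float
    sample_center: tuple
    sample_radius: float
    red_mask: np.ndarray | None = None
    reference_mask: np.ndarray | None = None
    qc_flags: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return np.isfinite(self.ratio) and self.reference_area > 0

    def to_dict(self) -> dict:
        return {
            "red_area": self.red_area,
            "reference_area": self.reference_area,
            "ratio": self.ratio,
            "sample_center": list(self.sample_center),
            "sample_radius": self.sample_radius,
            "qc_flags": list(self.qc_flags),
        }


def _as_pixels(frame) -> np.ndarray:
    px = frame.pixels if isinstance(frame, ImageFrame) else np.asarray(frame)
    if px.ndim != 3 or px.shape[2] != 3:
        raise ValueError("expected an RGB frame")
    return px


def to_gray_binary(frame) -> np.ndarray:
    """Gray conversion and multi-level threshold binarisation (step I).

    Luminance grayscale, then a two-threshold (three-class) inter-class-
    variance threshold; the brightest class is foreground.  Rasters with
    fewer than three distinct gray levels fall back to a single threshold,
    which makes the operation idempotent on already-binary images.
    """
    px = _as_pixels(frame)
    gray = rgb2gray(px) * 255.0
    values = np.unique(gray)
    if values.size < 2 or values[-1] - values[0] < 1e-9:
        raise SegmentationError("to_gray_binary", "no foreground")
    if values.size < 3:
        thr = threshold_otsu(gray)
        return gray > thr
    thresholds = threshold_multiotsu(gray, classes=3)
    return gray > thresholds[-1]


def clean_binary(mask: np.ndarray, min_object_px: int = 64,
                 erosion_radius: int = 2, closing_radius: int = 2):
    """Morphological cleanup (steps II–IV): erode, drop specks, close.

    Returns ``(cleaned mask, qc flags)``.  The output is contained in the
    dilation of the input (all three steps are non-expanding beyond it) and
    never has more connected components than the input.
    """
    mask = np.asarray(mask, dtype=bool)
    flags = []
    out = erosion(mask, disk(erosion_radius)) if erosion_radius > 0 else mask
    out = remove_small_objects(out, max_size=min_object_px - 1)
    if closing_radius > 0:
        out = closing(out, disk(closing_radius))
    if not out.any():
        flags.append("empty-after-clean")
    return out, flags


def fit_circle(points: np.ndarray):
    """Algebraic least-squares circle through ≥ 3 (row, col) points.

    Returns ``(center (row, col), radius, relative RMS residual)``.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise SegmentationError("fit_circle", "need at least 3 edge points")
    model = CircleModel.from_estimate(pts)
    if not model:
        raise SegmentationError("fit_circle", "degenerate point set")
    (cr, cc), radius = model.center, model.radius
    dists = np.hypot(pts[:, 0] - cr, pts[:, 1] - cc)
    rms = float(np.sqrt(np.mean((dists - radius) ** 2)) / radius)
    return (float(cr), float(cc)), float(radius), rms


def find_reference_circle(mask: np.ndarray, boundary_offset: float = 0.0,
                          residual_tol: float = 0.02) -> ReferenceCircle:
    """Fit the sample's outer circle from a cleaned binary mask (step V).

    Holes are filled so that a closed rim annulus counts as the full sample
    region; the largest region wins (ties broken by centroid distance to the
    frame centre), its outer edge pixels are extracted and a circle fitted by
    algebraic least squares.  ``boundary_offset`` is added to the fitted
    radius (plus a half-pixel rasterisation term) before computing the
    reference area π·r²; pass the erosion radius of the preceding cleanup to
    undo its inward shift.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise SegmentationError("find_reference_circle", "empty mask")
    filled = binary_fill_holes(mask)
    labels = label(filled)
    props = regionprops(labels)
    sizes = np.array([p.area for p in props])
    best = sizes.max()
    candidates = [p for p in props if p.area >= best - 0.5]
    if len(candidates) > 1:  # tie → nearest the frame centre
        fc = (mask.shape[0] / 2.0, mask.shape[1] / 2.0)
        candidates.sort(key=lambda p: np.hypot(p.centroid[0] - fc[0],
                                               p.centroid[1] - fc[1]))
    comp = labels == candidates[0].label
    edge = comp & ~erosion(comp, disk(1))
    points = np.argwhere(edge)
    center, radius, rms = fit_circle(points)
    flags = []
    if rms > residual_tol:
        flags.append("non-circular reference")
    # edge pixel centres sit about half a pixel inside the true circle
    radius = radius + 0.5 + boundary_offset
    return ReferenceCircle(center=center, radius=radius,
                           area=float(np.pi * radius**2),
                           rms_residual=rms, flags=tuple(flags))


def find_red_area(frame, reference: ReferenceCircle):
    """Excess-red segmentation of the light disc inside the reference circle.

    The excess-red map ``R - (G+B)/2`` (clipped at zero) is thresholded with
    a single-level histogram threshold over its nonzero values, restricted to
    the reference circle interior, and the largest surviving component is the
    red area.  A 1-px closing consolidates the speckle ring that 8-bit
    rounding produces where the disc's soft edge crosses the threshold, so
    the component count is not inflated by rasterisation.  Returns
    ``(red_mask, red_area, qc flags)``.
    """
    px = _as_pixels(frame).astype(float)
    excess = np.clip(px[:, :, 0] - (px[:, :, 1] + px[:, :, 2]) / 2.0, 0.0, None)
    nonzero = excess[excess > 0]
    if nonzero.size == 0:
        raise SegmentationError("find_red_area", "no red area")
    if np.ptp(nonzero) < 1e-9:
        thr = nonzero.min() / 2.0
    else:
        thr = threshold_otsu(nonzero)
    red = closing(excess > thr, disk(1))

    rr, cc = np.ogrid[: red.shape[0], : red.shape[1]]
    inside = ((rr - reference.center[0]) ** 2 + (cc - reference.center[1]) ** 2
              <= reference.radius**2)
    red &= inside
    if not red.any():
        raise SegmentationError("find_red_area", "no red area")
    labels = label(red)
    props = regionprops(labels)
    props.sort(key=lambda p: (-p.area,
                              np.hypot(p.centroid[0] - reference.center[0],
                                       p.centroid[1] - reference.center[1])))
    red_mask = labels == props[0].label
    return red_mask, int(red_mask.sum()), []


def compute_ratio(frame, config: SegmentationConfig | None = None) -> SegmentationResult:
    """Run the full pipeline on one frame (step VI).

    Deterministic for a fixed frame.  Stage errors do not raise: they yield a
    failed result (NaN ratio) whose ``qc_flags`` name the failing stage.
    The function sees pixels only — never generator ground truth.
    """
    cfg = config or SegmentationConfig()
    px = _as_pixels(frame)
    flags: list = []
    try:
        binary = to_gray_binary(px)
        cleaned, fl = clean_binary(binary, min_object_px=cfg.min_object_px,
                                   erosion_radius=cfg.erosion_radius,
                                   closing_radius=cfg.closing_radius)
        flags += fl
        if not cleaned.any():
            raise SegmentationError("clean_binary", "empty mask")
        reference = find_reference_circle(cleaned,
                                          boundary_offset=cfg.erosion_radius,
                                          residual_tol=cfg.circle_residual_tol)
        flags += list(reference.flags)
        red_mask, red_area, fl = find_red_area(px, reference)
        flags += fl
    except SegmentationError as err:
        flags.append(f"error:{err.stage}:{err}")
        return SegmentationResult(red_area=0.0, reference_area=0.0,
                                  ratio=float("nan"), sample_center=(np.nan, np.nan),
                                  sample_radius=float("nan"), qc_flags=flags)

    ratio = red_area / reference.area
    if ratio > 1.0:
        flags.append("ratio-above-one")
    if ratio > cfg.ratio_hard_max:
        flags.append("ratio-out-of-bounds")
    rr, cc = np.ogrid[: px.shape[0], : px.shape[1]]
    ref_mask = ((rr - reference.center[0]) ** 2 + (cc - reference.center[1]) ** 2
                <= reference.radius**2)
    return SegmentationResult(red_area=float(red_area),
                              reference_area=reference.area,
                              ratio=float(ratio),
                              sample_center=reference.center,
                              sample_radius=reference.radius,
                              red_mask=red_mask, reference_mask=ref_mask,
                              qc_flags=flags)


def segment_images(paths, config: SegmentationConfig | None = None) -> pd.DataFrame:
    """Batch segmentation: one CSV-ready row per image file."""
    rows = []
    for path in paths:
        result = compute_ratio(ImageFrame.from_png(path), config)
        rows.append({
            "filename": str(path),
            "red_area": result.red_area,
            "reference_area": result.reference_area,
            "ratio": result.ratio,
            "flags": ";".join(result.qc_flags),
        })
    return pd.DataFrame(rows)
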