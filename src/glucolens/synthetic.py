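"""Seeded synthetic smartphone photographs of the illuminated lens sample.

The rendered scene emulates the bench platform: a circular sample sitting on
a dark stage, its outer edge lit as a bright rim (the "red reference"), a
concentric red-light disc whose area fraction encodes sample thickness,
mid-brightness background clutter (stray red-light scatter the multi-level
threshold is meant to reject), a linear illumination gradient, and CMOS-style
noise (additive Gaussian read noise, optional Poisson shot noise).

Geometry uses 0-based (row, col) coordinates with pixel centres at integers;
a pixel belongs to a disc when its centre lies within the radius.  Layer
edges are softened with a small Gaussian before compositing.  Pixel-counted
ground-truth areas accompany every rendered frame so the segmentation
pipeline can be scored without ever reading scene metadata.

Noise is driven solely by ``SceneSpec.seed``; clutter placement has its own
fixed ``clutter_seed`` so that noise-free renders are bit-identical across
seeds.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .sensor_model import (
    GlucoseSchedule,
    OpticalMap,
    SwellingParams,
    thickness_to_ratio,
    thickness_trace,
)

__all__ = ["SceneSpec", "ImageFrame", "render_frame", "render_sequence",
           "write_sequence", "read_sequence"]


@dataclass(frozen=True)
class SceneSpec:
    """Parametric description of one rendered sensor photograph."""

    height: int = 512
    width: int = 512
    sample_center: tuple = (256.0, 256.0)  # (row, col), px
    sample_radius: float = 200.0  # px
    red_area_fraction: float = 0.418  # ground-truth red/reference area ratio
    edge_brightness: int = 210  # rim intensity (neutral gray)
    red_peak: int = 250  # peak red-channel intensity of the light disc
    background_level: int = 20  # mean background intensity
    illumination_tilt: int = 30  # linear gradient amplitude across frame
    noise_sigma: float = 4.0  # Gaussian read noise SD (intensity units)
    shot_noise: bool = False
    seed: int = 0  # drives noise only
    rim_width: float = 12.0  # radial extent of the bright rim, px
    edge_softness: float = 2.0  # Gaussian sigma for soft layer edges, px
    clutter_blobs: int = 6  # number of stray mid-brightness blobs
    clutter_seed: int = 7  # fixed so noise-free frames ignore `seed`

    def __post_init__(self) -> None:
        if not 0 < self.red_area_fraction <= 1:
            raise ValueError("red_area_fraction must lie in (0, 1]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        r, c = self.sample_center
        pad = self.sample_radius
        if (r - pad < 0 or c - pad < 0
                or r + pad > self.height - 1 or c + pad > self.width - 1):
            raise ValueError("sample disc exceeds the frame")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sample_center"] = list(self.sample_center)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SceneSpec":
        d = dict(d)
        if "sample_center" in d:
            d["sample_center"] = tuple(d["sample_center"])
        return cls(**d)


@dataclass
class ImageFrame:
    """An 8-bit RGB raster with an optional acquisition time (min)."""

    pixels: np.ndarray
    timestamp: float | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError("pixels must be height × width × 3")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ValueError("channel values must lie in [0, 255]")
            px = px.astype(np.uint8)
        self.pixels = px

    def to_png(self, path) -> None:
        iio.imwrite(Path(path), self.pixels)

    @classmethod
    def from_png(cls, path, timestamp: float | None = None) -> "ImageFrame":
        px = iio.imread(Path(path))
        if px.ndim == 3 and px.shape[2] == 4:  # drop alpha
            px = px[:, :, :3]
        return cls(pixels=px, timestamp=timestamp)


def _disc_mask(shape, center, radius) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def _soft_alpha(mask: np.ndarray, sigma: float) -> np.ndarray:
    m = mask.astype(float)
    return gaussian_filter(m, sigma) if sigma > 0 else m


def _composite_disc(img, center, radius, color, sigma) -> None:
    """Soft-edged disc blended in place, restricted to its bounding box."""
    h, w = img.shape[:2]
    pad = radius + 4 * sigma + 2
    r0 = max(int(np.floor(center[0] - pad)), 0)
    r1 = min(int(np.ceil(center[0] + pad)) + 1, h)
    c0 = max(int(np.floor(center[1] - pad)), 0)
    c1 = min(int(np.ceil(center[1] + pad)) + 1, w)
    if r0 >= r1 or c0 >= c1:
        return
    rr, cc = np.ogrid[r0:r1, c0:c1]
    mask = ((rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2)
    alpha = gaussian_filter(mask.astype(float), sigma) if sigma > 0 else mask.astype(float)
    for ch in range(3):
        img[r0:r1, c0:c1, ch] *= 1 - alpha
        img[r0:r1, c0:c1, ch] += color[ch] * alpha




def render_frame(spec: SceneSpec, timestamp: float | None = None):
    """Render one photograph; returns ``(ImageFrame, ground_truth dict)``.

    The ground truth holds the analytic radii and the pixel-centre-counted
    red and reference areas; ``ratio_pixel`` is their quotient and tracks
    ``red_area_fraction`` to rasterisation error.
    """
    h, w = spec.height, spec.width
    center = spec.sample_center
    r_sample = spec.sample_radius
    r_red = r_sample * np.sqrt(spec.red_area_fraction)

    # background with linear illumination gradient across the columns
    cols = np.arange(w, dtype=float)
    bg_row = spec.background_level + spec.illumination_tilt * (cols / max(w - 1, 1) - 0.5)
    img = np.repeat(np.clip(bg_row, 0, 255)[None, :], h, axis=0)
    img = np.stack([img] * 3, axis=2)

    # stray mid-brightness clutter outside the sample (fixed sub-seed)
    crng = np.random.default_rng(spec.clutter_seed)
    clutter_color = (150, 90, 70)  # dim reddish scatter, mid luminance
    placed = 0
    attempts = 0
    while placed < spec.clutter_blobs and attempts < 200:
        attempts += 1
        rr = crng.uniform(0, h - 1)
        cc = crng.uniform(0, w - 1)
        rad = crng.uniform(3, 8)
        d = np.hypot(rr - center[0], cc - center[1])
        if d < r_sample + spec.rim_width + rad + 6:
            continue
        _composite_disc(img, (rr, cc), rad, clutter_color, spec.edge_softness)
        placed += 1

    # rim (annulus just inside the sample edge, the "red reference") and the
    # red-light disc are both luminous structures: composite them jointly,
    # the locally brighter layer winning, so that coincident soft edges at
    # full coverage do not stack into an outward-shifted luminance edge
    gr, gc = np.ogrid[:h, :w]
    d2 = (gr - center[0]) ** 2 + (gc - center[1]) ** 2
    rim_mask = (d2 <= r_sample**2) & (d2 > max(r_sample - spec.rim_width, 0.0) ** 2)
    a_rim = _soft_alpha(rim_mask, spec.edge_softness)
    a_red = _soft_alpha(d2 <= r_red**2, spec.edge_softness)
    alpha = np.maximum(a_rim, a_red)
    eb = spec.edge_brightness
    rp = spec.red_peak
    rim_rgb = np.array([eb, eb, eb], dtype=float)
    red_rgb = np.array([rp, 0.80 * rp, 0.55 * rp])
    use_red = (a_red >= a_rim)[:, :, None]
    color = np.where(use_red, red_rgb[None, None, :], rim_rgb[None, None, :])
    img *= 1 - alpha[:, :, None]
    img += color * alpha[:, :, None]

    # sensor noise, applied last
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    if spec.shot_noise:
        img = rng.poisson(np.clip(img, 0, None)).astype(float)
    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, size=img.shape)
    frame = ImageFrame(np.clip(np.rint(img), 0, 255).astype(np.uint8), timestamp)

    red_area_px = int(_disc_mask((h, w), center, r_red).sum())
    ref_area_px = int(_disc_mask((h, w), center, r_sample).sum())
    ground_truth = {
        "sample_center": center,
        "sample_radius_px": float(r_sample),
        "red_radius_px": float(r_red),
        "red_area_px": red_area_px,
        "reference_area_px": ref_area_px,
        "ratio_pixel": red_area_px / ref_area_px,
        "ratio_true": spec.red_area_fraction,
    }
    return frame, ground_truth


def render_sequence(schedule: GlucoseSchedule, params: SwellingParams,
                    optical_map: OpticalMap, base_spec: SceneSpec,
                    frame_interval: float, duration: float | None = None):
    """Render a timestamped monitoring sequence driven by the forward model.

    Per frame, the lens thickness comes from :func:`thickness_trace`, the
    red-area fraction from :func:`thickness_to_ratio`, and the raster from
    :func:`render_frame` under a per-frame seed derived by splitting the base
    spec's master seed.

    Returns
    -------
    (frames, ground_truth) : list of :class:`ImageFrame` and a DataFrame with
        columns ``time_min, glucose_mM, thickness_um, true_ratio``.
    """
    if frame_interval <= 0:
        raise ValueError("frame_interval must be positive")
    times, thick = thickness_trace(schedule, params, dt=frame_interval,
                                   duration=duration)
    ratios = np.asarray(thickness_to_ratio(optical_map, thick / 1000.0))
    glucose = np.array([schedule.level_at(t) for t in times])

    children = np.random.SeedSequence(base_spec.seed).spawn(len(times))
    frames = []
    for i, (t, ratio) in enumerate(zip(times, ratios)):
        seed_i = int(children[i].generate_state(1)[0] % (2**31))
        spec_i = dataclasses.replace(base_spec, red_area_fraction=float(ratio),
                                     seed=seed_i)
        frame, _ = render_frame(spec_i, timestamp=float(t))
        frames.append(frame)
    ground_truth = pd.DataFrame({
        "time_min": times,
        "glucose_mM": glucose,
        "thickness_um": thick,
        "true_ratio": ratios,
    })
    return frames, ground_truth


def write_sequence(out_dir, frames, ground_truth: pd.DataFrame | None = None) -> pd.DataFrame:
    """Write numbered PNGs plus ``frames.csv`` (filename, time_min).

    Also writes ``ground_truth.csv`` when a ground-truth table is given.
    Returns the frame index table.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, frame in enumerate(frames):
        name = f"frame_{i:04d}.png"
        frame.to_png(out / name)
        rows.append({"filename": name, "time_min": frame.timestamp})
    index = pd.DataFrame(rows)
    index.to_csv(out / "frames.csv", index=False)
    if ground_truth is not None:
        ground_truth.to_csv(out / "ground_truth.csv", index=False)
    return index


def read_sequence(in_dir):
    """Load a ``frames.csv``-indexed PNG sequence as timestamped frames."""
    in_dir = Path(in_dir)
    index = pd.read_csv(in_dir / "frames.csv")
    return [ImageFrame.from_png(in_dir / row.filename, timestamp=float(row.time_min))
            for row in index.itertuples()]
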