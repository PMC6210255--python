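"""Continuous-monitoring analysis of timestamped frame sequences.

Each frame is reduced to its red-area/reference ratio; the ratio trace is
median-smoothed and scanned for concentration steps.  For the first upward
step the 90 % response time (t90) is estimated: baseline is the median of the
pre-step frames, plateau the median of the last quarter of the post-step
phase, and t90 the first (linearly interpolated) crossing of
``baseline + 0.9 · (plateau − baseline)`` measured from the step onset.
Soak cycles (an up-step followed by a down-step) are summarised by their
baseline, plateau and return-to-baseline deviation — the reversibility
statistic of repeated glucose exposure.

Glucose is far above the physiological tear range in the bench soak
protocol, so the analysis stays in ratio units; conversion to glucose is the
calibration module's job and only meaningful inside the isotherm's dynamic
range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter

from .segmentation import SegmentationConfig, compute_ratio

__all__ = ["MonitoringTrace", "StepEvent", "analyze_trace", "analyze_ratio_trace"]


@dataclass(frozen=True)
class StepEvent:
    """A detected monotone jump in the smoothed ratio trace."""

    index: int  # frame index of the last pre-step sample
    time: float  # min
    direction: int  # +1 up, -1 down


@dataclass
class MonitoringTrace:
    """Per-frame ratio trace with step-response and cycle statistics."""

    times: np.ndarray  # min
    ratios: np.ndarray
    smoothed: np.ndarray
    t90: float | None  # min after the first up-step; None if no step
    step_time: float | None  # onset of the first up-step (min)
    baseline: float | None  # pre-step median ratio
    plateau: float | None  # post-step plateau median ratio
    events: list = field(default_factory=list)
    cycle_stats: list = field(default_factory=list)
    flags: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_min": self.times, "ratio": self.ratios,
                             "smoothed": self.smoothed})

    def to_dict(self) -> dict:
        return {
            "t90": self.t90,
            "step_time": self.step_time,
            "baseline": self.baseline,
            "plateau": self.plateau,
            "n_frames": int(len(self.times)),
            "events": [{"index": e.index, "time": e.time,
                        "direction": e.direction} for e in self.events],
            "cycle_stats": list(self.cycle_stats),
            "flags": list(self.flags),
        }


def _detect_steps(times: np.ndarray, smoothed: np.ndarray,
                  noise_factor: float = 3.0):
    """Sign-consistent runs of super-threshold increments → step events.

    The per-increment threshold is ``noise_factor`` times the robust
    (MAD-based) spread of the frame-to-frame increments; consecutive large
    increments of one sign collapse into a single event anchored at the last
    quiet frame.  A run only counts as a step if its cumulative amplitude is
    well clear of the noise floor (6× the robust increment spread) *and* a
    substantial fraction (20 %) of the trace's total range — a single noisy
    increment sneaking past the 3σ gate is not a concentration step.
    """
    d = np.diff(smoothed)
    if d.size == 0:
        return []
    mad = np.median(np.abs(d - np.median(d)))
    noise = 1.4826 * mad
    threshold = max(noise_factor * noise, 1e-6)
    min_amplitude = max(2 * noise_factor * noise, 0.2 * np.ptp(smoothed), 1e-6)
    events = []
    i = 0
    while i < d.size:
        if abs(d[i]) > threshold:
            sign = 1 if d[i] > 0 else -1
            start = i
            while i < d.size and abs(d[i]) > threshold and (d[i] > 0) == (sign > 0):
                i += 1
            amplitude = smoothed[i] - smoothed[start]
            if abs(amplitude) >= min_amplitude:
                events.append(StepEvent(index=start, time=float(times[start]),
                                        direction=sign))
        else:
            i += 1
    return events


def _phase_plateau(segment: np.ndarray) -> float:
    k = max(1, segment.size // 4)
    return float(np.median(segment[-k:]))


def analyze_ratio_trace(times, ratios, flags=None) -> MonitoringTrace:
    """Step/cycle analysis of a numeric ratio trace (the core of
    :func:`analyze_trace`, usable directly on ground-truth tables)."""
    times = np.asarray(times, dtype=float)
    ratios = np.asarray(ratios, dtype=float)
    flags = list(flags or [])
    if times.size < 3:
        raise ValueError("need at least three frames")
    if np.any(np.diff(times) <= 0):
        raise ValueError("timestamps must be strictly increasing")

    smoothed = median_filter(ratios, size=3, mode="nearest")
    events = _detect_steps(times, smoothed)
    trace = MonitoringTrace(times=times, ratios=ratios, smoothed=smoothed,
                            t90=None, step_time=None, baseline=None,
                            plateau=None, events=events, flags=flags)
    if not events:
        trace.flags.append("no step")
        return trace

    bounds = [e.index for e in events] + [smoothed.size - 1]
    initial_baseline = float(np.median(smoothed[: events[0].index + 1]))

    # t90 of the first upward step
    up = next((k for k, e in enumerate(events) if e.direction > 0), None)
    if up is not None:
        e = events[up]
        seg_end = bounds[up + 1]
        baseline = float(np.median(smoothed[: e.index + 1])) if up == 0 else \
            float(np.median(smoothed[bounds[up - 1] + 1: e.index + 1]))
        plateau = _phase_plateau(smoothed[e.index + 1: seg_end + 1])
        level = baseline + 0.9 * (plateau - baseline)
        trace.step_time = e.time
        trace.baseline = baseline
        trace.plateau = plateau
        for j in range(e.index + 1, seg_end + 1):
            if smoothed[j] >= level:
                t_prev, t_cur = times[j - 1], times[j]
                v_prev, v_cur = smoothed[j - 1], smoothed[j]
                if v_cur > v_prev:
                    t_cross = t_prev + (level - v_prev) / (v_cur - v_prev) * (t_cur - t_prev)
                else:
                    t_cross = t_cur
                trace.t90 = float(t_cross - e.time)
                break
        if trace.t90 is None:
            trace.flags.append("t90-not-reached")

    # cycles: each up-step paired with the next down-step
    k = 0
    while k < len(events):
        if events[k].direction > 0:
            down = next((m for m in range(k + 1, len(events))
                         if events[m].direction < 0), None)
            if down is None:
                trace.flags.append("unpaired-up-step")
                break
            up_seg = smoothed[events[k].index + 1: bounds[k + 1] + 1]
            down_seg = smoothed[events[down].index + 1: bounds[down + 1] + 1]
            pre = smoothed[bounds[k - 1] + 1: events[k].index + 1] if k > 0 \
                else smoothed[: events[k].index + 1]
            trace.cycle_stats.append({
                "baseline": float(np.median(pre)),
                "plateau": _phase_plateau(up_seg),
                "return_deviation": abs(_phase_plateau(down_seg) - initial_baseline),
            })
            k = down + 1
        else:
            k += 1
    return trace


def analyze_trace(frames, config: SegmentationConfig | None = None) -> MonitoringTrace:
    """Segment every timestamped frame and analyse the resulting ratio trace.

    Frames whose segmentation fails are dropped with a flag; at least three
    usable frames with strictly increasing timestamps are required.
    """
    if len(frames) < 3:
        raise ValueError("need at least three frames")
    times, ratios, flags = [], [], []
    for i, frame in enumerate(frames):
        if frame.timestamp is None:
            raise ValueError("frames must carry timestamps")
        result = compute_ratio(frame, config)
        if not result.ok:
            flags.append(f"frame-dropped:{i}")
            continue
        times.append(frame.timestamp)
        ratios.append(result.ratio)
    if len(times) < 3:
        raise ValueError("fewer than three frames segmented successfully")
    return analyze_ratio_trace(times, ratios, flags)
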