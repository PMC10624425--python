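"""Full-field visual stimulus protocols.

Four protocols drive the whole pipeline: an OFF-ON-OFF contrast inversion
followed by a sinusoid whose amplitude ramps from 0 to 100% contrast, a
series of full-contrast sinusoids at fixed temporal frequencies, a binary
random ("white-noise") flicker, and a moving-grating direction protocol.
Contrast is dimensionless in [-1, +1] with 0 the mean luminance.  All
generators are deterministic given their parameters and seed.

Gratings are never rasterized: every grating analysis downstream uses only
per-direction mean rates, so the direction protocol carries a trial schedule
of direction labels and the grating geometry as metadata.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Segment",
    "StimulusTrace",
    "DirectionProtocol",
    "make_contrast_ramp_flicker",
    "make_frequency_series",
    "make_random_flicker",
    "make_direction_protocol",
    "DIRECTIONS_8",
]

#: the 8 equally spaced grating directions, radians in [0, 2*pi)
DIRECTIONS_8 = tuple(k * math.pi / 4.0 for k in range(8))


@dataclass(frozen=True)
class Segment:
    """Half-open labelled interval [start_s, end_s) of a stimulus trace."""

    label: str
    trial: int
    start_s: float
    end_s: float

    def duration(self) -> float:
        return self.end_s - self.start_s


@dataclass
class StimulusTrace:
    """Sampled full-field contrast waveform with segment bookkeeping.

    Attributes
    ----------
    times:
        Frame start times in seconds, uniformly spaced at ``1/frame_rate``.
        Frame ``i`` covers ``[times[i], times[i] + 1/frame_rate)``.
    contrast:
        Contrast per frame, in [-1, +1].
    frame_rate:
        Frames per second.
    segments:
        Ordered, non-overlapping labelled intervals covering the trace.
    """

    times: np.ndarray
    contrast: np.ndarray
    frame_rate: float
    segments: list[Segment] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.contrast = np.asarray(self.contrast, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.contrast.shape:
            raise ValueError("times and contrast must be 1-D arrays of equal length")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        dt = np.diff(self.times)
        if dt.size and (np.any(dt <= 0) or np.max(np.abs(dt - 1.0 / self.frame_rate)) > 1e-9):
            raise ValueError("times must increase with constant step 1/frame_rate")
        if np.any(np.abs(self.contrast) > 1.0 + 1e-12):
            raise ValueError("contrast values must lie in [-1, 1]")
        end = self.times[-1] + 1.0 / self.frame_rate if self.times.size else 0.0
        prev = self.times[0] if self.times.size else 0.0
        for seg in self.segments:
            if seg.start_s < prev - 1e-9 or seg.end_s > end + 1e-9 or seg.end_s <= seg.start_s:
                raise ValueError(f"segment {seg} overlaps, is empty, or exceeds the trace span")
            prev = seg.end_s

    # -- basic geometry -------------------------------------------------

    @property
    def frame_interval(self) -> float:
        return 1.0 / self.frame_rate

    @property
    def n_frames(self) -> int:
        return int(self.times.size)

    @property
    def duration(self) -> float:
        return self.n_frames * self.frame_interval

    def frame_index(self, t: float) -> int:
        """Index of the frame containing time ``t``."""
        return int(np.floor((t - self.times[0]) * self.frame_rate + 1e-9))

    def segment_slice(self, seg: Segment) -> slice:
        i0 = self.frame_index(seg.start_s)
        i1 = self.frame_index(seg.end_s - 0.5 * self.frame_interval) + 1
        return slice(max(i0, 0), min(i1, self.n_frames))

    def find_segments(self, label: str, trial: int | None = None) -> list[Segment]:
        return [
            s
            for s in self.segments
            if s.label == label and (trial is None or s.trial == trial)
        ]

    # -- I/O -------------------------------------------------------------

    def to_csv(self, trace_path: str | Path, segments_path: str | Path) -> None:
        """Write the trace and its segment table as two CSV files."""
        pd.DataFrame({"time_s": self.times, "contrast": self.contrast}).to_csv(
            trace_path, index=False
        )
        pd.DataFrame(
            [
                {"label": s.label, "trial": s.trial, "start_s": s.start_s, "end_s": s.end_s}
                for s in self.segments
            ]
        ).to_csv(segments_path, index=False)

    @classmethod
    def from_csv(cls, trace_path: str | Path, segments_path: str | Path) -> "StimulusTrace":
        trace = pd.read_csv(trace_path)
        segs = pd.read_csv(segments_path)
        times = trace["time_s"].to_numpy()
        if times.size < 2:
            raise ValueError("trace must contain at least two frames")
        frame_rate = 1.0 / float(np.median(np.diff(times)))
        segments = [
            Segment(str(r.label), int(r.trial), float(r.start_s), float(r.end_s))
            for r in segs.itertuples()
        ]
        return cls(times, trace["contrast"].to_numpy(), frame_rate, segments)


@dataclass(frozen=True)
class DirectionProtocol:
    """Trial schedule for the moving-grating stimulus (metadata only)."""

    directions: tuple[float, ...]
    schedule: tuple[tuple[float, float, float], ...]  # (direction, start_s, end_s)
    trial_duration: float
    spatial_period_deg: float = 20.0
    speed_deg_per_s: float = 7.5

    def __post_init__(self) -> None:
        if len(set(self.directions)) != 8:
            raise ValueError("exactly 8 distinct directions are required")
        for w in self.directions:
            if not 0.0 <= w < 2.0 * math.pi:
                raise ValueError("directions must lie in [0, 2*pi)")

    @property
    def n_trials(self) -> int:
        return len(self.schedule) // 8


def _validate_timing(frame_rate: float, *durations: float) -> None:
    if frame_rate <= 0:
        raise ValueError("frame_rate must be positive")
    for d in durations:
        if d <= 0:
            raise ValueError("durations must be positive")


def _off_on_off(frame_rate: float, trial: int, t0: float, seg_s: float = 2.0):
    """OFF-ON-OFF full-contrast inversion prefix: 2 s each at -1, +1, -1."""
    n = int(round(seg_s * frame_rate))
    contrast = np.concatenate([np.full(n, -1.0), np.full(n, 1.0), np.full(n, -1.0)])
    segs = [
        Segment("off1", trial, t0, t0 + seg_s),
        Segment("on", trial, t0 + seg_s, t0 + 2 * seg_s),
        Segment("off2", trial, t0 + 2 * seg_s, t0 + 3 * seg_s),
    ]
    return contrast, segs


def make_contrast_ramp_flicker(
    frame_rate: float = 60.0,
    freq_h: float = 1.5,
    ramp_duration: float = 10.0,
    n_trials: int = 1,
    gray_s: float = 1.0,
) -> StimulusTrace:
    """Sinusoid with linearly increasing amplitude, after an OFF-ON-OFF prefix.

    On the ramp segment, ``contrast(t) = (t/ramp_duration) * sin(2*pi*freq_h*t)``
    with ``t`` local to the segment start, so the envelope reaches full
    contrast exactly at the ramp end.  Trials beyond the first are separated
    by a ``gray_s``-second zero-contrast screen.
    """
    _validate_timing(frame_rate, ramp_duration)
    if frame_rate <= 2.0 * freq_h:
        raise ValueError("frame_rate must exceed twice the flicker frequency")
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")

    pieces: list[np.ndarray] = []
    segments: list[Segment] = []
    t0 = 0.0
    n_ramp = int(round(ramp_duration * frame_rate))
    for trial in range(n_trials):
        prefix, segs = _off_on_off(frame_rate, trial, t0)
        pieces.append(prefix)
        segments.extend(segs)
        t0 += 6.0
        t_local = np.arange(n_ramp) / frame_rate
        pieces.append((t_local / ramp_duration) * np.sin(2.0 * np.pi * freq_h * t_local))
        segments.append(Segment("ramp", trial, t0, t0 + ramp_duration))
        t0 += ramp_duration
        if trial < n_trials - 1 and gray_s > 0:
            n_gray = int(round(gray_s * frame_rate))
            pieces.append(np.zeros(n_gray))
            segments.append(Segment("gray", trial, t0, t0 + n_gray / frame_rate))
            t0 += n_gray / frame_rate
    contrast = np.concatenate(pieces)
    times = np.arange(contrast.size) / frame_rate
    return StimulusTrace(times, contrast, frame_rate, segments)


def make_frequency_series(
    frame_rate: float = 60.0,
    freqs: tuple[float, ...] = (1.875, 3.75, 7.5, 15.0),
    durations: tuple[float, ...] = (2.0, 2.0, 2.0, 1.0),
    n_trials: int = 1,
    gray_s: float = 1.0,
) -> StimulusTrace:
    """Full-contrast sinusoidal flicker at a series of temporal frequencies.

    Each frequency ``h`` gets a labelled segment ``freq_<h>`` with
    ``contrast = sin(2*pi*h*t_local)``, preceded (per trial) by the
    OFF-ON-OFF prefix; trials are separated by a gray screen.
    """
    _validate_timing(frame_rate, *durations)
    if len(freqs) != len(durations):
        raise ValueError("freqs and durations must have the same length")
    for h in freqs:
        if h >= frame_rate / 2.0:
            raise ValueError(f"frequency {h} Hz violates the Nyquist limit")
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")

    pieces: list[np.ndarray] = []
    segments: list[Segment] = []
    t0 = 0.0
    for trial in range(n_trials):
        prefix, segs = _off_on_off(frame_rate, trial, t0)
        pieces.append(prefix)
        segments.extend(segs)
        t0 += 6.0
        for h, dur in zip(freqs, durations):
            n = int(round(dur * frame_rate))
            t_local = np.arange(n) / frame_rate
            pieces.append(np.sin(2.0 * np.pi * h * t_local))
            segments.append(Segment(f"freq_{h:g}", trial, t0, t0 + n / frame_rate))
            t0 += n / frame_rate
        if trial < n_trials - 1 and gray_s > 0:
            n_gray = int(round(gray_s * frame_rate))
            pieces.append(np.zeros(n_gray))
            segments.append(Segment("gray", trial, t0, t0 + n_gray / frame_rate))
            t0 += n_gray / frame_rate
    contrast = np.concatenate(pieces)
    times = np.arange(contrast.size) / frame_rate
    return StimulusTrace(times, contrast, frame_rate, segments)


def make_random_flicker(
    frame_rate: float = 60.0, duration: float = 300.0, seed: int = 0
) -> StimulusTrace:
    """Binary random full-field flicker: each frame independently +-1."""
    _validate_timing(frame_rate, duration)
    rng = np.random.default_rng(seed)
    n = int(round(duration * frame_rate))
    contrast = rng.choice([-1.0, 1.0], size=n)
    times = np.arange(n) / frame_rate
    segments = [Segment("flicker", 0, 0.0, n / frame_rate)]
    return StimulusTrace(times, contrast, frame_rate, segments)


def make_direction_protocol(
    n_trials: int = 1,
    trial_duration: float = 2.0,
    seed: int = 0,
    spatial_period_deg: float = 20.0,
    speed_deg_per_s: float = 7.5,
) -> DirectionProtocol:
    """Schedule all 8 grating directions per trial in a seed-controlled order."""
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if trial_duration <= 0:
        raise ValueError("trial_duration must be positive")
    rng = np.random.default_rng(seed)
    schedule: list[tuple[float, float, float]] = []
    t0 = 0.0
    for _ in range(n_trials):
        order = rng.permutation(8)
        for k in order:
            schedule.append((DIRECTIONS_8[k], t0, t0 + trial_duration))
            t0 += trial_duration
    return DirectionProtocol(
        DIRECTIONS_8,
        tuple(schedule),
        trial_duration,
        spatial_period_deg,
        speed_deg_per_s,
    )
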