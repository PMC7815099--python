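"""Oculomotor control measures: OKN slow-phase velocity and head-movement count.

The rotating striped drum drives optokinetic nystagmus (OKN): pursuit-like
slow phases that follow the stimulus alternating with fast resetting
saccades against it.  Two control measures are extracted:

* SPEV — the median slow-phase eye velocity.  Eye position (220 Hz) is
  smoothed with a Gaussian low-pass filter; velocity and acceleration come
  from three-point central differences.  Fast phases are detected with an
  acceleration-threshold algorithm (1200 deg/s^2, in the spirit of
  Behrens & Weiss), extended to cover the whole saccade, and removed.  The
  desaccaded velocity is median-filtered over a 0.25 s window and its median
  is the participant's SPEV.
* nHM — the number of inadvertent head movements: distinct excursions of
  the Earth-horizontal head angular velocity above 3 deg/s after a 10 Hz
  low-pass, a guard against pseudo-Coriolis contamination.

Sign convention: positive = direction of stimulus motion, so OKN slow
phases are positive and the median is taken with sign.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal

__all__ = [
    "EyeTrace",
    "HeadTrace",
    "NystagmusResult",
    "eye_kinematics",
    "detect_fast_phases",
    "spev",
    "count_head_movements",
]

DEFAULT_SAMPLE_RATE = 220.0
#: Acceleration threshold seeding fast-phase detection (deg/s^2).
FAST_PHASE_ACCEL_THRESHOLD = 1200.0
#: Median-filter window applied to the desaccaded velocity (s).
SPEV_MEDIAN_WINDOW_S = 0.25
#: Gaussian position-smoothing SD (s); ~one sample at 220 Hz, enough to
#: suppress tracker quantization noise without pushing saccade acceleration
#: below the detection threshold.
DEFAULT_GAUSSIAN_SD_S = 0.005

_UNIFORMITY_RTOL = 0.05


def _check_uniform(times: np.ndarray, sample_rate: float) -> float:
    dt = np.diff(times)
    if dt.size == 0:
        return 1.0 / sample_rate
    nominal = 1.0 / sample_rate
    if np.any(np.abs(dt - nominal) > _UNIFORMITY_RTOL * nominal):
        raise ValueError("trace sampling is not uniform at the declared rate")
    return float(nominal)


@dataclass(frozen=True)
class EyeTrace:
    """Horizontal eye position (deg, positive = stimulus direction)."""

    times: np.ndarray
    horizontal_position: np.ndarray
    sample_rate: float = DEFAULT_SAMPLE_RATE

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        p = np.asarray(self.horizontal_position, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "horizontal_position", p)
        if t.shape != p.shape or t.ndim != 1:
            raise ValueError("times and positions must be 1-D of equal length")
        if not np.all(np.isfinite(p)):
            raise ValueError("eye positions must be finite")
        _check_uniform(t, self.sample_rate)


@dataclass(frozen=True)
class HeadTrace:
    """Head angular velocity (deg/s), three axes in a head-fixed frame.

    Axes: x forward (roll), y leftward (pitch), z up (yaw).  With the head
    upright, z is Earth-vertical and the Earth-horizontal component is the
    norm of (x, y).  A static head tilt may be declared via ``roll_deg`` /
    ``pitch_deg``; the velocity is rotated into the Earth frame before the
    horizontal component is taken.
    """

    times: np.ndarray
    angular_velocity: np.ndarray  # (n, 3)
    sample_rate: float = DEFAULT_SAMPLE_RATE
    roll_deg: float = 0.0
    pitch_deg: float = 0.0

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        w = np.asarray(self.angular_velocity, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "angular_velocity", w)
        if w.ndim != 2 or w.shape[1] != 3 or w.shape[0] != t.size:
            raise ValueError("angular_velocity must be (n, 3) matching times")
        if not np.all(np.isfinite(w)):
            raise ValueError("angular velocities must be finite")
        _check_uniform(t, self.sample_rate)


@dataclass(frozen=True)
class NystagmusResult:
    slow_phase_velocity: np.ndarray  # NaN at fast-phase samples
    median_spev: float
    fast_phase_intervals: tuple[tuple[int, int], ...] = field(default_factory=tuple)


def eye_kinematics(
    trace: EyeTrace, gaussian_sd_s: float = DEFAULT_GAUSSIAN_SD_S
) -> tuple[np.ndarray, np.ndarray]:
    """Smoothed velocity and acceleration series (deg/s, deg/s^2).

    Position is low-passed with a Gaussian kernel (SD in seconds), then
    differentiated twice with the three-point central operator
    v[i] = (p[i+1] - p[i-1]) / (2 dt), one-sided at the endpoints.
    """
    if trace.times.size < 3:
        raise ValueError("eye kinematics need at least 3 samples")
    dt = 1.0 / trace.sample_rate
    sigma_samples = gaussian_sd_s / dt
    pos = trace.horizontal_position
    if sigma_samples > 0:
        pos = ndimage.gaussian_filter1d(pos, sigma_samples, mode="nearest")
    velocity = np.gradient(pos, dt)
    acceleration = np.gradient(velocity, dt)
    return velocity, acceleration


def detect_fast_phases(
    velocity: np.ndarray,
    acceleration: np.ndarray,
    sample_rate: float = DEFAULT_SAMPLE_RATE,
    accel_threshold: float = FAST_PHASE_ACCEL_THRESHOLD,
    flank_window_s: float = 0.100,
    band_n_sd: float = 3.0,
    band_floor: float = 2.0,
    max_extension_s: float = 0.150,
    merge_gap_s: float = 0.025,
    edge_guard_s: float = 0.05,
) -> list[tuple[int, int]]:
    """Fast-phase (saccade) intervals as half-open sample-index ranges.

    Samples whose |acceleration| exceeds ``accel_threshold`` seed intervals.
    Each seed extends outward until the velocity re-enters a band around the
    local slow-phase velocity — the median of the flanking ``flank_window_s``
    of signal, with half-width ``band_n_sd`` x its SD (at least
    ``band_floor`` deg/s).  Extension is capped at ``max_extension_s`` per
    side; intervals closer than ``merge_gap_s`` are merged.  Seeds within
    ``edge_guard_s`` of either end are ignored: the one-sided differences
    and smoothing padding make acceleration unreliable at the boundaries.
    """
    v = np.asarray(velocity, dtype=float)
    a = np.asarray(acceleration, dtype=float)
    n = v.size
    seeds = np.abs(a) > accel_threshold
    guard = int(round(edge_guard_s * sample_rate))
    if guard > 0 and n > 2 * guard:
        seeds[:guard] = False
        seeds[-guard:] = False
    if not np.any(seeds):
        return []
    # contiguous seed runs
    edges = np.flatnonzero(np.diff(seeds.astype(int)))
    starts = list(np.flatnonzero(seeds[1:] & ~seeds[:-1]) + 1)
    if seeds[0]:
        starts.insert(0, 0)
    ends = list(np.flatnonzero(~seeds[1:] & seeds[:-1]) + 1)
    if seeds[-1]:
        ends.append(n)
    del edges

    win = max(1, int(round(flank_window_s * sample_rate)))
    max_ext = int(round(max_extension_s * sample_rate))

    def _band(lo: int, hi: int) -> tuple[float, float]:
        chunk = v[max(0, lo) : max(0, hi)]
        if chunk.size == 0:
            return 0.0, band_floor
        ref = float(np.median(chunk))
        half = max(band_n_sd * float(np.std(chunk)), band_floor)
        return ref, half

    intervals: list[tuple[int, int]] = []
    for s, e in zip(starts, ends):
        ref, half = _band(s - win, s)
        j = s
        while j > 0 and (s - j) < max_ext and abs(v[j - 1] - ref) > half:
            j -= 1
        ref, half = _band(e, e + win)
        k = e
        while k < n and (k - e) < max_ext and abs(v[k] - ref) > half:
            k += 1
        intervals.append((j, k))

    # merge overlapping / near-adjacent intervals
    gap = int(round(merge_gap_s * sample_rate))
    merged = [intervals[0]]
    for s, e in intervals[1:]:
        ps, pe = merged[-1]
        if s - pe < gap:
            merged[-1] = (ps, max(pe, e))
        else:
            merged.append((s, e))
    return merged


def spev(
    trace: EyeTrace,
    gaussian_sd_s: float = DEFAULT_GAUSSIAN_SD_S,
    accel_threshold: float = FAST_PHASE_ACCEL_THRESHOLD,
    median_window_s: float = SPEV_MEDIAN_WINDOW_S,
    **detect_kwargs,
) -> NystagmusResult:
    """Desaccaded, median-filtered slow-phase velocity and its median (SPEV).

    Fast-phase samples become NaN gaps (never interpolated); the surviving
    velocity samples are median-filtered over a 0.25 s window and the scalar
    SPEV is the median of the filtered series over retained samples.
    """
    velocity, acceleration = eye_kinematics(trace, gaussian_sd_s=gaussian_sd_s)
    intervals = detect_fast_phases(
        velocity,
        acceleration,
        sample_rate=trace.sample_rate,
        accel_threshold=accel_threshold,
        **detect_kwargs,
    )
    keep = np.ones(velocity.size, dtype=bool)
    for s, e in intervals:
        keep[s:e] = False
    if not np.any(keep):
        raise ValueError("every sample was classified as fast phase")

    kernel = int(round(median_window_s * trace.sample_rate))
    kernel = max(1, kernel | 1)  # odd
    slow = velocity[keep]
    filtered = ndimage.median_filter(slow, size=kernel, mode="nearest")
    series = np.full(velocity.size, np.nan)
    series[keep] = filtered
    return NystagmusResult(
        slow_phase_velocity=series,
        median_spev=float(np.median(filtered)),
        fast_phase_intervals=tuple(intervals),
    )


def count_head_movements(
    trace: HeadTrace,
    cutoff_hz: float = 10.0,
    threshold: float = 3.0,
    count_samples: bool = False,
) -> int:
    """Inadvertent head movements: Earth-horizontal angular speed above
    ``threshold`` deg/s after a zero-phase ``cutoff_hz`` low-pass.

    By default an "instance" is a maximal contiguous above-threshold run
    (an excursion); ``count_samples=True`` counts samples instead.
    """
    w = trace.angular_velocity
    n = w.shape[0]
    if n == 0:
        return 0
    nyq = trace.sample_rate / 2.0
    if 0 < cutoff_hz < nyq and n > 15:
        sos = signal.butter(4, cutoff_hz / nyq, output="sos")
        w = signal.sosfiltfilt(sos, w, axis=0)
    # rotate head-frame velocity into the Earth frame (static roll/pitch)
    if trace.roll_deg or trace.pitch_deg:
        r = np.deg2rad(trace.roll_deg)
        p = np.deg2rad(trace.pitch_deg)
        rx = np.array(
            [[1, 0, 0], [0, np.cos(r), -np.sin(r)], [0, np.sin(r), np.cos(r)]]
        )
        ry = np.array(
            [[np.cos(p), 0, np.sin(p)], [0, 1, 0], [-np.sin(p), 0, np.cos(p)]]
        )
        w = w @ (ry @ rx).T
    horiz = np.hypot(w[:, 0], w[:, 1])
    above = horiz > threshold
    if count_samples:
        return int(np.count_nonzero(above))
    if not np.any(above):
        return 0
    entries = int(np.count_nonzero(above[1:] & ~above[:-1])) + int(above[0])
    return entries
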