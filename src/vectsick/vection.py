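"""Vection-trace featurization.

During the optokinetic stimulus the participant continuously reports
perceived self-motion with a knob whose position maps to a fraction in
[0, 1]: 0 means "I am stationary, the surround rotates" (no vection) and
1 means "I rotate, the surround is stationary" (full vection).  The trace
is reduced to three per-participant features:

* ``full_vection_pct`` — percentage of samples strictly above 0.95,
* ``no_vection_pct``   — percentage of samples strictly below 0.05,
* ``sd_dv``            — standard deviation of the first derivative of the
  raw rating (1/s), a measure of how much the percept fluctuated.

State thresholds are strict: a rating of exactly 0.05 or 0.95 is "partial".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "NO_VECTION_THRESHOLD",
    "FULL_VECTION_THRESHOLD",
    "VectionTrace",
    "VectionFeatures",
    "classify_states",
    "vection_features",
    "count_full_vection_episodes",
]

NO_VECTION_THRESHOLD = 0.05
FULL_VECTION_THRESHOLD = 0.95

MAX_DURATION_S = 20 * 60.0


@dataclass(frozen=True)
class VectionTrace:
    """Knob position over time: seconds from stimulus onset, rating in [0, 1]."""

    times: np.ndarray
    ratings: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        r = np.asarray(self.ratings, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "ratings", r)
        if t.ndim != 1 or t.shape != r.shape:
            raise ValueError("times and ratings must be 1-D arrays of equal length")
        if t.size == 0:
            raise ValueError("empty vection trace")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if t[-1] - t[0] > MAX_DURATION_S + 1e-9:
            raise ValueError("trace exceeds the 20-minute trial duration")
        if np.any(r < 0) or np.any(r > 1) or not np.all(np.isfinite(r)):
            raise ValueError("ratings must be finite and within [0, 1]")


@dataclass(frozen=True)
class VectionFeatures:
    full_vection_pct: float
    no_vection_pct: float
    partial_pct: float
    sd_dv: float


def classify_states(trace: VectionTrace) -> np.ndarray:
    """Label each sample 'no' (< 0.05), 'full' (> 0.95) or 'partial'."""
    r = trace.ratings
    labels = np.full(r.shape, "partial", dtype=object)
    labels[r < NO_VECTION_THRESHOLD] = "no"
    labels[r > FULL_VECTION_THRESHOLD] = "full"
    return labels


def vection_features(trace: VectionTrace) -> VectionFeatures:
    """Time-in-state percentages and rating variability (SDdV).

    Percentages count samples, which equals time-weighting under the uniform
    sampling the knob recorder produces.  SDdV is the population standard
    deviation of consecutive-sample difference quotients of the *raw* rating
    (the categorized states play no role), in units of 1/s.
    """
    if trace.times.size < 2:
        raise ValueError("sd_dv undefined: trace has fewer than 2 samples")
    labels = classify_states(trace)
    n = labels.size
    full_pct = 100.0 * np.count_nonzero(labels == "full") / n
    no_pct = 100.0 * np.count_nonzero(labels == "no") / n
    dv = np.diff(trace.ratings) / np.diff(trace.times)
    sd_dv = float(np.std(dv))  # population SD
    return VectionFeatures(
        full_vection_pct=float(full_pct),
        no_vection_pct=float(no_pct),
        partial_pct=float(100.0 - full_pct - no_pct),
        sd_dv=sd_dv,
    )


def count_full_vection_episodes(labels: np.ndarray) -> int:
    """Number of distinct full-vection episodes (entries into 'full',
    counting an initial 'full' sample as one episode)."""
    is_full = np.asarray(labels) == "full"
    if is_full.size == 0:
        return 0
    entries = int(np.count_nonzero(is_full[1:] & ~is_full[:-1]))
    return entries + int(is_full[0])
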