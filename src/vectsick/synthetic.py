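"""Synthetic cohort generator.

Emulates the drum study's raw data for a cohort of (by default) 19
participants so that every pipeline stage — trace featurization,
questionnaire scoring, signal processing, regression — can be exercised
without the deposited dataset:

* a state-switching vection trace (semi-Markov alternation between the
  no-vection and full-vection endpoints with short partial-level plateaus
  and smooth ramps), heterogeneous across participants;
* a sawtooth OKN eye-position trace under the 60 deg/s stimulus: slow
  phases at ``gain x 60`` deg/s, Poisson-timed raised-cosine resetting fast
  phases, with the programmed saccade intervals kept as ground truth;
* low-amplitude head angular velocity with a known number of injected
  suprathreshold transients (ground truth for the nHM counter);
* questionnaire outcomes generated from the logit-linear sickness model:
  logit(SSQ-TS / 235.62) = intercept + b_mssq * MSSQ + b_conf * Conflict_PB
  + Gaussian noise, with the SSQ item ratings allocated so they re-score to
  the target total, an FMS ramp monotone in the total (stop rule at 15),
  and a thresholded sick flag.

Beliefs are drawn with a configurable negative coupling to the vection
propensity (Gaussian copula), reproducing the study's qualitative structure
in which participants with more pervasive vection tended to be *less*
convinced the chair actually rotated.

Everything is driven by a single cohort seed through spawned per-participant
substreams, so identical (config, seed) gives an identical cohort.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd
from scipy import signal, stats as sps

from . import beliefs as bel
from . import scales
from .oculomotor import EyeTrace, HeadTrace
from .vection import VectionTrace, vection_features

__all__ = [
    "SyntheticCohortConfig",
    "ParticipantRecord",
    "generate_vection_trace",
    "generate_okn_trace",
    "generate_head_trace",
    "generate_beliefs",
    "allocate_ssq_items",
    "generate_outcomes",
    "generate_participant",
    "generate_cohort",
    "generate_cohort_features",
]


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """Generative parameters; defaults state the study's conditions."""

    n_participants: int = 19
    seed: int = 0

    # trial / sampling
    duration_s: float = 1200.0  # 20 min exposure
    knob_rate_hz: float = 10.0
    eye_sample_rate: float = 220.0

    # vection state switching (mean dwell times; fractions of the cycle give
    # FullVection ~44%, no-vection ~30% as observed at the cohort level)
    dwell_full_s: float = 53.0
    dwell_no_s: float = 36.0
    dwell_partial_s: float = 15.0
    ramp_s: float = 1.5
    knob_noise_sd: float = 0.01
    vection_heterogeneity: float = 0.6  # log-scale spread of dwell ratios

    # beliefs (Gaussian-copula coupling against the vection propensity)
    belief_coupling: float = -0.58
    drum_coupling: float = 0.2

    # MSSQ susceptibility (raw-item generation; cohort mean ~16.6)
    mssq_propensity_alpha: float = 1.7
    mssq_propensity_beta: float = 3.8
    mssq_not_experienced_p: float = 0.04

    # sickness outcome model (logit scale)
    intercept: float = -1.64
    beta_mssq: float = 0.02
    beta_conflict: float = 2.15
    residual_sd: float = 0.40
    scale_max: float = scales.SSQ_MAX_TOTAL
    sick_threshold: float = 80.0
    fms_stop: int = 15

    # OKN
    stimulus_velocity: float = 60.0
    okn_gain: float = 0.85
    saccade_rate_hz: float = 3.0
    saccade_peak_velocity: float = 500.0
    saccade_refractory_s: float = 0.10
    eye_noise_sd: float = 0.02  # deg, position noise

    # head motion
    head_noise_sd: float = 0.5  # deg/s per axis before band-limiting
    head_noise_cutoff_hz: float = 2.0
    head_transient_rate_per_min: float = 0.25
    head_transient_count: int | None = None  # overrides the Poisson draw
    head_transient_amplitude: float = 6.0
    head_transient_duration_s: float = 0.5

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be positive")
        for name in (
            "duration_s",
            "knob_rate_hz",
            "eye_sample_rate",
            "dwell_partial_s",
            "residual_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not -1.0 <= self.belief_coupling <= 1.0:
            raise ValueError("belief_coupling must be a correlation in [-1, 1]")


@dataclass
class ParticipantRecord:
    pid: str
    vection_trace: VectionTrace
    eye_trace: EyeTrace
    eye_truth_intervals: tuple[tuple[int, int], ...]
    head_trace: HeadTrace
    head_truth_count: int
    mssq_response: scales.MssqResponse
    belief_report: bel.BeliefReport
    ssq_response: scales.SsqResponse
    fms_series: scales.FmsSeries
    sick: bool
    latent_vection_z: float


def _as_rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def generate_vection_trace(
    config: SyntheticCohortConfig, seed_or_rng, vection_z: float = 0.0
) -> VectionTrace:
    """Semi-Markov state-switching knob trace.

    Plateaus alternate no -> partial -> full -> partial -> ... with
    exponential dwell times (participant-scaled through ``vection_z``),
    partial plateau values drawn in the interior, and linear ramps of
    ``ramp_s`` between plateaus.  An infinite dwell mean pins the trace to
    that state for the rest of the trial.
    """
    rng = _as_rng(seed_or_rng)
    h = config.vection_heterogeneity
    dwell = {
        "no": config.dwell_no_s * math.exp(-h * vection_z),
        "full": config.dwell_full_s * math.exp(h * vection_z),
        "partial": config.dwell_partial_s,
    }
    cycle = ("no", "partial", "full", "partial")
    idx = int(rng.integers(0, 2)) * 2  # start at no or full

    knot_t: list[float] = []
    knot_v: list[float] = []
    t = 0.0
    while t < config.duration_s:
        state = cycle[idx % 4]
        if state == "no":
            value = 0.0
        elif state == "full":
            value = 1.0
        else:
            value = float(rng.uniform(0.1, 0.9))
        mean = dwell[state]
        length = config.duration_s - t if math.isinf(mean) else float(
            rng.exponential(mean)
        )
        knot_t += [t, t + length]
        knot_v += [value, value]
        t += length + config.ramp_s
        idx += 1

    times = np.arange(0.0, config.duration_s, 1.0 / config.knob_rate_hz)
    ratings = np.interp(times, knot_t, knot_v)
    if config.knob_noise_sd > 0:
        ratings = ratings + rng.normal(0.0, config.knob_noise_sd, times.size)
    ratings = np.clip(ratings, 0.0, 1.0)
    return VectionTrace(times=times, ratings=ratings)


def generate_okn_trace(
    config: SyntheticCohortConfig, seed_or_rng
) -> tuple[EyeTrace, tuple[tuple[int, int], ...]]:
    """Sawtooth OKN eye-position trace plus ground-truth saccade intervals.

    Slow phases run at ``okn_gain x stimulus_velocity``; fast phases occur at
    Poisson times (with a refractory gap), each resetting the accumulated
    slow-phase drift with a raised-cosine velocity profile whose peak is
    ``saccade_peak_velocity``.  Returns sample-index [start, end) intervals.
    """
    rng = _as_rng(seed_or_rng)
    fs = config.eye_sample_rate
    dt = 1.0 / fs
    n = int(round(config.duration_s * fs))
    v_slow = config.okn_gain * config.stimulus_velocity
    velocity = np.full(n, v_slow)

    truth: list[tuple[int, int]] = []
    if config.saccade_rate_hz > 0:
        t = 0.0
        last_reset = 0.0
        while True:
            t += config.saccade_refractory_s + float(
                rng.exponential(1.0 / config.saccade_rate_hz)
            )
            amplitude = v_slow * (t - last_reset)
            dur = np.clip(math.pi * amplitude / (2 * config.saccade_peak_velocity),
                          0.02, 0.12)
            if t + dur >= config.duration_s:
                break
            i0 = int(round(t * fs))
            i1 = min(n, i0 + max(3, int(round(dur * fs))))
            tau = (np.arange(i0, i1) - i0) * dt
            d = (i1 - i0) * dt
            velocity[i0:i1] = v_slow - amplitude * (math.pi / (2 * d)) * np.sin(
                math.pi * tau / d
            )
            truth.append((i0, i1))
            last_reset = t + dur
            t += dur

    position = np.cumsum(velocity) * dt
    if config.eye_noise_sd > 0:
        position = position + rng.normal(0.0, config.eye_noise_sd, n)
    times = np.arange(n) * dt
    trace = EyeTrace(times=times, horizontal_position=position, sample_rate=fs)
    return trace, tuple(truth)


def generate_head_trace(
    config: SyntheticCohortConfig, seed_or_rng
) -> tuple[HeadTrace, int]:
    """Band-limited low-amplitude head noise plus k injected transients.

    Returns the trace and k (the ground truth for the nHM counter).  The
    transients are raised-cosine pulses on a horizontal axis, peaking at
    ``head_transient_amplitude`` deg/s, spaced at least one pulse width
    apart.
    """
    rng = _as_rng(seed_or_rng)
    fs = config.eye_sample_rate
    n = int(round(config.duration_s * fs))
    times = np.arange(n) / fs
    pad = int(round(2.0 * fs))  # discard filter startup transients
    w = rng.normal(0.0, 1.0, (n + 2 * pad, 3))
    nyq = fs / 2.0
    if 0 < config.head_noise_cutoff_hz < nyq and n > 30:
        sos = signal.butter(4, config.head_noise_cutoff_hz / nyq, output="sos")
        w = signal.sosfiltfilt(sos, w, axis=0)
        w = w[pad : pad + n]
        w /= max(np.std(w), 1e-12)
    else:
        w = w[pad : pad + n]
    w *= config.head_noise_sd

    if config.head_transient_count is not None:
        k = int(config.head_transient_count)
    else:
        k = int(rng.poisson(config.head_transient_rate_per_min
                            * config.duration_s / 60.0))
    width = int(round(config.head_transient_duration_s * fs))
    k = min(k, max(0, n // (3 * max(width, 1)) - 1))
    if k > 0:
        slots = np.sort(rng.choice(n // (3 * width) - 1, size=k, replace=False))
        for s in slots:
            i0 = (s + 1) * 3 * width
            tau = np.arange(width) / fs
            pulse = config.head_transient_amplitude * 0.5 * (
                1 - np.cos(2 * math.pi * tau / config.head_transient_duration_s)
            )
            axis = int(rng.integers(0, 2))
            w[i0 : i0 + width, axis] += pulse * (1 if rng.random() < 0.5 else -1)
    trace = HeadTrace(times=times, angular_velocity=w, sample_rate=fs)
    return trace, k


def generate_beliefs(
    config: SyntheticCohortConfig, seed_or_rng, vection_z: float
) -> bel.BeliefReport:
    """Post-exposure belief answers coupled to the vection propensity.

    A Gaussian copula with correlation ``belief_coupling`` (default -0.58)
    links the latent chair-belief to ``vection_z``; the latent maps through
    the normal CDF to a Rotation Likelihood, which is split back into the
    recorded Y/N answer (RL >= 0.5) and certainty (|2 RL - 1|).
    """
    rng = _as_rng(seed_or_rng)
    rho_c = config.belief_coupling
    rho_d = config.drum_coupling
    z_c = rho_c * vection_z + math.sqrt(1 - rho_c**2) * rng.standard_normal()
    z_d = rho_d * vection_z + math.sqrt(1 - rho_d**2) * rng.standard_normal()
    rl_c = float(sps.norm.cdf(z_c))
    rl_d = float(sps.norm.cdf(z_d))
    return bel.BeliefReport(
        chair_answer=rl_c >= 0.5,
        chair_certainty=abs(2 * rl_c - 1),
        drum_answer=rl_d >= 0.5,
        drum_certainty=abs(2 * rl_d - 1),
    )


def _generate_mssq(config: SyntheticCohortConfig, rng) -> scales.MssqResponse:
    q = rng.beta(config.mssq_propensity_alpha, config.mssq_propensity_beta)
    sections = []
    for _ in range(2):
        ratings = {}
        flagged = set()
        for t in scales.MSSQ_MOTION_TYPES:
            if rng.random() < config.mssq_not_experienced_p:
                flagged.add(t)
                ratings[t] = 0
            else:
                ratings[t] = int(rng.binomial(3, q))
        if len(flagged) == len(scales.MSSQ_MOTION_TYPES):
            flagged.discard(next(iter(flagged)))
        sections.append(scales.MssqSection(ratings=ratings,
                                           not_experienced=frozenset(flagged)))
    return scales.MssqResponse(child_section=sections[0], adult_section=sections[1])


# SSQ items by how many subscales they load on (allocation weights)
_SSQ_W2 = ("general_discomfort", "difficulty_focusing", "nausea",
           "difficulty_concentrating", "blurred_vision")
_SSQ_W1 = tuple(i for i in scales.SSQ_ITEMS if i not in _SSQ_W2)


def allocate_ssq_items(target_ts: float) -> scales.SsqResponse:
    """Allocate 16 item ratings whose Kennedy score approximates a target TS.

    The Total Score is 3.74 per unit of summed subscale loadings; items load
    on one or two subscales, so ratings are filled greedily over the
    two-loading items first, then the one-loading items, hitting the target
    to within half a quantum (1.87 points) for any attainable TS.
    """
    units = int(round(np.clip(target_ts / scales.SSQ_TS_FACTOR, 1, 62)))
    ratings = {item: 0 for item in scales.SSQ_ITEMS}
    remaining = units
    for item in _SSQ_W2:
        r = min(3, remaining // 2)
        ratings[item] = r
        remaining -= 2 * r
        if remaining < 2:
            break
    for item in _SSQ_W1:
        r = min(3, remaining)
        ratings[item] = r
        remaining -= r
        if remaining == 0:
            break
    return scales.SsqResponse(ratings=ratings)


def _fms_from_ts(
    config: SyntheticCohortConfig, rng, ts: float
) -> scales.FmsSeries:
    level = int(np.clip(round(22 * ts / config.scale_max + rng.normal(0, 1.0)),
                        0, 20))
    times, scores = [], []
    for minute in range(2, 21, 2):
        s = int(round(level * minute / 20.0))
        times.append(float(minute))
        scores.append(s)
        if s >= config.fms_stop:
            break
    return scales.FmsSeries(times=tuple(times), scores=tuple(scores))


def generate_outcomes(
    config: SyntheticCohortConfig, seed_or_rng, mssq: float, conflict: float
) -> dict:
    """Sickness outcomes from the logit-linear model.

    Draws the logit-scale outcome, inverts it to an SSQ-TS target, allocates
    SSQ item ratings that re-score to it, derives a monotone FMS ramp
    (truncated at the stop rule) and thresholds the sick flag.
    """
    rng = _as_rng(seed_or_rng)
    eta = (
        config.intercept
        + config.beta_mssq * mssq
        + config.beta_conflict * conflict
        + rng.normal(0.0, config.residual_sd)
    )
    ts_target = config.scale_max / (1.0 + math.exp(-eta))
    ssq_response = allocate_ssq_items(ts_target)
    ts = scales.score_ssq(ssq_response).total_score
    return {
        "ssq_response": ssq_response,
        "ssq_ts": ts,
        "fms_series": _fms_from_ts(config, rng, ts),
        "sick": bool(ts >= config.sick_threshold),
    }


def generate_participant(
    config: SyntheticCohortConfig, seed, pid: str
) -> ParticipantRecord:
    """Generate one participant's full raw record from a dedicated seed."""
    rng = _as_rng(seed)
    z = float(rng.standard_normal())
    vection_trace = generate_vection_trace(config, rng, vection_z=z)
    eye_trace, eye_truth = generate_okn_trace(config, rng)
    head_trace, head_k = generate_head_trace(config, rng)
    belief_report = generate_beliefs(config, rng, z)
    mssq_response = _generate_mssq(config, rng)

    fv = vection_features(vection_trace).full_vection_pct
    rl_chair = bel.likelihoods_from_report(belief_report).rl_chair
    conflict = bel.conflict_pb(fv, rl_chair)
    mssq_score = scales.score_mssq(mssq_response)
    outcomes = generate_outcomes(config, rng, mssq_score, conflict)

    return ParticipantRecord(
        pid=pid,
        vection_trace=vection_trace,
        eye_trace=eye_trace,
        eye_truth_intervals=eye_truth,
        head_trace=head_trace,
        head_truth_count=head_k,
        mssq_response=mssq_response,
        belief_report=belief_report,
        ssq_response=outcomes["ssq_response"],
        fms_series=outcomes["fms_series"],
        sick=outcomes["sick"],
        latent_vection_z=z,
    )


def generate_cohort(config: SyntheticCohortConfig) -> list[ParticipantRecord]:
    """Generate the full cohort, one spawned substream per participant."""
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.n_participants)
    return [
        generate_participant(config, np.random.default_rng(child), f"p{i + 1:02d}")
        for i, child in enumerate(children)
    ]


def generate_cohort_features(
    config: SyntheticCohortConfig,
    n: int | None = None,
    seed: int | None = None,
    noise_sign: int = 1,
) -> pd.DataFrame:
    """Feature-level cohort draw (no raw traces) from the same joint model.

    FullVection is drawn from its cohort marginal (mean 44%, SD 21%
    clipped to [0, 100]); beliefs come from the same copula as the raw-trace
    path; the outcome follows the logit-linear model.  The signal-processing
    covariates (SDdV, SPEV, nHM) are plausible fillers uncorrelated with the
    outcome, as in the study's screen.  Used for replicate-heavy parameter
    recovery where trace synthesis would dominate runtime.

    ``noise_sign=-1`` flips the sign of the outcome residuals while keeping
    every other draw identical, giving the antithetic twin of the same
    seed's cohort (a standard variance-reduction pairing for bias studies;
    each twin is marginally distributed exactly like an ordinary cohort).
    """
    n = config.n_participants if n is None else int(n)
    rng = np.random.default_rng(config.seed if seed is None else seed)
    z = rng.standard_normal(n)
    fv_frac = np.clip(0.44 + 0.21 * z + rng.normal(0, 0.04, n), 0.0, 1.0)
    rho = config.belief_coupling
    z_c = rho * z + math.sqrt(1 - rho**2) * rng.standard_normal(n)
    rl_chair = sps.norm.cdf(z_c)
    z_d = config.drum_coupling * z + math.sqrt(
        1 - config.drum_coupling**2
    ) * rng.standard_normal(n)
    rl_drum = sps.norm.cdf(z_d)
    mssq = rng.gamma(2.2, 7.545, n)
    conflict = np.abs(fv_frac - rl_chair)
    eta = (
        config.intercept
        + config.beta_mssq * mssq
        + config.beta_conflict * conflict
        + noise_sign * rng.normal(0.0, config.residual_sd, n)
    )
    ssq_ts = config.scale_max / (1.0 + np.exp(-eta))
    return pd.DataFrame(
        {
            "id": [f"p{i + 1:03d}" for i in range(n)],
            "ssq_ts": ssq_ts,
            "mssq": mssq,
            "conflict_pb": conflict,
            "rl_chair": rl_chair,
            "rl_drum": rl_drum,
            "certainty_chair": np.abs(2 * rl_chair - 1),
            "certainty_drum": np.abs(2 * rl_drum - 1),
            "full_vection_pct": 100 * fv_frac,
            "sd_dv": np.abs(rng.normal(0.15, 0.05, n)),
            "spev": rng.normal(config.okn_gain * config.stimulus_velocity, 4.0, n),
            "n_hm": rng.poisson(5.0, n),
            "sick": ssq_ts >= config.sick_threshold,
        }
    )
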