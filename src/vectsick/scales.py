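"""Questionnaire scoring: SSQ, MSSQ-Short and the FMS nausea series.

Three instruments quantify motion sickness in this pipeline:

* the Simulator Sickness Questionnaire (SSQ): sixteen symptoms rated 0-3
  immediately after exposure, combined through Kennedy's weighted subscales
  (Nausea, Oculomotor, Disorientation) into a Total Score (TS);
* the short-form Motion Sickness Susceptibility Questionnaire (MSSQ):
  lifetime sickness history over nine transport/motion types, reported
  separately for childhood and adulthood;
* the Fast Motion Sickness scale (FMS): a verbal 0-20 nausea rating given
  every two minutes during the stimulus, with a stop rule at 15.

The SSQ Total Score is the outcome variable of the downstream regression;
MSSQ is the susceptibility covariate; FMS is summarized only (peak / final /
early-abort) because its between-subject reliability was too poor to model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "SSQ_ITEMS",
    "SSQ_SUBSCALE_ITEMS",
    "SSQ_WEIGHTS",
    "SSQ_TS_FACTOR",
    "SSQ_MAX_TOTAL",
    "MSSQ_MOTION_TYPES",
    "SsqResponse",
    "SsqScores",
    "MssqSection",
    "MssqResponse",
    "FmsSeries",
    "score_ssq",
    "score_mssq",
    "summarize_fms",
]

# Kennedy, Lane, Berbaum & Lilienthal (1993) item-to-subscale map.  Each of
# the 16 symptoms loads on one or two of the three subscales; subscale raw
# scores are plain sums of the member items' 0-3 ratings.
SSQ_ITEMS: tuple[str, ...] = (
    "general_discomfort",
    "fatigue",
    "headache",
    "eye_strain",
    "difficulty_focusing",
    "increased_salivation",
    "sweating",
    "nausea",
    "difficulty_concentrating",
    "fullness_of_head",
    "blurred_vision",
    "dizzy_eyes_open",
    "dizzy_eyes_closed",
    "vertigo",
    "stomach_awareness",
    "burping",
)

SSQ_SUBSCALE_ITEMS: dict[str, tuple[str, ...]] = {
    "nausea": (
        "general_discomfort",
        "increased_salivation",
        "sweating",
        "nausea",
        "difficulty_concentrating",
        "stomach_awareness",
        "burping",
    ),
    "oculomotor": (
        "general_discomfort",
        "fatigue",
        "headache",
        "eye_strain",
        "difficulty_focusing",
        "difficulty_concentrating",
        "blurred_vision",
    ),
    "disorientation": (
        "difficulty_focusing",
        "nausea",
        "fullness_of_head",
        "blurred_vision",
        "dizzy_eyes_open",
        "dizzy_eyes_closed",
        "vertigo",
    ),
}

SSQ_WEIGHTS: dict[str, float] = {
    "nausea": 9.54,
    "oculomotor": 7.58,
    "disorientation": 13.92,
}

#: Total Score = 3.74 x (sum of the three unweighted subscale sums).
SSQ_TS_FACTOR: float = 3.74

#: Ceiling of the Total Score: every item at 3 gives raw sums 21+21+21.
SSQ_MAX_TOTAL: float = SSQ_TS_FACTOR * 63  # 235.62

# Golding (2006) MSSQ-Short motion types (same nine in each life section).
MSSQ_MOTION_TYPES: tuple[str, ...] = (
    "cars",
    "buses_or_coaches",
    "trains",
    "aircraft",
    "small_boats",
    "ships",
    "swings",
    "roundabouts",
    "big_rides",
)

_VALID_RATINGS = frozenset({0, 1, 2, 3})


@dataclass(frozen=True)
class SsqResponse:
    """Sixteen 0-3 severity ratings keyed by canonical SSQ item name."""

    ratings: Mapping[str, int]

    def __post_init__(self) -> None:
        keys = set(self.ratings)
        if keys != set(SSQ_ITEMS):
            missing = sorted(set(SSQ_ITEMS) - keys)
            extra = sorted(keys - set(SSQ_ITEMS))
            raise ValueError(
                f"SSQ response must contain exactly the 16 canonical items; "
                f"missing={missing}, unexpected={extra}"
            )
        for item, r in self.ratings.items():
            if r not in _VALID_RATINGS:
                raise ValueError(
                    f"SSQ item {item!r} rated {r!r}; ratings must be in {{0,1,2,3}}"
                )


@dataclass(frozen=True)
class SsqScores:
    nausea_raw: int
    oculomotor_raw: int
    disorientation_raw: int
    nausea: float
    oculomotor: float
    disorientation: float
    total_score: float


@dataclass(frozen=True)
class MssqSection:
    """One life section (child <12y or adult): per-type rating or a
    not-experienced flag.  ``ratings[t]`` is ignored when ``not_experienced[t]``
    is set."""

    ratings: Mapping[str, int]
    not_experienced: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if set(self.ratings) != set(MSSQ_MOTION_TYPES):
            raise ValueError(
                "MSSQ section must rate exactly the 9 canonical motion types"
            )
        unknown = set(self.not_experienced) - set(MSSQ_MOTION_TYPES)
        if unknown:
            raise ValueError(f"unknown motion types flagged: {sorted(unknown)}")
        for t, r in self.ratings.items():
            if t in self.not_experienced:
                continue
            if r not in _VALID_RATINGS:
                raise ValueError(
                    f"MSSQ type {t!r} rated {r!r}; ratings must be in {{0,1,2,3}}"
                )


@dataclass(frozen=True)
class MssqResponse:
    child_section: MssqSection
    adult_section: MssqSection


@dataclass(frozen=True)
class FmsSeries:
    """FMS ratings on the 2-minute reporting grid.

    The series ends at the 20-minute mark or at the first rating >= 15
    (the stop rule); ratings after a stop-rule hit are invalid.
    """

    times: tuple[float, ...]
    scores: tuple[int, ...]

    STOP_SCORE = 15
    MAX_MINUTES = 20.0

    def __post_init__(self) -> None:
        if len(self.times) != len(self.scores):
            raise ValueError("times and scores must have equal length")
        if len(self.times) == 0:
            raise ValueError("FMS series is empty")
        t = np.asarray(self.times, dtype=float)
        if not np.all(np.diff(t) > 0):
            raise ValueError("FMS times must be strictly increasing")
        if t[-1] > self.MAX_MINUTES:
            raise ValueError("FMS series extends beyond the 20-minute trial")
        for s in self.scores:
            if not (0 <= int(s) <= 20):
                raise ValueError(f"FMS score {s!r} outside [0, 20]")
        hits = [i for i, s in enumerate(self.scores) if s >= self.STOP_SCORE]
        if hits and hits[0] != len(self.scores) - 1:
            raise ValueError("FMS series continues past the stop rule (score >= 15)")


def score_ssq(response: SsqResponse) -> SsqScores:
    """Score an SSQ response with Kennedy's weighted-subscale scheme.

    Raw subscale scores are unweighted sums over the member items; weighted
    subscales multiply by 9.54 (N), 7.58 (O) and 13.92 (D); the Total Score
    is 3.74 x (N_raw + O_raw + D_raw), giving a 0-235.62 scale.
    """
    raw = {
        sub: sum(response.ratings[item] for item in items)
        for sub, items in SSQ_SUBSCALE_ITEMS.items()
    }
    total = SSQ_TS_FACTOR * (raw["nausea"] + raw["oculomotor"] + raw["disorientation"])
    return SsqScores(
        nausea_raw=raw["nausea"],
        oculomotor_raw=raw["oculomotor"],
        disorientation_raw=raw["disorientation"],
        nausea=raw["nausea"] * SSQ_WEIGHTS["nausea"],
        oculomotor=raw["oculomotor"] * SSQ_WEIGHTS["oculomotor"],
        disorientation=raw["disorientation"] * SSQ_WEIGHTS["disorientation"],
        total_score=total,
    )


def _score_mssq_section(section: MssqSection) -> float:
    n_flagged = len(section.not_experienced)
    if n_flagged >= len(MSSQ_MOTION_TYPES):
        raise ValueError(
            "MSSQ section score undefined: all 9 motion types flagged not-experienced"
        )
    rating_sum = sum(
        section.ratings[t]
        for t in MSSQ_MOTION_TYPES
        if t not in section.not_experienced
    )
    return rating_sum * 9.0 / (9.0 - n_flagged)


def score_mssq(response: MssqResponse) -> float:
    """Golding (2006) short-form susceptibility score.

    Each section's rating sum is rescaled by 9/(9 - n_not_experienced) to
    correct for motion types never encountered; the total is the child plus
    adult section score, on a 0-54 scale.
    """
    return _score_mssq_section(response.child_section) + _score_mssq_section(
        response.adult_section
    )


def summarize_fms(series: FmsSeries) -> dict:
    """Peak and final FMS rating plus whether the stop rule aborted the trial."""
    peak = max(series.scores)
    final = series.scores[-1]
    aborted = final >= FmsSeries.STOP_SCORE and series.times[-1] < FmsSeries.MAX_MINUTES
    return {"peak": int(peak), "final": int(final), "aborted_early": bool(aborted)}
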