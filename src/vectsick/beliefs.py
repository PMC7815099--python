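"""Post-exposure beliefs about the actual motion and the conflict statistic.

After the stimulus the participant answers, for chair and drum separately,
"did it actually rotate the whole time?" (Y/N) plus a visual-analogue
certainty in [0, 1].  Answer and certainty combine into a Rotation
Likelihood (RL): the certainty is signed (+ for Y, - for N) and remapped to
[0, 1], so RL = 1 means "certain it rotated throughout", RL = 0 "certain it
did not", RL = 0.5 "maximally uncertain".

The headline statistic Conflict_PB is the absolute difference between the
perceived self-rotation (fraction of time in full vection) and the believed
self-rotation (RL of the chair) — both on [0, 1], so the conflict is too.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "BeliefReport",
    "RotationLikelihoods",
    "rotation_likelihood",
    "likelihoods_from_report",
    "conflict_pb",
]


def _check_certainty(value: float, label: str) -> float:
    v = float(value)
    if not 0.0 <= v <= 1.0:
        raise ValueError(f"{label} certainty {value!r} outside [0, 1]")
    return v


@dataclass(frozen=True)
class BeliefReport:
    chair_answer: bool
    chair_certainty: float
    drum_answer: bool
    drum_certainty: float

    def __post_init__(self) -> None:
        _check_certainty(self.chair_certainty, "chair")
        _check_certainty(self.drum_certainty, "drum")


@dataclass(frozen=True)
class RotationLikelihoods:
    rl_chair: float
    rl_drum: float


def rotation_likelihood(answer: bool, certainty: float) -> float:
    """Map (Y/N, certainty) to a Rotation Likelihood in [0, 1].

    The certainty is signed positive for "yes" and negative for "no", then
    the signed score in [-1, 1] is remapped to [0, 1] via (s + 1) / 2.
    Certainty 0 gives 0.5 regardless of the answer.
    """
    c = _check_certainty(certainty, "answer")
    signed = c if answer else -c
    return (signed + 1.0) / 2.0


def likelihoods_from_report(report: BeliefReport) -> RotationLikelihoods:
    return RotationLikelihoods(
        rl_chair=rotation_likelihood(report.chair_answer, report.chair_certainty),
        rl_drum=rotation_likelihood(report.drum_answer, report.drum_certainty),
    )


def conflict_pb(full_vection_pct: float, rl_chair: float) -> float:
    """Perception-belief conflict: |FullVection/100 - RL_chair|, in [0, 1]."""
    fv = float(full_vection_pct)
    rl = float(rl_chair)
    if not 0.0 <= fv <= 100.0:
        raise ValueError(f"full_vection_pct {full_vection_pct!r} outside [0, 100]")
    if not 0.0 <= rl <= 1.0:
        raise ValueError(f"rl_chair {rl_chair!r} outside [0, 1]")
    return abs(fv / 100.0 - rl)
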