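"""Scoring of allocentric spatial working-memory trial logs.

Each trial of the task presents three goal pads hidden among 18 floor pads;
the participant indicates the goals by stepping on pads. Two summary scores
are computed per subject over the 10 trials:

* **CBE** (correct before error): the number of distinct goal pads visited
  before the first visit to a non-goal pad, averaged over trials. A trial
  with no error scores 3. CBE is a memory-capacity proxy in [0, 3].
* **NET** (number of errorless trials): how many of the 10 trials contain
  no visit to a non-goal pad; a perfect-memory measure in [0, 10].

Revisiting an already-found goal pad is neutral: it is neither an error nor
a new correct choice, because an error is defined solely as visiting a
non-goal pad.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

__all__ = ["Trial", "TrialLog", "MemoryScores", "score_trial_cbe", "score_subject"]

N_TRIALS = 10
N_GOALS = 3


@dataclass(frozen=True)
class Trial:
    """One trial: the three goal pad ids and the ordered recall visits."""

    goals: frozenset
    visits: tuple

    def __post_init__(self):
        if len(self.goals) != N_GOALS:
            raise ValueError(f"a trial needs exactly {N_GOALS} distinct goals, got {len(self.goals)}")
        if len(self.visits) == 0:
            raise ValueError("empty visit sequence")


@dataclass(frozen=True)
class TrialLog:
    """Ordered list of exactly 10 trials for one subject."""

    trials: tuple

    def __post_init__(self):
        if len(self.trials) != N_TRIALS:
            raise ValueError(f"a trial log needs exactly {N_TRIALS} trials, got {len(self.trials)}")


@dataclass(frozen=True)
class MemoryScores:
    """Subject-level scores: cbe in [0, 3], net integer in [0, 10]."""

    cbe: float
    net: int


def score_trial_cbe(trial: Trial) -> int:
    """Count distinct goal pads visited before the first non-goal visit.

    Returns 3 when the visit sequence contains no error at all, regardless
    of how many goals were actually reached (an errorless sequence that
    stops early still made no incorrect choice; in practice the task ends
    a trial once all three goals are found).
    """
    found = set()
    for pad in trial.visits:
        if pad in trial.goals:
            found.add(pad)
            if len(found) == N_GOALS:
                return N_GOALS
        else:
            return len(found)
    # sequence exhausted without any error
    return N_GOALS


def _has_error(trial: Trial) -> bool:
    return any(pad not in trial.goals for pad in trial.visits)


def score_subject(log: TrialLog) -> MemoryScores:
    """Score one subject's 10-trial log into CBE (mean) and NET (count)."""
    per_trial = [score_trial_cbe(t) for t in log.trials]
    net = sum(1 for t in log.trials if not _has_error(t))
    return MemoryScores(cbe=float(sum(per_trial)) / N_TRIALS, net=net)


def make_trial(goals: Sequence, visits: Sequence) -> Trial:
    """Convenience constructor from plain sequences."""
    return Trial(goals=frozenset(goals), visits=tuple(visits))
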