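"""Gaze targets, their square geometry, and per-trial records.

Four light spots sit on the corners of a square: right-up (RU), left-up
(LU), left-down (LD) and right-down (RD).  An agent's action is a gaze
at one of them.  A trial is summarised by a :class:`TrialRecord` — the
action taken and whether it was rewarded.
"""

from __future__ import annotations

from enum import IntEnum
from typing import NamedTuple


class Action(IntEnum):
    """One of the four gaze targets, in the fixed sampling order."""

    RU = 0
    LU = 1
    LD = 2
    RD = 3


ACTIONS: tuple[Action, ...] = (Action.RU, Action.LU, Action.LD, Action.RD)

#: Diagonal partner on the square (an involution: RU<->LD, LU<->RD).
DIAGONAL: dict[Action, Action] = {
    Action.RU: Action.LD,
    Action.LD: Action.RU,
    Action.LU: Action.RD,
    Action.RD: Action.LU,
}

#: The four valid pairs of adjacent (non-diagonal) spots, keyed by side.
PAIRS: dict[str, tuple[Action, Action]] = {
    "R": (Action.RU, Action.RD),
    "L": (Action.LU, Action.LD),
    "U": (Action.RU, Action.LU),
    "D": (Action.LD, Action.RD),
}

PAIR_IDS: tuple[str, ...] = ("R", "L", "U", "D")

#: Pairs containing each spot (each corner belongs to exactly two sides).
PAIRS_OF_SPOT: dict[Action, tuple[str, str]] = {
    a: tuple(pid for pid in PAIR_IDS if a in PAIRS[pid]) for a in ACTIONS
}


def adjacent(action: Action) -> tuple[Action, Action]:
    """The two spots sharing a pair with ``action`` (its non-diagonal neighbours)."""
    return tuple(a for a in ACTIONS if a != action and a != DIAGONAL[action])


class Outcome(NamedTuple):
    """Result of one trial: the correct flag and the binary reward."""

    correct: bool
    reward: int

    @classmethod
    def from_correct(cls, correct: bool) -> "Outcome":
        return cls(correct=correct, reward=1 if correct else 0)


class TrialRecord(NamedTuple):
    """Immutable (action, correct) pair; the unit of the agent's history."""

    action: Action
    correct: bool


# A history is a chronological list of TrialRecords; ``history[-1]`` is the
# previous trial, ``history[-2]`` two trials ago, and so on.  State keys are
# recent-first tuples of TrialRecords: ``key[0]`` is the most recent trial
# the state refers to.
History = list
StateKey = tuple
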