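"""Seeded task simulators: two-target search, three-target search, bandit.

All three expose ``step(action) -> (Outcome, switched)`` where ``switched``
flags the trial on which the hidden configuration changed (always False
for the bandit, which has no hidden dynamics).  One time step is one trial:
the agent gazes at a spot and receives the binary outcome.
"""

from __future__ import annotations

import random

from .actions import ACTIONS, Action, Outcome, PAIR_IDS, PAIRS


class TwoTargetEnv:
    """Two-target search: a hidden valid pair of adjacent spots.

    Within the pair the correct spot alternates after every correct trial;
    an error leaves the pair and correct spot unchanged (the trial is
    effectively repeated) but resets the run of consecutive correct
    answers.  After ``switch_threshold`` consecutive correct trials the
    pair switches uniformly at random to one of the other three pairs and
    the new correct spot is a uniform member of the new pair.
    """

    name = "two-target"

    def __init__(self, rng: random.Random, switch_threshold: int = 7) -> None:
        self.rng = rng
        self.switch_threshold = switch_threshold
        self.valid_pair: str = PAIR_IDS[rng.randrange(4)]
        self.correct_spot: Action = PAIRS[self.valid_pair][rng.randrange(2)]
        self.consecutive_correct = 0

    def _other_member(self) -> Action:
        a, b = PAIRS[self.valid_pair]
        return b if self.correct_spot == a else a

    def step(self, action: Action) -> tuple[Outcome, bool]:
        if action != self.correct_spot:
            self.consecutive_correct = 0
            return Outcome.from_correct(False), False
        self.consecutive_correct += 1
        if self.consecutive_correct >= self.switch_threshold:
            others = [p for p in PAIR_IDS if p != self.valid_pair]
            self.valid_pair = others[self.rng.randrange(3)]
            self.correct_spot = PAIRS[self.valid_pair][self.rng.randrange(2)]
            self.consecutive_correct = 0
            return Outcome.from_correct(True), True
        self.correct_spot = self._other_member()
        return Outcome.from_correct(True), False

    def hidden_state(self) -> tuple[str, str]:
        return self.valid_pair, self.correct_spot.name


#: Rotational order of the corners as drawn on screen (counterclockwise).
CCW_CYCLE: tuple[Action, ...] = (Action.RU, Action.LU, Action.LD, Action.RD)


class ThreeTargetEnv:
    """Three-target search: three of the four spots are cycled in order.

    One spot is excluded; correct answers advance the rewarded spot through
    the remaining three in a fixed rotational direction.  After
    ``switch_threshold`` consecutive correct trials a new configuration
    (excluded spot, direction) different from the current one is drawn
    uniformly, with a uniform initial correct spot among its three targets.
    """

    name = "three-target"

    _CONFIGS = [(spot, d) for spot in ACTIONS for d in ("ccw", "cw")]

    def __init__(self, rng: random.Random, switch_threshold: int = 7) -> None:
        self.rng = rng
        self.switch_threshold = switch_threshold
        self.excluded_spot, self.direction = self._CONFIGS[rng.randrange(8)]
        self.correct_spot = self._random_valid_spot()
        self.consecutive_correct = 0

    def _random_valid_spot(self) -> Action:
        valid = [a for a in ACTIONS if a != self.excluded_spot]
        return valid[self.rng.randrange(3)]

    def _next_spot(self, spot: Action) -> Action:
        step = 1 if self.direction == "ccw" else -1
        i = CCW_CYCLE.index(spot)
        while True:
            i = (i + step) % 4
            if CCW_CYCLE[i] != self.excluded_spot:
                return CCW_CYCLE[i]

    def step(self, action: Action) -> tuple[Outcome, bool]:
        if action != self.correct_spot:
            self.consecutive_correct = 0
            return Outcome.from_correct(False), False
        self.consecutive_correct += 1
        if self.consecutive_correct >= self.switch_threshold:
            current = (self.excluded_spot, self.direction)
            others = [c for c in self._CONFIGS if c != current]
            self.excluded_spot, self.direction = others[self.rng.randrange(7)]
            self.correct_spot = self._random_valid_spot()
            self.consecutive_correct = 0
            return Outcome.from_correct(True), True
        self.correct_spot = self._next_spot(self.correct_spot)
        return Outcome.from_correct(True), False

    def hidden_state(self) -> tuple[str, str]:
        return f"ex-{self.excluded_spot.name}-{self.direction}", self.correct_spot.name


class BanditEnv:
    """Four-armed Bernoulli bandit on the same four gaze targets.

    Each spot has a fixed reward probability; a rewarded pull counts as
    correct.  There is no hidden state to switch.
    """

    name = "bandit"

    #: single best arm (distinct probabilities)
    DISTINCT = (0.8, 0.6, 0.4, 0.2)
    #: two arms tied at the highest probability
    TWO_BEST = (0.7, 0.7, 0.4, 0.2)

    def __init__(self, rng: random.Random,
                 reward_probabilities=DISTINCT) -> None:
        if len(reward_probabilities) != 4 or not all(
            0.0 <= p <= 1.0 for p in reward_probabilities
        ):
            raise ValueError(
                f"need 4 probabilities in [0, 1], got {reward_probabilities!r}"
            )
        self.rng = rng
        self.reward_probabilities = tuple(reward_probabilities)

    def step(self, action: Action) -> tuple[Outcome, bool]:
        rewarded = self.rng.random() < self.reward_probabilities[action]
        return Outcome.from_correct(rewarded), False

    def hidden_state(self) -> tuple[str, str]:
        return "", ""
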