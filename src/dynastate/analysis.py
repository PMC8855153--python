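"""Behavioral readouts computed from per-trial run logs.

A run log is a pandas DataFrame with one row per trial and columns::

    trial, action, correct, reward, depth_used, n_states,
    valid_pair, correct_spot, pair_switched, total_learning

``action`` and ``correct_spot`` hold spot names ("RU", ...); ``depth_used``
is the number of previous trials the state used for action selection
referred to (0 on bootstrap trials with insufficient history);
``pair_switched`` marks the trial whose seventh consecutive correct answer
triggered a hidden-pair switch; ``total_learning`` is filled on switch
trials only (NaN elsewhere).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .actions import Action, DIAGONAL, PAIRS

#: categories for the second exploration-trial gaze, relative to the first
#: (error) exploration gaze: its diagonal partner, the same spot again, the
#: adjacent spot that was correct two trials earlier, or the other adjacent.
EXPLORATION_CATEGORIES = (
    "diagonal",
    "same",
    "adjacent_prev_correct",
    "adjacent_other",
)


def moving_correct_rate(log: pd.DataFrame, window: int = 1000) -> pd.Series:
    """Sliding-window mean of the correct flag, indexed by trial."""
    if window < 1:
        raise ValueError(f"window must be >= 1, got {window}")
    correct = log["correct"].astype(float)
    if window > len(log):
        return pd.Series([correct.mean()], index=[len(log)], name="correct_rate")
    s = correct.rolling(window).mean().dropna()
    s.index = log["trial"].iloc[window - 1:]
    s.name = "correct_rate"
    return s


def reference_depth_fractions(log: pd.DataFrame, window: int = 1000) -> pd.DataFrame:
    """Fractions of action selections using depth 1, 2, >=3 per trial block.

    Bootstrap trials (depth 0: not enough history to match any state) are
    excluded from the denominator; within each non-overlapping block of
    ``window`` trials the three fractions sum to 1.
    """
    depth = log["depth_used"].to_numpy()
    trial = log["trial"].to_numpy()
    block = (trial - 1) // window
    df = pd.DataFrame(
        {
            "block": block,
            "d1": depth == 1,
            "d2": depth == 2,
            "d3plus": depth >= 3,
            "counted": depth >= 1,
        }
    )
    g = df.groupby("block").sum()
    denom = g["counted"].replace(0, np.nan)
    out = pd.DataFrame(
        {
            "depth_1": g["d1"] / denom,
            "depth_2": g["d2"] / denom,
            "depth_3plus": g["d3plus"] / denom,
        }
    )
    out.index = (out.index + 1) * window
    out.index.name = "trial"
    return out


def classify_second_trial(first_error_gaze: Action, second_gaze: Action,
                          prev_correct_gaze: Action) -> str:
    """Category of the second exploration gaze relative to the first error."""
    if second_gaze == DIAGONAL[first_error_gaze]:
        return "diagonal"
    if second_gaze == first_error_gaze:
        return "same"
    if second_gaze == prev_correct_gaze:
        return "adjacent_prev_correct"
    return "adjacent_other"


def exploration_second_trial_rates(log: pd.DataFrame,
                                   window: int = 5000) -> pd.DataFrame:
    """Where does the agent look on the second trial after a pair switch?

    An episode anchors on a switch at trial t-2 (the last, correct,
    exploitation trial), requires an error on trial t-1 (the first
    exploration trial — switches the agent survives by chance are
    excluded), and classifies trial t's gaze relative to trial t-1's.
    Rates are per non-overlapping block of ``window`` trials and sum to 1
    over the four categories within each block that has episodes.
    """
    switched = log["pair_switched"].to_numpy().astype(bool)
    correct = log["correct"].to_numpy().astype(bool)
    actions = log["action"].to_numpy()
    trial = log["trial"].to_numpy()
    n = len(log)

    rows = []
    for i in np.flatnonzero(switched):
        if i + 2 >= n or correct[i + 1]:
            continue
        cat = classify_second_trial(
            Action[actions[i + 1]], Action[actions[i + 2]], Action[actions[i]]
        )
        rows.append((int((trial[i] - 1) // window), cat))
    counts = pd.DataFrame(rows, columns=["block", "category"])
    if counts.empty:
        return pd.DataFrame(columns=EXPLORATION_CATEGORIES)
    table = (
        counts.groupby("block")["category"]
        .value_counts(normalize=True)
        .unstack(fill_value=0.0)
        .reindex(columns=EXPLORATION_CATEGORIES, fill_value=0.0)
    )
    table.index = (table.index + 1) * window
    table.index.name = "trial"
    return table


def total_learning(q_rows, q_init: float = 0.5) -> float:
    """Sum over all states and actions of |Q - q_init|.

    Zero iff every action value sits at its initial value; adding a fresh
    (all-``q_init``) state leaves it unchanged.
    """
    return float(sum(abs(q - q_init) for row in q_rows for q in row))


@dataclass
class SwitchEvent:
    """One hidden-pair switch with its perseveration run length."""

    trial: int
    old_pair: str
    new_pair: str
    perseveration: int
    total_learning: float


def extract_switch_events(log: pd.DataFrame) -> list[SwitchEvent]:
    """Switch events with post-switch perseveration counts.

    Perseveration is the maximal run of trials immediately after the
    switch whose gaze stays within the previously valid pair's two spots
    (a gaze at a spot shared with the new pair still counts as adhering
    to the old pair).
    """
    switched = log["pair_switched"].to_numpy().astype(bool)
    actions = log["action"].to_numpy()
    pairs = log["valid_pair"].to_numpy()
    trial = log["trial"].to_numpy()
    tl = log["total_learning"].to_numpy()
    n = len(log)

    events = []
    for i in np.flatnonzero(switched):
        old_pair = pairs[i]
        new_pair = pairs[i + 1] if i + 1 < n else ""
        members = {a.name for a in PAIRS[old_pair]}
        count = 0
        j = i + 1
        while j < n and actions[j] in members:
            count += 1
            j += 1
        events.append(
            SwitchEvent(
                trial=int(trial[i]),
                old_pair=old_pair,
                new_pair=new_pair,
                perseveration=count,
                total_learning=float(tl[i]),
            )
        )
    return events


def perseveration_analysis(
    log: pd.DataFrame,
    trial_range: tuple[int, int] = (50_000, 100_000),
) -> tuple[list[SwitchEvent], float | None]:
    """Switch events in range and Pearson r between learning and perseveration.

    Returns ``(events, r)``; ``r`` is None when fewer than two events exist
    or either variable has zero variance.
    """
    lo, hi = trial_range
    events = [e for e in extract_switch_events(log) if lo <= e.trial <= hi]
    if len(events) < 2:
        return events, None
    x = np.array([e.total_learning for e in events])
    y = np.array([e.perseveration for e in events], dtype=float)
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        return events, None
    r = float(stats.pearsonr(x, y).statistic)
    return events, r


def count_pair_switches(log: pd.DataFrame,
                        trial_range: tuple[int, int] | None = None) -> int:
    """Number of hidden-pair switches, optionally within [lo, hi] inclusive."""
    mask = log["pair_switched"].to_numpy().astype(bool)
    if trial_range is not None:
        lo, hi = trial_range
        trial = log["trial"].to_numpy()
        mask = mask & (trial >= lo) & (trial <= hi)
    return int(mask.sum())


def summarize(log: pd.DataFrame, window: int = 1000) -> dict:
    """Headline numbers of one run: final rate, state counts, switches."""
    rate = moving_correct_rate(log, window)
    return {
        "n_trials": int(len(log)),
        "final_correct_rate": float(rate.iloc[-1]),
        "max_n_states": int(log["n_states"].max()),
        "final_n_states": int(log["n_states"].iloc[-1]),
        "max_depth_used": int(log["depth_used"].max()),
        "pair_switches": count_pair_switches(log),
    }
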