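import random

import pandas as pd
import pytest

from dynastate.actions import ACTIONS, TrialRecord


@pytest.fixture
def rng():
    return random.Random(12345)


def make_log(rows):
    """Build a run-log DataFrame from (action, correct, valid_pair, switched,
    total_learning) tuples; depth/state columns filled with placeholders."""
    df = pd.DataFrame(
        rows, columns=["action", "correct", "valid_pair", "pair_switched",
                       "total_learning"],
    )
    df.insert(0, "trial", range(1, len(df) + 1))
    df["reward"] = df["correct"].astype(int)
    df["depth_used"] = 1
    df["n_states"] = 8
    df["correct_spot"] = ""
    return df


@pytest.fixture
def record_pool():
    return [TrialRecord(a, c) for a in ACTIONS for c in (False, True)]
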