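"""Q-learning substrate shared by every agent.

Action values are updated by the one-step, undiscounted reward-prediction
error rule

    Q(s, a) <- Q(s, a) + alpha * (r - Q(s, a)),

and actions are drawn from the softmax policy

    P(a_j | s) = exp(beta * Q(s, a_j)) / sum_k exp(beta * Q(s, a_k)),

where ``beta`` is the inverse temperature.  States are keyed by suffixes of
the trial history (most recent trial first); action selection always uses
the deepest state whose key matches the recent history.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field

from .actions import ACTIONS, Action, StateKey, TrialRecord

N_ACTIONS = 4


@dataclass
class AgentConfig:
    """Parameters of the dynamic-state agent.

    alpha : learning rate, in (0, 1].
    beta : softmax inverse temperature, >= 0; higher is greedier.
    zeta : experience-saturation threshold on the update KLD, in nats.
    eta : decision-uniqueness threshold on the ideal-policy KLD, in nats.
    bias : margin a child state must beat its parent's uniqueness KLD by
        before it is kept (negative values demand strict improvement).
    q_init : initial action value for every new state.
    """

    alpha: float = 0.1
    beta: float = 7.0
    zeta: float = 1e-6
    eta: float = 3.0
    bias: float = -1.0
    q_init: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError(f"alpha must be in (0, 1], got {self.alpha}")
        if self.beta < 0.0:
            raise ValueError(f"beta must be >= 0, got {self.beta}")
        if self.zeta <= 0.0:
            raise ValueError(f"zeta must be > 0, got {self.zeta}")
        if self.eta <= 0.0:
            raise ValueError(f"eta must be > 0, got {self.eta}")
        if not 0.0 <= self.q_init <= 1.0:
            raise ValueError(f"q_init must be in [0, 1], got {self.q_init}")


def softmax_policy(q_values, beta: float):
    """Softmax over four action values; returns a list of 4 probabilities.

    Strictly positive and sums to 1 for finite inputs.  Shift-invariant
    (the max is subtracted) so large ``beta * q`` cannot overflow.
    """
    if beta < 0.0:
        raise ValueError(f"beta must be >= 0, got {beta}")
    z = [beta * q for q in q_values]
    for v in z:
        if not math.isfinite(v):
            raise ValueError(f"non-finite action value in {q_values!r}")
    m = max(z)
    e = [math.exp(v - m) for v in z]
    s = e[0] + e[1] + e[2] + e[3]
    return [v / s for v in e]


@dataclass
class StateNode:
    """One state: a history suffix with its Q-values and policy statistics.

    ``mean_policy`` is the running (Cesàro) average of the per-update
    softmax policies; ``prev_mean_policy`` is the average before the most
    recent update.  ``parent_d_kld`` holds the decision-uniqueness KLD the
    parent saved when it first expanded (None for depth-1 nodes, which have
    no parent); ``d_kld_as_parent`` is this node's own saved value, set at
    its first expansion and inherited by every child it creates.
    """

    key: StateKey
    q_values: list = field(default_factory=lambda: [0.5] * N_ACTIONS)
    n_update: int = 0
    mean_policy: list | None = None
    prev_mean_policy: list | None = None
    parent_d_kld: float | None = None
    d_kld_as_parent: float | None = None
    children: dict = field(default_factory=dict)

    @property
    def depth(self) -> int:
        return len(self.key)


def q_update(node: StateNode, action: Action, reward: int, alpha: float) -> float:
    """Apply the prediction-error update to one action value.

    Returns the prediction error ``delta = r - Q`` and increments the
    node's update counter.
    """
    if reward not in (0, 1):
        raise ValueError(f"reward must be 0 or 1, got {reward}")
    delta = reward - node.q_values[action]
    node.q_values[action] += alpha * delta
    node.n_update += 1
    return delta


class StateStore:
    """Tree of :class:`StateNode` keyed by recent-first history suffixes.

    The eight depth-1 nodes (4 actions x 2 outcomes) always exist; every
    deeper node's parent (its key minus the earliest record) is present —
    the store is a forest of eight trees.
    """

    def __init__(self, q_init: float = 0.5) -> None:
        self.q_init = q_init
        self.nodes: dict[StateKey, StateNode] = {}
        for a in ACTIONS:
            for correct in (False, True):
                key = (TrialRecord(a, correct),)
                self.nodes[key] = StateNode(key=key, q_values=[q_init] * N_ACTIONS)

    def __len__(self) -> int:
        return len(self.nodes)

    def __contains__(self, key: StateKey) -> bool:
        return key in self.nodes

    def get(self, key: StateKey) -> StateNode | None:
        return self.nodes.get(key)

    def add_child(self, parent: StateNode, preceding: TrialRecord) -> StateNode:
        key = parent.key + (preceding,)
        if key in self.nodes:
            raise ValueError(f"state {key!r} already exists")
        child = StateNode(key=key, q_values=[self.q_init] * N_ACTIONS)
        self.nodes[key] = child
        parent.children[preceding] = child
        return child

    def prune(self, node: StateNode) -> int:
        """Remove ``node`` and its whole descendant subtree; returns count removed."""
        if node.depth == 1:
            raise ValueError("depth-1 states are never pruned")
        parent = self.nodes[node.key[:-1]]
        del parent.children[node.key[-1]]
        removed = 0
        stack = [node]
        while stack:
            n = stack.pop()
            del self.nodes[n.key]
            removed += 1
            stack.extend(n.children.values())
        return removed

    def snapshot(self) -> list[dict]:
        """JSON-serialisable view of the store (key, Q, update count, parent KLD)."""
        out = []
        for key in sorted(self.nodes, key=lambda k: (len(k), k)):
            n = self.nodes[key]
            out.append(
                {
                    "key": [[rec.action.name, rec.correct] for rec in key],
                    "q_values": list(n.q_values),
                    "n_update": n.n_update,
                    "parent_d_kld": n.parent_d_kld,
                }
            )
        return out


def match_state(history, store: StateStore) -> StateNode:
    """Deepest state whose key matches the most recent trials of ``history``.

    Always succeeds for non-empty history because the eight depth-1 nodes
    exist at all times.
    """
    if not history:
        raise ValueError("empty history: no state to match (bootstrap trial)")
    node = store.nodes[(history[-1],)]
    d = 1
    n = len(history)
    while d < n:
        child = node.children.get(history[-1 - d])
        if child is None:
            break
        node = child
        d += 1
    return node


def select_action(policy, rng: random.Random) -> Action:
    """Sample one action by inverse CDF over the fixed order (RU, LU, LD, RD)."""
    total = policy[0] + policy[1] + policy[2] + policy[3]
    if not math.isfinite(total) or abs(total - 1.0) > 1e-9 or min(policy) < 0.0:
        raise ValueError(f"policy is not a probability vector: {policy!r}")
    u = rng.random()
    acc = 0.0
    for a in ACTIONS:
        acc += policy[a]
        if u < acc:
            return a
    return ACTIONS[-1]
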