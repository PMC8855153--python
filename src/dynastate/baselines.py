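"""Comparison agents: fixed-state Q-learners, a belief-state (POMDP) agent,
and Chinese-restaurant-process (iHMM-style) agents.

The fixed agents share the Q-learning substrate but key their states by a
fixed-arity window of recent trials: the previous action only (4 states),
the previous action and outcome (8 states), or the previous two trials
(8 x 8 = 64 states — the ideal state space for the two-target task).

The POMDP agent refers only to the previous trial but maintains a belief
over the four candidate valid pairs; its Q-table has one row per
(one-trial state, pair) — 32 rows — and actions are chosen from the
belief-weighted composite Q.

The CRP agents grow a suffix tree of states without any appropriateness
criterion: at each state, per-action guest counts g_j give action
probabilities g_j / (sum g + lambda), and the residual lambda mass
triggers creation of a child state referring to one more previous trial.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .actions import ACTIONS, Action, Outcome, PAIRS_OF_SPOT, PAIR_IDS, TrialRecord
from .core import AgentConfig, q_update, select_action, softmax_policy, StateNode


# ---------------------------------------------------------------- fixed-state

SCHEMES = {"action-only": 1, "action+outcome": 1, "two-trial": 2}


def fixed_state_key(history, scheme: str):
    """State key for a fixed-arity scheme, from the most recent trials."""
    if scheme == "action-only":
        return history[-1].action
    if scheme == "action+outcome":
        return history[-1]
    if scheme == "two-trial":
        return (history[-1], history[-2])
    raise ValueError(f"unknown scheme {scheme!r}")


def _all_keys(scheme: str):
    records = [TrialRecord(a, c) for a in ACTIONS for c in (False, True)]
    if scheme == "action-only":
        return list(ACTIONS)
    if scheme == "action+outcome":
        return records
    return [(r1, r2) for r1 in records for r2 in records]


class FixedStateAgent:
    """Q-learner over a fixed state space (4, 8 or 64 states)."""

    def __init__(self, scheme: str = "action+outcome",
                 config: AgentConfig | None = None,
                 rng: random.Random | None = None) -> None:
        if scheme not in SCHEMES:
            raise ValueError(f"unknown scheme {scheme!r}")
        self.scheme = scheme
        self.arity = SCHEMES[scheme]
        self.config = config or AgentConfig()
        self.rng = rng or random.Random()
        self.nodes = {
            k: StateNode(key=k, q_values=[self.config.q_init] * 4)
            for k in _all_keys(scheme)
        }
        self.history: list[TrialRecord] = []
        self._node: StateNode | None = None
        self.name = f"fixed-{len(self.nodes)}"

    def act(self) -> tuple[Action, int]:
        if len(self.history) < self.arity:
            self._node = None
            return ACTIONS[self.rng.randrange(4)], 0
        node = self.nodes[fixed_state_key(self.history, self.scheme)]
        self._node = node
        policy = softmax_policy(node.q_values, self.config.beta)
        return select_action(policy, self.rng), self.arity

    def observe(self, action: Action, outcome: Outcome) -> None:
        if self._node is not None:
            q_update(self._node, action, outcome.reward, self.config.alpha)
        self.history.append(TrialRecord(action, outcome.correct))

    @property
    def n_states(self) -> int:
        return len(self.nodes)

    def iter_q_values(self):
        for node in self.nodes.values():
            yield node.q_values


# --------------------------------------------------------------------- POMDP


def pomdp_composite_q(table, beliefs, state):
    """Belief-weighted composite Q over the four pair hypotheses."""
    if abs(sum(beliefs) - 1.0) > 1e-9 or min(beliefs) < 0.0:
        raise ValueError(f"beliefs are not a probability vector: {beliefs!r}")
    out = [0.0, 0.0, 0.0, 0.0]
    for k, b in enumerate(beliefs):
        row = table[(PAIR_IDS[k], state)]
        for j in range(4):
            out[j] += b * row[j]
    return out


def pomdp_update(table, beliefs, state, action: Action, outcome: Outcome,
                 alpha: float, kappa: float = 0.2, floor: float = 0.01):
    """Per-pair prediction-error updates plus the belief update.

    Each pair's row for the selected action moves by alpha * b_k * delta_k.
    Beliefs of the two pairs containing the gazed spot move by +kappa on a
    correct trial and -kappa on an error, are floored at ``floor``, then
    renormalised to sum to 1.
    """
    r = outcome.reward
    for k, b in enumerate(beliefs):
        row = table[(PAIR_IDS[k], state)]
        row[action] += alpha * b * (r - row[action])
    step = kappa if outcome.correct else -kappa
    touched = PAIRS_OF_SPOT[action]
    new_b = [
        max(b + (step if PAIR_IDS[k] in touched else 0.0), floor)
        for k, b in enumerate(beliefs)
    ]
    total = sum(new_b)
    return [b / total for b in new_b]


class PomdpAgent:
    """Belief-state agent: one-trial states, belief over the valid pair.

    The task's four candidate pairs are prior knowledge here — the agent
    infers which is valid rather than discovering the structure.
    """

    name = "pomdp"

    def __init__(self, config: AgentConfig | None = None,
                 rng: random.Random | None = None,
                 kappa: float = 0.2, belief_floor: float = 0.01) -> None:
        self.config = config or AgentConfig()
        self.rng = rng or random.Random()
        self.kappa = kappa
        self.belief_floor = belief_floor
        states = [TrialRecord(a, c) for a in ACTIONS for c in (False, True)]
        self.table = {
            (pid, s): [self.config.q_init] * 4 for pid in PAIR_IDS for s in states
        }
        self.beliefs = [0.25, 0.25, 0.25, 0.25]
        self.history: list[TrialRecord] = []
        self._state: TrialRecord | None = None

    def act(self) -> tuple[Action, int]:
        if not self.history:
            self._state = None
            return ACTIONS[self.rng.randrange(4)], 0
        self._state = self.history[-1]
        composite = pomdp_composite_q(self.table, self.beliefs, self._state)
        policy = softmax_policy(composite, self.config.beta)
        return select_action(policy, self.rng), 1

    def observe(self, action: Action, outcome: Outcome) -> None:
        if self._state is not None:
            self.beliefs = pomdp_update(
                self.table, self.beliefs, self._state, action, outcome,
                self.config.alpha, self.kappa, self.belief_floor,
            )
        self.history.append(TrialRecord(action, outcome.correct))

    @property
    def n_states(self) -> int:
        return len(self.table)

    def iter_q_values(self):
        for row in self.table.values():
            yield row


# ----------------------------------------------------------------------- CRP


@dataclass
class CrpConfig:
    """Concentration parameter and process variant for the CRP agents."""

    lam: float = 0.2
    version: str = "dirichlet"  # or "hierarchical"

    def __post_init__(self) -> None:
        if self.lam < 0.0:
            raise ValueError(f"lambda must be >= 0, got {self.lam}")
        if self.version not in ("dirichlet", "hierarchical"):
            raise ValueError(f"unknown CRP version {self.version!r}")


@dataclass
class CrpNode:
    """One CRP state: permanent pseudo-guests plus earned guests per action table."""

    key: tuple
    pseudo: list = field(default_factory=lambda: [1.0] * 4)
    earned: list = field(default_factory=lambda: [0] * 4)
    children: dict = field(default_factory=dict)

    @property
    def depth(self) -> int:
        return len(self.key)

    def totals(self) -> list:
        return [p + e for p, e in zip(self.pseudo, self.earned)]


def crp_policy(node: CrpNode, config: CrpConfig):
    """Action masses g_j/(G + lambda) and the residual expansion mass lambda/(G + lambda)."""
    g = node.totals()
    denom = sum(g) + config.lam
    if denom <= 0.0:
        raise ValueError("CRP node has no guests and lambda = 0")
    return [gj / denom for gj in g], config.lam / denom


class CrpAgent:
    """iHMM-style agent growing states by the Chinese restaurant process.

    ``dirichlet`` children start with one permanent pseudo-guest per table
    (a uniform, from-scratch initialisation, mirroring the dynamic agent's
    neutral child Q); ``hierarchical`` children inherit the parent's
    normalised guest distribution as pseudo-guest mass (total 4).  On a
    correct trial a guest is seated at the chosen action's table; on an
    error one earned guest is removed, and a state left with an empty
    table is pruned with its subtree.
    """

    def __init__(self, crp_config: CrpConfig | None = None,
                 rng: random.Random | None = None) -> None:
        self.crp_config = crp_config or CrpConfig()
        self.rng = rng or random.Random()
        self.base = CrpNode(key=())
        self.nodes: dict[tuple, CrpNode] = {(): self.base}
        self.history: list[TrialRecord] = []
        self._node: CrpNode | None = None
        self.name = f"crp-{self.crp_config.version}"

    def _match(self) -> CrpNode:
        node = self.base
        d = 0
        n = len(self.history)
        while d < n:
            child = node.children.get(self.history[-1 - d])
            if child is None:
                break
            node = child
            d += 1
        return node

    def _make_child(self, parent: CrpNode, preceding: TrialRecord) -> CrpNode:
        if self.crp_config.version == "dirichlet":
            pseudo = [1.0] * 4
        else:
            g = parent.totals()
            total = sum(g)
            pseudo = [4.0 * gj / total for gj in g]
        child = CrpNode(key=parent.key + (preceding,), pseudo=pseudo)
        parent.children[preceding] = child
        self.nodes[child.key] = child
        return child

    def _draw_action(self, node: CrpNode) -> Action:
        g = node.totals()
        total = sum(g)
        u = self.rng.random() * total
        acc = 0.0
        for a in ACTIONS:
            acc += g[a]
            if u < acc:
                return a
        return ACTIONS[-1]

    def act(self) -> tuple[Action, int]:
        node = self._match()
        masses, expansion_mass = crp_policy(node, self.crp_config)
        u = self.rng.random()
        if u < expansion_mass:
            depth = node.depth
            preceding = (
                self.history[-(depth + 1)] if len(self.history) > depth else None
            )
            if preceding is not None and preceding not in node.children:
                node = self._make_child(node, preceding)
            # else: child exists (or history too short) — redraw from the
            # current node's action masses renormalised
        self._node = node
        return self._draw_action(node), node.depth

    def observe(self, action: Action, outcome: Outcome) -> None:
        node = self._node
        if node is not None:
            if outcome.correct:
                node.earned[action] += 1
            else:
                node.earned[action] = max(0, node.earned[action] - 1)
                if node.depth > 0 and min(node.totals()) <= 0.0:
                    self._prune(node)
        self.history.append(TrialRecord(action, outcome.correct))

    def _prune(self, node: CrpNode) -> None:
        parent = self.nodes[node.key[:-1]]
        del parent.children[node.key[-1]]
        stack = [node]
        while stack:
            n = stack.pop()
            del self.nodes[n.key]
            stack.extend(n.children.values())

    @property
    def n_states(self) -> int:
        return len(self.nodes)
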