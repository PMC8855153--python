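"""Dynamic state-space agent: expansion and contraction by two KLD criteria.

Each state keeps a Cesàro (running) average of the softmax policies it has
produced, one per Q-update.  After every trial the state just used is put
through a two-gate test:

* **Experience saturation** — the Kullback-Leibler divergence between the
  current and previous mean policies (the information gained by the last
  update) has fallen below ``zeta``: updating this state no longer teaches
  the agent anything.
* **Decision uniqueness** — the KLD between the mean policy and an
  idealised policy (softmax of a one-hot Q at the argmax) is below ``eta``:
  the state already supports a near-deterministic choice.

A saturated state that is *not* unique is a candidate for expansion: a
child state is created that refers to one more previous trial, on the bet
that the longer history disambiguates the decision.  A deeper state whose
uniqueness KLD fails to beat its parent's stored value by ``bias`` is
instead pruned together with its subtree — the extra history did not help.
Depth-1 states are never pruned (they have no parent to compare with).

A state saves its uniqueness KLD the first time it expands, and that value
— the parent's uniqueness at the moment it first judged its own history
insufficient — is the reference every one of its children is compared
against, including children re-created after pruning.  Freezing the
reference early keeps the parent-child comparison anchored to the
uncertainty that motivated expansion in the first place; later transient
spikes of the parent's KLD (a state whose mean policy is concentrated on
an action that momentarily loses the Q argmax scores a large divergence)
would otherwise license runaway deepening of the tree.

Both divergences use natural logarithms; ``zeta`` and ``eta`` are in nats.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass

from .actions import ACTIONS, Action, Outcome, TrialRecord
from .core import (
    AgentConfig,
    StateNode,
    StateStore,
    match_state,
    q_update,
    select_action,
    softmax_policy,
)


def kl_divergence(p, q) -> float:
    """KLD sum_j p_j ln(p_j / q_j) in nats; both vectors must be positive."""
    total = 0.0
    for pj, qj in zip(p, q):
        if pj <= 0.0 or qj <= 0.0:
            raise ValueError("KLD requires strictly positive probabilities")
        total += pj * math.log(pj / qj)
    return total


def update_kld(new_mean, old_mean) -> float:
    """Information gained by the latest mean-policy update (Eq-saturation KLD)."""
    return kl_divergence(new_mean, old_mean)


def d_kld(mean_policy, ideal) -> float:
    """Decision-uniqueness KLD between the mean policy and the ideal policy."""
    return kl_divergence(mean_policy, ideal)


def ideal_policy(q_values, beta: float):
    """Softmax of the one-hot Q placing 1 at the argmax (ties: lowest index)."""
    one_hot = [0.0] * len(q_values)
    one_hot[q_values.index(max(q_values))] = 1.0
    return softmax_policy(one_hot, beta)


def cesaro_update(node: StateNode, new_policy) -> None:
    """Fold this trial's policy into the node's running mean.

    ``node.n_update`` must already count the current update; the previous
    mean is retained so the saturation KLD can be computed.
    """
    n = node.n_update
    if n < 1:
        raise ValueError("cesaro_update before any Q-update")
    if node.mean_policy is None:
        node.prev_mean_policy = None
        node.mean_policy = list(new_policy)
    else:
        node.prev_mean_policy = list(node.mean_policy)
        m = node.mean_policy
        for j in range(len(m)):
            m[j] += (new_policy[j] - m[j]) / n


@dataclass
class KldReport:
    """The two divergences and their threshold verdicts for one state/trial."""

    update_kld: float
    d_kld: float | None
    saturated: bool
    unique: bool | None


@dataclass
class ExpansionDecision:
    """Outcome of one pass through the expansion/contraction flowchart."""

    verdict: str  # "no-action" | "kept" | "expanded" | "pruned"
    report: KldReport | None = None
    child_key: tuple | None = None


def expand_state(parent: StateNode, preceding: TrialRecord, store: StateStore,
                 parent_d_kld: float) -> StateNode:
    """Create the child extending ``parent`` by one more previous trial.

    The child starts from scratch: all Q at ``q_init``, no policy history;
    ``parent_d_kld`` (the parent's saved uniqueness KLD) is stored on it
    for the later parent-child comparison.
    """
    child = store.add_child(parent, preceding)
    child.parent_d_kld = parent_d_kld
    return child


def expansion_step(node: StateNode, history, store: StateStore,
                   config: AgentConfig) -> ExpansionDecision:
    """Run the expansion/contraction flowchart on the state just used.

    ``history`` is the trial history *before* the current trial's record is
    appended, i.e. the history the node was matched against; the child key
    extends the node's key by ``history[-(depth+1)]``.  Until a node has
    two updates the saturation KLD is undefined (treated as +inf).
    """
    if node.n_update < 2 or node.prev_mean_policy is None:
        return ExpansionDecision(
            "no-action",
            KldReport(math.inf, None, saturated=False, unique=None),
        )
    u_kld = update_kld(node.mean_policy, node.prev_mean_policy)
    if not u_kld < config.zeta:
        return ExpansionDecision(
            "no-action", KldReport(u_kld, None, saturated=False, unique=None)
        )
    ideal = ideal_policy(node.q_values, config.beta)
    dk = d_kld(node.mean_policy, ideal)
    if dk < config.eta:
        return ExpansionDecision(
            "kept", KldReport(u_kld, dk, saturated=True, unique=True)
        )
    report = KldReport(u_kld, dk, saturated=True, unique=False)
    depth = node.depth
    if depth == 1 or dk < node.parent_d_kld + config.bias:
        if len(history) < depth + 1:
            # cannot name the child yet; defer to a later encounter
            return ExpansionDecision("no-action", report)
        preceding = history[-(depth + 1)]
        if node.key + (preceding,) in store:
            return ExpansionDecision("no-action", report)
        if node.d_kld_as_parent is None:
            node.d_kld_as_parent = dk
        child = expand_state(node, preceding, store,
                             parent_d_kld=node.d_kld_as_parent)
        return ExpansionDecision("expanded", report, child_key=child.key)
    store.prune(node)
    return ExpansionDecision("pruned", report)


class DynamicStateAgent:
    """Q-learning agent whose state space grows and shrinks with experience.

    Starts with the eight one-trial states (4 actions x 2 outcomes) and,
    per trial: matches the deepest state consistent with recent history,
    acts by softmax, updates that state's Q and mean policy, then runs the
    expansion/contraction flowchart on it.  On the very first trial there
    is no history, so the action is uniform random and nothing is updated.
    """

    name = "dynamic"

    def __init__(self, config: AgentConfig | None = None,
                 rng: random.Random | None = None) -> None:
        self.config = config or AgentConfig()
        self.rng = rng or random.Random()
        self.store = StateStore(q_init=self.config.q_init)
        self.history: list[TrialRecord] = []
        self._node: StateNode | None = None
        self.last_decision: ExpansionDecision | None = None

    def act(self) -> tuple[Action, int]:
        """Choose an action; returns (action, depth of the state used; 0 = bootstrap)."""
        if not self.history:
            self._node = None
            return ACTIONS[self.rng.randrange(4)], 0
        node = match_state(self.history, self.store)
        self._node = node
        policy = softmax_policy(node.q_values, self.config.beta)
        return select_action(policy, self.rng), node.depth

    def observe(self, action: Action, outcome: Outcome) -> None:
        """Learn from the trial just completed and log its record."""
        node = self._node
        if node is not None:
            q_update(node, action, outcome.reward, self.config.alpha)
            cesaro_update(node, softmax_policy(node.q_values, self.config.beta))
            self.last_decision = expansion_step(
                node, self.history, self.store, self.config
            )
        self.history.append(TrialRecord(action, outcome.correct))

    @property
    def n_states(self) -> int:
        return len(self.store)

    def iter_q_values(self):
        """Q-values of every state, for the total-learning statistic."""
        for node in self.store.nodes.values():
            yield node.q_values

    def snapshot(self) -> list[dict]:
        return self.store.snapshot()
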