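"""Expansion/contraction machinery: KLDs, Cesàro means, the flowchart."""

import math
import random

import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from dynastate.actions import ACTIONS, Action, Outcome, TrialRecord
from dynastate.core import AgentConfig, StateNode, StateStore, softmax_policy
from dynastate.dynamic import (
    DynamicStateAgent, cesaro_update, d_kld, expand_state, expansion_step,
    ideal_policy, kl_divergence, update_kld,
)
from dynastate.tasks import BanditEnv, TwoTargetEnv

positive_policy = st.lists(
    st.floats(1e-6, 1.0), min_size=4, max_size=4
).map(lambda v: [x / sum(v) for x in v])


class TestKlDivergence:
    def test_identity(self):
        assert kl_divergence([0.25] * 4, [0.25] * 4) == 0.0

    def test_spec_example(self):
        new = [0.6236361547, 0.1254546151, 0.1254546151, 0.1254546151]
        assert update_kld(new, [0.25] * 4) == pytest.approx(0.3106, abs=5e-4)

    def test_uniform_vs_sharp_ideal(self):
        ideal = ideal_policy([1.0, 0.0, 0.0, 0.0], beta=7.0)
        assert d_kld([0.25] * 4, ideal) == pytest.approx(3.867, abs=5e-3)

    def test_mildly_concentrated_is_unique(self):
        ideal = ideal_policy([1.0, 0.0, 0.0, 0.0], beta=7.0)
        mean = [0.9, 0.1 / 3, 0.1 / 3, 0.1 / 3]
        assert d_kld(mean, ideal) == pytest.approx(0.27, abs=5e-3)

    @given(p=positive_policy, q=positive_policy)
    @settings(derandomize=True, max_examples=200)
    def test_matches_scipy_oracle_and_gibbs(self, p, q):
        ours = kl_divergence(p, q)
        assert ours == pytest.approx(float(stats.entropy(p, q)), abs=1e-10)
        assert ours >= -1e-12

    def test_rejects_zero_entries(self):
        with pytest.raises(ValueError):
            kl_divergence([0.5, 0.5, 0.0, 0.0], [0.25] * 4)


class TestIdealPolicy:
    def test_one_hot_at_argmax(self):
        # Q {0.1, 0.4, 0.2, 0.1} -> one-hot {0,1,0,0} -> sharp softmax
        policy = ideal_policy([0.1, 0.4, 0.2, 0.1], beta=7.0)
        assert policy[1] == pytest.approx(0.9972718174, abs=1e-9)
        assert policy[0] == pytest.approx(0.0009093942, abs=1e-9)

    def test_tie_breaks_to_lowest_index(self):
        policy = ideal_policy([0.5, 0.5, 0.5, 0.5], beta=7.0)
        assert policy[0] == max(policy)
        assert policy == ideal_policy([1.0, 0.0, 0.0, 0.0], beta=7.0)


class TestCesaroUpdate:
    def test_first_update_sets_mean(self):
        node = StateNode(key=("k",), n_update=1)
        cesaro_update(node, [0.1, 0.2, 0.3, 0.4])
        assert node.mean_policy == [0.1, 0.2, 0.3, 0.4]
        assert node.prev_mean_policy is None

    def test_constant_sequence_is_fixed_point(self):
        node = StateNode(key=("k",))
        p = [0.1, 0.2, 0.3, 0.4]
        for _ in range(3):
            node.n_update += 1
            cesaro_update(node, p)
        assert node.mean_policy == pytest.approx(p, abs=1e-15)

    def test_two_policy_average(self):
        node = StateNode(key=("k",), n_update=1)
        cesaro_update(node, [0.25] * 4)
        node.n_update += 1
        cesaro_update(node, softmax_policy([1.0, 0.0, 0.0, 0.0], 7.0))
        assert node.mean_policy == pytest.approx(
            [0.62364, 0.12545, 0.12545, 0.12545], abs=5e-5
        )
        assert node.prev_mean_policy == [0.25] * 4

    def test_requires_an_update_first(self):
        with pytest.raises(ValueError):
            cesaro_update(StateNode(key=("k",)), [0.25] * 4)

    @given(policies=st.lists(positive_policy, min_size=1, max_size=30))
    @settings(derandomize=True, max_examples=100)
    def test_matches_brute_force_average(self, policies):
        node = StateNode(key=("k",))
        for p in policies:
            node.n_update += 1
            cesaro_update(node, p)
        brute = [sum(p[j] for p in policies) / len(policies) for j in range(4)]
        assert node.mean_policy == pytest.approx(brute, abs=1e-10)


def saturated_node(key, q_values, mean, parent_d_kld=None):
    """A node whose last update left the mean unchanged (update KLD = 0)."""
    node = StateNode(key=key, q_values=list(q_values), n_update=50,
                     mean_policy=list(mean), prev_mean_policy=list(mean),
                     parent_d_kld=parent_d_kld)
    return node


def rec(a, c=True):
    return TrialRecord(a, c)


class TestExpansionStep:
    def setup_method(self):
        self.config = AgentConfig()
        self.store = StateStore()

    def test_unsaturated_is_no_action(self):
        node = self.store.nodes[(rec(Action.RU),)]
        node.n_update = 2
        node.mean_policy = [0.25] * 4
        node.prev_mean_policy = [0.4, 0.2, 0.2, 0.2]  # large update KLD
        decision = expansion_step(node, [rec(Action.RU)], self.store, self.config)
        assert decision.verdict == "no-action"
        assert not decision.report.saturated

    def test_fewer_than_two_updates_is_no_action(self):
        node = self.store.nodes[(rec(Action.RU),)]
        node.n_update = 1
        node.mean_policy = [0.25] * 4
        decision = expansion_step(node, [rec(Action.RU)], self.store, self.config)
        assert decision.verdict == "no-action"
        assert decision.report.update_kld == math.inf

    def test_saturated_unique_is_kept(self):
        mean = softmax_policy([1.0, 0.2, 0.2, 0.2], 7.0)
        node = self.store.nodes[(rec(Action.RU),)]
        node.q_values = [1.0, 0.2, 0.2, 0.2]
        node.n_update, node.mean_policy, node.prev_mean_policy = 50, mean, list(mean)
        decision = expansion_step(node, [rec(Action.RU)], self.store, self.config)
        assert decision.verdict == "kept"
        assert decision.report.unique
        assert len(self.store) == 8

    def test_depth_one_expands_with_fresh_child(self):
        node = self.store.nodes[(rec(Action.LD),)]
        node.n_update, node.mean_policy, node.prev_mean_policy = (
            50, [0.25] * 4, [0.25] * 4
        )
        history = [rec(Action.RD), rec(Action.LD)]
        decision = expansion_step(node, history, self.store, self.config)
        assert decision.verdict == "expanded"
        child = self.store.get((rec(Action.LD), rec(Action.RD)))
        assert child is not None
        assert child.q_values == [0.5] * 4
        assert child.n_update == 0
        assert child.parent_d_kld == pytest.approx(decision.report.d_kld)
        assert len(self.store) == 9

    def test_short_history_defers_expansion(self):
        node = self.store.nodes[(rec(Action.LD),)]
        node.n_update, node.mean_policy, node.prev_mean_policy = (
            50, [0.25] * 4, [0.25] * 4
        )
        decision = expansion_step(node, [rec(Action.LD)], self.store, self.config)
        assert decision.verdict == "no-action"
        assert len(self.store) == 8

    def test_existing_child_is_no_action(self):
        node = self.store.nodes[(rec(Action.LD),)]
        expand_state(node, rec(Action.RD), self.store, parent_d_kld=3.5)
        node.n_update, node.mean_policy, node.prev_mean_policy = (
            50, [0.25] * 4, [0.25] * 4
        )
        history = [rec(Action.RD), rec(Action.LD)]
        decision = expansion_step(node, history, self.store, self.config)
        assert decision.verdict == "no-action"
        assert len(self.store) == 9

    def test_deep_node_failing_parent_comparison_is_pruned(self):
        parent = self.store.nodes[(rec(Action.LD),)]
        child = expand_state(parent, rec(Action.RD), self.store, parent_d_kld=3.9)
        grandchild = expand_state(child, rec(Action.RU), self.store, parent_d_kld=3.9)
        child.n_update, child.mean_policy, child.prev_mean_policy = (
            50, [0.25] * 4, [0.25] * 4
        )
        history = [rec(Action.RU), rec(Action.RD), rec(Action.LD)]
        # uniform mean: D_KLD ~ 3.87, not < 3.9 - 1 -> prune child and subtree
        decision = expansion_step(child, history, self.store, self.config)
        assert decision.verdict == "pruned"
        assert child.key not in self.store
        assert grandchild.key not in self.store
        assert len(self.store) == 8

    def test_deep_node_beating_parent_expands(self):
        parent = self.store.nodes[(rec(Action.LD),)]
        child = expand_state(parent, rec(Action.RD), self.store, parent_d_kld=5.2)
        child.n_update = 50
        child.mean_policy = child.prev_mean_policy = [0.25] * 4
        history = [rec(Action.RU), rec(Action.RD), rec(Action.LD)]
        decision = expansion_step(child, history, self.store, self.config)
        assert decision.verdict == "expanded"
        assert (child.key + (rec(Action.RU),)) in self.store

    def test_depth_one_is_never_pruned(self):
        # same uniform mean that prunes a deep node only expands a root
        node = self.store.nodes[(rec(Action.LD, False),)]
        node.n_update, node.mean_policy, node.prev_mean_policy = (
            50, [0.25] * 4, [0.25] * 4
        )
        history = [rec(Action.RU), rec(Action.LD, False)]
        decision = expansion_step(node, history, self.store, self.config)
        assert decision.verdict == "expanded"
        assert node.key in self.store

    def test_parent_d_kld_saved_once_and_reused(self):
        node = self.store.nodes[(rec(Action.LD),)]
        node.n_update, node.mean_policy, node.prev_mean_policy = (
            50, [0.25] * 4, [0.25] * 4
        )
        first = expansion_step(node, [rec(Action.RD), rec(Action.LD)],
                               self.store, self.config)
        saved = node.d_kld_as_parent
        assert saved == pytest.approx(first.report.d_kld)
        # later the node's mean concentrates away from the Q argmax (a much
        # larger uniqueness KLD); a second child still inherits the
        # originally saved value
        node.q_values = [0.9, 0.1, 0.1, 0.1]
        node.mean_policy = node.prev_mean_policy = [0.1, 0.7, 0.1, 0.1]
        second = expansion_step(node, [rec(Action.LU), rec(Action.LD)],
                                self.store, self.config)
        assert second.verdict == "expanded"
        child = self.store.get((rec(Action.LD), rec(Action.LU)))
        assert child.parent_d_kld == saved


def check_tree_invariants(store):
    assert len(store) >= 8
    depth1 = [k for k in store.nodes if len(k) == 1]
    assert len(depth1) == 8
    for key in store.nodes:
        if len(key) > 1:
            assert key[:-1] in store.nodes


class TestDynamicAgentRuns:
    @pytest.mark.parametrize("env_factory", [
        TwoTargetEnv,
        lambda rng: BanditEnv(rng, BanditEnv.TWO_BEST),
    ])
    @pytest.mark.parametrize("seed", [0, 1])
    def test_invariants_hold_every_trial(self, env_factory, seed):
        rng = random.Random(seed)
        agent = DynamicStateAgent(AgentConfig(), rng)
        env = env_factory(rng)
        for _ in range(3000):
            action, depth = agent.act()
            outcome, _ = env.step(action)
            agent.observe(action, outcome)
            check_tree_invariants(agent.store)
            for node in agent.store.nodes.values():
                assert all(0.0 <= q <= 1.0 for q in node.q_values)

    def test_bootstrap_trial_has_no_state(self, rng):
        agent = DynamicStateAgent(AgentConfig(), rng)
        action, depth = agent.act()
        assert depth == 0
        agent.observe(action, Outcome.from_correct(True))
        assert len(agent.history) == 1
        assert all(n.n_update == 0 for n in agent.store.nodes.values())

    def test_pruned_state_restarts_fresh(self):
        store = StateStore()
        parent = store.nodes[(rec(Action.LD),)]
        child = expand_state(parent, rec(Action.RD), store, parent_d_kld=3.9)
        child.q_values = [0.9, 0.1, 0.1, 0.1]
        child.n_update = 7
        store.prune(child)
        reborn = expand_state(parent, rec(Action.RD), store, parent_d_kld=3.9)
        assert reborn.q_values == [0.5] * 4
        assert reborn.n_update == 0
        assert reborn.mean_policy is None

    def test_snapshot_is_json_serialisable(self, rng):
        import json

        agent = DynamicStateAgent(AgentConfig(), rng)
        env = TwoTargetEnv(rng)
        for _ in range(200):
            a, _ = agent.act()
            out, _ = env.step(a)
            agent.observe(a, out)
        payload = json.dumps(agent.snapshot())
        assert '"q_values"' in payload
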