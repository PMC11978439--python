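"""The weekly update step: flows, growth, abandonment, budding, trails."""

from dataclasses import replace

import numpy as np
import pytest

from antnets import ColonyNetwork, ModelParams
from antnets.dynamics import (abandon_nests, abandon_trails, bud_nests,
                              compute_flows, food_income, form_trails,
                              grow_nests, step, update_strengths)


def two_nest_net(size_a=100.0, size_b=100.0, inflow_a=2.0):
    """Nest A with a foraging trail of strength ``inflow_a``, linked to
    nest B (no foraging) by an internest trail of strength 0.5."""
    net = ColonyNetwork(60.0)
    a = net.add_nest(10, 10, size_a)
    b = net.add_nest(20, 10, size_b)
    t = net.add_tree(10, 20)
    net.add_trail(a, b, strength=0.5)
    net.add_trail(a, t, strength=inflow_a)
    return net, a, b


class TestFlows:
    def test_flow_from_forager_to_dependent(self, params):
        net, a, b = two_nest_net()
        flows = compute_flows(net, params)
        assert flows.foraging_inflow == {a: 2.0, b: 0.0}
        ((src, dst, mag),) = flows.internest_flows.values()
        assert (src, dst, mag) == (a, b, 0.5)

    def test_symmetric_nests_no_net_flow(self, params):
        net = ColonyNetwork(60.0)
        a = net.add_nest(10, 10, 100)
        b = net.add_nest(20, 10, 100)
        net.add_trail(a, b, strength=0.7)
        flows = compute_flows(net, params)
        assert flows.internest_flows == {}

    def test_isolated_nest(self, params):
        net = ColonyNetwork(60.0)
        a = net.add_nest(10, 10, 100)
        flows = compute_flows(net, params)
        assert flows.foraging_inflow == {a: 0.0}
        assert flows.internest_flows == {}

    def test_income_from_flows(self, params):
        net, a, b = two_nest_net()
        income = food_income(net, compute_flows(net, params))
        assert income[a] == pytest.approx(1.5)
        assert income[b] == pytest.approx(0.5)

    def test_internest_terms_conserve(self, params):
        """Summed income minus summed foraging inflow is zero: internest
        flows only redistribute."""
        rng = np.random.default_rng(3)
        for seed in range(20):
            from antnets import generate_network

            net = generate_network(params, seed)
            flows = compute_flows(net, params)
            income = food_income(net, flows)
            assert sum(income.values()) == pytest.approx(
                sum(flows.foraging_inflow.values()), abs=1e-9)


class TestGrowth:
    def test_zero_income_unchanged(self, params):
        net = ColonyNetwork(60.0)
        a = net.add_nest(10, 10, 500.0)
        grow_nests(net, params, compute_flows(net, params))
        assert net.nests[a].size == 500.0

    def test_at_capacity_no_growth(self):
        p = replace(ModelParams(), carrying_capacity=1000.0)
        net, a, b = two_nest_net(size_a=1000.0)
        grow_nests(net, p, compute_flows(net, p))
        assert net.nests[a].size == pytest.approx(1000.0)

    def test_logistic_arithmetic(self):
        p = replace(ModelParams(), growth_rate_scale=0.01,
                    carrying_capacity=1000.0)
        net = ColonyNetwork(60.0)
        a = net.add_nest(10, 10, 100.0)
        t = net.add_tree(10, 20)
        net.add_trail(a, t, strength=1.5)
        grow_nests(net, p, compute_flows(net, p))
        # 100 + 0.01 * 1.5 * 100 * (1 - 100/1000)
        assert net.nests[a].size == pytest.approx(101.35)

    def test_shrinkage_not_capacity_limited(self):
        p = replace(ModelParams(), growth_rate_scale=0.1,
                    carrying_capacity=50.0)  # both nests far above K
        net = ColonyNetwork(60.0)
        a = net.add_nest(10, 10, 100.0)
        b = net.add_nest(20, 10, 100.0)
        t = net.add_tree(10, 20)
        net.add_trail(a, t, strength=1.0)
        net.add_trail(a, b, strength=2.0)
        grow_nests(net, p, compute_flows(net, p))
        # f_a = 1 - 2 = -1 -> shrink by kappa*|f|*s regardless of K
        assert net.nests[a].size == pytest.approx(100.0 - 0.1 * 1 * 100.0)


class TestAbandonment:
    def test_all_above_threshold_no_change(self, params, small_net):
        assert abandon_nests(small_net, replace(params,
                                                nest_abandon_threshold=1.0)) \
            == []

    def test_below_threshold_removed_with_trails(self, params, small_net):
        a, b, t = small_net._ids
        p = replace(params, nest_abandon_threshold=60.0)  # b has size 50
        doomed = abandon_nests(small_net, p)
        assert doomed == [b]
        assert all(b not in (tr.a, tr.b) for tr in small_net.trails.values())
        assert small_net.nests[a].status == "active"

    def test_abandonment_single_pass_no_cascade(self, params):
        """Removing a starving nest does not, within the same step,
        re-evaluate nests that only lose support through that removal."""
        net, a, b = two_nest_net(size_a=100.0, size_b=100.0)
        p = replace(params, nest_abandon_threshold=150.0,
                    growth_rate_scale=0.0, budding_coefficient=0.0,
                    new_trail_prob=0.0, trail_abandon_threshold=0.0)
        net.nests[a].size = 200.0  # survives this pass
        doomed = abandon_nests(net, p)
        assert doomed == [b]
        assert net.nests[a].status == "active"

    def test_trail_threshold(self, params, small_net):
        p = replace(params, trail_abandon_threshold=1.5)
        removed = abandon_trails(small_net, p)  # internest str 1.0 dies
        assert removed == 1
        assert all(tr.strength >= 1.5 for tr in small_net.trails.values())
        assert len(small_net.nests) == 2  # node set untouched

    def test_zero_threshold_no_removals(self, params, small_net):
        assert abandon_trails(
            small_net, replace(params, trail_abandon_threshold=0.0)) == 0


class TestBudding:
    def test_zero_coefficient_never_buds(self, params, small_net, rng):
        p = replace(params, budding_coefficient=0.0)
        assert bud_nests(small_net, p, rng) == []

    def test_certain_budding(self, params, rng):
        net = ColonyNetwork(60.0)
        net.add_nest(30, 30, 100.0)
        p = replace(params, budding_coefficient=1.0)  # p = min(1, 100)
        new = bud_nests(net, p, rng)
        assert len(new) == 1
        (nid,) = new
        assert net.trails_of(nid)[0].kind == "internest"

    def test_bud_rate_matches_probability(self, params):
        """Empirical budding rate within 3 SE of c_bud * size = 0.3."""
        p = replace(params, budding_coefficient=0.003)
        rng = np.random.default_rng(99)
        n, hits = 10_000, 0
        for _ in range(n):
            net = ColonyNetwork(60.0)
            net.add_nest(30, 30, 100.0)
            hits += len(bud_nests(net, p, rng))
        se = np.sqrt(0.3 * 0.7 / n)
        assert abs(hits / n - 0.3) < 3 * se

    def test_bud_takes_fraction_of_parent(self, params, rng):
        net = ColonyNetwork(60.0)
        a = net.add_nest(30, 30, 1000.0)
        p = replace(params, budding_coefficient=1.0, bud_size_fraction=0.25)
        (nid,) = bud_nests(net, p, rng)
        assert net.nests[nid].size == pytest.approx(250.0)
        assert net.nests[a].size == pytest.approx(750.0)


class TestFormTrails:
    def test_zero_probability_no_trails(self, params, small_net, rng):
        before = len(small_net.trails)
        form_trails(small_net, replace(params, new_trail_prob=0.0), rng)
        assert len(small_net.trails) == before

    def test_single_candidate_certain_formation(self, params, rng):
        net = ColonyNetwork(60.0)
        a = net.add_nest(10, 10, 100)
        net.add_tree(10, 20)
        form_trails(net, replace(params, new_trail_prob=1.0), rng)
        kinds = [tr.kind for tr in net.trails_of(a)]
        assert kinds == ["foraging"]

    def test_excluded_tree_never_chosen(self, params):
        net = ColonyNetwork(60.0)
        a = net.add_nest(10, 10, 100)
        t1 = net.add_tree(10, 20)
        net.abandon_tree(t1)
        rng = np.random.default_rng(0)
        for _ in range(50):
            form_trails(net, replace(params, new_trail_prob=1.0), rng)
        assert net.degree(t1) == 0


class TestStrengthUpdate:
    def test_internest_gravity_arithmetic(self, params):
        p = replace(params, gravity_internest=(1.0, 0.5, 1.0))
        net = ColonyNetwork(60.0)
        a = net.add_nest(10, 10, 100.0)
        b = net.add_nest(20, 10, 100.0)
        tr = net.add_trail(a, b)
        update_strengths(net, p)
        assert tr.strength == pytest.approx(1.0 * 100.0 / 10.0)  # 10

    def test_beta_power_law_in_length(self, params):
        theta, alpha, beta = params.gravity_foraging
        net = ColonyNetwork(60.0)
        a = net.add_nest(10, 10, 100.0)
        t1 = net.add_tree(10, 15)   # 5 m away
        t2 = net.add_tree(16, 18)   # 10 m away, off the first trail's line
        tr1 = net.add_trail(a, t1)
        tr2 = net.add_trail(a, t2)
        update_strengths(net, params)
        assert beta == 1.0
        assert tr2.strength == pytest.approx(tr1.strength / 2)

    def test_zero_size_nest_zero_strength(self, params):
        net = ColonyNetwork(60.0)
        a = net.add_nest(10, 10, 0.0)
        t = net.add_tree(10, 20)
        tr = net.add_trail(a, t, strength=5.0)
        update_strengths(net, params)
        assert tr.strength == 0.0


class TestStep:
    def test_empty_network_only_clock_advances(self, params, rng):
        net = ColonyNetwork(60.0)
        net.t = 3
        step(net, params, rng)
        assert net.t == 4 and not net.nests and not net.trails

    def test_frozen_dynamics_leave_network_unchanged(self, rng):
        """With all stochastic rates zero, zero thresholds and balanced
        flows, a step only advances the clock and re-derives strengths."""
        p = replace(ModelParams(), budding_coefficient=0.0,
                    new_trail_prob=0.0, trail_abandon_threshold=0.0,
                    nest_abandon_threshold=0.0)
        net = ColonyNetwork(60.0)
        a = net.add_nest(10, 10, 100.0)
        b = net.add_nest(20, 10, 100.0)
        net.add_trail(a, b)
        update_strengths(net, p)
        before = net.state_dict()
        step(net, p, rng)
        after = net.state_dict()
        assert after["t"] == before["t"] + 1
        before["t"] = after["t"]
        assert after == before

    def test_fixed_seed_reproducible(self, params):
        from antnets import generate_network

        nets = []
        for _ in range(2):
            net = generate_network(params, 11)
            rng = np.random.default_rng(5)
            for _ in range(10):
                step(net, params, rng)
            nets.append(net.state_dict())
        assert nets[0] == nets[1]

    def test_planarity_and_uniqueness_preserved(self, params):
        """Structural invariants hold across many random steps."""
        from antnets import generate_network

        total_steps = 0
        for seed in range(10):
            net = generate_network(params, seed)
            rng = np.random.default_rng(seed)
            for _ in range(20):
                step(net, params, rng)
                total_steps += 1
            net.check_planarity()
            keys = [tr.key for tr in net.trails.values()]
            assert len(keys) == len(set(keys))
            for tr in net.trails.values():
                assert net.node(tr.a).status == "active"
                assert net.node(tr.b).status == "active"
        assert total_steps == 200

    def test_raising_trail_threshold_monotone(self, params):
        """A higher abandonment threshold never leaves more trails after
        an identically seeded step on the same state."""
        from antnets import generate_network

        base = generate_network(params, 21)
        counts = []
        for thr in (0.0, 0.25, 0.6, 1.2):
            net = base.copy()
            step(net, replace(params, trail_abandon_threshold=thr),
                 np.random.default_rng(7))
            counts.append(len(net.trails))
        assert counts == sorted(counts, reverse=True)
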