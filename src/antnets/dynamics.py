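"""The weekly update step.

Each timestep (one week of the active season) applies, in order:

1. logistic nest growth driven by net food income,
2. abandonment of nests below the size threshold,
3. probabilistic nest budding (new nest tied to its parent),
4. stochastic formation of new foraging and internest trails,
5. gravity-formula update of all trail strengths,
6. abandonment of trails below the strength threshold.

Food moves from trees into nests along foraging trails and is redistributed
between nests along internest trails; an internest trail carries its full
strength from the endpoint with the higher per-capita foraging inflow toward
the poorer endpoint, so well-supplied nests subsidise dependent ones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .colony_graph import (FORAGING, INTERNEST, ColonyNetwork, ModelParams)
from .morphogenesis import place_offset_from

logger = logging.getLogger(__name__)


@dataclass
class FlowAssignment:
    """Directed food flows for one timestep.

    ``foraging_inflow`` maps nest id -> summed strength of its foraging
    trails.  ``internest_flows`` maps a trail key -> (source, sink,
    magnitude); magnitude equals the trail strength, and ties in per-capita
    inflow yield no entry (zero net flow).
    """

    foraging_inflow: dict[int, float] = field(default_factory=dict)
    internest_flows: dict[tuple[int, int], tuple[int, int, float]] = \
        field(default_factory=dict)


def compute_flows(net: ColonyNetwork, params: ModelParams) -> FlowAssignment:
    flows = FlowAssignment()
    inflow = {n.id: 0.0 for n in net.active_nests()}
    for tr in net.trails.values():
        if tr.kind == FORAGING:
            nest_id = tr.a if net.is_nest(tr.a) else tr.b
            inflow[nest_id] += tr.strength
    flows.foraging_inflow = inflow

    for tr in net.trails.values():
        if tr.kind != INTERNEST:
            continue
        sa = net.nests[tr.a].size
        sb = net.nests[tr.b].size
        pa = inflow[tr.a] / sa if sa > 0 else 0.0
        pb = inflow[tr.b] / sb if sb > 0 else 0.0
        if pa > pb:
            flows.internest_flows[tr.key] = (tr.a, tr.b, tr.strength)
        elif pb > pa:
            flows.internest_flows[tr.key] = (tr.b, tr.a, tr.strength)
        # exact tie: no net flow
    return flows


def food_income(net: ColonyNetwork, flows: FlowAssignment) -> dict[int, float]:
    """Net income per nest: foraging inflow plus incoming minus outgoing
    internest flows.  Internest terms cancel over the colony."""
    income = dict(flows.foraging_inflow)
    for src, dst, mag in flows.internest_flows.values():
        income[src] -= mag
        income[dst] += mag
    return income


def grow_nests(net: ColonyNetwork, params: ModelParams,
               flows: FlowAssignment) -> None:
    """Discrete logistic growth with income-scaled realized rate.

    s <- s + kappa * f * s * (1 - s/K) for non-negative income; shrinkage
    (negative income) is not capacity-limited: s <- s + kappa * f * s.
    Sizes are floored at zero.
    """
    income = food_income(net, flows)
    k = params.growth_rate_scale
    K = params.carrying_capacity
    for nest in net.active_nests():
        f = income.get(nest.id, 0.0)
        if f >= 0:
            s = nest.size + k * f * nest.size * (1.0 - nest.size / K)
        else:
            s = nest.size + k * f * nest.size
        if not np.isfinite(s):
            raise ValueError(f"non-finite size for nest {nest.id}")
        nest.size = max(0.0, s)


def abandon_nests(net: ColonyNetwork, params: ModelParams) -> list[int]:
    """Single-pass abandonment of nests below the size threshold (the 5th
    percentile of the nest-size distribution), with their trails."""
    doomed = [n.id for n in net.active_nests()
              if n.size < params.nest_abandon_threshold]
    for nid in doomed:
        net.abandon_nest(nid)
    return doomed


def bud_nests(net: ColonyNetwork, params: ModelParams,
              rng: np.random.Generator) -> list[int]:
    """Each active nest buds with probability min(1, c_bud * size).

    The daughter nest takes ``bud_size_fraction`` of the parent's workers
    (deducted from the parent), is placed by the initialization offset rule
    relative to its parent, and is connected to it by an internest trail;
    if that trail would cross an existing one, the placement is redrawn
    (bounded retries, then the bud is skipped with a warning).
    """
    new_ids = []
    for nest in list(net.active_nests()):
        p = min(1.0, params.budding_coefficient * nest.size)
        if rng.random() >= p:
            continue
        size = params.bud_size_fraction * nest.size
        for _ in range(100):
            x, y = place_offset_from(net, (nest.x, nest.y), params, rng)
            if not net.segment_feasible((nest.x, nest.y), (x, y)):
                continue
            nid = net.add_nest(x, y, size)
            nest.size -= size
            net.add_trail(nest.id, nid)
            new_ids.append(nid)
            break
        else:
            logger.debug("nest %d: bud placement failed, skipped", nest.id)
    return new_ids


def form_trails(net: ColonyNetwork, params: ModelParams,
                rng: np.random.Generator) -> None:
    """Stochastic new-trail formation.

    Each active nest, independently for the internest and foraging kinds,
    adds one trail with probability ``new_trail_prob`` to a target chosen
    uniformly among feasible candidates (active, not yet connected to the
    nest, reachable without crossing; excluded trees are never candidates).
    """
    p = params.new_trail_prob
    nest_ids = [n.id for n in net.active_nests()]
    tree_ids = [t.id for t in net.active_trees()]
    for nid in nest_ids:
        for pool in (nest_ids, tree_ids):
            if rng.random() >= p:
                continue
            cands = [c for c in pool
                     if c != nid and net.feasible_trail(nid, c)]
            if not cands:
                continue
            target = cands[rng.integers(len(cands))]
            net.add_trail(nid, target)


def update_strengths(net: ColonyNetwork, params: ModelParams) -> None:
    """Gravity strength update.

    Internest trail (a, b): theta_i * (s_a * s_b)^alpha_i / length^beta_i.
    Foraging trail (nest n, tree): theta_f * s_n^alpha_f / length^beta_f —
    trees carry no mass term (all trees are assumed equal quality).
    """
    ti, ai, bi = params.gravity_internest
    tf, af, bf = params.gravity_foraging
    for tr in net.trails.values():
        if tr.kind == INTERNEST:
            mass = net.nests[tr.a].size * net.nests[tr.b].size
            tr.strength = ti * mass ** ai / tr.length ** bi
        else:
            nest_id = tr.a if net.is_nest(tr.a) else tr.b
            tr.strength = tf * net.nests[nest_id].size ** af \
                / tr.length ** bf


def abandon_trails(net: ColonyNetwork, params: ModelParams) -> int:
    weak = [tr.key for tr in net.trails.values()
            if tr.strength < params.trail_abandon_threshold]
    for key in weak:
        del net.trails[key]
    return len(weak)


def step(net: ColonyNetwork, params: ModelParams,
         rng: np.random.Generator) -> ColonyNetwork:
    """Advance the network by one week, applying the six processes in
    their fixed order, then increment the clock."""
    flows = compute_flows(net, params)
    grow_nests(net, params, flows)
    abandon_nests(net, params)
    bud_nests(net, params, rng)
    form_trails(net, params, rng)
    update_strengths(net, params)
    abandon_trails(net, params)
    net.t += 1
    return net
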