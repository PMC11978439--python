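"""Initial network generation: tree field, nest layout, first trails.

The sequence mirrors how a polydomous wood-ant colony map is laid down:
trees scattered with a short-range inhibition, a truncated negative-binomial
number of nests placed sequentially by gamma-distributed offsets from
already-placed nests, one internest trail per nest, then Poisson-distributed
foraging trails assigned nest by nest in ascending size order, each to the
closest tree reachable without crossing an existing trail.
"""

from __future__ import annotations

import logging
import math

import numpy as np

from .colony_graph import ColonyNetwork, ModelParams, Tree

logger = logging.getLogger(__name__)


def place_trees(params: ModelParams, rng: np.random.Generator) -> list[Tree]:
    """Scatter ``round(density * area)`` trees by inhibition (rejection)
    sampling: uniform proposals, rejected within ``tree_inhibition`` metres
    of an accepted tree."""
    area = params.arena_size ** 2
    n = int(round(params.tree_density * area))
    placed: list[tuple[float, float]] = []
    proposals = 0
    min_d2 = params.tree_inhibition ** 2
    while len(placed) < n:
        if proposals >= params.max_place_retries:
            raise RuntimeError(
                f"could not place {n} trees with inhibition "
                f"{params.tree_inhibition} m in a {params.arena_size} m arena")
        x, y = rng.uniform(0.0, params.arena_size, size=2)
        proposals += 1
        if all((x - px) ** 2 + (y - py) ** 2 >= min_d2 for px, py in placed):
            placed.append((x, y))
    return [Tree(-1, x, y) for x, y in placed]


def draw_nest_count(params: ModelParams, rng: np.random.Generator) -> int:
    """Negative-binomial draw, redrawn until inside the observed range."""
    lo, hi = params.nest_count_range
    for _ in range(params.max_place_retries):
        k = rng.negative_binomial(params.nest_count_n, params.nest_count_p)
        if lo <= k <= hi:
            return int(k)
    raise RuntimeError("nest-count truncation range unreachable")


def draw_offset(params: ModelParams, rng: np.random.Generator
                ) -> tuple[float, float]:
    """One placement offset: gamma distance (short draws replaced by a
    uniform draw just above the minimum spacing) at a uniform angle."""
    d = rng.gamma(params.nest_distance_shape, params.nest_distance_scale)
    if d < params.nest_min_spacing:
        d = rng.uniform(*params.nest_spacing_redraw)
    ang = rng.uniform(0.0, 2.0 * math.pi)
    return d * math.cos(ang), d * math.sin(ang)


def draw_nest_size(params: ModelParams, rng: np.random.Generator) -> float:
    s = rng.gamma(params.nest_size_shape, params.nest_size_scale)
    return min(s, params.nest_size_cap)


def place_offset_from(net: ColonyNetwork, anchor: tuple[float, float],
                      params: ModelParams, rng: np.random.Generator
                      ) -> tuple[float, float]:
    """Draw offsets from ``anchor`` until the point lands inside the arena."""
    ax, ay = anchor
    for _ in range(params.max_place_retries):
        dx, dy = draw_offset(params, rng)
        x, y = ax + dx, ay + dy
        if 0.0 <= x <= net.arena and 0.0 <= y <= net.arena:
            return x, y
    raise RuntimeError("could not place nest inside arena")


def init_nests(net: ColonyNetwork, params: ModelParams,
               rng: np.random.Generator) -> list[int]:
    """Place the initial nests sequentially.

    The first nest lands uniformly in the arena; each later nest is offset
    from a uniformly chosen already-placed nest.  Sizes are gamma draws
    capped at the configured 95th percentile.
    """
    count = draw_nest_count(params, rng)
    ids: list[int] = []
    x0, y0 = rng.uniform(0.0, net.arena, size=2)
    ids.append(net.add_nest(x0, y0, draw_nest_size(params, rng)))
    for _ in range(count - 1):
        anchor_id = ids[rng.integers(len(ids))]
        x, y = place_offset_from(net, net.position(anchor_id), params, rng)
        ids.append(net.add_nest(x, y, draw_nest_size(params, rng)))
    return ids


def _nearest_feasible(net: ColonyNetwork, nid: int,
                      candidates: list[int]) -> int | None:
    """Closest candidate reachable from ``nid``; ties to the lowest id."""
    px, py = net.position(nid)

    def d2(cid):
        cx, cy = net.position(cid)
        return (cx - px) ** 2 + (cy - py) ** 2

    for cid in sorted(candidates, key=lambda c: (d2(c), c)):
        if net.feasible_trail(nid, cid):
            return cid
    return None


def init_trails(net: ColonyNetwork, params: ModelParams,
                rng: np.random.Generator) -> ColonyNetwork:
    """Lay the first trails.

    Every nest first attempts one internest trail to its nearest feasible
    nest (skipped with a warning when boxed in).  Foraging-trail counts are
    then drawn per nest from a Poisson distribution and assigned in reverse
    order of size — smallest nest first — each trail to the closest tree
    still reachable without crossing existing trails; a nest wanting more
    trails than it can feasibly reach simply gets fewer.
    """
    nests = net.active_nests()
    nest_ids = [n.id for n in nests]
    for nid in nest_ids:
        already = {tr.a if tr.b == nid else tr.b for tr in net.trails_of(nid)}
        partners = [m for m in nest_ids if m != nid and m not in already]
        target = _nearest_feasible(net, nid, partners)
        if target is None:
            logger.warning("nest %d: no feasible internest partner", nid)
        else:
            net.add_trail(nid, target)

    counts = {n.id: int(rng.poisson(params.foraging_count_mean))
              for n in nests}
    tree_ids = [t.id for t in net.active_trees()]
    for nest in sorted(nests, key=lambda n: (n.size, n.id)):
        for _ in range(counts[nest.id]):
            used = {tr.a if tr.b == nest.id else tr.b
                    for tr in net.trails_of(nest.id)}
            target = _nearest_feasible(
                net, nest.id, [t for t in tree_ids if t not in used])
            if target is None:
                logger.warning("nest %d: no feasible foraging tree", nest.id)
                break
            net.add_trail(nest.id, target)
    return net


def generate_network(params: ModelParams, seed) -> ColonyNetwork:
    """Generate one initial colony network; a pure function of (params, seed).

    ``seed`` may be an int or a ``numpy.random.SeedSequence``.  The clock is
    set to ``-burn_in`` and an initial gravity strength update is applied so
    the network starts with consistent trail strengths.
    """
    from .dynamics import update_strengths  # cycle: dynamics needs the net

    params.validate()
    rng = np.random.default_rng(seed)
    net = ColonyNetwork(params.arena_size)
    for tree in place_trees(params, rng):
        net.add_tree(tree.x, tree.y)
    init_nests(net, params, rng)
    init_trails(net, params, rng)
    update_strengths(net, params)
    net.t = -params.burn_in
    return net
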