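"""Network measures: efficiency, robustness, cost and colony statistics.

Global efficiency is the mean of inverse shortest-path distances (trail
metres) over all unordered node pairs, with disconnected pairs contributing
zero — it is *not* normalized by an ideal complete graph, so its unit is
1/m (about 0.1 for colonies with ~10 m spacing).  Robustness is the mean,
over single-trail deletions, of the efficiency remaining relative to the
intact network; a complementary "loss" convention is available via
``ModelParams.robustness_as_loss``.

The measured node set is the active nests plus the *used* trees (trees with
at least one foraging trail): an available but unvisited tree is part of the
environment, not of the transportation network.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields as dc_fields

import numpy as np

from .colony_graph import FORAGING, INTERNEST, ColonyNetwork, ModelParams


def _apsp(w: np.ndarray) -> np.ndarray:
    """All-pairs shortest paths by vectorised Floyd-Warshall.

    The measured graphs have a few dozen nodes at most, where this beats
    sparse-solver overhead by a wide margin."""
    d = w.copy()
    n = d.shape[0]
    for k in range(n):
        np.minimum(d, d[:, k:k + 1] + d[k:k + 1, :], out=d)
    return d


@dataclass
class SpatialGraph:
    """A minimal weighted graph: node ids and edges with lengths."""

    nodes: list[int]
    edges: list[tuple[int, int, float]]  # (a, b, length)


def n_components(graph: SpatialGraph) -> int:
    """Connected, disjunct subgraphs of the measured node set."""
    parent = {n: n for n in graph.nodes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b, _ in graph.edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    return len({find(n) for n in graph.nodes})


def _distance_matrix(graph: SpatialGraph) -> np.ndarray:
    n = len(graph.nodes)
    idx = {nid: i for i, nid in enumerate(graph.nodes)}
    w = np.full((n, n), np.inf)
    np.fill_diagonal(w, 0.0)
    for a, b, length in graph.edges:
        i, j = idx[a], idx[b]
        if length < w[i, j]:
            w[i, j] = w[j, i] = length
    return _apsp(w)


def global_efficiency(graph: SpatialGraph) -> float:
    """Mean inverse shortest-path distance over unordered node pairs."""
    n = len(graph.nodes)
    if n < 2:
        return 0.0
    d = _distance_matrix(graph)
    iu = np.triu_indices(n, k=1)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d[iu]
    inv[~np.isfinite(inv)] = 0.0
    return float(inv.mean())


def _matrix_efficiency(w: np.ndarray) -> float:
    n = w.shape[0]
    if n < 2:
        return 0.0
    d = _apsp(w)
    iu = np.triu_indices(n, k=1)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d[iu]
    inv[~np.isfinite(inv)] = 0.0
    return float(inv.mean())


def robustness(graph: SpatialGraph, as_loss: bool = False) -> float:
    """Average single-edge-removal response of global efficiency.

    For each edge e the ratio E(G - e) / E(G) is computed; the default
    convention reports the mean remaining fraction (high = robust), the
    ``as_loss`` convention its complement.  Graphs with no edges or zero
    efficiency score 0.
    """
    if not graph.edges:
        return 0.0
    n = len(graph.nodes)
    idx = {nid: i for i, nid in enumerate(graph.nodes)}
    w = np.full((n, n), np.inf)
    np.fill_diagonal(w, 0.0)
    parallel = False
    for a, b, length in graph.edges:
        i, j = idx[a], idx[b]
        if np.isfinite(w[i, j]):
            parallel = True
        w[i, j] = w[j, i] = min(w[i, j], length)
    e0 = _matrix_efficiency(w)
    if e0 <= 0.0:
        return 0.0
    ratios = []
    if parallel:
        # duplicate node pairs: the matrix shortcut is invalid, remove
        # edges one at a time from the edge list instead
        for i in range(len(graph.edges)):
            sub = SpatialGraph(graph.nodes,
                               graph.edges[:i] + graph.edges[i + 1:])
            ratios.append(global_efficiency(sub) / e0)
    else:
        for a, b, length in graph.edges:
            i, j = idx[a], idx[b]
            w[i, j] = w[j, i] = np.inf
            ratios.append(_matrix_efficiency(w) / e0)
            w[i, j] = w[j, i] = length
    r = float(np.mean(ratios))
    return 1.0 - r if as_loss else r


def cost(graph: SpatialGraph) -> float:
    """Total physical trail length (metres)."""
    return float(sum(length for _, _, length in graph.edges))


# ---------------------------------------------------------------------------


@dataclass
class MeasureRecord:
    """All measures for one (network, arm, timestep)."""

    network: int = 0
    arm: str = ""
    t: int = 0
    efficiency: float = 0.0
    robustness: float = 0.0
    cost: float = 0.0
    normalized_cost: float = math.nan
    n_nests: int = 0
    n_trees: int = 0
    n_internest: int = 0
    n_foraging: int = 0
    trees_per_nest: float = 0.0
    internest_per_nest: float = 0.0
    foraging_per_nest: float = 0.0
    n_components: int = 0
    colony_population: float = 0.0
    internest_efficiency: float = 0.0
    internest_robustness: float = 0.0
    internest_cost: float = 0.0
    internest_normalized_cost: float = math.nan

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in dc_fields(self)}


MEASURE_COLUMNS = [f.name for f in dc_fields(MeasureRecord)]


def whole_graph(net: ColonyNetwork) -> SpatialGraph:
    """Active nests + used trees, with all trails."""
    used_trees = {tr.a if tr.a in net.trees else tr.b
                  for tr in net.trails.values() if tr.kind == FORAGING}
    nodes = sorted([n.id for n in net.active_nests()] + sorted(used_trees))
    edges = [(tr.a, tr.b, tr.length) for tr in net.trails.values()]
    return SpatialGraph(nodes, edges)


def internest_graph(net: ColonyNetwork) -> SpatialGraph:
    """The nest subnetwork: trees and foraging trails excluded."""
    nodes = sorted(n.id for n in net.active_nests())
    edges = [(tr.a, tr.b, tr.length) for tr in net.trails.values()
             if tr.kind == INTERNEST]
    return SpatialGraph(nodes, edges)


def measure_all(net: ColonyNetwork, params: ModelParams | None = None,
                network: int = 0, arm: str = "", fast: bool = False
                ) -> MeasureRecord:
    """Compute the full measure record for one network state.

    ``fast`` skips the efficiency/robustness family (used for long sweeps
    where only counts are needed).  ``normalized_cost`` is missing (NaN)
    when the colony population is zero.
    """
    as_loss = bool(params and params.robustness_as_loss)
    nests = net.active_nests()
    n_internest = sum(1 for tr in net.trails.values()
                      if tr.kind == INTERNEST)
    n_foraging = len(net.trails) - n_internest
    used_trees = {tr.a if tr.a in net.trees else tr.b
                  for tr in net.trails.values() if tr.kind == FORAGING}
    pop = float(sum(n.size for n in nests))
    n_nests = len(nests)

    rec = MeasureRecord(network=network, arm=arm, t=net.t)
    rec.n_nests = n_nests
    rec.n_trees = len(used_trees)
    rec.n_internest = n_internest
    rec.n_foraging = n_foraging
    rec.trees_per_nest = rec.n_trees / n_nests if n_nests else 0.0
    rec.internest_per_nest = n_internest / n_nests if n_nests else 0.0
    rec.foraging_per_nest = n_foraging / n_nests if n_nests else 0.0
    rec.colony_population = pop

    g = whole_graph(net)
    rec.n_components = n_components(g)
    gi = internest_graph(net)
    rec.cost = cost(g)
    rec.internest_cost = cost(gi)
    rec.normalized_cost = rec.cost / pop if pop > 0 else math.nan
    rec.internest_normalized_cost = \
        rec.internest_cost / pop if pop > 0 else math.nan
    if not fast:
        rec.efficiency = global_efficiency(g)
        rec.robustness = robustness(g, as_loss=as_loss)
        rec.internest_efficiency = global_efficiency(gi)
        rec.internest_robustness = robustness(gi, as_loss=as_loss)
    return rec
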