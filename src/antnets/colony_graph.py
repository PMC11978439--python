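"""Core domain types and geometric primitives for wood-ant colony networks.

A colony network is a spatial graph: nests and trees are point nodes in a
square arena (metres, origin at the lower-left corner), trails are straight
edges carrying a strength (density of ants, ants/mm).  Trails never cross,
matching field observations of wood-ant trail systems; the planarity test
lives here because every other module relies on it.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, fields

import numpy as np

ACTIVE = "active"
ABANDONED = "abandoned"

INTERNEST = "internest"
FORAGING = "foraging"


@dataclass
class Nest:
    """An ant nest: a point with a population size (number of ants)."""

    id: int
    x: float
    y: float
    size: float
    status: str = ACTIVE


@dataclass
class Tree:
    """A foraging tree (aphid-hosting food source). Excluded trees are
    flagged ``abandoned`` and may later be reintroduced."""

    id: int
    x: float
    y: float
    status: str = ACTIVE


@dataclass
class Trail:
    """A straight trail between two nodes.

    ``kind`` is ``internest`` (nest-nest) or ``foraging`` (nest-tree);
    ``length`` is the Euclidean endpoint distance in metres, cached at
    creation; ``strength`` is ants per mm.
    """

    a: int
    b: int
    kind: str
    length: float
    strength: float = 0.0

    @property
    def key(self) -> tuple[int, int]:
        return (self.a, self.b) if self.a < self.b else (self.b, self.a)


# ---------------------------------------------------------------------------
# Segment geometry


def _orient(ax, ay, bx, by, cx, cy):
    """Signed area of the triangle a-b-c (positive = counter-clockwise)."""
    return (bx - ax) * (cy - ay) - (by - ay) * (cx - ax)


def segments_cross(p1, p2, q1, q2) -> bool:
    """True iff segments p1-p2 and q1-q2 properly cross or overlap collinearly.

    Trails that merely touch at a point are legal: sharing an endpoint, or an
    endpoint of one segment lying on the other, is *not* a crossing.  Two
    collinear segments overlapping in more than a point *is* a crossing (this
    forbids stacked trails).  Zero-length segments are rejected.
    """
    p1x, p1y = p1
    p2x, p2y = p2
    q1x, q1y = q1
    q2x, q2y = q2
    if (p1x == p2x and p1y == p2y) or (q1x == q2x and q1y == q2y):
        raise ValueError("degenerate zero-length segment")

    d1 = _orient(q1x, q1y, q2x, q2y, p1x, p1y)
    d2 = _orient(q1x, q1y, q2x, q2y, p2x, p2y)
    d3 = _orient(p1x, p1y, p2x, p2y, q1x, q1y)
    d4 = _orient(p1x, p1y, p2x, p2y, q2x, q2y)

    if d1 == 0.0 and d2 == 0.0 and d3 == 0.0 and d4 == 0.0:
        # collinear: crossing iff the 1-D projections overlap in >1 point
        if abs(p2x - p1x) >= abs(p2y - p1y):
            lo1, hi1 = sorted((p1x, p2x))
            lo2, hi2 = sorted((q1x, q2x))
        else:
            lo1, hi1 = sorted((p1y, p2y))
            lo2, hi2 = sorted((q1y, q2y))
        return min(hi1, hi2) > max(lo1, lo2)

    # proper crossing: strict sign changes on both sides; any touch at a
    # point (shared endpoint, T-junction) leaves a zero product and is legal
    return (d1 * d2 < 0.0) and (d3 * d4 < 0.0)


def segment_crosses_any(p1, p2, segs: np.ndarray) -> bool:
    """Vectorised test of one candidate segment against many.

    ``segs`` is an (n, 4) array of (x1, y1, x2, y2) rows.  Same conventions
    as :func:`segments_cross`.
    """
    if len(segs) == 0:
        return False
    p1x, p1y = p1
    p2x, p2y = p2
    ax, ay, bx, by = segs[:, 0], segs[:, 1], segs[:, 2], segs[:, 3]

    d1 = (bx - ax) * (p1y - ay) - (by - ay) * (p1x - ax)
    d2 = (bx - ax) * (p2y - ay) - (by - ay) * (p2x - ax)
    d3 = (p2x - p1x) * (ay - p1y) - (p2y - p1y) * (ax - p1x)
    d4 = (p2x - p1x) * (by - p1y) - (p2y - p1y) * (bx - p1x)

    proper = (d1 * d2 < 0.0) & (d3 * d4 < 0.0)
    if proper.any():
        return True

    coll = (d1 == 0.0) & (d2 == 0.0) & (d3 == 0.0) & (d4 == 0.0)
    if coll.any():
        for i in np.flatnonzero(coll):
            if segments_cross(p1, p2, (ax[i], ay[i]), (bx[i], by[i])):
                return True
    return False


# ---------------------------------------------------------------------------
# Model parameters


@dataclass
class ModelParams:
    """Every constant of initialization and weekly dynamics.

    Values printed in the source field system: a 60 x 60 m arena, trees at
    0.01 / m^2 with 2 m inhibition, 4-20 nests, 1.5 m minimum placement
    offset with a U(1.5, 2) redraw, 28-week active seasons and an 8-week
    burn-in.  The remaining constants (distribution parameters, gravity
    coefficients, growth and thresholds) are package defaults chosen to
    yield realistic Formica lugubris colonies; see docs/methods.md.
    """

    arena_size: float = 60.0

    # tree field
    tree_density: float = 0.01          # trees per m^2
    tree_inhibition: float = 2.0        # minimum tree-tree distance, m

    # nest count ~ negative binomial truncated to the observed range
    nest_count_n: float = 8.0
    nest_count_p: float = 0.4
    nest_count_range: tuple[int, int] = (4, 20)

    # sequential nest placement offsets ~ gamma, short offsets redrawn
    nest_distance_shape: float = 2.2
    nest_distance_scale: float = 2.7    # m
    nest_min_spacing: float = 1.5       # m
    nest_spacing_redraw: tuple[float, float] = (1.5, 2.0)

    # nest sizes ~ gamma, capped at its 95th percentile; nests below the
    # 5th percentile are abandoned
    nest_size_shape: float = 2.0
    nest_size_scale: float = 5000.0     # ants
    nest_size_cap: float = 23719.0      # 95th pct of the default gamma
    nest_abandon_threshold: float = 1777.0  # 5th pct of the default gamma

    # initial foraging trails per nest ~ Poisson
    foraging_count_mean: float = 1.5

    # weekly dynamics
    growth_rate_scale: float = 0.1      # kappa, per unit net income per week
    carrying_capacity: float = 30000.0  # K, ants
    budding_coefficient: float = 3.0e-7  # P(bud) = min(1, c_bud * size)
    bud_size_fraction: float = 0.1      # share of parent workers in a bud
    new_trail_prob: float = 0.005       # per nest per kind per week
    trail_abandon_threshold: float = 0.25  # ants/mm

    # gravity formulae: strength = theta * mass^alpha / length^beta
    gravity_internest: tuple[float, float, float] = (3.0e-4, 0.5, 1.0)
    gravity_foraging: tuple[float, float, float] = (0.06, 0.5, 1.0)

    # schedule units (weeks)
    season_length: int = 28
    burn_in: int = 8

    # robustness convention: remaining fraction E(G-e)/E(G) by default;
    # True reports the complementary loss 1 - E(G-e)/E(G)
    robustness_as_loss: bool = False

    max_place_retries: int = 100_000

    def validate(self) -> "ModelParams":
        if self.arena_size <= 0:
            raise ValueError("arena_size must be positive")
        if self.tree_density < 0:
            raise ValueError("tree_density must be non-negative")
        if self.tree_inhibition < 0:
            raise ValueError("tree_inhibition must be non-negative")
        if not (0 < self.nest_count_p <= 1) or self.nest_count_n <= 0:
            raise ValueError("invalid negative-binomial parameters")
        lo, hi = self.nest_count_range
        if lo > hi or lo < 1:
            raise ValueError(f"empty nest count range [{lo}, {hi}]")
        if self.nest_distance_shape <= 0 or self.nest_distance_scale <= 0:
            raise ValueError("invalid nest distance gamma parameters")
        rlo, rhi = self.nest_spacing_redraw
        if not (0 < rlo <= rhi):
            raise ValueError("invalid spacing redraw range")
        if self.nest_size_shape <= 0 or self.nest_size_scale <= 0:
            raise ValueError("invalid nest size gamma parameters")
        if self.nest_size_cap <= 0:
            raise ValueError("nest_size_cap must be positive")
        if self.foraging_count_mean < 0:
            raise ValueError("foraging_count_mean must be non-negative")
        if not (0 <= self.new_trail_prob <= 1):
            raise ValueError("new_trail_prob must be a probability")
        if self.budding_coefficient < 0:
            raise ValueError("budding_coefficient must be non-negative")
        if not (0 < self.bud_size_fraction < 1):
            raise ValueError("bud_size_fraction must be in (0, 1)")
        if self.carrying_capacity <= 0:
            raise ValueError("carrying_capacity must be positive")
        if self.trail_abandon_threshold < 0 or self.nest_abandon_threshold < 0:
            raise ValueError("abandonment thresholds must be non-negative")
        for name in ("gravity_internest", "gravity_foraging"):
            theta, _, _ = getattr(self, name)
            if theta < 0:
                raise ValueError(f"{name} theta must be non-negative")
        if self.season_length <= 0 or self.burn_in < 0:
            raise ValueError("invalid schedule lengths")
        return self

    def to_dict(self) -> dict:
        def plain(v):
            if isinstance(v, tuple):
                return [plain(x) for x in v]
            if isinstance(v, np.integer):
                return int(v)
            if isinstance(v, np.floating):
                return float(v)
            return v

        return {f.name: plain(getattr(self, f.name)) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        known = {f.name: f for f in fields(cls)}
        kwargs = {}
        for k, v in d.items():
            if k not in known:
                raise ValueError(f"unknown parameter: {k}")
            if isinstance(v, list):
                v = tuple(v)
            kwargs[k] = v
        return cls(**kwargs).validate()


# ---------------------------------------------------------------------------
# The network


class ColonyNetwork:
    """The single evolving state object: nests, trees, trails and the clock.

    All mutation goes through the add/remove/abandon methods below, which
    maintain the structural invariants (planarity, no duplicate trails,
    endpoint validity).  Node ids are monotone integers shared between nests
    and trees and are never reused.
    """

    def __init__(self, arena_size: float = 60.0):
        self.arena = float(arena_size)
        self.nests: dict[int, Nest] = {}
        self.trees: dict[int, Tree] = {}
        self.trails: dict[tuple[int, int], Trail] = {}
        self.t: int = 0
        self._next_id: int = 0

    # -- node management ----------------------------------------------------

    def _new_id(self) -> int:
        nid = self._next_id
        self._next_id += 1
        return nid

    def add_nest(self, x: float, y: float, size: float) -> int:
        if not (0 <= x <= self.arena and 0 <= y <= self.arena):
            raise ValueError("nest outside arena")
        if size < 0:
            raise ValueError("nest size must be non-negative")
        nid = self._new_id()
        self.nests[nid] = Nest(nid, float(x), float(y), float(size))
        return nid

    def add_tree(self, x: float, y: float) -> int:
        if not (0 <= x <= self.arena and 0 <= y <= self.arena):
            raise ValueError("tree outside arena")
        nid = self._new_id()
        self.trees[nid] = Tree(nid, float(x), float(y))
        return nid

    def node(self, nid: int):
        if nid in self.nests:
            return self.nests[nid]
        if nid in self.trees:
            return self.trees[nid]
        raise KeyError(f"unknown node id {nid}")

    def position(self, nid: int) -> tuple[float, float]:
        n = self.node(nid)
        return (n.x, n.y)

    def is_nest(self, nid: int) -> bool:
        return nid in self.nests

    def active_nests(self) -> list[Nest]:
        return [n for n in self.nests.values() if n.status == ACTIVE]

    def active_trees(self) -> list[Tree]:
        return [t for t in self.trees.values() if t.status == ACTIVE]

    # -- trail management ---------------------------------------------------

    def trail_segments(self) -> np.ndarray:
        """(n_trails, 4) array of trail endpoint coordinates."""
        if not self.trails:
            return np.empty((0, 4))
        rows = []
        for tr in self.trails.values():
            xa, ya = self.position(tr.a)
            xb, yb = self.position(tr.b)
            rows.append((xa, ya, xb, yb))
        return np.asarray(rows)

    def trail_kind(self, a: int, b: int) -> str:
        an, bn = self.is_nest(a), self.is_nest(b)
        if an and bn:
            return INTERNEST
        if an != bn:
            return FORAGING
        raise ValueError("tree-tree trails are not allowed")

    def feasible_trail(self, a: int, b: int) -> bool:
        """Can a straight trail legally join nodes ``a`` and ``b``?

        Requires two distinct active nodes, at least one a nest, no existing
        trail between them, and a connecting segment that crosses no existing
        trail.
        """
        na, nb = self.node(a), self.node(b)
        if a == b:
            return False
        if na.status != ACTIVE or nb.status != ACTIVE:
            return False
        if not (self.is_nest(a) or self.is_nest(b)):
            return False
        key = (a, b) if a < b else (b, a)
        if key in self.trails:
            return False
        pa, pb = (na.x, na.y), (nb.x, nb.y)
        if pa == pb:
            return False
        return self.segment_feasible(pa, pb)

    def segment_feasible(self, pa, pb) -> bool:
        """Would a straight segment pa-pb cross any existing trail?"""
        return not segment_crosses_any(pa, pb, self.trail_segments())

    def add_trail(self, a: int, b: int, strength: float = 0.0,
                  check: bool = True) -> Trail:
        kind = self.trail_kind(a, b)
        if check and not self.feasible_trail(a, b):
            raise ValueError(f"infeasible trail {a}-{b}")
        pa, pb = self.position(a), self.position(b)
        length = math.hypot(pb[0] - pa[0], pb[1] - pa[1])
        if length <= 0:
            raise ValueError("coincident endpoints")
        tr = Trail(a, b, kind, length, float(strength))
        self.trails[tr.key] = tr
        return tr

    def remove_trail(self, a: int, b: int) -> None:
        key = (a, b) if a < b else (b, a)
        del self.trails[key]

    def trails_of(self, nid: int) -> list[Trail]:
        return [tr for tr in self.trails.values() if nid in (tr.a, tr.b)]

    def degree(self, nid: int) -> int:
        return len(self.trails_of(nid))

    def abandon_nest(self, nid: int) -> None:
        """Mark a nest abandoned and drop exactly its incident trails."""
        nest = self.nests[nid]
        nest.status = ABANDONED
        for tr in self.trails_of(nid):
            del self.trails[tr.key]

    def abandon_tree(self, nid: int) -> None:
        tree = self.trees[nid]
        tree.status = ABANDONED
        for tr in self.trails_of(nid):
            del self.trails[tr.key]

    def reactivate_tree(self, nid: int) -> None:
        self.trees[nid].status = ACTIVE

    # -- queries ------------------------------------------------------------

    def connected_components(self) -> list[set[int]]:
        """Partition of active nodes into trail-connected components
        (union-find; isolated active nodes are singleton components)."""
        ids = [n.id for n in self.active_nests()] + \
              [t.id for t in self.active_trees()]
        parent = {i: i for i in ids}

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for tr in self.trails.values():
            ra, rb = find(tr.a), find(tr.b)
            if ra != rb:
                parent[ra] = rb
        comps: dict[int, set[int]] = {}
        for i in ids:
            comps.setdefault(find(i), set()).add(i)
        return list(comps.values())

    def check_planarity(self) -> None:
        """Raise if any two trails cross (exhaustive pairwise test)."""
        trs = list(self.trails.values())
        pos = {nid: self.position(nid)
               for tr in trs for nid in (tr.a, tr.b)}
        for i in range(len(trs)):
            for j in range(i + 1, len(trs)):
                ti, tj = trs[i], trs[j]
                if segments_cross(pos[ti.a], pos[ti.b],
                                  pos[tj.a], pos[tj.b]):
                    raise ValueError(
                        f"trails {ti.key} and {tj.key} cross")

    def copy(self) -> "ColonyNetwork":
        return copy.deepcopy(self)

    def state_dict(self) -> dict:
        """Canonical plain-data snapshot (used for serialization and for
        byte-identity comparisons between experiment arms)."""
        return {
            "arena": self.arena,
            "t": self.t,
            "next_id": self._next_id,
            "nests": [
                {"id": n.id, "x": n.x, "y": n.y, "size": n.size,
                 "status": n.status}
                for n in sorted(self.nests.values(), key=lambda n: n.id)
            ],
            "trees": [
                {"id": t.id, "x": t.x, "y": t.y, "status": t.status}
                for t in sorted(self.trees.values(), key=lambda t: t.id)
            ],
            "trails": [
                {"a": tr.key[0], "b": tr.key[1], "kind": tr.kind,
                 "length": tr.length, "strength": tr.strength}
                for tr in sorted(self.trails.values(), key=lambda tr: tr.key)
            ],
        }

    @classmethod
    def from_state_dict(cls, d: dict, check: bool = True) -> "ColonyNetwork":
        net = cls(d["arena"])
        net.t = int(d["t"])
        for n in d["nests"]:
            net.nests[n["id"]] = Nest(n["id"], n["x"], n["y"], n["size"],
                                      n["status"])
        for t in d["trees"]:
            net.trees[t["id"]] = Tree(t["id"], t["x"], t["y"], t["status"])
        net._next_id = int(d.get(
            "next_id", 1 + max((n["id"] for n in d["nests"] + d["trees"]),
                               default=-1)))
        for tr in d["trails"]:
            for nid in (tr["a"], tr["b"]):
                if net.node(nid).status != ACTIVE:
                    raise ValueError(
                        f"trail {tr['a']}-{tr['b']} touches inactive node")
            trail = net.add_trail(tr["a"], tr["b"], tr["strength"],
                                  check=False)
            if abs(trail.length - tr["length"]) > 1e-6:
                raise ValueError("stored trail length inconsistent "
                                 f"for {tr['a']}-{tr['b']}")
        if check:
            net.check_planarity()
        return net
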