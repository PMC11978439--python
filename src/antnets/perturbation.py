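"""Resource-exclusion experiments.

One experiment takes a single simulated colony through a paired design: the
network is generated, burned in for eight weeks, then copied at t = 0 into
four branches — an unperturbed control and three exclusions targeting the
tree with the strongest cumulative foraging trail strength, a random tree,
and the weakest.  Branches run one active season to t = 28, where each
exclusion branch forks into a *sustained* version (the tree stays excluded;
a press perturbation) and a *reintroduced* version (the tree becomes
available again, though its trails must re-form on their own; a pulse
perturbation).  All seven arms then run to t = 84 with measures recorded at
every timestep.

Because every arm shares the identical t = 0 network and hierarchically
seeded random streams, treatment effects can be evaluated as paired
differences against each network's own control.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .colony_graph import FORAGING, ColonyNetwork, ModelParams
from .dynamics import step
from .measures import MeasureRecord, measure_all
from .morphogenesis import generate_network

logger = logging.getLogger(__name__)

TARGETS = ("control", "weakest", "random", "strongest")
TYPES = ("sustained", "reintroduced")


@dataclass(frozen=True)
class ExperimentArm:
    target: str   # control | weakest | random | strongest
    type: str     # none | sustained | reintroduced

    def __post_init__(self):
        if self.target not in TARGETS:
            raise ValueError(f"unknown target {self.target!r}")
        if (self.type != "none") == (self.target == "control") or \
                (self.target != "control" and self.type not in TYPES):
            raise ValueError(f"invalid arm ({self.target}, {self.type})")

    @property
    def name(self) -> str:
        return self.target if self.target == "control" \
            else f"{self.target}_{self.type}"


ARMS: tuple[ExperimentArm, ...] = (
    ExperimentArm("control", "none"),
    ExperimentArm("weakest", "sustained"),
    ExperimentArm("weakest", "reintroduced"),
    ExperimentArm("random", "sustained"),
    ExperimentArm("random", "reintroduced"),
    ExperimentArm("strongest", "sustained"),
    ExperimentArm("strongest", "reintroduced"),
)


@dataclass
class Schedule:
    """Experiment timeline in weekly timesteps."""

    burn_in_start: int = -8
    exclusion_time: int = 0
    reintroduction_time: int = 28
    end: int = 84

    def __post_init__(self):
        if not (self.burn_in_start < self.exclusion_time
                < self.reintroduction_time < self.end):
            raise ValueError("schedule times must be strictly increasing")

    @classmethod
    def from_params(cls, params: ModelParams) -> "Schedule":
        return cls(burn_in_start=-params.burn_in,
                   exclusion_time=0,
                   reintroduction_time=params.season_length,
                   end=3 * params.season_length)


# ---------------------------------------------------------------------------


def cumulative_foraging_strength(net: ColonyNetwork) -> dict[int, float]:
    """Summed foraging-trail strength per tree, for trees with >= 1 trail."""
    out: dict[int, float] = {}
    for tr in net.trails.values():
        if tr.kind == FORAGING:
            tree_id = tr.a if tr.a in net.trees else tr.b
            out[tree_id] = out.get(tree_id, 0.0) + tr.strength
    return out


def select_focal_tree(net: ColonyNetwork, target: str,
                      rng: np.random.Generator | None = None) -> int:
    """Choose the focal tree for an exclusion target.

    ``strongest``/``weakest`` rank trees by cumulative incident foraging
    strength among trees carrying at least one trail (ties to the lowest
    id); ``random`` draws uniformly over the same used-tree pool, so every
    exclusion arm removes exactly one tree that the colony actually
    forages on.
    """
    strengths = cumulative_foraging_strength(net)
    if target == "random":
        trees = sorted(strengths)
        if not trees:
            raise ValueError("no used tree to exclude")
        if rng is None:
            raise ValueError("random target needs a random stream")
        return trees[rng.integers(len(trees))]
    if not strengths:
        raise ValueError("no tree with a foraging trail")
    sign = 1.0 if target == "strongest" else -1.0
    if target not in ("strongest", "weakest"):
        raise ValueError(f"unknown target {target!r}")
    return min(strengths, key=lambda t: (-sign * strengths[t], t))


def exclude_tree(net: ColonyNetwork, tree_id: int) -> ColonyNetwork:
    """Exclude a tree: abandon it and all of its foraging trails; while
    excluded it can receive no new trails."""
    net.abandon_tree(tree_id)
    return net


def reintroduce_tree(net: ColonyNetwork, tree_id: int) -> ColonyNetwork:
    """Make an excluded tree available again.  No trails are re-formed
    automatically; the colony must rediscover it."""
    if net.trees[tree_id].status == "active":
        logger.warning("tree %d already active; reintroduce is a no-op",
                       tree_id)
        return net
    net.reactivate_tree(tree_id)
    return net


# ---------------------------------------------------------------------------


def _stream(master_seed: int, network: int, *codes: int
            ) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([master_seed, network, *codes]))


@dataclass
class ExperimentResult:
    """Trajectories of one paired experiment."""

    network: int
    seed: int
    focal_trees: dict[str, int]
    records: list[MeasureRecord]
    snapshots: dict[tuple[str, int], dict]
    base_state: dict | None = None   # shared t=0 state, pre-exclusion
    regenerations: int = 0


def simulate_trajectory(params: ModelParams, seed, *, network: int = 0,
                        arm: str = "control", t_end: int | None = None,
                        fast: bool = False) -> tuple[ColonyNetwork,
                                                     list[MeasureRecord]]:
    """Generate, burn in and run one unperturbed network to ``t_end``,
    recording measures at every timestep from t = 0."""
    sched = Schedule.from_params(params)
    t_end = sched.end if t_end is None else t_end
    net = generate_network(params, np.random.SeedSequence([seed, network, 0]))
    rng = _stream(seed, network, 1)
    while net.t < 0:
        step(net, params, rng)
    records = [measure_all(net, params, network=network, arm=arm, fast=fast)]
    while net.t < t_end:
        step(net, params, rng)
        records.append(measure_all(net, params, network=network, arm=arm,
                                   fast=fast))
    return net, records


def run_experiment(params: ModelParams, seed: int, *, network: int = 0,
                   snapshot_times: tuple[int, ...] = (),
                   fast: bool = False) -> ExperimentResult:
    """Run the full seven-arm paired experiment on one network.

    Networks whose burn-in endpoint has no tree with a foraging trail are
    regenerated from the next derived seed (logged), keeping ensembles full.
    Measures are recorded for every arm at every timestep t = 0 ... end;
    rows before a fork are shared by the arms descending from that branch.
    """
    params.validate()
    sched = Schedule.from_params(params)

    regenerations = 0
    while True:
        base = generate_network(
            params, np.random.SeedSequence([seed, network, 0, regenerations]))
        burn_rng = _stream(seed, network, 1, regenerations)
        while base.t < sched.exclusion_time:
            step(base, params, burn_rng)
        if cumulative_foraging_strength(base):
            break
        regenerations += 1
        logger.warning("network %d: no used tree at t=0, regenerating "
                       "(attempt %d)", network, regenerations)

    base_state = base.state_dict()

    # focal trees chosen on the shared pre-exclusion state
    focal = {
        "weakest": select_focal_tree(base, "weakest"),
        "strongest": select_focal_tree(base, "strongest"),
        "random": select_focal_tree(base, "random",
                                    _stream(seed, network, 2, regenerations)),
    }

    records: list[MeasureRecord] = []
    snapshots: dict[tuple[str, int], dict] = {}
    target_code = {t: i for i, t in enumerate(TARGETS)}
    type_code = {"none": 0, "sustained": 0, "reintroduced": 1}

    def record(net, arms, t_snapshot=True):
        rec = None
        for arm in arms:
            rec = measure_all(net, params, network=network, arm=arm.name,
                              fast=fast)
            records.append(rec)
            if t_snapshot and net.t in snapshot_times:
                snapshots[(arm.name, net.t)] = net.state_dict()
        return rec

    # --- season 1: four branches -----------------------------------------
    branches: dict[str, ColonyNetwork] = {}
    for target in TARGETS:
        branch = base.copy()
        if target != "control":
            exclude_tree(branch, focal[target])
        branches[target] = branch
        arms = [a for a in ARMS if a.target == target]
        record(branch, arms)

    for target, branch in branches.items():
        rng = _stream(seed, network, 3, regenerations, target_code[target])
        arms = [a for a in ARMS if a.target == target]
        while branch.t < sched.reintroduction_time:
            step(branch, params, rng)
            record(branch, arms)

    # --- seasons 2-3: fork sustained / reintroduced ----------------------
    finals: dict[str, ColonyNetwork] = {}
    for arm in ARMS:
        if arm.target == "control":
            net = branches["control"]
        else:
            net = branches[arm.target].copy()
            if arm.type == "reintroduced":
                reintroduce_tree(net, focal[arm.target])
        rng = _stream(seed, network, 4, regenerations,
                      target_code[arm.target], type_code[arm.type])
        while net.t < sched.end:
            step(net, params, rng)
            record(net, [arm])
        finals[arm.name] = net

    return ExperimentResult(network=network, seed=seed, focal_trees=focal,
                            records=records, snapshots=snapshots,
                            base_state=base_state,
                            regenerations=regenerations)
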