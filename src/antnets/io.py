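"""Serialization of networks, configuration and measure tables.

Networks round-trip losslessly through GraphML (interchange with graph
tools) or a versioned JSON snapshot format (exact precision, used in
tests).  Configuration is a YAML mapping of model parameters and is
validated field by field on load.
"""

from __future__ import annotations

import json
import os

import networkx as nx
import yaml

from .colony_graph import ACTIVE, ColonyNetwork, ModelParams
from .perturbation import Schedule

JSON_SCHEMA = "antnets-network/1"


def network_to_nx(net: ColonyNetwork) -> nx.Graph:
    g = nx.Graph(arena=net.arena, t=net.t, next_id=net._next_id)
    for n in net.nests.values():
        g.add_node(n.id, kind="nest", x=n.x, y=n.y, size=n.size,
                   status=n.status)
    for t in net.trees.values():
        g.add_node(t.id, kind="tree", x=t.x, y=t.y, status=t.status)
    for tr in net.trails.values():
        g.add_edge(tr.key[0], tr.key[1], kind=tr.kind, length=tr.length,
                   strength=tr.strength)
    return g


def nx_to_network(g: nx.Graph, check: bool = True) -> ColonyNetwork:
    d = {
        "arena": float(g.graph["arena"]),
        "t": int(g.graph["t"]),
        "next_id": int(g.graph["next_id"]),
        "nests": [], "trees": [], "trails": [],
    }
    for nid, a in g.nodes(data=True):
        nid = int(nid)
        if a["kind"] == "nest":
            d["nests"].append({"id": nid, "x": float(a["x"]),
                               "y": float(a["y"]), "size": float(a["size"]),
                               "status": a.get("status", ACTIVE)})
        elif a["kind"] == "tree":
            d["trees"].append({"id": nid, "x": float(a["x"]),
                               "y": float(a["y"]),
                               "status": a.get("status", ACTIVE)})
        else:
            raise ValueError(f"node {nid}: unknown kind {a['kind']!r}")
    for u, v, a in g.edges(data=True):
        d["trails"].append({"a": int(u), "b": int(v), "kind": a["kind"],
                            "length": float(a["length"]),
                            "strength": float(a["strength"])})
    return ColonyNetwork.from_state_dict(d, check=check)


def write_network(net: ColonyNetwork, path: str,
                  format: str | None = None) -> None:
    fmt = format or _guess_format(path)
    if fmt == "graphml":
        nx.write_graphml(network_to_nx(net), path)
    elif fmt == "json":
        doc = {"schema": JSON_SCHEMA, **net.state_dict()}
        with open(path, "w") as fh:
            json.dump(doc, fh)
    else:
        raise ValueError(f"unknown network format {fmt!r}")


def read_network(path: str, format: str | None = None,
                 check: bool = True) -> ColonyNetwork:
    fmt = format or _guess_format(path)
    if fmt == "graphml":
        return nx_to_network(nx.read_graphml(path), check=check)
    if fmt == "json":
        with open(path) as fh:
            doc = json.load(fh)
        if doc.get("schema") != JSON_SCHEMA:
            raise ValueError(f"unknown snapshot schema "
                             f"{doc.get('schema')!r}; expected {JSON_SCHEMA}")
        return ColonyNetwork.from_state_dict(doc, check=check)
    raise ValueError(f"unknown network format {fmt!r}")


def _guess_format(path: str) -> str:
    ext = os.path.splitext(path)[1].lower()
    if ext == ".graphml":
        return "graphml"
    if ext == ".json":
        return "json"
    raise ValueError(f"cannot infer network format from {path!r}")


# ---------------------------------------------------------------------------
# Configuration


def load_config(path: str) -> tuple[ModelParams, Schedule]:
    """Read a YAML parameter file and validate every field.

    The file is a flat mapping of ``ModelParams`` field names; missing
    fields keep their defaults, unknown fields raise.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    if not isinstance(doc, dict):
        raise ValueError("config must be a mapping of parameter names")
    params = ModelParams.from_dict(doc)
    return params, Schedule.from_params(params)


def save_config(params: ModelParams, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(params.to_dict(), fh, sort_keys=False)
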