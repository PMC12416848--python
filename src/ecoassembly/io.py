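"""Serialization: community snapshots (JSON), edge lists (CSV), GraphML,
trajectory tables (CSV) and scenario configuration files (YAML)."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Union

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .assembly import AssemblyConfig
from .community import Community, InteractionMatrices, ModelParams, SpeciesTraits
from .metrics import undirected_pair_graph

__all__ = [
    "save_community_json",
    "load_community_json",
    "write_edge_list",
    "write_graphml",
    "write_trajectory",
    "read_trajectory",
    "load_config",
    "save_config",
]

PathLike = Union[str, Path]


def save_community_json(com: Community, path: PathLike) -> None:
    """Write a full community snapshot (matrices, traits, abundances, ids)."""
    payload = {
        "species_ids": com.species_ids,
        "x": com.x.tolist(),
        "r": com.traits.r.tolist(),
        "s": com.traits.s.tolist(),
        "parent_of": {str(k): v for k, v in com.parent_of.items()},
        "event_index": com.event_index,
        "matrices": {
            "c": com.net.c.tolist(),
            "pplus": com.net.pplus.tolist(),
            "pminus": com.net.pminus.tolist(),
            "m": com.net.m.tolist(),
        },
    }
    Path(path).write_text(json.dumps(payload))


def load_community_json(path: PathLike) -> Community:
    payload = json.loads(Path(path).read_text())
    mats = payload["matrices"]
    net = InteractionMatrices(
        np.array(mats["c"]), np.array(mats["pplus"]), np.array(mats["pminus"]), np.array(mats["m"])
    )
    traits = SpeciesTraits(np.array(payload["r"]), np.array(payload["s"]))
    com = Community(
        net,
        traits,
        np.array(payload["x"]),
        [int(i) for i in payload["species_ids"]],
        {int(k): v for k, v in payload["parent_of"].items()},
        int(payload["event_index"]),
    )
    com.validate()
    return com


def _typed_edges(com: Community):
    """Yield (source_id, target_id, type, weight_ij, weight_ji) per pair.

    For consumer-resource pairs the source is the consumer; ``weight_ij``
    is the consumer's gain and ``weight_ji`` the resource's loss.
    """
    net = com.net
    ids = com.species_ids
    for i in range(net.S):
        for j in range(i + 1, net.S):
            if net.c[i, j] > 0:
                yield ids[i], ids[j], "competition", net.c[i, j], net.c[j, i]
            elif net.m[i, j] > 0:
                yield ids[i], ids[j], "mutualism", net.m[i, j], net.m[j, i]
            elif net.pplus[i, j] > 0:
                yield ids[i], ids[j], "consumer_resource", net.pplus[i, j], net.pminus[j, i]
            elif net.pplus[j, i] > 0:
                yield ids[j], ids[i], "consumer_resource", net.pplus[j, i], net.pminus[i, j]


def write_edge_list(com: Community, path: PathLike) -> pd.DataFrame:
    """Typed, weighted edge list CSV; returns the frame written."""
    df = pd.DataFrame(
        list(_typed_edges(com)),
        columns=["source_id", "target_id", "type", "weight_ij", "weight_ji"],
    )
    df.to_csv(path, index=False)
    return df


def write_graphml(com: Community, path: PathLike) -> None:
    """GraphML export of the typed interaction network (node traits attached)."""
    G = undirected_pair_graph(com.net)
    H = nx.relabel_nodes(G, dict(enumerate(com.species_ids)))
    for k, sid in enumerate(com.species_ids):
        H.nodes[sid]["abundance"] = float(com.x[k])
        H.nodes[sid]["r"] = float(com.traits.r[k])
        H.nodes[sid]["s"] = float(com.traits.s[k])
    nx.write_graphml(H, path)


def write_trajectory(traj: pd.DataFrame, path: PathLike) -> None:
    traj.to_csv(path, index=False)


def read_trajectory(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path)


def save_config(config: AssemblyConfig, path: PathLike) -> None:
    """YAML config mirroring :class:`AssemblyConfig` field-for-field."""
    d = dataclasses.asdict(config)
    d["params"] = dataclasses.asdict(config.params)
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def load_config(path: PathLike) -> AssemblyConfig:
    d = yaml.safe_load(Path(path).read_text())
    params = ModelParams(**d.pop("params", {}))
    return AssemblyConfig(params=params, **d)
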