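"""Consensus Louvain communities and a deterministic force-directed layout.

Louvain community detection is stochastic: different run seeds can return
different local optima.  The consensus procedure (Lancichinetti–Fortunato
style) runs Louvain many times, records how often each pair of nodes is
co-assigned, thresholds that co-assignment frequency matrix at tau, and
re-clusters the thresholded matrix — iterating until every run returns the
same partition.  Community detection operates on absolute edge weights,
the same unsigned convention used by the nodal metrics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .association import AssociationNetwork

__all__ = [
    "CommunityPartition",
    "Layout",
    "consensus_louvain",
    "layout_network",
    "partition_agreement",
    "write_partition_csv",
    "write_layout_json",
    "write_annotated_graphml",
]


@dataclass(frozen=True)
class CommunityPartition:
    """Node -> community assignment from consensus Louvain."""

    assignment: dict
    n_runs: int
    resolution: float
    tau: float
    consensus_matrix: np.ndarray
    node_names: tuple[str, ...]
    seed: int

    @property
    def n_communities(self) -> int:
        return len(set(self.assignment.values()))

    def as_labels(self) -> np.ndarray:
        return np.asarray([self.assignment[n] for n in self.node_names], dtype=int)

    def communities(self) -> list[set]:
        out: dict[int, set] = {}
        for node, c in self.assignment.items():
            out.setdefault(c, set()).add(node)
        return [out[c] for c in sorted(out)]


@dataclass(frozen=True)
class Layout:
    coordinates: dict
    k: float
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "node": list(self.coordinates),
                "x": [xy[0] for xy in self.coordinates.values()],
                "y": [xy[1] for xy in self.coordinates.values()],
            }
        )


def _louvain_labels(g: nx.Graph, nodes: tuple[str, ...], resolution: float, seed: int) -> np.ndarray:
    comms = nx.community.louvain_communities(
        g, weight="weight", resolution=resolution, seed=int(seed)
    )
    label = {}
    for c, members in enumerate(comms):
        for node in members:
            label[node] = c
    return np.asarray([label[n] for n in nodes], dtype=int)


def _canonical(labels: np.ndarray) -> tuple[int, ...]:
    """Relabel community ids in order of first appearance (comparison key)."""
    mapping: dict[int, int] = {}
    out = []
    for v in labels:
        if v not in mapping:
            mapping[v] = len(mapping)
        out.append(mapping[v])
    return tuple(out)


def consensus_louvain(
    net: AssociationNetwork,
    n_runs: int = 1000,
    resolution: float = 1.0,
    tau: float = 0.5,
    seed: int = 0,
    max_consensus_iter: int = 20,
) -> CommunityPartition:
    """Consensus partition from `n_runs` Louvain runs on absolute weights.

    The co-assignment frequency matrix of the runs is thresholded at `tau`
    (entries below tau are dropped) and re-clustered with another round of
    Louvain runs; this repeats until all runs agree, which is the returned
    "best" partition.  Deterministic given `seed`.
    """
    if net.n_nodes == 0:
        raise ValueError("empty network")
    if not 0.0 < tau < 1.0:
        raise ValueError("tau must be in (0, 1)")
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    nodes = net.node_names
    p = net.n_nodes
    rng = np.random.default_rng(seed)
    weights = net.abs_weights()
    first_consensus: np.ndarray | None = None
    for _ in range(max_consensus_iter):
        g = nx.Graph()
        g.add_nodes_from(nodes)
        for i in range(p):
            for j in range(i + 1, p):
                if weights[i, j] > 0:
                    g.add_edge(nodes[i], nodes[j], weight=float(weights[i, j]))
        runs = np.empty((n_runs, p), dtype=int)
        for r in range(n_runs):
            sub_seed = int(rng.integers(0, 2**31 - 1))
            runs[r] = _louvain_labels(g, nodes, resolution, sub_seed)
        consensus = np.zeros((p, p))
        for r in range(n_runs):
            consensus += runs[r][:, None] == runs[r][None, :]
        consensus /= n_runs
        if first_consensus is None:
            first_consensus = consensus.copy()
        distinct = {_canonical(runs[r]) for r in range(n_runs)}
        if len(distinct) == 1:
            labels = runs[0]
            return CommunityPartition(
                assignment={nodes[i]: int(_canonical(labels)[i]) for i in range(p)},
                n_runs=n_runs,
                resolution=resolution,
                tau=tau,
                consensus_matrix=first_consensus,
                node_names=nodes,
                seed=seed,
            )
        weights = np.where(consensus >= tau, consensus, 0.0)
        np.fill_diagonal(weights, 0.0)
    raise RuntimeError("consensus clustering did not stabilise")


def partition_agreement(a: CommunityPartition, b: CommunityPartition) -> float:
    """Adjusted Rand index between two partitions of the same node set."""
    if a.node_names != b.node_names:
        raise ValueError("partitions cover different node sets")
    la, lb = a.as_labels(), b.as_labels()
    return _adjusted_rand(la, lb)


def _adjusted_rand(la: np.ndarray, lb: np.ndarray) -> float:
    n = len(la)
    table: dict[tuple[int, int], int] = {}
    for x, y in zip(la, lb):
        table[(x, y)] = table.get((x, y), 0) + 1

    def comb2(v: int) -> float:
        return v * (v - 1) / 2.0

    sum_ij = sum(comb2(v) for v in table.values())
    a_marg: dict[int, int] = {}
    b_marg: dict[int, int] = {}
    for (x, y), v in table.items():
        a_marg[x] = a_marg.get(x, 0) + v
        b_marg[y] = b_marg.get(y, 0) + v
    sum_a = sum(comb2(v) for v in a_marg.values())
    sum_b = sum(comb2(v) for v in b_marg.values())
    total = comb2(n)
    expected = sum_a * sum_b / total if total else 0.0
    max_index = (sum_a + sum_b) / 2.0
    if max_index == expected:
        return 1.0
    return (sum_ij - expected) / (max_index - expected)


def layout_network(net: AssociationNetwork, k: float = 0.03, seed: int = 0) -> Layout:
    """Fruchterman–Reingold coordinates on absolute weights (seeded)."""
    if k <= 0:
        raise ValueError("k must be positive")
    g = net.to_graph(absolute=True)
    pos = nx.spring_layout(g, k=k, seed=int(seed), weight="weight")
    coords = {n: (float(x), float(y)) for n, (x, y) in pos.items()}
    if any(not np.isfinite(v).all() for v in (np.asarray(list(coords.values())),)):
        raise RuntimeError("layout produced non-finite coordinates")
    return Layout(coordinates=coords, k=k, seed=seed)


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------


def write_partition_csv(partition: CommunityPartition, path: str | Path) -> None:
    pd.DataFrame(
        {
            "node": list(partition.node_names),
            "community": [partition.assignment[n] for n in partition.node_names],
        }
    ).to_csv(path, index=False)


def write_layout_json(layout: Layout, path: str | Path) -> None:
    payload = {
        "k": layout.k,
        "seed": layout.seed,
        "coordinates": {n: list(xy) for n, xy in layout.coordinates.items()},
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def write_annotated_graphml(
    net: AssociationNetwork,
    partition: CommunityPartition,
    layout: Layout,
    path: str | Path,
) -> None:
    """GraphML with community and x/y position node attributes."""
    g = net.to_graph()
    for n in g.nodes:
        g.nodes[n]["community"] = int(partition.assignment[n])
        g.nodes[n]["x"] = float(layout.coordinates[n][0])
        g.nodes[n]["y"] = float(layout.coordinates[n][1])
    nx.write_graphml(g, str(path))
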