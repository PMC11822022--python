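"""Edge-level cluster permutation test (network-based-statistic style).

Per-edge contrasts on a network with thousands of edges face a severe
multiple-comparison penalty.  Instead of testing edges one at a time, the
cluster statistic thresholds the absolute pain-minus-nopain difference
matrix, finds the connected component containing the most suprathreshold
edges, and compares that component's edge count to the largest-cluster
sizes obtained under cohort-label permutations (one-tailed: big clusters
are the evidence).  Because the choice of threshold is arbitrary, the test
is swept over a grid of thresholds (default 0.025 to 0.05 in steps of
0.001) with one shared permutation set, and each edge is scored by the
fraction of thresholds at which it sits inside a significant cluster.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .association import AssociationNetwork, NetworkBuilder
from .permutation import one_tailed_p, permute_labels
from .synthetic import NOPAIN, PAIN, CohortTable

__all__ = [
    "ClusterResult",
    "ThresholdSweep",
    "DEFAULT_THRESHOLDS",
    "difference_matrix",
    "largest_cluster",
    "cluster_test",
    "threshold_sweep",
    "write_cluster_csv",
    "write_cluster_graphml",
]

DEFAULT_THRESHOLDS: tuple[float, ...] = tuple(
    np.round(np.arange(0.025, 0.0501, 0.001), 3)
)


def difference_matrix(
    pain_net: AssociationNetwork, nopain_net: AssociationNetwork
) -> np.ndarray:
    """Entrywise pain - nopain edge weights (signed, symmetric)."""
    if pain_net.node_names != nopain_net.node_names:
        raise ValueError("networks must share the same node set and ordering")
    return pain_net.weights - nopain_net.weights


def largest_cluster(
    diff: np.ndarray, threshold: float, node_names: Sequence[str] | None = None
) -> tuple[set[tuple[int, int]], int]:
    """Largest connected component of suprathreshold edges.

    Keeps edges with ``|difference| > threshold``, finds connected
    components over the kept edges, and returns the component containing
    the most *edges* (cluster size counts edges, not nodes) as a set of
    ``(i, j)`` index pairs with ``i < j``.  Ties between equally large
    components are broken by the lexicographically smallest node label.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    diff = np.asarray(diff, dtype=float)
    p = diff.shape[0]
    supra = np.triu(np.abs(diff) > threshold, 1)
    if not supra.any():
        return set(), 0
    adj = csr_matrix(supra + supra.T)
    n_comp, labels = connected_components(adj, directed=False)
    ii, jj = np.nonzero(supra)
    comp_of_edge = labels[ii]
    sizes = np.bincount(comp_of_edge, minlength=n_comp)
    best = sizes.max()
    candidates = np.flatnonzero(sizes == best)
    if len(candidates) > 1:
        names = list(node_names) if node_names is not None else [f"{k:06d}" for k in range(p)]
        keyed = sorted(
            candidates, key=lambda c: min(names[v] for v in np.flatnonzero(labels == c))
        )
        winner = keyed[0]
    else:
        winner = candidates[0]
    edges = {
        (int(a), int(b)) for a, b, c in zip(ii, jj, comp_of_edge) if c == winner
    }
    return edges, int(best)


def _largest_size(diff_abs_supra: np.ndarray) -> int:
    """Largest-component edge count from a boolean upper-triangular matrix."""
    if not diff_abs_supra.any():
        return 0
    adj = csr_matrix(diff_abs_supra + diff_abs_supra.T)
    _, labels = connected_components(adj, directed=False)
    ii, _ = np.nonzero(diff_abs_supra)
    return int(np.bincount(labels[ii]).max())


@dataclass(frozen=True)
class ClusterResult:
    """Observed suprathreshold cluster and its permutation null."""

    threshold: float
    cluster_edges: frozenset[tuple[int, int]]
    cluster_size: int
    p_one_tailed: float
    null_sizes: np.ndarray
    signs: dict
    node_names: tuple[str, ...]
    n_perm: int
    seed: int

    def significant(self, alpha: float = 0.05) -> bool:
        return self.p_one_tailed <= alpha

    def edge_names(self) -> list[tuple[str, str]]:
        return [
            (self.node_names[i], self.node_names[j])
            for i, j in sorted(self.cluster_edges)
        ]

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "cluster_size": self.cluster_size,
            "p_one_tailed": self.p_one_tailed,
            "n_perm": self.n_perm,
            "seed": self.seed,
            "edges": [
                {
                    "node_a": self.node_names[i],
                    "node_b": self.node_names[j],
                    "sign": self.signs[(i, j)],
                }
                for i, j in sorted(self.cluster_edges)
            ],
        }


def _observed_cluster(
    diff: np.ndarray,
    threshold: float,
    null_sizes: np.ndarray,
    node_names: tuple[str, ...],
    n_perm: int,
    seed: int,
) -> ClusterResult:
    edges, size = largest_cluster(diff, threshold, node_names)
    signs = {
        (i, j): ("pain>nopain" if diff[i, j] > 0 else "nopain>pain") for i, j in edges
    }
    return ClusterResult(
        threshold=float(threshold),
        cluster_edges=frozenset(edges),
        cluster_size=size,
        p_one_tailed=one_tailed_p(null_sizes, size),
        null_sizes=np.asarray(null_sizes, dtype=float),
        signs=signs,
        node_names=node_names,
        n_perm=n_perm,
        seed=seed,
    )


def _permutation_diffs(table: CohortTable, n_perm: int, seed: int):
    """Observed difference matrix plus a generator of permuted ones."""
    labels = table.labels()
    if not ((labels == PAIN).any() and (labels == NOPAIN).any()):
        raise ValueError("table must contain both cohorts")
    builder = NetworkBuilder(table)

    def diff_for(lab: np.ndarray) -> np.ndarray:
        net_p = builder.build(np.flatnonzero(lab == PAIN))
        net_n = builder.build(np.flatnonzero(lab == NOPAIN))
        return net_p.weights - net_n.weights

    observed = diff_for(labels)
    rng = np.random.default_rng(seed)

    def nulls():
        for _ in range(n_perm):
            yield diff_for(permute_labels(labels, rng))

    return observed, nulls


def cluster_test(
    table: CohortTable, threshold: float, n_perm: int = 10_000, seed: int = 0
) -> ClusterResult:
    """One-tailed largest-cluster permutation test at a single threshold."""
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    observed, nulls = _permutation_diffs(table, n_perm, seed)
    null_sizes = np.empty(n_perm)
    for b, diff in enumerate(nulls()):
        null_sizes[b] = _largest_size(np.triu(np.abs(diff) > threshold, 1))
    return _observed_cluster(
        observed, threshold, null_sizes, tuple(table.names), n_perm, seed
    )


@dataclass(frozen=True)
class ThresholdSweep:
    """Cluster tests over a threshold grid with one shared permutation set."""

    thresholds: tuple[float, ...]
    results: tuple[ClusterResult, ...]
    edge_frequency: np.ndarray
    node_names: tuple[str, ...]
    alpha: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": [r.threshold for r in self.results],
                "cluster_size": [r.cluster_size for r in self.results],
                "p_one_tailed": [r.p_one_tailed for r in self.results],
                "significant": [r.significant(self.alpha) for r in self.results],
            }
        )

    def edge_frequency_frame(self) -> pd.DataFrame:
        p = len(self.node_names)
        rows = []
        for i in range(p):
            for j in range(i + 1, p):
                if self.edge_frequency[i, j] > 0:
                    rows.append(
                        {
                            "node_a": self.node_names[i],
                            "node_b": self.node_names[j],
                            "edge_frequency": self.edge_frequency[i, j],
                        }
                    )
        return pd.DataFrame(rows, columns=["node_a", "node_b", "edge_frequency"])


def threshold_sweep(
    table: CohortTable,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    n_perm: int = 10_000,
    seed: int = 0,
    alpha: float = 0.05,
) -> ThresholdSweep:
    """Cluster test at every threshold, reusing one permutation set.

    ``edge_frequency[i, j]`` is the fraction of thresholds at which edge
    (i, j) belongs to a *significant* cluster (0 everywhere the cluster is
    not significant at `alpha`).
    """
    thresholds = [float(t) for t in thresholds]
    if any(b <= a for a, b in zip(thresholds, thresholds[1:])):
        raise ValueError("thresholds must be ascending")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    observed, nulls = _permutation_diffs(table, n_perm, seed)
    n_thr = len(thresholds)
    null_sizes = np.empty((n_perm, n_thr))
    for b, diff in enumerate(nulls()):
        absdiff = np.triu(np.abs(diff), 1)
        for t, thr in enumerate(thresholds):
            null_sizes[b, t] = _largest_size(absdiff > thr)
    names = tuple(table.names)
    results = [
        _observed_cluster(observed, thr, null_sizes[:, t], names, n_perm, seed)
        for t, thr in enumerate(thresholds)
    ]
    p = len(names)
    freq = np.zeros((p, p))
    for r in results:
        if r.significant(alpha):
            for i, j in r.cluster_edges:
                freq[i, j] += 1.0
                freq[j, i] += 1.0
    freq /= n_thr
    return ThresholdSweep(
        thresholds=tuple(thresholds),
        results=tuple(results),
        edge_frequency=freq,
        node_names=names,
        alpha=alpha,
    )


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------


def write_cluster_csv(result: ClusterResult, diff: np.ndarray, path: str | Path) -> None:
    """Edge list of the observed difference matrix with cluster membership."""
    names = result.node_names
    p = len(names)
    rows = []
    for i in range(p):
        for j in range(i + 1, p):
            in_cluster = (i, j) in result.cluster_edges
            rows.append(
                {
                    "node_a": names[i],
                    "node_b": names[j],
                    "difference": diff[i, j],
                    "sign": "pain>nopain" if diff[i, j] > 0 else "nopain>pain",
                    "threshold": result.threshold,
                    "in_cluster": in_cluster,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_cluster_graphml(result: ClusterResult, diff: np.ndarray, path: str | Path) -> None:
    g = nx.Graph()
    for i, j in sorted(result.cluster_edges):
        g.add_edge(
            result.node_names[i],
            result.node_names[j],
            difference=float(diff[i, j]),
            sign=result.signs[(i, j)],
        )
    nx.write_graphml(g, str(path))


def write_sweep_json(sweep: ThresholdSweep, path: str | Path) -> None:
    payload = {
        "alpha": sweep.alpha,
        "results": [r.to_dict() for r in sweep.results],
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
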