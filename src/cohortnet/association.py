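"""Mixed-type pairwise association networks.

Nodes are variables, edges are unregularised pairwise association
coefficients, with the estimator dispatched by the variable-type pair:

=============  ============  =============  =============
               binary        ordinal        continuous
=============  ============  =============  =============
binary         phi           point-biserial point-biserial
ordinal        point-biserial spearman      spearman
continuous     point-biserial spearman      spearman
=============  ============  =============  =============

All three estimators are Pearson correlations on a suitable coding (0/1
values for phi and point-biserial, mid-ranks for Spearman), which is what
makes whole-network construction a pair of correlation-matrix evaluations
when there is no missing data — the hot path of every permutation test.

Missing data is handled by pairwise-complete deletion per edge; the
per-edge complete sample size is kept in ``n_effective``.  An edge whose
pairwise-complete data leaves either variable constant is *undefined*: its
weight is set to 0 and it is flagged in ``undefined`` (and a warning names
the variable), so that matrices stay comparable across permutation
replicates instead of dropping nodes mid-test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import PAIN, NOPAIN, CohortTable, VariableSchema

__all__ = [
    "AssociationNetwork",
    "NetworkBuilder",
    "select_method",
    "phi_coefficient",
    "point_biserial",
    "spearman",
    "build_network",
    "network_from_weights",
    "write_graphml",
    "read_graphml",
    "write_edge_csv",
]

PHI = "phi"
POINTBISERIAL = "pointbiserial"
SPEARMAN = "spearman"
METHODS = (PHI, POINTBISERIAL, SPEARMAN)


def select_method(vtype_a: str, vtype_b: str) -> str:
    """Estimator for a pair of variable types (symmetric in its arguments)."""
    for v in (vtype_a, vtype_b):
        if v not in ("binary", "ordinal", "continuous"):
            raise ValueError(f"unknown vtype {v!r}")
    a_bin = vtype_a == "binary"
    b_bin = vtype_b == "binary"
    if a_bin and b_bin:
        return PHI
    if a_bin or b_bin:
        return POINTBISERIAL
    return SPEARMAN


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.std() == 0.0 or y.std() == 0.0:
        return np.nan
    r = np.corrcoef(x, y)[0, 1]
    return float(np.clip(r, -1.0, 1.0))


def phi_coefficient(x: Sequence[float], y: Sequence[float]) -> float:
    """Association of two 0/1 variables: Pearson on the 0/1 codings.

    Equals ``(ad - bc) / sqrt((a+b)(c+d)(a+c)(b+d))`` on the 2x2 table.
    Returns NaN (the undefined-edge signal) when either vector is constant.
    """
    return _pearson(x, y)


def point_biserial(g: Sequence[float], y: Sequence[float]) -> float:
    """Association of a 0/1 variable with a numeric one: plain Pearson."""
    return _pearson(g, y)


def spearman(x: Sequence[float], y: Sequence[float]) -> float:
    """Rank association: Pearson correlation of mid-ranks (ties averaged)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return _pearson(stats.rankdata(x), stats.rankdata(y))


_ESTIMATORS = {PHI: phi_coefficient, POINTBISERIAL: point_biserial, SPEARMAN: spearman}


@dataclass
class AssociationNetwork:
    """Symmetric weighted association matrix over variables.

    ``weights`` are signed coefficients in [-1, 1] with a zero diagonal;
    ``methods[i, j]`` names the estimator used for the pair;
    ``n_effective[i, j]`` is the pairwise-complete sample size;
    ``undefined`` flags edges forced to 0 because a variable was constant.
    """

    weights: np.ndarray
    methods: np.ndarray
    node_names: tuple[str, ...]
    n_effective: np.ndarray
    undefined: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.node_names = tuple(self.node_names)
        p = len(self.node_names)
        if self.weights.shape != (p, p):
            raise ValueError("weights shape does not match node_names")
        if not np.allclose(self.weights, self.weights.T, atol=1e-12):
            raise ValueError("weights must be symmetric")
        if np.any(np.abs(self.weights) > 1.0 + 1e-9):
            raise ValueError("weights must lie in [-1, 1]")
        if np.any(np.diag(self.weights) != 0.0):
            raise ValueError("diagonal must be zero")
        if self.undefined is None:
            self.undefined = np.zeros((p, p), dtype=bool)

    @property
    def n_nodes(self) -> int:
        return len(self.node_names)

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.weights, 1)))

    def abs_weights(self) -> np.ndarray:
        return np.abs(self.weights)

    def upper_triangle(self) -> np.ndarray:
        """Vectorised strict upper triangle of signed weights."""
        iu = np.triu_indices(self.n_nodes, 1)
        return self.weights[iu]

    def edge_iter(self):
        p = self.n_nodes
        for i in range(p):
            for j in range(i + 1, p):
                yield i, j

    def to_graph(self, absolute: bool = False, drop_zero: bool = True) -> nx.Graph:
        """networkx graph with weight / method / n_effective edge attributes."""
        g = nx.Graph()
        g.add_nodes_from(self.node_names)
        for i, j in self.edge_iter():
            w = self.weights[i, j]
            if drop_zero and w == 0.0:
                continue
            g.add_edge(
                self.node_names[i],
                self.node_names[j],
                weight=float(abs(w) if absolute else w),
                method=str(self.methods[i, j]),
                n_effective=int(self.n_effective[i, j]),
            )
        return g


def methods_matrix(schema: Sequence[VariableSchema]) -> np.ndarray:
    vtypes = [v.vtype for v in schema]
    p = len(vtypes)
    out = np.empty((p, p), dtype=object)
    for i in range(p):
        for j in range(p):
            out[i, j] = select_method(vtypes[i], vtypes[j]) if i != j else ""
    return out


class NetworkBuilder:
    """Reusable builder bound to one table's schema.

    Precomputes the estimator-dispatch matrix once so that thousands of
    permutation rebuilds only pay for ranking and two correlation-matrix
    evaluations each.
    """

    def __init__(self, table: CohortTable):
        self.table = table
        self.names = tuple(table.names)
        self.methods = methods_matrix(table.schema)
        self._spearman_mask = self.methods == SPEARMAN
        self._values = table.values
        self._has_missing = bool(np.isnan(self._values).any())

    def build(self, rows: np.ndarray | None = None) -> AssociationNetwork:
        values = self._values if rows is None else self._values[rows]
        if values.shape[0] < 2:
            raise ValueError("need at least 2 participants to estimate associations")
        if self._has_missing and np.isnan(values).any():
            return self._build_pairwise(values)
        return self._build_dense(values)

    # -- complete-data fast path -------------------------------------------
    def _build_dense(self, values: np.ndarray) -> AssociationNetwork:
        n, p = values.shape
        ranks = stats.rankdata(values, axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            c_raw = np.corrcoef(values, rowvar=False)
            c_rank = np.corrcoef(ranks, rowvar=False)
        weights = np.where(self._spearman_mask, c_rank, c_raw)
        undefined = ~np.isfinite(weights)
        np.fill_diagonal(undefined, False)
        if undefined.any():
            self._warn_constant(values)
            weights = np.where(undefined, 0.0, weights)
        np.clip(weights, -1.0, 1.0, out=weights)
        weights = (weights + weights.T) / 2.0
        np.fill_diagonal(weights, 0.0)
        n_eff = np.full((p, p), n, dtype=int)
        np.fill_diagonal(n_eff, 0)
        return AssociationNetwork(weights, self.methods, self.names, n_eff, undefined)

    # -- pairwise-complete path (missing data present) ---------------------
    def _build_pairwise(self, values: np.ndarray) -> AssociationNetwork:
        n, p = values.shape
        finite = np.isfinite(values)
        weights = np.zeros((p, p))
        undefined = np.zeros((p, p), dtype=bool)
        n_eff = np.zeros((p, p), dtype=int)
        constant_vars: set[str] = set()
        for i in range(p):
            for j in range(i + 1, p):
                m = finite[:, i] & finite[:, j]
                n_eff[i, j] = n_eff[j, i] = int(m.sum())
                if n_eff[i, j] < 2:
                    undefined[i, j] = undefined[j, i] = True
                    continue
                r = _ESTIMATORS[self.methods[i, j]](values[m, i], values[m, j])
                if not np.isfinite(r):
                    undefined[i, j] = undefined[j, i] = True
                    for k in (i, j):
                        if values[m, k].std() == 0.0:
                            constant_vars.add(self.names[k])
                    continue
                weights[i, j] = weights[j, i] = r
        if constant_vars:
            warnings.warn(
                "constant variable(s) on pairwise-complete data, edges set to 0: "
                + ", ".join(sorted(constant_vars)),
                stacklevel=3,
            )
        return AssociationNetwork(weights, self.methods, self.names, n_eff, undefined)

    def _warn_constant(self, values: np.ndarray) -> None:
        const = [self.names[k] for k in range(values.shape[1]) if values[:, k].std() == 0.0]
        if const:
            warnings.warn(
                "constant variable(s) in cohort, edges set to 0: " + ", ".join(const),
                stacklevel=4,
            )


def _resolve_rows(table: CohortTable, participants) -> np.ndarray | None:
    if participants is None:
        return None
    if isinstance(participants, str):
        if participants not in (PAIN, NOPAIN):
            raise ValueError(f"unknown cohort filter {participants!r}")
        return table.cohort_index(participants)
    participants = np.asarray(participants)
    if participants.dtype == bool:
        return np.flatnonzero(participants)
    return participants.astype(int)


def build_network(table: CohortTable, participants=None) -> AssociationNetwork:
    """Association network of `table`, optionally restricted to participants.

    `participants` may be ``None`` (everyone — the "general" network), a
    cohort label (``"pain"`` / ``"nopain"``), a boolean mask, or an array
    of positional row indices.
    """
    return NetworkBuilder(table).build(_resolve_rows(table, participants))


def network_from_weights(
    weights: np.ndarray,
    node_names: Sequence[str] | None = None,
    methods: np.ndarray | str = SPEARMAN,
    n: int = 0,
) -> AssociationNetwork:
    """Wrap a plain symmetric matrix as a network (tests, worked examples)."""
    weights = np.asarray(weights, dtype=float)
    p = weights.shape[0]
    if node_names is None:
        node_names = [f"v{i}" for i in range(p)]
    if isinstance(methods, str):
        m = np.full((p, p), methods, dtype=object)
        np.fill_diagonal(m, "")
        methods = m
    n_eff = np.full((p, p), n, dtype=int)
    np.fill_diagonal(n_eff, 0)
    return AssociationNetwork(weights, methods, tuple(node_names), n_eff)


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------


def write_graphml(net: AssociationNetwork, path: str | Path) -> None:
    nx.write_graphml(net.to_graph(), str(path))


def read_graphml(path: str | Path) -> nx.Graph:
    return nx.read_graphml(str(path))


def write_edge_csv(net: AssociationNetwork, path: str | Path) -> None:
    """Flat edge list: node_a, node_b, weight, method (zero edges included)."""
    rows = [
        {
            "node_a": net.node_names[i],
            "node_b": net.node_names[j],
            "weight": net.weights[i, j],
            "method": net.methods[i, j],
            "n_effective": int(net.n_effective[i, j]),
        }
        for i, j in net.edge_iter()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
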