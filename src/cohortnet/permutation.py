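"""Label-permutation inference for cohort contrasts.

The observed statistic of every contrast is ``stat(pain network) -
stat(nopain network)``; the null distribution is obtained by shuffling the
cohort labels (preserving the two cohort sizes), rebuilding both networks
from scratch for each permutation, and re-evaluating the statistic.
Nothing is permuted at the level of precomputed metric vectors — the
statistics depend on the whole network, so the networks are rebuilt.

Two-tailed p-values follow the doubling rule: the proportion of
permutations at least as extreme as the observed value on its own tail,
doubled and capped at 1.  The count is floored at 1 (so the smallest
reportable p is 2/n_perm two-tailed, 1/n_perm one-tailed): a permutation
test cannot certify p = 0.  Extremeness is evaluated per tail against the
raw null values, which is well defined for asymmetric nulls.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .association import AssociationNetwork, NetworkBuilder
from .metrics import (
    clustering_coefficient,
    global_metrics,
    network_distance,
    strength,
    eigenvector_centrality,
)
from .synthetic import NOPAIN, PAIN, CohortTable

__all__ = [
    "PermutationResult",
    "SampleSizeCurve",
    "SCALAR_STATISTICS",
    "NODAL_STATISTICS",
    "permute_labels",
    "two_tailed_p",
    "one_tailed_p",
    "group_difference_test",
    "fdr_correct",
    "nodal_report",
    "sample_size_analysis",
    "write_result_json",
]

SCALAR_STATISTICS = ("global_strength", "global_clustering", "network_distance_to_general")
NODAL_STATISTICS = ("strength", "eigencentrality", "clustering")


@dataclass(frozen=True)
class PermutationResult:
    """Observed group difference with its permutation null."""

    statistic: str
    observed: float
    null_sample: np.ndarray
    p_two_tailed: float
    ci_low: float
    ci_high: float
    n_perm: int
    seed: int
    node: str | None = None

    @property
    def significant(self) -> bool:
        """Observed value outside the 95% percentile band of the null."""
        return not (self.ci_low <= self.observed <= self.ci_high)

    def to_dict(self, include_null: bool = False) -> dict:
        out = {
            "statistic": self.statistic,
            "node": self.node,
            "observed": self.observed,
            "p_two_tailed": self.p_two_tailed,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n_perm": self.n_perm,
            "seed": self.seed,
        }
        if include_null:
            out["null_sample"] = [float(v) for v in self.null_sample]
        return out


def permute_labels(labels: Sequence[str], seed: int | np.random.Generator) -> np.ndarray:
    """Uniformly random relabelling preserving the group sizes."""
    labels = np.asarray(labels, dtype=object)
    if len(set(labels.tolist())) < 2:
        raise ValueError("need two cohort labels to permute")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.permutation(labels)


def _tail_counts(null: np.ndarray, observed: float) -> tuple[int, int]:
    upper = int(np.count_nonzero(null >= observed))
    lower = int(np.count_nonzero(null <= observed))
    return lower, upper


def two_tailed_p(null: np.ndarray, observed: float) -> float:
    """Doubled smaller-tail proportion, floored at 2/n_perm, capped at 1."""
    lower, upper = _tail_counts(np.asarray(null, dtype=float), float(observed))
    count = max(min(lower, upper), 1)
    return min(1.0, 2.0 * count / len(null))


def one_tailed_p(null: np.ndarray, observed: float) -> float:
    """Upper-tail proportion (null >= observed), floored at 1/n_perm."""
    null = np.asarray(null, dtype=float)
    count = max(int(np.count_nonzero(null >= float(observed))), 1)
    return min(1.0, count / len(null))


def _make_result(
    statistic: str,
    observed: float,
    null: np.ndarray,
    seed: int,
    node: str | None = None,
) -> PermutationResult:
    lo, hi = np.percentile(null, [2.5, 97.5])
    return PermutationResult(
        statistic=statistic,
        observed=float(observed),
        null_sample=np.asarray(null, dtype=float),
        p_two_tailed=two_tailed_p(null, observed),
        ci_low=float(lo),
        ci_high=float(hi),
        n_perm=len(null),
        seed=seed,
        node=node,
    )


def _stat_evaluators(
    names: Sequence[str], general: AssociationNetwork | None
) -> dict[str, Callable[[AssociationNetwork], np.ndarray | float]]:
    evals: dict[str, Callable] = {}
    for name in names:
        if name == "global_strength":
            evals[name] = lambda net: global_metrics(net).global_strength
        elif name == "global_clustering":
            evals[name] = lambda net: global_metrics(net).global_clustering
        elif name == "network_distance_to_general":
            assert general is not None
            evals[name] = lambda net, g=general: network_distance(net, g)
        elif name == "strength":
            evals[name] = strength
        elif name == "eigencentrality":
            evals[name] = eigenvector_centrality
        elif name == "clustering":
            evals[name] = clustering_coefficient
        else:
            raise ValueError(
                f"unknown statistic {name!r}; choose from "
                f"{SCALAR_STATISTICS + NODAL_STATISTICS}"
            )
    return evals


def group_difference_test(
    table: CohortTable,
    statistic: str | Sequence[str],
    n_perm: int = 10_000,
    seed: int = 0,
) -> PermutationResult | dict:
    """Permutation contrast of pain vs nopain for one or more statistics.

    Returns a :class:`PermutationResult` for a single scalar statistic, a
    ``{node: PermutationResult}`` mapping for a single nodal statistic, and
    a ``{statistic: result}`` mapping when a sequence of statistic names is
    given.  All statistics in one call share a single permutation pass (the
    networks are rebuilt once per permutation, not once per statistic).
    """
    single = isinstance(statistic, str)
    names = [statistic] if single else list(statistic)
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    labels = table.labels()
    if not ((labels == PAIN).any() and (labels == NOPAIN).any()):
        raise ValueError("table must contain both cohorts")
    builder = NetworkBuilder(table)
    general = (
        builder.build(None) if "network_distance_to_general" in names else None
    )
    evals = _stat_evaluators(names, general)

    def differences(lab: np.ndarray) -> dict[str, np.ndarray | float]:
        net_p = builder.build(np.flatnonzero(lab == PAIN))
        net_n = builder.build(np.flatnonzero(lab == NOPAIN))
        return {k: np.asarray(f(net_p)) - np.asarray(f(net_n)) for k, f in evals.items()}

    observed = differences(labels)
    rng = np.random.default_rng(seed)
    nulls = {k: [] for k in names}
    for _ in range(n_perm):
        perm = differences(permute_labels(labels, rng))
        for k in names:
            nulls[k].append(perm[k])

    results: dict[str, PermutationResult | dict[str, PermutationResult]] = {}
    for k in names:
        null = np.asarray(nulls[k], dtype=float)
        obs = observed[k]
        if np.ndim(obs) == 0:
            results[k] = _make_result(k, float(obs), null, seed)
        else:
            results[k] = {
                node: _make_result(k, float(obs[i]), null[:, i], seed, node=node)
                for i, node in enumerate(table.names)
            }
    return results[names[0]] if single else results


def fdr_correct(p_values: Sequence[float], q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up at level `q`.

    Returns ``(reject, p_adjusted)``; rejection flags are monotone in p.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, p_adj


def nodal_report(
    nodal_results: Mapping[str, Mapping[str, PermutationResult]],
    q: float = 0.05,
) -> pd.DataFrame:
    """Long-format per-node table with BH-FDR flags per statistic."""
    frames = []
    for stat, per_node in nodal_results.items():
        nodes = list(per_node)
        p = [per_node[n].p_two_tailed for n in nodes]
        reject, p_adj = fdr_correct(p, q)
        frames.append(
            pd.DataFrame(
                {
                    "node": nodes,
                    "statistic": stat,
                    "observed": [per_node[n].observed for n in nodes],
                    "p": p,
                    "p_adjusted": p_adj,
                    "significant": reject,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


@dataclass(frozen=True)
class SampleSizeCurve:
    """Distance-to-general curves over subsample sizes.

    ``pain_distance[k]`` is the distance between a network built from
    ``sizes[k]`` random pain participants and the general (everyone)
    network; the random band holds the median and 95% interval of the same
    distance for random same-size subsets of *all* participants.
    ``threshold_size`` is the smallest size whose pain distance exceeds the
    97.5th percentile of the random band (None if none does).
    """

    sizes: tuple[int, ...]
    pain_distance: np.ndarray
    random_median: np.ndarray
    random_low: np.ndarray
    random_high: np.ndarray
    n_perm: int
    seed: int

    @property
    def normalised_distance(self) -> np.ndarray:
        return self.pain_distance - self.random_median

    @property
    def threshold_size(self) -> int | None:
        above = np.flatnonzero(self.pain_distance > self.random_high)
        return int(self.sizes[above[0]]) if above.size else None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "size": self.sizes,
                "pain_distance": self.pain_distance,
                "random_median": self.random_median,
                "random_low": self.random_low,
                "random_high": self.random_high,
                "normalised_distance": self.normalised_distance,
            }
        )


DEFAULT_SIZES = (100, 500, 1000, 3000, 5000, 7000, 9000)


def sample_size_analysis(
    table: CohortTable,
    sizes: Sequence[int] | None = None,
    n_perm: int = 1000,
    seed: int = 0,
) -> SampleSizeCurve:
    """How many pain participants does a detectable cohort difference need?

    For each size s, a network from s random pain participants is compared
    (Euclidean distance of upper triangles) to the general network, against
    a band of `n_perm` networks from random s-subsets of all participants.
    """
    pain_idx = table.cohort_index(PAIN)
    if sizes is None:
        sizes = [s for s in DEFAULT_SIZES if s <= len(pain_idx)]
        if not sizes:
            raise ValueError("pain cohort smaller than the smallest default size")
    sizes = sorted(int(s) for s in sizes)
    if sizes[0] < 2:
        raise ValueError("sizes must be >= 2")
    if sizes[-1] > len(pain_idx):
        raise ValueError(
            f"size {sizes[-1]} exceeds the pain cohort ({len(pain_idx)} participants)"
        )
    builder = NetworkBuilder(table)
    general = builder.build(None)
    n_all = table.n_participants
    rng = np.random.default_rng(seed)
    pain_d, med, lo, hi = [], [], [], []
    for s in sizes:
        sub = rng.choice(pain_idx, size=s, replace=False)
        pain_d.append(network_distance(builder.build(sub), general))
        rand = np.empty(n_perm)
        for b in range(n_perm):
            rows = rng.choice(n_all, size=s, replace=False)
            rand[b] = network_distance(builder.build(rows), general)
        q_lo, q_med, q_hi = np.percentile(rand, [2.5, 50.0, 97.5])
        med.append(q_med)
        lo.append(q_lo)
        hi.append(q_hi)
    return SampleSizeCurve(
        sizes=tuple(sizes),
        pain_distance=np.asarray(pain_d),
        random_median=np.asarray(med),
        random_low=np.asarray(lo),
        random_high=np.asarray(hi),
        n_perm=n_perm,
        seed=seed,
    )


def write_result_json(
    results: PermutationResult | Mapping, path: str | Path, include_null: bool = False
) -> None:
    def encode(obj):
        if isinstance(obj, PermutationResult):
            return obj.to_dict(include_null)
        if isinstance(obj, Mapping):
            return {k: encode(v) for k, v in obj.items()}
        return obj

    Path(path).write_text(json.dumps(encode(results), indent=2) + "\n")
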