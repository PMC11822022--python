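"""End-to-end orchestration: simulate/load, build, contrast, report.

A :class:`RunConfig` (YAML-serialisable) fully determines a run: the data
source (paths to a cohort table + schema, or a synthetic spec), the
statistics to contrast, permutation counts, the FDR level, the cluster
threshold grid, community-detection and layout parameters, and one master
seed.  ``run_pipeline`` executes the stages in order and writes every
module's outputs plus a single ``manifest.json`` whose content is a pure
function of config + seed (no timestamps), so two identical runs produce
byte-identical manifests.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from . import __version__
from .association import NetworkBuilder, write_edge_csv, write_graphml
from .clusters import (
    DEFAULT_THRESHOLDS,
    difference_matrix,
    threshold_sweep,
    write_cluster_csv,
    write_cluster_graphml,
    write_sweep_json,
)
from .community import (
    consensus_louvain,
    layout_network,
    write_annotated_graphml,
    write_layout_json,
    write_partition_csv,
)
from .metrics import global_metrics, nodal_metrics, write_global_json, write_nodal_csv
from .permutation import (
    NODAL_STATISTICS,
    SCALAR_STATISTICS,
    PermutationResult,
    group_difference_test,
    nodal_report,
    sample_size_analysis,
    write_result_json,
)
from .synthetic import (
    CohortTable,
    default_spec,
    generate_cohorts,
    read_table,
    write_table,
)

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]

log = logging.getLogger("cohortnet")


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Everything a reproducible run needs.

    Data source: either ``table_path`` (+ ``schema_path``) for a saved
    cohort table, or the synthetic block (``synthetic=True`` with sizes,
    planted effect and missingness).  All named constants default to the
    motivating study's values: 10,000 contrast permutations, 1,000
    sample-size permutations, q = 0.05, thresholds 0.025–0.05 step 0.001,
    1,000 Louvain runs at resolution 1 with tau 0.5, layout k = 0.03.
    """

    # data source
    synthetic: bool = True
    table_path: str | None = None
    schema_path: str | None = None
    n_pain: int = 1000
    n_nopain: int = 2500
    effect_delta: float = 0.0
    missing_rate: float = 0.0
    # contrasts
    statistics: tuple[str, ...] = SCALAR_STATISTICS[:2] + NODAL_STATISTICS
    n_perm: int = 10_000
    fdr_q: float = 0.05
    # sample-size analysis
    sample_sizes: tuple[int, ...] | None = None
    n_perm_sample_size: int = 1000
    # cluster sweep
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    # communities + layout
    community_runs: int = 1000
    resolution: float = 1.0
    tau: float = 0.5
    layout_k: float = 0.03
    # bookkeeping
    seed: int = 0
    out_dir: str = "cohortnet_out"

    def validate(self) -> None:
        if not self.synthetic:
            if not self.table_path:
                raise ValueError("table_path required when synthetic=False")
            if not Path(self.table_path).exists():
                raise ValueError(f"table_path {self.table_path!r} does not exist")
            schema = self.schema_path or str(
                Path(self.table_path).with_suffix(".schema.yaml")
            )
            if not Path(schema).exists():
                raise ValueError(f"schema file {schema!r} does not exist")
        if self.n_perm < 100 or self.n_perm_sample_size < 100:
            raise ValueError("permutation counts must be >= 100")
        if not 0.0 < self.fdr_q < 1.0:
            raise ValueError("fdr_q must be in (0, 1)")
        known = set(SCALAR_STATISTICS) | set(NODAL_STATISTICS)
        unknown = [s for s in self.statistics if s not in known]
        if unknown:
            raise ValueError(f"unknown statistics {unknown}")

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["statistics"] = list(self.statistics)
        out["thresholds"] = [float(t) for t in self.thresholds]
        if self.sample_sizes is not None:
            out["sample_sizes"] = [int(s) for s in self.sample_sizes]
        return out

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        for key in ("statistics", "thresholds", "sample_sizes"):
            if key in data and data[key] is not None:
                data[key] = tuple(data[key])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def _load_table(config: RunConfig) -> CohortTable:
    if config.synthetic:
        spec = default_spec(
            n_pain=config.n_pain,
            n_nopain=config.n_nopain,
            effect_delta=config.effect_delta,
            missing_rate=config.missing_rate,
            seed=config.seed,
        )
        return generate_cohorts(spec)
    return read_table(config.table_path, config.schema_path)


def _stage(manifest: dict, name: str):
    class _StageCtx:
        def __enter__(self):
            log.info("stage %s: start", name)
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                manifest["failed_stage"] = name
                raise PipelineError(name, exc) from exc
            log.info("stage %s: done in %.2fs", name, time.perf_counter() - self.t0)
            manifest["stages"].append(name)
            return False

    return _StageCtx()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns the manifest dictionary.

    Stages: load/simulate -> general/pain/nopain networks -> global and
    nodal permutation contrasts with FDR -> sample-size analysis ->
    cluster threshold sweep -> consensus communities + layout.  Every
    output lands under ``config.out_dir``.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "cohortnet",
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "stages": [],
        "results": {},
    }
    try:
        with _stage(manifest, "data"):
            table = _load_table(config)
            if config.synthetic:
                write_table(table, out / "cohorts.csv", out / "cohorts.schema.yaml")
            manifest["results"]["data"] = {
                "n_participants": table.n_participants,
                "n_pain": int(len(table.cohort_index("pain"))),
                "n_nopain": int(len(table.cohort_index("nopain"))),
                "n_variables": len(table.schema),
            }

        with _stage(manifest, "networks"):
            builder = NetworkBuilder(table)
            nets = {
                "general": builder.build(None),
                "pain": builder.build(table.cohort_index("pain")),
                "nopain": builder.build(table.cohort_index("nopain")),
            }
            for name, net in nets.items():
                write_graphml(net, out / f"network_{name}.graphml")
                write_edge_csv(net, out / f"network_{name}_edges.csv")
                gm = global_metrics(net)
                write_global_json(gm, out / f"global_{name}.json")
                write_nodal_csv(nodal_metrics(net), out / f"nodal_{name}.csv")
                manifest["results"].setdefault("global_metrics", {})[name] = gm.to_dict()

        with _stage(manifest, "contrasts"):
            results = group_difference_test(
                table, list(config.statistics), n_perm=config.n_perm, seed=config.seed
            )
            scalar = {
                k: v for k, v in results.items() if isinstance(v, PermutationResult)
            }
            nodal = {k: v for k, v in results.items() if k not in scalar}
            write_result_json(scalar, out / "contrasts_global.json")
            manifest["results"]["contrasts"] = {
                k: {"observed": v.observed, "p": v.p_two_tailed} for k, v in scalar.items()
            }
            if nodal:
                report = nodal_report(nodal, q=config.fdr_q)
                report.to_csv(out / "contrasts_nodal.csv", index=False)
                manifest["results"]["nodal_significant"] = {
                    stat: sorted(
                        report.loc
                        [(report.statistic == stat) & report.significant, "node"]
                    )
                    for stat in nodal
                }

        with _stage(manifest, "sample_size"):
            curve = sample_size_analysis(
                table,
                sizes=config.sample_sizes,
                n_perm=config.n_perm_sample_size,
                seed=config.seed,
            )
            curve.to_frame().to_csv(out / "sample_size_curve.csv", index=False)
            manifest["results"]["sample_size"] = {
                "sizes": list(curve.sizes),
                "threshold_size": curve.threshold_size,
            }

        with _stage(manifest, "cluster_sweep"):
            sweep = threshold_sweep(
                table,
                thresholds=config.thresholds,
                n_perm=config.n_perm,
                seed=config.seed,
                alpha=0.05,
            )
            diff = difference_matrix(nets["pain"], nets["nopain"])
            sweep.to_frame().to_csv(out / "cluster_sweep.csv", index=False)
            sweep.edge_frequency_frame().to_csv(out / "cluster_edge_frequency.csv", index=False)
            write_sweep_json(sweep, out / "cluster_sweep.json")
            mid = sweep.results[len(sweep.results) // 2]
            write_cluster_csv(mid, diff, out / "cluster_edges.csv")
            write_cluster_graphml(mid, diff, out / "cluster.graphml")
            manifest["results"]["cluster_sweep"] = {
                "n_thresholds": len(sweep.thresholds),
                "significant_thresholds": [
                    r.threshold for r in sweep.results if r.significant(sweep.alpha)
                ],
            }

        with _stage(manifest, "communities"):
            partition = consensus_louvain(
                nets["general"],
                n_runs=config.community_runs,
                resolution=config.resolution,
                tau=config.tau,
                seed=config.seed,
            )
            layout = layout_network(nets["general"], k=config.layout_k, seed=config.seed)
            write_partition_csv(partition, out / "communities.csv")
            write_layout_json(layout, out / "layout.json")
            write_annotated_graphml(nets["general"], partition, layout, out / "network_annotated.graphml")
            manifest["results"]["communities"] = {
                "n_communities": partition.n_communities,
            }
    finally:
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n"
        )
    return manifest
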