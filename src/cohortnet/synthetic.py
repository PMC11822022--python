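"""Synthetic two-cohort generator with a latent Gaussian-copula dependence model.

Registry data of the kind this package analyses (participants x mixed
binary / ordinal / continuous variables, two cohorts) cannot be shared, so
every downstream stage is exercised on simulated cohorts with *known*
association structure.  The generative model is a latent multivariate
normal: each participant draws a latent Gaussian vector with a
cohort-specific correlation matrix, discrete variables are obtained by
thresholding their latent coordinate at fixed cutpoints, continuous
variables are the latent coordinate itself.  Between-cohort differences are
planted by adding an offset ``effect_delta`` to the latent correlations of
a connected block of variable pairs in the "pain" cohort only.

The default spec is deliberately desk-scale: 30 variables (10 binary, 10
four-level ordinal, 10 continuous) in three latent blocks, cohort sizes
1,000 ("pain") and 2,500 ("nopain") preserving the roughly 1 : 2.5 ratio of
the motivating registry cohorts.
"""

from __future__ import annotations

import dataclasses
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from ._matrix import PSDRepairError, is_valid_correlation, nearest_psd_correlation

__all__ = [
    "VariableSchema",
    "SyntheticSpec",
    "CohortTable",
    "generate_cohorts",
    "plant_effect",
    "write_table",
    "read_table",
    "default_spec",
    "PAIN",
    "NOPAIN",
    "MISSING_MARKER",
]

PAIN = "pain"
NOPAIN = "nopain"
MISSING_MARKER = "NA"
COHORT_COLUMN = "cohort"

VTYPES = ("binary", "ordinal", "continuous")


@dataclass(frozen=True)
class VariableSchema:
    """Declared type of one variable.

    Parameters
    ----------
    name : str
        Column label.
    vtype : {"binary", "ordinal", "continuous"}
    cutpoints : tuple of float, optional
        Ascending latent thresholds; one for binary, ``n_levels - 1`` for
        ordinal, absent for continuous.
    """

    name: str
    vtype: str
    cutpoints: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.vtype not in VTYPES:
            raise ValueError(f"unknown vtype {self.vtype!r} for variable {self.name!r}")
        if self.vtype == "continuous":
            if self.cutpoints is not None:
                raise ValueError(f"continuous variable {self.name!r} takes no cutpoints")
            return
        cps = tuple(float(c) for c in (self.cutpoints or ()))
        if self.vtype == "binary" and len(cps) != 1:
            raise ValueError(f"binary variable {self.name!r} needs exactly 1 cutpoint")
        if self.vtype == "ordinal" and len(cps) < 1:
            raise ValueError(f"ordinal variable {self.name!r} needs >= 1 cutpoint")
        if any(b <= a for a, b in zip(cps, cps[1:])):
            raise ValueError(f"cutpoints of {self.name!r} must be strictly increasing")
        object.__setattr__(self, "cutpoints", cps)

    @property
    def n_levels(self) -> int | None:
        if self.vtype == "continuous":
            return None
        return len(self.cutpoints) + 1

    @property
    def is_discrete(self) -> bool:
        return self.vtype != "continuous"


def _block_edges(variables: Sequence[int]) -> frozenset[tuple[int, int]]:
    """All pairs among `variables` (a clique, hence connected)."""
    var = sorted(set(int(v) for v in variables))
    return frozenset(
        (a, b) for k, a in enumerate(var) for b in var[k + 1 :]
    )


def _edges_connected(edges: frozenset[tuple[int, int]]) -> bool:
    if not edges:
        return True
    nodes = sorted({v for e in edges for v in e})
    seen = {nodes[0]}
    frontier = [nodes[0]]
    adj: dict[int, list[int]] = {v: [] for v in nodes}
    for a, b in edges:
        adj[a].append(b)
        adj[b].append(a)
    while frontier:
        v = frontier.pop()
        for w in adj[v]:
            if w not in seen:
                seen.add(w)
                frontier.append(w)
    return len(seen) == len(nodes)


@dataclass(frozen=True)
class SyntheticSpec:
    """Complete description of a reproducible simulated two-cohort dataset.

    ``latent_corr`` is the shared ("nopain" and general) latent correlation
    matrix; the pain cohort's matrix is ``latent_corr`` with
    ``effect_delta`` added on every pair in ``effect_block`` (then
    PSD-repaired).  ``effect_block`` must form a connected subgraph so the
    planted difference emulates a connected cluster of differing edges.
    """

    schema: tuple[VariableSchema, ...]
    latent_corr: np.ndarray
    n_pain: int = 1000
    n_nopain: int = 2500
    effect_block: frozenset[tuple[int, int]] = frozenset()
    effect_delta: float = 0.0
    missing_rate: float = 0.0
    seed: int = 0
    repair_tolerance: float = 1e-3

    def __post_init__(self) -> None:
        object.__setattr__(self, "schema", tuple(self.schema))
        corr = np.array(self.latent_corr, dtype=float)
        corr.setflags(write=False)
        object.__setattr__(self, "latent_corr", corr)
        p = len(self.schema)
        if corr.shape != (p, p):
            raise ValueError(f"latent_corr shape {corr.shape} != ({p}, {p})")
        if not is_valid_correlation(corr):
            raise ValueError("latent_corr is not a valid correlation matrix")
        if self.n_pain < 1 or self.n_nopain < 1:
            raise ValueError("cohort sizes must be positive")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        block = frozenset(
            (min(a, b), max(a, b)) for a, b in self.effect_block
        )
        if any(a == b or a < 0 or b >= p for a, b in block):
            raise ValueError("effect_block contains an invalid variable pair")
        if not _edges_connected(block):
            raise ValueError("effect_block edges must form a connected subgraph")
        object.__setattr__(self, "effect_block", block)

    @property
    def names(self) -> list[str]:
        return [v.name for v in self.schema]

    def replace(self, **kwargs) -> "SyntheticSpec":
        return dataclasses.replace(self, **kwargs)


def plant_effect(spec: SyntheticSpec) -> np.ndarray:
    """Latent correlation matrix of the pain cohort.

    Adds ``effect_delta`` (symmetrised) on the planted block of
    ``spec.latent_corr`` and PSD-repairs the result.  Raises
    :class:`PSDRepairError` if the repair moves any entry *outside* the
    planted block by more than ``spec.repair_tolerance`` — the planted
    difference must stay where it was planted.
    """
    corr = np.array(spec.latent_corr, dtype=float)
    if not spec.effect_block or spec.effect_delta == 0.0:
        return corr
    target = corr.copy()
    for a, b in spec.effect_block:
        target[a, b] += spec.effect_delta
        target[b, a] = target[a, b]
    np.clip(target, -1.0, 1.0, out=target)
    repaired = nearest_psd_correlation(target)
    off_block = np.ones_like(corr, dtype=bool)
    np.fill_diagonal(off_block, False)
    for a, b in spec.effect_block:
        off_block[a, b] = off_block[b, a] = False
    drift = np.abs(repaired - corr)[off_block]
    if drift.size and drift.max() > spec.repair_tolerance:
        raise PSDRepairError(
            "PSD repair of the planted block perturbed non-block entries by "
            f"{drift.max():.2e} (> {spec.repair_tolerance:g}); the requested "
            "effect is incompatible with the base correlation structure"
        )
    return repaired


@dataclass
class CohortTable:
    """Participants x variables values with cohort labels and a schema.

    ``data`` holds float values (binary in {0, 1}, ordinal in
    {0..n_levels-1}, continuous unrestricted) with NaN as the missing
    marker.  ``cohort`` is a per-participant label in {"pain", "nopain"}.
    """

    data: pd.DataFrame
    cohort: pd.Series
    schema: tuple[VariableSchema, ...]

    def __post_init__(self) -> None:
        self.schema = tuple(self.schema)
        names = [v.name for v in self.schema]
        missing = [n for n in names if n not in self.data.columns]
        extra = [c for c in self.data.columns if c not in names]
        if missing or extra:
            raise ValueError(
                f"schema/column mismatch: missing columns {missing}, unmatched columns {extra}"
            )
        self.data = self.data[names].astype(float)
        self.cohort = pd.Series(self.cohort, index=self.data.index, dtype=object)
        bad = set(self.cohort.unique()) - {PAIN, NOPAIN}
        if bad:
            raise ValueError(f"unknown cohort labels {sorted(bad)}")
        for v in self.schema:
            if not v.is_discrete:
                continue
            col = self.data[v.name].to_numpy()
            observed = col[np.isfinite(col)]
            allowed = np.arange(v.n_levels)
            if observed.size and not np.isin(observed, allowed).all():
                raise ValueError(
                    f"column {v.name!r} ({v.vtype}) holds values outside 0..{v.n_levels - 1}"
                )

    @property
    def n_participants(self) -> int:
        return len(self.data)

    @property
    def names(self) -> list[str]:
        return [v.name for v in self.schema]

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def labels(self) -> np.ndarray:
        return self.cohort.to_numpy(dtype=object)

    def cohort_index(self, label: str) -> np.ndarray:
        """Positional indices of the participants in `label`."""
        return np.flatnonzero(self.labels() == label)

    def subset(self, rows: np.ndarray) -> "CohortTable":
        """Positional row subset as a new table."""
        return CohortTable(
            data=self.data.iloc[rows].reset_index(drop=True),
            cohort=self.cohort.iloc[rows].reset_index(drop=True),
            schema=self.schema,
        )

    def equals(self, other: "CohortTable") -> bool:
        return (
            self.schema == other.schema
            and self.data.equals(other.data)
            and self.cohort.reset_index(drop=True).equals(
                other.cohort.reset_index(drop=True)
            )
        )


def _draw_cohort(
    rng: np.random.Generator,
    corr: np.ndarray,
    n: int,
    schema: Sequence[VariableSchema],
) -> np.ndarray:
    # eigh factor instead of cholesky: repaired matrices may be exactly singular
    eigvals, eigvecs = np.linalg.eigh(corr)
    factor = eigvecs * np.sqrt(np.clip(eigvals, 0.0, None))
    latent = rng.standard_normal((n, corr.shape[0])) @ factor.T
    out = latent
    for j, v in enumerate(schema):
        if v.is_discrete:
            out[:, j] = np.searchsorted(np.asarray(v.cutpoints), latent[:, j], side="left")
    return out


def generate_cohorts(spec: SyntheticSpec) -> CohortTable:
    """Draw the two cohorts described by `spec` (reproducible per seed)."""
    rng = np.random.default_rng(spec.seed)
    pain_corr = plant_effect(spec)
    pain = _draw_cohort(rng, pain_corr, spec.n_pain, spec.schema)
    nopain = _draw_cohort(rng, spec.latent_corr, spec.n_nopain, spec.schema)
    values = np.vstack([pain, nopain])
    if spec.missing_rate > 0:
        mask = rng.random(values.shape) < spec.missing_rate
        values[mask] = np.nan
    data = pd.DataFrame(values, columns=spec.names)
    cohort = pd.Series([PAIN] * spec.n_pain + [NOPAIN] * spec.n_nopain, dtype=object)
    return CohortTable(data=data, cohort=cohort, schema=spec.schema)


# ---------------------------------------------------------------------------
# Default stated world
# ---------------------------------------------------------------------------

#: latent correlation inside / between the three variable blocks
_WITHIN_BLOCK_RHO = 0.35
_BETWEEN_BLOCK_RHO = 0.05

#: binary prevalences cycle over these values (common, moderate, rare traits)
_BINARY_PREVALENCES = (0.5, 0.3, 0.15)

#: cumulative probabilities of the four ordinal levels
_ORDINAL_CUMULATIVE = (0.4, 0.7, 0.9)


def default_schema(n_per_type: int = 10) -> tuple[VariableSchema, ...]:
    """10 binary + 10 four-level ordinal + 10 continuous variables."""
    schema: list[VariableSchema] = []
    for i in range(n_per_type):
        prev = _BINARY_PREVALENCES[i % len(_BINARY_PREVALENCES)]
        schema.append(
            VariableSchema(f"bin_{i:02d}", "binary", (float(stats.norm.ppf(1 - prev)),))
        )
    ord_cuts = tuple(float(stats.norm.ppf(q)) for q in _ORDINAL_CUMULATIVE)
    for i in range(n_per_type):
        schema.append(VariableSchema(f"ord_{i:02d}", "ordinal", ord_cuts))
    for i in range(n_per_type):
        schema.append(VariableSchema(f"cont_{i:02d}", "continuous"))
    return tuple(schema)


def block_latent_corr(
    n_vars: int = 30,
    n_blocks: int = 3,
    within: float = _WITHIN_BLOCK_RHO,
    between: float = _BETWEEN_BLOCK_RHO,
) -> np.ndarray:
    """Round-robin block structure: variable i belongs to block ``i % n_blocks``.

    Round-robin (rather than contiguous) assignment mixes binary, ordinal
    and continuous variables within every latent block, so planted
    communities are not confounded with estimator type.
    """
    blocks = np.arange(n_vars) % n_blocks
    corr = np.where(blocks[:, None] == blocks[None, :], within, between)
    np.fill_diagonal(corr, 1.0)
    return corr


def default_effect_variables() -> tuple[int, ...]:
    """Planted-profile variables: six ordinal/continuous members of block 0.

    The motivating difference cluster is a psychosocial profile of mostly
    scale-type variables; restricting the planted block to ordinal and
    continuous members keeps the planted latent effect visible on the
    observed scale (binary margins attenuate latent correlations most).
    """
    return (12, 15, 18, 21, 24, 27)


def default_spec(
    n_pain: int = 1000,
    n_nopain: int = 2500,
    effect_delta: float = 0.0,
    seed: int = 0,
    missing_rate: float = 0.0,
) -> SyntheticSpec:
    """The package's stated synthetic world (see docs/methods.md)."""
    schema = default_schema()
    corr = block_latent_corr(len(schema))
    block = _block_edges(default_effect_variables()) if effect_delta else frozenset()
    return SyntheticSpec(
        schema=schema,
        latent_corr=corr,
        n_pain=n_pain,
        n_nopain=n_nopain,
        effect_block=block,
        effect_delta=effect_delta,
        missing_rate=missing_rate,
        seed=seed,
    )


def effect_block_from_variables(variables: Sequence[int]) -> frozenset[tuple[int, int]]:
    """Clique of pairs over `variables` (the planted connected block)."""
    return _block_edges(variables)


# ---------------------------------------------------------------------------
# IO: CSV table + YAML schema
# ---------------------------------------------------------------------------


def schema_to_records(schema: Sequence[VariableSchema]) -> list[dict]:
    records = []
    for v in schema:
        rec: dict = {"name": v.name, "vtype": v.vtype}
        if v.is_discrete:
            rec["n_levels"] = v.n_levels
            rec["cutpoints"] = [float(c) for c in v.cutpoints]
        records.append(rec)
    return records


def schema_from_records(records: Sequence[dict]) -> tuple[VariableSchema, ...]:
    schema = []
    for rec in records:
        cps = rec.get("cutpoints")
        v = VariableSchema(
            name=str(rec["name"]),
            vtype=str(rec["vtype"]),
            cutpoints=tuple(cps) if cps is not None else None,
        )
        if v.is_discrete and "n_levels" in rec and int(rec["n_levels"]) != v.n_levels:
            raise ValueError(
                f"variable {v.name!r}: n_levels {rec['n_levels']} inconsistent with "
                f"{len(v.cutpoints)} cutpoints"
            )
        schema.append(v)
    return tuple(schema)


def write_schema(schema: Sequence[VariableSchema], path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(schema_to_records(schema), sort_keys=False))


def read_schema(path: str | Path) -> tuple[VariableSchema, ...]:
    return schema_from_records(yaml.safe_load(Path(path).read_text()))


def write_table(table: CohortTable, path: str | Path, schema_path: str | Path | None = None) -> None:
    """Write the table as CSV (missing marker ``NA``) and schema as YAML.

    With `schema_path` omitted the schema lands next to the table as
    ``<stem>.schema.yaml``.
    """
    path = Path(path)
    out = table.data.copy()
    # discrete columns as integers so the round trip is exact
    for v in table.schema:
        if v.is_discrete:
            out[v.name] = out[v.name].astype("Int64")
    out.insert(0, COHORT_COLUMN, table.cohort.to_numpy())
    # %.17g round-trips float64 exactly
    out.to_csv(path, index=False, na_rep=MISSING_MARKER, float_format="%.17g")
    if schema_path is None:
        schema_path = path.with_suffix(".schema.yaml")
    write_schema(table.schema, schema_path)


def read_table(path: str | Path, schema_path: str | Path | None = None) -> CohortTable:
    path = Path(path)
    if schema_path is None:
        schema_path = path.with_suffix(".schema.yaml")
    schema = read_schema(schema_path)
    df = pd.read_csv(
        path,
        na_values=[MISSING_MARKER],
        keep_default_na=False,
        float_precision="round_trip",
    )
    if COHORT_COLUMN not in df.columns:
        raise ValueError(f"table {path} lacks the {COHORT_COLUMN!r} column")
    cohort = df[COHORT_COLUMN]
    data = df.drop(columns=[COHORT_COLUMN])
    return CohortTable(data=data, cohort=cohort, schema=schema)


def table_to_csv_text(table: CohortTable) -> str:
    buf = io.StringIO()
    out = table.data.copy()
    for v in table.schema:
        if v.is_discrete:
            out[v.name] = out[v.name].astype("Int64")
    out.insert(0, COHORT_COLUMN, table.cohort.to_numpy())
    out.to_csv(buf, index=False, na_rep=MISSING_MARKER, float_format="%.17g")
    return buf.getvalue()
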