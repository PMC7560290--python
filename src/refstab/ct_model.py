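"""Replicate-level Ct data model and I/O.

qPCR quantification cycles (Ct) are the universal currency of the package:
every stability algorithm, the pairwise-variation analysis and the ddCt
quantification start from a table of (sample, gene, replicate, Ct)
observations.  This module validates those tables, collapses replicates
into one value per (gene, sample) cell, and converts Ct into the relative
quantities (q = E^(Ctmin - Ct)) that geNorm-style analyses operate on.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "CtRecord",
    "CtTable",
    "SampleSet",
    "CtMatrix",
    "RelativeQuantities",
    "CtValidationError",
    "read_ct_table",
    "write_ct_table",
    "read_sample_sets",
    "aggregate_replicates",
    "to_relative_quantities",
]

#: Default plausible Ct window.  The thermal program runs a few dozen cycles;
#: values at or below 0, or far beyond the cycle count, indicate instrument
#: or transcription errors.  Configurable at the call sites that validate.
CT_MIN_EXCLUSIVE = 0.0
CT_MAX_INCLUSIVE = 45.0


class CtValidationError(ValueError):
    """Raised when a Ct table violates a structural invariant."""


@dataclass(frozen=True)
class CtRecord:
    sample_id: str
    gene_id: str
    replicate_id: str
    ct: float


@dataclass
class CtTable:
    """Validated collection of replicate-level Ct observations.

    Invariants: (sample, gene, replicate) triples are unique, Ct values are
    finite, and out-of-range values (outside ``(0, 45]`` by default) either
    raise (strict) or are flagged via :attr:`warnings_` (permissive).
    """

    records: list[CtRecord]
    warnings_: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.records:
            raise CtValidationError("Ct table is empty")
        seen: set[tuple[str, str, str]] = set()
        for r in self.records:
            key = (r.sample_id, r.gene_id, r.replicate_id)
            if key in seen:
                raise CtValidationError(
                    f"duplicate (sample, gene, replicate) triple: {key}"
                )
            seen.add(key)
            if not np.isfinite(r.ct):
                raise CtValidationError(f"non-finite Ct for {key}: {r.ct!r}")

    @property
    def sample_ids(self) -> list[str]:
        out: list[str] = []
        for r in self.records:
            if r.sample_id not in out:
                out.append(r.sample_id)
        return out

    @property
    def gene_ids(self) -> list[str]:
        out: list[str] = []
        for r in self.records:
            if r.gene_id not in out:
                out.append(r.gene_id)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.sample_id, r.gene_id, r.replicate_id, r.ct) for r in self.records],
            columns=["sample", "gene", "replicate", "ct"],
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, *, strict: bool = True) -> "CtTable":
        required = {"sample", "gene", "replicate", "ct"}
        missing = required - set(df.columns)
        if missing:
            raise CtValidationError(f"missing required columns: {sorted(missing)}")
        ct = pd.to_numeric(df["ct"], errors="coerce")
        bad = df[ct.isna()]
        if len(bad):
            raise CtValidationError(
                f"non-numeric ct in rows: {bad.index.tolist()[:10]}"
            )
        warns: list[str] = []
        out_of_range = (ct <= CT_MIN_EXCLUSIVE) | (ct > CT_MAX_INCLUSIVE)
        if out_of_range.any():
            rows = df[out_of_range]
            msg = (
                "Ct outside ({}, {}] for triples: {}".format(
                    CT_MIN_EXCLUSIVE,
                    CT_MAX_INCLUSIVE,
                    [
                        (r["sample"], r["gene"], r["replicate"], float(c))
                        for (_, r), c in zip(rows.iterrows(), ct[out_of_range])
                    ][:10],
                )
            )
            if strict:
                raise CtValidationError(msg)
            warns.append(msg)
            warnings.warn(msg, stacklevel=2)
        records = [
            CtRecord(str(s), str(g), str(r), float(c))
            for s, g, r, c in zip(df["sample"], df["gene"], df["replicate"], ct)
        ]
        return cls(records, warnings_=warns)


@dataclass
class SampleSet:
    """Named ordered subset of samples, optionally partitioned into groups.

    Mirrors the experimental-set notion of a stability study (for example
    "all samples", "seedlings", "seeds", "endosperms"), each an ordered list
    of sample ids with optional group labels such as tissue or stage.
    """

    name: str
    sample_ids: list[str]
    groups: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if not self.sample_ids:
            raise CtValidationError(f"sample set {self.name!r} is empty")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise CtValidationError(f"sample set {self.name!r} has duplicate ids")
        if self.groups is not None:
            missing = [s for s in self.sample_ids if s not in self.groups]
            if missing:
                raise CtValidationError(
                    f"sample set {self.name!r}: samples without group label: {missing}"
                )
            if len(set(self.groups[s] for s in self.sample_ids)) < 2:
                raise CtValidationError(
                    f"sample set {self.name!r}: grouping requires >=2 distinct groups"
                )

    def validate_against(self, samples: Iterable[str]) -> None:
        pool = set(samples)
        absent = [s for s in self.sample_ids if s not in pool]
        if absent:
            raise CtValidationError(
                f"sample set {self.name!r}: samples not in table: {absent}"
            )

    def group_of(self, sample_id: str) -> str | None:
        return None if self.groups is None else self.groups[sample_id]

    @classmethod
    def whole_table(cls, table_or_matrix, name: str = "all") -> "SampleSet":
        ids = (
            list(table_or_matrix.samples)
            if hasattr(table_or_matrix, "samples")
            else table_or_matrix.sample_ids
        )
        return cls(name=name, sample_ids=ids)


@dataclass
class CtMatrix:
    """Genes x samples grid of aggregated Ct values.

    ``replicate_counts`` retains how many replicate observations entered
    each cell; NaN cells only appear under a permissive missing policy.
    """

    genes: list[str]
    samples: list[str]
    ct: np.ndarray
    replicate_counts: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.ct = np.asarray(self.ct, dtype=float)
        if self.ct.shape != (len(self.genes), len(self.samples)):
            raise CtValidationError(
                f"ct grid shape {self.ct.shape} != "
                f"({len(self.genes)}, {len(self.samples)})"
            )

    def subset(self, sample_set: SampleSet) -> "CtMatrix":
        sample_set.validate_against(self.samples)
        idx = [self.samples.index(s) for s in sample_set.sample_ids]
        counts = (
            None
            if self.replicate_counts is None
            else self.replicate_counts[:, idx]
        )
        return CtMatrix(list(self.genes), list(sample_set.sample_ids),
                        self.ct[:, idx], counts)

    def require_complete(self) -> None:
        if np.isnan(self.ct).any():
            gi, si = np.nonzero(np.isnan(self.ct))
            pairs = [(self.genes[g], self.samples[s]) for g, s in zip(gi, si)]
            raise CtValidationError(f"missing Ct cells: {pairs[:10]}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.ct, index=self.genes, columns=self.samples)


@dataclass
class RelativeQuantities:
    """Relative expression quantities q = E^(Ctmin - Ct), per gene scaled so
    that the best-expressed sample has q = 1."""

    genes: list[str]
    samples: list[str]
    q: np.ndarray
    efficiency_per_gene: dict[str, float]

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        if np.any(self.q <= 0) or np.any(self.q > 1 + 1e-12):
            raise CtValidationError("relative quantities must lie in (0, 1]")


# ---------------------------------------------------------------------------
# I/O


def read_ct_table(
    path: str | Path,
    dialect: Literal["long", "wide"] = "long",
    *,
    strict: bool = True,
) -> CtTable:
    """Read a Ct table from CSV/TSV.

    Long dialect: columns ``sample, gene, replicate, ct``.  Wide dialect:
    one row per (sample, replicate) with columns ``sample, replicate`` and
    one column per gene.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    if dialect == "wide":
        id_cols = [c for c in ("sample", "replicate") if c in df.columns]
        if "sample" not in id_cols:
            raise CtValidationError("wide dialect requires a 'sample' column")
        if "replicate" not in df.columns:
            df["replicate"] = "r1"
            id_cols = ["sample", "replicate"]
        gene_cols = [c for c in df.columns if c not in id_cols]
        if not gene_cols:
            raise CtValidationError("wide dialect has no gene columns")
        df = df.melt(
            id_vars=id_cols, value_vars=gene_cols,
            var_name="gene", value_name="ct",
        )
    elif dialect != "long":
        raise ValueError(f"unknown dialect {dialect!r}")
    return CtTable.from_frame(df, strict=strict)


def write_ct_table(table: CtTable, path: str | Path) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    table.to_frame().to_csv(path, sep=sep, index=False)


def read_sample_sets(path: str | Path) -> list[SampleSet]:
    """Read sample-set definitions from a YAML/JSON config.

    Schema: a list (or a ``sets:`` list) of mappings with ``name``,
    ``samples`` (ordered) and optional ``groups`` (sample -> label).
    """
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    if isinstance(data, dict) and "sets" in data:
        data = data["sets"]
    if isinstance(data, dict):
        data = [data]
    out = []
    for entry in data:
        out.append(
            SampleSet(
                name=str(entry["name"]),
                sample_ids=[str(s) for s in entry["samples"]],
                groups={str(k): str(v) for k, v in entry["groups"].items()}
                if entry.get("groups")
                else None,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Transforms


def aggregate_replicates(
    table: CtTable,
    policy: Literal["mean", "median"] = "mean",
    *,
    missing: Literal["error", "nan"] = "error",
) -> CtMatrix:
    """Collapse replicate observations into one Ct per (gene, sample) cell."""
    if policy not in ("mean", "median"):
        raise ValueError(f"unknown aggregation policy {policy!r}")
    df = table.to_frame()
    genes = table.gene_ids
    samples = table.sample_ids
    agg = df.groupby(["gene", "sample"], sort=False)["ct"].agg([policy, "size"])
    grid = np.full((len(genes), len(samples)), np.nan)
    counts = np.zeros((len(genes), len(samples)), dtype=int)
    gidx = {g: i for i, g in enumerate(genes)}
    sidx = {s: j for j, s in enumerate(samples)}
    for (g, s), row in agg.iterrows():
        grid[gidx[g], sidx[s]] = row[policy]
        counts[gidx[g], sidx[s]] = int(row["size"])
    if np.isnan(grid).any():
        if missing == "error":
            gi, si = np.nonzero(np.isnan(grid))
            pairs = [(genes[g], samples[s]) for g, s in zip(gi, si)]
            raise CtValidationError(f"missing (gene, sample) pairs: {pairs[:10]}")
    return CtMatrix(genes, samples, grid, counts)


def collapse_biological_replicates(
    table: CtTable, sep: str = ".", policy: Literal["mean", "median"] = "mean"
) -> CtMatrix:
    """One-step "average everything per condition" aggregation.

    Sample ids of the form ``condition<sep>rep`` are pooled per condition.
    Not the default route: averaging biological replicates away removes the
    biological variance the stability statistics are meant to see.
    """
    df = table.to_frame()
    df["sample"] = [s.rsplit(sep, 1)[0] for s in df["sample"]]
    df["replicate"] = [
        f"{s}{sep}{r}" for s, r in zip(
            (r.sample_id for r in table.records),
            (r.replicate_id for r in table.records),
        )
    ]
    return aggregate_replicates(CtTable.from_frame(df, strict=False), policy)


def to_relative_quantities(
    m: CtMatrix,
    efficiency_per_gene: Mapping[str, float] | float | None = None,
    subset: SampleSet | None = None,
) -> RelativeQuantities:
    """Ct -> relative quantity transform: q = E^(Ctmin - Ct) per gene.

    ``E`` is the fold-amplification per cycle (2.0 = perfect doubling); the
    within-subset minimum Ct anchors each gene's maximum q at exactly 1.
    """
    if subset is not None:
        m = m.subset(subset)
        if not m.samples:
            raise CtValidationError("empty sample subset")
    m.require_complete()
    if efficiency_per_gene is None:
        eff = {g: 2.0 for g in m.genes}
    elif isinstance(efficiency_per_gene, (int, float)):
        eff = {g: float(efficiency_per_gene) for g in m.genes}
    else:
        eff = {g: float(efficiency_per_gene.get(g, 2.0)) for g in m.genes}
    for g, e in eff.items():
        if not (1.6 <= e <= 2.2):
            warnings.warn(
                f"per-cycle fold amplification {e} for {g} outside [1.6, 2.2]",
                stacklevel=2,
            )
        if e <= 1.0:
            raise CtValidationError(f"fold amplification must exceed 1 ({g}: {e})")
    evec = np.array([eff[g] for g in m.genes])[:, None]
    ct_min = np.nanmin(m.ct, axis=1, keepdims=True)
    q = evec ** (ct_min - m.ct)
    return RelativeQuantities(list(m.genes), list(m.samples), q, eff)
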