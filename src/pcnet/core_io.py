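"""Containers and file I/O for expression matrices, covariates, gene sets
and networks.

Expression matrices are stored genes x samples (the orientation every other
module consumes). Delimited text dialect: tab for ``.tsv``/``.txt``, comma
for ``.csv``; UTF-8 only. Gene identifiers are matched by exact,
case-sensitive string equality throughout — no symbol aliasing.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

Pair = tuple[str, str]


def canonical_pair(a: str, b: str) -> Pair:
    """Return the unordered gene pair (a, b) in canonical (sorted) order."""
    if a == b:
        raise ValueError(f"self-pair not allowed: {a!r}")
    return (a, b) if a < b else (b, a)


def _sep_for(path: str | Path) -> str:
    suffix = Path(path).suffix.lower()
    if suffix == ".csv":
        return ","
    if suffix in (".tsv", ".txt", ""):
        return "\t"
    raise ValueError(f"unsupported extension {suffix!r} (use .tsv, .txt or .csv)")


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: dict[str, int] = {}
    dups = []
    for i in ids:
        seen[i] = seen.get(i, 0) + 1
        if seen[i] == 2:
            dups.append(i)
    if dups:
        raise ValueError(f"duplicate {what}: {', '.join(map(repr, dups))}")


@dataclass(frozen=True)
class ExpressionMatrix:
    """Real-valued genes x samples matrix with identifiers.

    Values are assumed already normalized (e.g. log-scale quantifications);
    no entry may be missing or non-finite.
    """

    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "gene_ids", tuple(self.gene_ids))
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        if values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        if values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"shape {values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        _check_unique(self.gene_ids, "gene ids")
        _check_unique(self.sample_ids, "sample ids")
        if not np.isfinite(values).all():
            bad = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                "non-finite value at gene "
                f"{self.gene_ids[bad[0]]!r}, sample {self.sample_ids[bad[1]]!r}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def with_values(self, values: np.ndarray) -> "ExpressionMatrix":
        """Same ids, new values (must keep the shape)."""
        return ExpressionMatrix(self.gene_ids, self.sample_ids, values)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.gene_ids), columns=list(self.sample_ids)
        )


@dataclass(frozen=True)
class CovariateTable:
    """Per-sample numeric covariates (samples x covariates)."""

    sample_ids: tuple[str, ...]
    covariate_names: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        object.__setattr__(self, "covariate_names", tuple(self.covariate_names))
        if values.shape != (len(self.sample_ids), len(self.covariate_names)):
            raise ValueError("values shape does not match ids")
        _check_unique(self.sample_ids, "sample ids")
        _check_unique(self.covariate_names, "covariate names")
        if not np.isfinite(values).all():
            raise ValueError("covariate table contains missing/non-finite values")

    @property
    def constant_covariates(self) -> tuple[str, ...]:
        """Names of covariates with zero variance (useless as regressors)."""
        flat = np.ptp(self.values, axis=0) == 0
        return tuple(n for n, c in zip(self.covariate_names, flat) if c)

    def aligned_to(self, sample_ids: Sequence[str]) -> np.ndarray:
        """Covariate rows reordered to the given sample ids."""
        index = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in index]
        if missing:
            raise ValueError(f"samples missing from covariate table: {missing}")
        return self.values[[index[s] for s in sample_ids]]


@dataclass(frozen=True)
class GeneSetCollection:
    """Named pathway gene sets with a database label per pathway."""

    sets: Mapping[str, frozenset[str]]
    source_db: Mapping[str, str]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "sets", {k: frozenset(v) for k, v in self.sets.items()}
        )
        object.__setattr__(self, "source_db", dict(self.source_db))
        if set(self.sets) != set(self.source_db):
            raise ValueError("sets and source_db must have identical pathway names")

    @staticmethod
    def merge(collections: Iterable["GeneSetCollection"]) -> "GeneSetCollection":
        """Combine collections (e.g. one per GMT file / database).

        Pathway names colliding across databases are disambiguated with a
        ``db/`` prefix.
        """
        sets: dict[str, frozenset[str]] = {}
        dbs: dict[str, str] = {}
        for coll in collections:
            for name, genes in coll.sets.items():
                key = name
                if key in sets:
                    key = f"{coll.source_db[name]}/{name}"
                if key in sets:
                    raise ValueError(f"duplicate pathway name {key!r} after merge")
                sets[key] = genes
                dbs[key] = coll.source_db[name]
        return GeneSetCollection(sets, dbs)


@dataclass(frozen=True)
class GroundTruthEdges:
    """Canonical unordered gene pairs assumed functionally related, with the
    number of distinct source databases supporting each pair."""

    pairs: frozenset[Pair]
    db_count: Mapping[Pair, int]

    def __post_init__(self) -> None:
        pairs = frozenset(canonical_pair(*p) for p in self.pairs)
        object.__setattr__(self, "pairs", pairs)
        db_count = {canonical_pair(*k): int(v) for k, v in self.db_count.items()}
        object.__setattr__(self, "db_count", db_count)
        if set(db_count) != set(pairs):
            raise ValueError("db_count keys must equal pairs")
        if any(v < 1 for v in db_count.values()):
            raise ValueError("db_count must be >= 1 for every stored pair")

    def restricted_to(self, universe: Iterable[str]) -> "GroundTruthEdges":
        uni = set(universe)
        keep = {p for p in self.pairs if p[0] in uni and p[1] in uni}
        return GroundTruthEdges(
            frozenset(keep), {p: self.db_count[p] for p in keep}
        )


@dataclass(frozen=True)
class NetworkGraph:
    """Undirected network: unordered gene pairs over a declared universe."""

    gene_universe: frozenset[str]
    edges: frozenset[Pair]
    weights: Mapping[Pair, float] | None = field(default=None)

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene_universe", frozenset(self.gene_universe))
        edges = frozenset(canonical_pair(*e) for e in self.edges)
        object.__setattr__(self, "edges", edges)
        for a, b in edges:
            if a not in self.gene_universe or b not in self.gene_universe:
                raise ValueError(f"edge ({a!r}, {b!r}) outside gene universe")
        if self.weights is not None:
            weights = {canonical_pair(*k): float(v) for k, v in self.weights.items()}
            object.__setattr__(self, "weights", weights)
            if set(weights) != set(edges):
                raise ValueError("weights keys must equal the edge set")

    @property
    def n_edges(self) -> int:
        return len(self.edges)


# ---------------------------------------------------------------------------
# readers / writers


def read_expression(
    path: str | Path, orientation: str = "genes_in_rows"
) -> ExpressionMatrix:
    """Read a delimited expression table (header row + one id column).

    ``orientation="samples_in_rows"`` transposes the parsed table so the
    result is always genes x samples.
    """
    if orientation not in ("genes_in_rows", "samples_in_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    raw = pd.read_csv(
        path, sep=_sep_for(path), index_col=0, dtype=str, keep_default_na=False
    )
    raw.index = raw.index.astype(str)
    if orientation == "samples_in_rows":
        raw = raw.T
    _check_unique(list(raw.index), "gene ids")
    _check_unique(list(raw.columns), "sample ids")
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = np.argwhere(numeric.isna().to_numpy())
    if bad.size:
        i, j = bad[0]
        cell = raw.iat[i, j]
        kind = "missing" if cell.strip() in ("", "NA", "NaN", "nan", "null") else (
            f"non-numeric ({cell!r})"
        )
        raise ValueError(
            f"{kind} value at gene {raw.index[i]!r}, sample {raw.columns[j]!r}"
        )
    return ExpressionMatrix(
        tuple(raw.index), tuple(map(str, raw.columns)), numeric.to_numpy(float)
    )


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    expr.to_dataframe().to_csv(path, sep=_sep_for(path), index_label="gene_id")


def select_most_variable(expr: ExpressionMatrix, k: int) -> ExpressionMatrix:
    """The k genes with largest sample variance, in decreasing-variance order.

    Variance is the unbiased (n-1 denominator) estimator; the choice only
    rescales every gene's score so the ranking is estimator-invariant.
    Ties are broken by input gene order (stable sort).
    """
    if not 1 <= k <= expr.n_genes:
        raise ValueError(f"k={k} out of range [1, {expr.n_genes}]")
    variances = expr.values.var(axis=1, ddof=1)
    order = np.argsort(-variances, kind="stable")[:k]
    return ExpressionMatrix(
        tuple(expr.gene_ids[i] for i in order),
        expr.sample_ids,
        expr.values[order],
    )


def read_gmt(path: str | Path, db_label: str | None = None) -> GeneSetCollection:
    """Parse a GMT file (name TAB description TAB gene TAB gene ...).

    One file is treated as one database; ``db_label`` defaults to the file
    stem. Duplicate genes within a set are deduplicated (set semantics);
    duplicate pathway names are an error.
    """
    label = db_label if db_label is not None else Path(path).stem
    sets: dict[str, frozenset[str]] = {}
    dbs: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: expected >= 3 tab-separated fields"
                )
            name = fields[0]
            if name in sets:
                raise ValueError(f"{path}: line {lineno}: duplicate pathway {name!r}")
            genes = frozenset(g for g in fields[2:] if g)
            sets[name] = genes
            dbs[name] = label
    return GeneSetCollection(sets, dbs)


def pathway_pairs(
    gsc: GeneSetCollection, universe: Iterable[str]
) -> GroundTruthEdges:
    """Ground-truth pairs: genes sharing >= 1 pathway, restricted to universe.

    ``db_count`` per pair is the number of distinct source databases with at
    least one pathway containing both genes.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("universe must be non-empty")
    pair_dbs: dict[Pair, set[str]] = {}
    for name, genes in gsc.sets.items():
        members = sorted(genes & uni)
        db = gsc.source_db[name]
        for a, b in itertools.combinations(members, 2):
            pair_dbs.setdefault((a, b), set()).add(db)
    return GroundTruthEdges(
        frozenset(pair_dbs), {p: len(d) for p, d in pair_dbs.items()}
    )


def write_edges(net: NetworkGraph, path: str | Path) -> None:
    """Write a 3-column edge list (gene1, gene2, weight; weight may be empty)."""
    sep = _sep_for(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(sep.join(("gene1", "gene2", "weight")) + "\n")
        for a, b in sorted(net.edges):
            w = "" if net.weights is None else repr(net.weights[(a, b)])
            fh.write(sep.join((a, b, w)) + "\n")


def read_edges(path: str | Path, universe: Iterable[str]) -> NetworkGraph:
    """Read an edge list written by :func:`write_edges`.

    Pairs listed in either order collapse to one canonical edge; endpoints
    outside the universe are an error.
    """
    uni = frozenset(universe)
    table = pd.read_csv(path, sep=_sep_for(path), dtype={"gene1": str, "gene2": str})
    edges: set[Pair] = set()
    weights: dict[Pair, float] = {}
    any_weight = False
    for row in table.itertuples(index=False):
        a, b = str(row.gene1), str(row.gene2)
        if a not in uni or b not in uni:
            raise ValueError(f"edge endpoint outside universe: ({a!r}, {b!r})")
        pair = canonical_pair(a, b)
        edges.add(pair)
        if not pd.isna(row.weight):
            any_weight = True
            weights[pair] = float(row.weight)
    return NetworkGraph(uni, frozenset(edges), weights if any_weight else None)


def read_universe(path: str | Path) -> frozenset[str]:
    """One gene id per line."""
    with open(path, encoding="utf-8") as fh:
        return frozenset(line.strip() for line in fh if line.strip())


def write_universe(universe: Iterable[str], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for g in sorted(universe):
            fh.write(g + "\n")


def read_covariates(path: str | Path) -> CovariateTable:
    """TSV/CSV with first column sample id, remaining columns numeric."""
    table = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    table.index = table.index.astype(str)
    values = table.apply(pd.to_numeric, errors="coerce")
    if values.isna().to_numpy().any():
        i, j = np.argwhere(values.isna().to_numpy())[0]
        raise ValueError(
            f"missing/non-numeric covariate value at sample {table.index[i]!r}, "
            f"covariate {table.columns[j]!r}"
        )
    return CovariateTable(
        tuple(table.index), tuple(map(str, table.columns)), values.to_numpy(float)
    )
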