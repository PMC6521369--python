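"""Co-expression network reconstruction.

Two routes, matching common practice:

* **Graphical lasso** — L1-penalized maximum-likelihood estimation of the
  precision matrix of the gene-gene *correlation* matrix (so the penalty
  ``lam`` is scale-free), swept over a decreasing penalty path. The penalty
  applies to off-diagonal entries only; an edge is called where the
  estimated partial-correlation structure is numerically nonzero
  (|theta_ij| > edge_tolerance).

* **Signed weighted co-expression (WGCNA-style)** — signed soft-threshold
  adjacency a_ij = ((1 + cor_ij)/2)^beta, topological overlap similarity,
  average-linkage hierarchical clustering of 1 - TOM, a static cut of the
  dendrogram at each requested height, and modules interpreted as fully
  connected subgraphs (cliques). Genes in clusters smaller than
  ``min_module_size`` stay unassigned (the conventional "grey" module).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.covariance import graphical_lasso as _sk_graphical_lasso
from sklearn.exceptions import ConvergenceWarning

from pcnet.core_io import ExpressionMatrix, NetworkGraph, canonical_pair

UNASSIGNED = "grey"


@dataclass(frozen=True)
class GlassoConfig:
    """Penalty path and solver controls for the graphical lasso.

    ``convergence_tol`` is the duality-gap stopping criterion, which sums
    over all matrix entries and therefore scales with the gene count; the
    default (1e-2) is tight for hundreds of genes. Tests on toy instances
    pass a much smaller value. The default path stays above the region
    where heavily confounded correlation matrices make the coordinate-
    descent solver numerically singular.
    """

    lambdas: tuple[float, ...] = (0.7, 0.6, 0.5)
    edge_tolerance: float = 1e-8
    max_iter: int = 300
    convergence_tol: float = 1e-2
    mode: str = "cd"  # "cd" scales better; "lars" is steadier on small problems

    def __post_init__(self) -> None:
        lams = tuple(float(l) for l in self.lambdas)
        object.__setattr__(self, "lambdas", lams)
        if any(l <= 0 for l in lams):
            raise ValueError("all lambdas must be positive")
        if any(a <= b for a, b in zip(lams, lams[1:])):
            raise ValueError("lambdas must be strictly decreasing")
        if self.edge_tolerance <= 0:
            raise ValueError("edge_tolerance must be positive")


@dataclass(frozen=True)
class WgcnaConfig:
    """Signed-network construction and module-detection controls.

    beta=6 is the conventional signed-network soft threshold;
    min_module_size=30 the conventional smallest reportable module.
    Linkage is fixed to average, as in standard module detection.
    """

    beta: float = 6.0
    cut_heights: tuple[float, ...] = (0.9, 0.95, 0.98, 0.99, 0.995)
    min_module_size: int = 30

    def __post_init__(self) -> None:
        cuts = tuple(float(c) for c in self.cut_heights)
        object.__setattr__(self, "cut_heights", cuts)
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if any(not 0 < c <= 1 for c in cuts):
            raise ValueError("cut_heights must lie in (0, 1]")
        if any(a >= b for a, b in zip(cuts, cuts[1:])):
            raise ValueError("cut_heights must be strictly increasing")
        if self.min_module_size < 1:
            raise ValueError("min_module_size must be >= 1")


@dataclass(frozen=True)
class ModuleAssignment:
    """Gene -> module label map at one cut height; UNASSIGNED is grey."""

    labels: Mapping[str, str]
    cut_height: float

    def module_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for label in self.labels.values():
            if label != UNASSIGNED:
                sizes[label] = sizes.get(label, 0) + 1
        return sizes

    @property
    def n_unassigned(self) -> int:
        return sum(1 for v in self.labels.values() if v == UNASSIGNED)


class GlassoConvergenceError(RuntimeError):
    pass


def _correlation(expr: ExpressionMatrix) -> np.ndarray:
    sd = expr.values.std(axis=1, ddof=1)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        names = [expr.gene_ids[i] for i in zero[:10]]
        raise ValueError(f"zero-variance genes: {names}")
    corr = np.corrcoef(expr.values)
    np.fill_diagonal(corr, 1.0)
    return corr


def _precision_to_network(
    precision: np.ndarray, gene_ids: tuple[str, ...], edge_tolerance: float
) -> NetworkGraph:
    rows, cols = np.nonzero(np.triu(np.abs(precision) > edge_tolerance, k=1))
    edges = {}
    for i, j in zip(rows, cols):
        edges[canonical_pair(gene_ids[i], gene_ids[j])] = float(precision[i, j])
    return NetworkGraph(frozenset(gene_ids), frozenset(edges), edges)


def glasso_precision(
    expr: ExpressionMatrix, lam: float, cfg: GlassoConfig | None = None
) -> np.ndarray:
    """Estimated precision matrix of the gene correlation matrix at penalty lam."""
    cfg = cfg or GlassoConfig()
    if expr.n_samples < 3:
        raise ValueError("need >= 3 samples")
    corr = _correlation(expr)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        try:
            _, precision = _sk_graphical_lasso(
                corr,
                alpha=lam,
                mode=cfg.mode,
                tol=cfg.convergence_tol,
                max_iter=cfg.max_iter,
            )
        except FloatingPointError as exc:
            raise GlassoConvergenceError(
                f"graphical lasso failed at lam={lam}: {exc}"
            ) from exc
    for warning in caught:
        # inner lasso sub-solves may warn harmlessly; only the outer
        # solver's own non-convergence is fatal
        if issubclass(warning.category, ConvergenceWarning) and (
            "graphical_lasso" in str(warning.message)
        ):
            raise GlassoConvergenceError(
                f"graphical lasso did not converge at lam={lam} "
                f"within {cfg.max_iter} iterations: {warning.message}"
            )
    return precision


def glasso_network(
    expr: ExpressionMatrix, lam: float, cfg: GlassoConfig | None = None
) -> NetworkGraph:
    """Edges where the penalized precision estimate is nonzero at penalty lam."""
    cfg = cfg or GlassoConfig()
    precision = glasso_precision(expr, lam, cfg)
    return _precision_to_network(precision, expr.gene_ids, cfg.edge_tolerance)


def glasso_path(
    expr: ExpressionMatrix, cfg: GlassoConfig | None = None
) -> list[tuple[float, NetworkGraph]]:
    """One network per penalty, largest penalty first.

    Each path point is solved independently from the same correlation
    matrix; the problem is strictly convex, so this is equivalent (within
    solver tolerance) to a warm-started sweep.
    """
    cfg = cfg or GlassoConfig()
    return [(lam, glasso_network(expr, lam, cfg)) for lam in cfg.lambdas]


def signed_adjacency(expr: ExpressionMatrix, beta: float = 6.0) -> np.ndarray:
    """Signed soft-threshold adjacency a_ij = ((1 + cor_ij)/2)^beta."""
    if beta <= 0:
        raise ValueError("beta must be positive")
    corr = _correlation(expr)
    adjacency = ((1.0 + corr) / 2.0) ** beta
    np.fill_diagonal(adjacency, 1.0)
    return adjacency


def tom_similarity(adjacency: np.ndarray) -> np.ndarray:
    """Topological overlap: direct adjacency boosted by shared neighbours.

    tom_ij = (sum_{u not in {i,j}} a_iu a_uj + a_ij)
             / (min(k_i, k_j) + 1 - a_ij),   k_i = sum_{u != i} a_iu,
    with tom_ii = 1. Requires a symmetric adjacency in [0, 1] with unit
    diagonal; output entries are again in [0, 1].
    """
    a = np.asarray(adjacency, dtype=float)
    if (
        a.ndim != 2
        or a.shape[0] != a.shape[1]
        or not np.allclose(a, a.T)
        or not np.allclose(np.diag(a), 1.0)
        or a.min() < -1e-12
        or a.max() > 1 + 1e-12
    ):
        raise ValueError("adjacency must be symmetric, in [0,1], unit diagonal")
    k = a.sum(axis=1) - 1.0
    shared = a @ a - a * (np.diag(a)[:, None] + np.diag(a)[None, :])
    numerator = shared + a
    denominator = np.minimum.outer(k, k) + 1.0 - a
    np.fill_diagonal(denominator, 1.0)  # diagonal is defined as 1 below
    tom = numerator / denominator
    np.fill_diagonal(tom, 1.0)
    return np.clip(tom, 0.0, 1.0)


def _linkage(tom: np.ndarray) -> np.ndarray:
    dissimilarity = 1.0 - tom
    np.fill_diagonal(dissimilarity, 0.0)
    condensed = squareform(dissimilarity, checks=False)
    return linkage(condensed, method="average")


def _cut(
    merge_tree: np.ndarray,
    gene_ids: tuple[str, ...],
    cut_height: float,
    min_module_size: int,
) -> ModuleAssignment:
    flat = fcluster(merge_tree, t=cut_height, criterion="distance")
    sizes: dict[int, int] = {}
    for c in flat:
        sizes[c] = sizes.get(c, 0) + 1
    # deterministic module numbering: decreasing size, ties by smallest gene index
    first_index = {c: int(np.argmax(flat == c)) for c in sizes}
    kept = sorted(
        (c for c, s in sizes.items() if s >= min_module_size),
        key=lambda c: (-sizes[c], first_index[c]),
    )
    rename = {c: f"M{rank + 1}" for rank, c in enumerate(kept)}
    labels = {
        g: rename.get(c, UNASSIGNED) for g, c in zip(gene_ids, flat)
    }
    return ModuleAssignment(labels, cut_height)


def detect_modules(
    tom: np.ndarray,
    gene_ids: tuple[str, ...],
    cut_height: float,
    min_module_size: int = 30,
) -> ModuleAssignment:
    """Average-linkage clustering of 1 - TOM with a static cut.

    Clusters joined below ``cut_height`` whose size reaches
    ``min_module_size`` become modules; all other genes are grey.
    """
    if not 0 < cut_height <= 1:
        raise ValueError("cut_height must be in (0, 1]")
    return _cut(_linkage(tom), gene_ids, cut_height, min_module_size)


def modules_to_network(
    assignment: ModuleAssignment, universe: frozenset[str] | None = None
) -> NetworkGraph:
    """Modules as cliques: every within-module pair is an edge."""
    universe = frozenset(assignment.labels) if universe is None else universe
    by_module: dict[str, list[str]] = {}
    for gene, label in assignment.labels.items():
        if label != UNASSIGNED:
            by_module.setdefault(label, []).append(gene)
    edges = set()
    for members in by_module.values():
        members = sorted(members)
        for i, a in enumerate(members):
            for b in members[i + 1 :]:
                edges.add((a, b))
    return NetworkGraph(universe, frozenset(edges))


def wgcna_path(
    expr: ExpressionMatrix, cfg: WgcnaConfig | None = None
) -> list[tuple[float, NetworkGraph, ModuleAssignment]]:
    """One clustering, one (network, assignment) per cut height."""
    cfg = cfg or WgcnaConfig()
    tom = tom_similarity(signed_adjacency(expr, cfg.beta))
    merge_tree = _linkage(tom)
    universe = frozenset(expr.gene_ids)
    out = []
    for cut in cfg.cut_heights:
        assignment = _cut(merge_tree, expr.gene_ids, cut, cfg.min_module_size)
        out.append((cut, modules_to_network(assignment, universe), assignment))
    return out
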