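"""Scale-free Gaussian graphical model simulation with injected confounders.

The generator emulates the structure of confounded bulk expression data:
a sparse, scale-free conditional-dependence network among genes (Barabasi-
Albert preferential attachment), a positive-definite precision matrix
supported exactly on that graph (random off-diagonal weights, diagonal-
dominance repair), zero-mean multivariate Gaussian "clean" expression, and
additive low-rank confounding — each latent confounder is a per-sample
Gaussian variable that loads on a random subset of genes.

Default configuration (300 genes x 200 samples, 5 confounders each
affecting 30% of genes with per-sample sd 3) is the standard confounded
instance used throughout the package's own evaluation; the reference
dimensions of a full-size run (5000 genes x 350 samples) are reachable by
configuration but not the default because the whole pipeline is exercised
many times in tests.

Seed policy: one master seed; graph, edge weights, sampling and confounder
draws use sub-streams derived from (seed, stage-offset) so each stage is
independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.linalg import solve_triangular

from pcnet.core_io import ExpressionMatrix, NetworkGraph, canonical_pair

_GRAPH, _WEIGHTS, _SAMPLES, _CONFOUNDERS = 0, 1, 2, 3


def _rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, stage]))


@dataclass(frozen=True)
class SimConfig:
    n_genes: int = 300
    n_samples: int = 200
    attachment_edges: int = 2
    edge_weight_range: tuple[float, float] = (0.3, 1.0)
    n_confounders: int = 5
    affected_fraction: float = 0.3
    confounder_sd: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.attachment_edges >= self.n_genes:
            raise ValueError("attachment_edges must be < n_genes")
        lo, hi = self.edge_weight_range
        if not 0 < lo <= hi:
            raise ValueError("edge_weight_range must be positive magnitudes")
        if not 0 <= self.affected_fraction <= 1:
            raise ValueError("affected_fraction must be in [0, 1]")
        if self.n_confounders > 0 and round(
            self.affected_fraction * self.n_genes
        ) < 1:
            raise ValueError("affected_fraction * n_genes must be >= 1")


@dataclass(frozen=True)
class SimulationTruth:
    """Everything the generator knows: the answer key for evaluation."""

    adjacency: np.ndarray  # genes x genes, binary symmetric
    precision: np.ndarray | None
    confounders: np.ndarray  # samples x k
    loadings: np.ndarray  # genes x k, zero outside affected sets
    clean_expr: ExpressionMatrix
    confounded_expr: ExpressionMatrix
    config: SimConfig | None = field(default=None)

    def true_network(self) -> NetworkGraph:
        genes = self.clean_expr.gene_ids
        rows, cols = np.nonzero(np.triu(self.adjacency, k=1))
        edges = frozenset(
            canonical_pair(genes[i], genes[j]) for i, j in zip(rows, cols)
        )
        return NetworkGraph(frozenset(genes), edges)


def generate_scale_free_graph(
    n_genes: int, attachment_edges: int, seed: int
) -> np.ndarray:
    """Barabasi-Albert adjacency matrix (binary, symmetric, connected).

    networkx's generator starts from ``attachment_edges`` isolated nodes and
    attaches every later node with ``attachment_edges`` edges, so the edge
    count is exactly attachment_edges * (n_genes - attachment_edges).
    """
    if n_genes < attachment_edges + 1:
        raise ValueError("need n_genes >= attachment_edges + 1")
    graph = nx.barabasi_albert_graph(
        n_genes, attachment_edges, seed=_rng(seed, _GRAPH)
    )
    adj = nx.to_numpy_array(graph, nodelist=range(n_genes), dtype=float)
    return (adj > 0).astype(float)


def graph_to_precision(
    adjacency: np.ndarray,
    edge_weight_range: tuple[float, float] = (0.3, 1.0),
    seed: int = 0,
) -> np.ndarray:
    """Random positive-definite precision matrix supported on the graph.

    Off-diagonal magnitudes are uniform in ``edge_weight_range`` with random
    signs; the diagonal is set to the absolute row sum plus 0.1 (strict
    diagonal dominance), which guarantees positive definiteness without
    perturbing the support.
    """
    adjacency = np.asarray(adjacency, dtype=float)
    if adjacency.ndim != 2 or adjacency.shape[0] != adjacency.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.array_equal(adjacency, adjacency.T) or np.diag(adjacency).any():
        raise ValueError("adjacency must be symmetric with zero diagonal")
    rng = _rng(seed, _WEIGHTS)
    n = adjacency.shape[0]
    lo, hi = edge_weight_range
    magnitudes = rng.uniform(lo, hi, size=(n, n))
    signs = rng.choice([-1.0, 1.0], size=(n, n))
    weights = np.triu(magnitudes * signs, k=1)
    weights = (weights + weights.T) * adjacency
    omega = weights.copy()
    np.fill_diagonal(omega, np.abs(weights).sum(axis=1) + 0.1)
    return omega


def sample_expression(
    precision: np.ndarray,
    n_samples: int,
    gene_ids: tuple[str, ...] | None = None,
    seed: int = 0,
) -> ExpressionMatrix:
    """IID draws from N(0, precision^-1), genes x samples.

    Sampling goes through the Cholesky factor of the precision (solve
    against standard normals) so the covariance is never formed explicitly.
    """
    precision = np.asarray(precision, dtype=float)
    n_genes = precision.shape[0]
    try:
        chol = np.linalg.cholesky(precision)
    except np.linalg.LinAlgError as exc:
        raise ValueError("precision matrix is not positive definite") from exc
    rng = _rng(seed, _SAMPLES)
    z = rng.standard_normal((n_genes, n_samples))
    # precision = L L^T  =>  x = L^-T z has covariance precision^-1
    x = solve_triangular(chol.T, z, lower=False)
    if gene_ids is None:
        gene_ids = tuple(f"g{i:04d}" for i in range(n_genes))
    sample_ids = tuple(f"s{j:04d}" for j in range(n_samples))
    return ExpressionMatrix(gene_ids, sample_ids, x)


def inject_confounders(
    clean: ExpressionMatrix,
    n_confounders: int,
    affected_fraction: float,
    confounder_sd: float,
    seed: int = 0,
    adjacency: np.ndarray | None = None,
    precision: np.ndarray | None = None,
    config: SimConfig | None = None,
) -> SimulationTruth:
    """Add low-rank confounding: confounded = clean + loadings @ confounders^T.

    Each confounder draws per-sample values ~ N(0, confounder_sd^2), picks a
    uniformly random affected subset of round(affected_fraction * n_genes)
    genes (subsets may overlap across confounders, as batch-like artifacts
    do), and gives affected genes loadings ~ N(0, 1).
    """
    if not 0 <= affected_fraction <= 1:
        raise ValueError("affected_fraction must be in [0, 1]")
    rng = _rng(seed, _CONFOUNDERS)
    n_genes, n_samples = clean.values.shape
    n_affected = int(round(affected_fraction * n_genes))
    confounders = np.zeros((n_samples, n_confounders))
    loadings = np.zeros((n_genes, n_confounders))
    for c in range(n_confounders):
        confounders[:, c] = rng.normal(0.0, confounder_sd, size=n_samples)
        affected = rng.choice(n_genes, size=n_affected, replace=False)
        loadings[affected, c] = rng.normal(0.0, 1.0, size=n_affected)
    confounded = clean.values + loadings @ confounders.T
    if adjacency is None:
        adjacency = np.zeros((n_genes, n_genes))
    return SimulationTruth(
        adjacency=adjacency,
        precision=precision,
        confounders=confounders,
        loadings=loadings,
        clean_expr=clean,
        confounded_expr=clean.with_values(confounded),
        config=config,
    )


def simulate_dataset(cfg: SimConfig) -> SimulationTruth:
    """Full pipeline: graph -> precision -> clean draws -> confounding."""
    adjacency = generate_scale_free_graph(
        cfg.n_genes, cfg.attachment_edges, cfg.seed
    )
    precision = graph_to_precision(adjacency, cfg.edge_weight_range, cfg.seed)
    clean = sample_expression(precision, cfg.n_samples, seed=cfg.seed)
    return inject_confounders(
        clean,
        cfg.n_confounders,
        cfg.affected_fraction,
        cfg.confounder_sd,
        seed=cfg.seed,
        adjacency=adjacency,
        precision=precision,
        config=cfg,
    )


def toy_example(seed: int = 0) -> SimulationTruth:
    """Small fixed-size instance for docs and tests.

    20 genes x 50 samples with one confounder (per-sample sd 3) affecting
    half the genes. The network is module-structured rather than
    preferential-attachment — six triangles plus one pair — so that every
    true edge carries a strong partial correlation and the clean data are
    recoverable by the graphical lasso at this small sample size; that
    makes the fixture a clear before/after demonstration of confounding.
    """
    n_genes, n_samples = 20, 50
    adjacency = np.zeros((n_genes, n_genes))
    for b in range(6):
        block = slice(3 * b, 3 * (b + 1))
        adjacency[block, block] = 1.0
    adjacency[18, 19] = adjacency[19, 18] = 1.0
    np.fill_diagonal(adjacency, 0.0)
    precision = graph_to_precision(adjacency, (0.5, 1.0), seed)
    clean = sample_expression(precision, n_samples, seed=seed)
    return inject_confounders(
        clean,
        n_confounders=1,
        affected_fraction=0.5,
        confounder_sd=3.0,
        seed=seed,
        adjacency=adjacency,
        precision=precision,
    )
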