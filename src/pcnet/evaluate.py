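"""Scoring inferred networks against ground-truth gene pairs.

An inferred edge present in the ground-truth pair list is a true positive,
one absent is a false positive, and a ground-truth pair with no inferred
edge is a false negative; FDR = FP/(TP+FP) and FNR = FN/(TP+FN). Both the
ground truth and the network are restricted to the same gene universe
(typically the most-variable genes used for reconstruction) *before*
counting, so FN never charges the network for genes it never saw.

When a network has no edges (or the truth is empty), FDR (FNR) is reported
as NaN and the point is excluded from summary curves — substituting 0
would fabricate a perfect score for an empty network.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Any, Iterable

import networkx as nx

from pcnet.core_io import GroundTruthEdges, NetworkGraph
from pcnet.reconstruct import ModuleAssignment

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EvalReport:
    """Confusion counts and topology diagnostics for one network."""

    tp: int
    fp: int
    fn: int
    fdr: float  # NaN when no edges
    fnr: float  # NaN when truth empty
    n_edges: int
    density: float
    mean_clustering_coefficient: float
    hub_count: int
    params: dict[str, Any] = field(default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "fdr": None if math.isnan(self.fdr) else self.fdr,
            "fnr": None if math.isnan(self.fnr) else self.fnr,
            "n_edges": self.n_edges,
            "density": self.density,
            "mean_clustering_coefficient": self.mean_clustering_coefficient,
            "hub_count": self.hub_count,
            "params": self.params,
        }


def confusion(
    net: NetworkGraph, truth: GroundTruthEdges, universe: Iterable[str]
) -> tuple[int, int, int]:
    """(tp, fp, fn) with truth restricted to the universe first."""
    uni = set(universe)
    if not net.gene_universe <= uni:
        extra = sorted(net.gene_universe - uni)[:10]
        raise ValueError(f"network genes outside evaluation universe: {extra}")
    true_pairs = truth.restricted_to(uni).pairs
    tp = len(net.edges & true_pairs)
    fp = len(net.edges - true_pairs)
    fn = len(true_pairs - net.edges)
    return tp, fp, fn


def fdr(tp: int, fp: int) -> float:
    """FP / (TP + FP); NaN when the network has no edges."""
    if tp < 0 or fp < 0:
        raise ValueError("counts must be non-negative")
    if tp + fp == 0:
        logger.info("FDR undefined: network has no edges")
        return math.nan
    return fp / (tp + fp)


def fnr(tp: int, fn: int) -> float:
    """FN / (TP + FN); NaN when the ground truth is empty."""
    if tp < 0 or fn < 0:
        raise ValueError("counts must be non-negative")
    if tp + fn == 0:
        logger.info("FNR undefined: no ground-truth pairs in universe")
        return math.nan
    return fn / (tp + fn)


def shared_truth(
    truth: GroundTruthEdges, min_databases: int = 2
) -> GroundTruthEdges:
    """Refined ground truth: pairs supported by >= min_databases databases."""
    if min_databases < 1:
        raise ValueError("min_databases must be >= 1")
    keep = {p for p, c in truth.db_count.items() if c >= min_databases}
    return GroundTruthEdges(
        frozenset(keep), {p: truth.db_count[p] for p in keep}
    )


def density(net: NetworkGraph, universe: Iterable[str] | None = None) -> float:
    """Edges over all possible unordered pairs of the universe."""
    uni = net.gene_universe if universe is None else frozenset(universe)
    n = len(uni)
    if n < 2:
        raise ValueError("universe must have >= 2 genes")
    return len(net.edges) / (n * (n - 1) / 2)


def _as_nx(net: NetworkGraph) -> nx.Graph:
    graph = nx.Graph()
    graph.add_nodes_from(net.gene_universe)
    graph.add_edges_from(net.edges)
    return graph


def clustering_stats(
    net: NetworkGraph, hub_quantile: float = 0.95, hub_threshold: int | None = None
) -> tuple[float, int]:
    """(mean local clustering coefficient, hub count).

    The mean runs over nodes of degree >= 2 only (the coefficient is not
    defined below that); it is 0.0 when no such node exists. Hubs are nodes
    with degree strictly above the ``hub_quantile`` quantile of the degree
    distribution, or above the absolute ``hub_threshold`` when given.
    """
    graph = _as_nx(net)
    degrees = dict(graph.degree())
    eligible = [n for n, d in degrees.items() if d >= 2]
    if eligible:
        coefficients = nx.clustering(graph, nodes=eligible)
        mean_cc = sum(coefficients.values()) / len(eligible)
    else:
        mean_cc = 0.0
    values = sorted(degrees.values())
    if hub_threshold is None:
        if not values:
            return mean_cc, 0
        # top-quantile cutoff on the degree distribution
        idx = max(0, math.ceil(hub_quantile * len(values)) - 1)
        hub_threshold = values[idx]
    hub_count = sum(1 for d in degrees.values() if d > hub_threshold)
    return mean_cc, hub_count


def module_size_stats(assignment: ModuleAssignment) -> tuple[float, int]:
    """(mean module size excluding unassigned, number of unassigned genes).

    Mean is NaN when there is no module at all.
    """
    sizes = assignment.module_sizes()
    mean_size = sum(sizes.values()) / len(sizes) if sizes else math.nan
    return mean_size, assignment.n_unassigned


def evaluate_network(
    net: NetworkGraph,
    truth: GroundTruthEdges,
    universe: Iterable[str] | None = None,
    hub_quantile: float = 0.95,
    hub_threshold: int | None = None,
) -> EvalReport:
    """Full report: confusion counts, rates and topology diagnostics."""
    uni = net.gene_universe if universe is None else frozenset(universe)
    tp, fp, fn = confusion(net, truth, uni)
    mean_cc, hubs = clustering_stats(net, hub_quantile, hub_threshold)
    return EvalReport(
        tp=tp,
        fp=fp,
        fn=fn,
        fdr=fdr(tp, fp),
        fnr=fnr(tp, fn),
        n_edges=net.n_edges,
        density=density(net, uni),
        mean_clustering_coefficient=mean_cc,
        hub_count=hubs,
        params={
            "hub_quantile": hub_quantile,
            "hub_threshold": hub_threshold,
            "universe_size": len(uni),
            "degree_lt2_excluded_from_clustering": True,
        },
    )
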