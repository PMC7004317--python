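"""Interaction-network cleaning, centrality, and hub/bottleneck calls.

An interaction edge list is reduced to a simple undirected graph (no
self-loops, no parallel edges, symbols upper-cased). Two centrality measures
drive the downstream subnetwork assembly:

* degree centrality (DC) — the number of interaction partners of a gene;
* betweenness centrality (BC) — the fraction of pairwise shortest paths
  passing through a gene, normalized by ``(n - 1)(n - 2) / 2`` to [0, 1].

Hubs are genes whose degree strictly exceeds ``mean(DC) + k * SD(DC)``
(k = 2 by default); bottlenecks are the top quartile of the betweenness
distribution, with deterministic tie extension at the boundary.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx
import numpy as np

from .errors import ValidationError

logger = logging.getLogger(__name__)


def clean_network(raw_edges: Iterable[tuple[str, str]]) -> nx.Graph:
    """Build a simple undirected graph from a raw edge list.

    Self-loops are dropped, ``(a, b)`` and ``(b, a)`` are merged, and gene
    symbols are upper-cased. Idempotent: cleaning an already-simple graph's
    edges returns the same graph.
    """
    g = nx.Graph()
    n_raw = 0
    for pair in raw_edges:
        a, b = pair
        a, b = str(a).strip().upper(), str(b).strip().upper()
        if not a or not b:
            raise ValidationError(f"empty gene symbol in edge {pair!r}")
        n_raw += 1
        if a == b:
            continue
        g.add_edge(a, b)
    if n_raw == 0:
        logger.warning("empty edge list: returning an empty network")
    return g


def induced_subgraph(network: nx.Graph, keep: Iterable[str]) -> nx.Graph:
    """Subgraph on ``nodes(network) & keep`` with all internal edges."""
    keep = {str(s).upper() for s in keep}
    return nx.Graph(network.subgraph(keep & set(network.nodes)))


def degree_centrality(network: nx.Graph) -> dict[str, int]:
    """Degree per node: the number of incident edges (interaction partners)."""
    return {n: d for n, d in network.degree()}


def betweenness_centrality(network: nx.Graph) -> dict[str, float]:
    """Normalized betweenness per node via Brandes' single-source scheme.

    ``BC(v) = sum_{s != v != t} sigma_st(v) / sigma_st`` over unordered node
    pairs, divided by ``(n - 1)(n - 2) / 2``. Pairs in different components
    contribute zero; disconnected graphs keep the global normalization.
    Graphs with fewer than 3 nodes have no intermediate vertices: all BC = 0.
    """
    n = network.number_of_nodes()
    if n < 3:
        if n > 0:
            logger.warning("betweenness undefined for n < 3; returning zeros")
        return {v: 0.0 for v in network.nodes}
    return nx.betweenness_centrality(network, normalized=True)


@dataclass(frozen=True)
class HubCutoff:
    """Degree cutoff ``avg_dc + multiplier * sd_dc`` for hub calling."""

    avg_dc: float
    sd_dc: float
    multiplier: float
    cutoff: float


def classify_hubs(
    dc: Mapping[str, int],
    multiplier: float = 2.0,
    sd_mode: str = "sample",
) -> tuple[HubCutoff, set[str]]:
    """Hubs: nodes whose degree strictly exceeds mean + multiplier * SD.

    The cutoff is computed over all nodes of the analyzed network. SD is
    the sample standard deviation (ddof = 1) by default; ``sd_mode =
    "population"`` uses ddof = 0. Strict inequality means a degenerate
    (constant-degree) network yields no hubs rather than all of them.
    """
    if not dc:
        raise ValidationError("empty degree map")
    if sd_mode not in ("sample", "population"):
        raise ValidationError(f"sd_mode must be 'sample' or 'population', got {sd_mode!r}")
    degrees = np.array(list(dc.values()), dtype=float)
    avg = float(degrees.mean())
    if degrees.size == 1 and sd_mode == "sample":
        logger.warning("single-node network: sample SD undefined, treated as 0")
        sd = 0.0
    else:
        sd = float(degrees.std(ddof=1 if sd_mode == "sample" else 0))
    cutoff = avg + multiplier * sd
    hubs = {node for node, d in dc.items() if d > cutoff}
    return HubCutoff(avg, sd, multiplier, cutoff), hubs


def classify_bottlenecks(bc: Mapping[str, float], quantile: float = 0.25) -> set[str]:
    """Bottlenecks: the top ``quantile`` of the betweenness distribution.

    Nodes are ranked by BC descending; the first ``ceil(quantile * n)`` are
    taken and the set is extended to every node tied with the last included
    BC value, so the call is deterministic and independent of node order.
    Zero-betweenness nodes are never called bottlenecks: an all-zero
    distribution yields an empty set with a warning, and a zero boundary
    (fewer than ``ceil(quantile * n)`` nodes with positive BC) keeps only
    the positive-BC nodes rather than tying in the whole network.
    """
    if not bc:
        raise ValidationError("empty betweenness map")
    if not 0 <= quantile <= 1:
        raise ValidationError(f"quantile must lie in [0, 1], got {quantile}")
    values = np.array(list(bc.values()), dtype=float)
    if np.all(values == 0):
        logger.warning("all betweenness values are zero: no meaningful bottlenecks")
        return set()
    k = math.ceil(quantile * len(values))
    if k == 0:
        return set()
    ranked = sorted(bc.items(), key=lambda kv: (-kv[1], kv[0]))
    boundary = ranked[k - 1][1]
    return {node for node, v in bc.items() if v >= boundary and v > 0}
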