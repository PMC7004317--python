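"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import math
from collections import deque

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from saltnet import ExpressionMatrix


# -- independent oracles ------------------------------------------------------

def brute_force_betweenness(g: nx.Graph) -> dict:
    """Exhaustive BFS shortest-path counting, independent of networkx's
    accumulation scheme: for every unordered pair (s, t) count the shortest
    paths through each intermediate node directly."""
    nodes = list(g.nodes)
    n = len(nodes)
    if n < 3:
        return {v: 0.0 for v in nodes}

    def bfs(src):
        dist = {src: 0}
        count = {src: 1}
        dq = deque([src])
        while dq:
            u = dq.popleft()
            for w in g[u]:
                if w not in dist:
                    dist[w] = dist[u] + 1
                    count[w] = 0
                    dq.append(w)
                if dist[w] == dist[u] + 1:
                    count[w] += count[u]
        return dist, count

    info = {v: bfs(v) for v in nodes}
    bc = {v: 0.0 for v in nodes}
    for i, s in enumerate(nodes):
        dist_s, cnt_s = info[s]
        for t in nodes[i + 1 :]:
            if t not in dist_s:
                continue
            dist_t, cnt_t = info[t]
            sigma_st = cnt_s[t]
            for v in nodes:
                if v in (s, t) or v not in dist_s or v not in dist_t:
                    continue
                if dist_s[v] + dist_t[v] == dist_s[t]:
                    bc[v] += cnt_s[v] * cnt_t[v] / sigma_st
    norm = (n - 1) * (n - 2) / 2
    return {v: bc[v] / norm for v in nodes}


def stepup_bh(p):
    """Direct evaluation of the Benjamini-Hochberg step-up definition."""
    p = list(p)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adjusted = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, min(1.0, p[i] * m / rank))
        adjusted[i] = running
    return adjusted


def hypergeom_upper_tail(population, successes, draws, overlap):
    """Exhaustive enumeration of P(X >= overlap) for the hypergeometric."""
    total = math.comb(population, draws)
    mass = 0
    for j in range(overlap, min(successes, draws) + 1):
        if draws - j > population - successes:
            continue
        mass += math.comb(successes, j) * math.comb(population - successes, draws - j)
    return mass / total


def random_simple_graph(rng: np.random.Generator, max_nodes: int = 12) -> nx.Graph:
    n = int(rng.integers(3, max_nodes + 1))
    p = float(rng.uniform(0.1, 0.9))
    g = nx.Graph()
    g.add_nodes_from(f"N{i}" for i in range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                g.add_edge(f"N{i}", f"N{j}")
    return g


# -- fixtures -----------------------------------------------------------------

@pytest.fixture
def small_matrix() -> ExpressionMatrix:
    """Six genes, 4 + 4 samples; G1 strongly shifted in the case group."""
    rng = np.random.default_rng(42)
    samples = [f"C{i}" for i in range(4)] + [f"D{i}" for i in range(4)]
    values = pd.DataFrame(
        8.0 + 0.3 * rng.standard_normal((6, 8)),
        index=[f"G{i}" for i in range(1, 7)],
        columns=samples,
    )
    values.loc["G1", [f"D{i}" for i in range(4)]] += 4.0
    conditions = pd.Series(["control"] * 4 + ["case"] * 4, index=samples)
    return ExpressionMatrix(values, conditions)


@pytest.fixture
def path_graph() -> nx.Graph:
    g = nx.Graph()
    g.add_edges_from([("A", "B"), ("B", "C")])
    return g
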