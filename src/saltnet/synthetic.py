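"""Seeded synthetic inputs with the statistical structure the pipeline assumes.

Two generators, both driven by a single integer seed:

* an expression matrix on the log2 scale with two conditions, planted
  mean-shift differentially expressed genes, and planted co-expression
  blocks built from a shared latent factor so the expected pairwise Pearson
  correlation inside a block equals the target rho;
* a scale-free-like interaction network made of dense random communities
  connected only through designated bridge nodes, plus high-degree hub
  nodes wired by preferential attachment.

Ground-truth labels (DE genes, block pairs, planted hubs and bridges) are
returned alongside for recovery tests.

The defaults emulate the visceral-adipose study design this pipeline
targets — 16 case and 14 control samples — at desk scale for the rest
(gene count, network size).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .expression import CASE, CONTROL, ExpressionMatrix


@dataclass(frozen=True)
class BlockSpec:
    """A planted co-expression block: ``size`` genes at pairwise ``rho``.

    ``condition`` is ``"case_only"`` (the block correlates only in the
    disease samples — the differential co-expression signal) or ``"both"``.
    """

    size: int
    rho: float
    condition: str = "case_only"


@dataclass(frozen=True)
class NetworkConfig:
    """Interaction-network generator settings."""

    n_nodes: int = 500
    n_hubs: int = 5
    hub_degree: int = 40
    n_communities: int = 4
    n_bridges: int = 3
    background_edge_prob: float = 0.03


@dataclass(frozen=True)
class SimulationConfig:
    """Settings for the synthetic expression matrix and interaction network.

    All expression values are in log2 units: the per-gene baseline is drawn
    once from N(8, 2), sample noise has standard deviation ``noise_sd``, and
    planted DE genes have their case-condition mean shifted by ``de_shift``.
    """

    n_genes: int = 500
    n_control: int = 14
    n_case: int = 16
    n_de: int = 50
    de_shift: float = 2.0
    blocks: tuple[BlockSpec, ...] = (BlockSpec(size=10, rho=0.9),)
    noise_sd: float = 0.5
    network: NetworkConfig = field(default_factory=NetworkConfig)
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ConfigurationError(f"n_genes must be >= 1, got {self.n_genes}")
        if self.n_control < 3:
            raise ConfigurationError(f"n_control must be >= 3, got {self.n_control}")
        if self.n_case < 3:
            raise ConfigurationError(f"n_case must be >= 3, got {self.n_case}")
        if not 0 <= self.n_de <= self.n_genes:
            raise ConfigurationError(
                f"n_de must lie in [0, n_genes], got {self.n_de}"
            )
        if self.noise_sd <= 0:
            raise ConfigurationError(f"noise_sd must be > 0, got {self.noise_sd}")
        total_block = 0
        for b in self.blocks:
            if not 0 <= b.rho < 1:
                raise ConfigurationError(f"blocks: rho must lie in [0, 1), got {b.rho}")
            if b.size < 2:
                raise ConfigurationError(f"blocks: block_size must be >= 2, got {b.size}")
            if b.condition not in ("case_only", "both"):
                raise ConfigurationError(
                    f"blocks: condition must be 'case_only' or 'both', got {b.condition!r}"
                )
            total_block += b.size
        if total_block > self.n_genes:
            raise ConfigurationError(
                f"blocks: planted block genes exceed n_genes "
                f"({total_block} > {self.n_genes})"
            )
        net = self.network
        for name in ("n_nodes", "n_hubs", "n_communities", "n_bridges"):
            if getattr(net, name) < 0:
                raise ConfigurationError(f"network.{name} must be >= 0")
        if net.n_communities < 1:
            raise ConfigurationError("network.n_communities must be >= 1")
        if net.hub_degree >= net.n_nodes:
            raise ConfigurationError(
                f"network.hub_degree must be < n_nodes, got {net.hub_degree}"
            )
        if not 0 <= net.background_edge_prob <= 1:
            raise ConfigurationError(
                "network.background_edge_prob must lie in [0, 1], "
                f"got {net.background_edge_prob}"
            )

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


@dataclass
class SyntheticTruth:
    """Ground truth of the planted structure, for recovery tests."""

    de_genes: set[str] = field(default_factory=set)
    block_pairs: dict[frozenset, float] = field(default_factory=dict)
    planted_hubs: set[str] = field(default_factory=set)
    planted_bridges: set[str] = field(default_factory=set)


def _streams(seed: int, n: int):
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def gene_symbols(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(1, n + 1)]


def generate_expression(config: SimulationConfig) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Two-condition log2 expression matrix with planted DE and blocks.

    Background entries are ``baseline_g + noise_sd * eps``; block genes in
    their active condition(s) replace the unit noise with
    ``sqrt(rho) * f_s + sqrt(1 - rho) * eps_gs`` where ``f_s`` is a latent
    factor shared across the block per sample, so the expected pairwise
    Pearson correlation within the block equals rho exactly.
    """
    config.validate()
    rng_base, rng_assign, rng_noise, rng_block, _ = _streams(config.seed, 5)

    genes = gene_symbols(config.n_genes)
    samples = [f"CTRL{i:03d}" for i in range(1, config.n_control + 1)] + [
        f"CASE{i:03d}" for i in range(1, config.n_case + 1)
    ]
    conditions = pd.Series(
        [CONTROL] * config.n_control + [CASE] * config.n_case, index=samples
    )
    case_cols = np.arange(config.n_control, config.n_control + config.n_case)

    baseline = rng_base.normal(8.0, 2.0, size=config.n_genes)
    values = baseline[:, None] + config.noise_sd * rng_noise.standard_normal(
        (config.n_genes, len(samples))
    )

    # One shuffle allocates planted structure: blocks take consecutive
    # slices from the front, DE genes are the first n_de entries, so blocks
    # nest inside the DE set whenever n_de covers them. This emulates the
    # study design where the disease-relevant co-expression modules sit
    # among the differentially expressed genes that form the network; the
    # case-condition mean shift is a constant per sample group and leaves
    # within-condition correlations untouched.
    order = rng_assign.permutation(config.n_genes)
    cursor = 0
    truth = SyntheticTruth()
    for block in config.blocks:
        idx = order[cursor : cursor + block.size]
        cursor += block.size
        cols = (
            case_cols
            if block.condition == "case_only"
            else np.arange(len(samples))
        )
        f = rng_block.standard_normal(len(cols))
        eps = rng_block.standard_normal((block.size, len(cols)))
        latent = math.sqrt(block.rho) * f[None, :] + math.sqrt(1 - block.rho) * eps
        values[np.ix_(idx, cols)] = baseline[idx, None] + config.noise_sd * latent
        members = [genes[i] for i in idx]
        for i, a in enumerate(members):
            for b in members[i + 1 :]:
                truth.block_pairs[frozenset((a, b))] = block.rho

    de_idx = order[: config.n_de]
    values[np.ix_(de_idx, case_cols)] += config.de_shift
    truth.de_genes = {genes[i] for i in de_idx}

    frame = pd.DataFrame(values, index=genes, columns=samples)
    return ExpressionMatrix(frame, conditions), truth


def generate_network(config: SimulationConfig) -> tuple[nx.Graph, SyntheticTruth]:
    """Community-structured interaction network with planted hubs and bridges.

    Nodes reuse the expression gene-symbol scheme so generated networks and
    matrices share a symbol universe. Communities are internally
    Erdos-Renyi at ``background_edge_prob`` and are connected only through
    the bridge nodes, each of which attaches to at least a quarter of every
    community; hub nodes then wire to ``hub_degree`` partners sampled by
    preferential attachment.
    """
    config.validate()
    net = config.network
    rng = _streams(config.seed, 5)[4]

    nodes = gene_symbols(net.n_nodes)
    order = list(rng.permutation(net.n_nodes))
    bridges = [nodes[i] for i in order[: net.n_bridges]]
    hubs = [nodes[i] for i in order[net.n_bridges : net.n_bridges + net.n_hubs]]
    rest = [nodes[i] for i in order[net.n_bridges + net.n_hubs :]]
    communities = [rest[i :: net.n_communities] for i in range(net.n_communities)]
    communities = [c for c in communities if c]

    g = nx.Graph()
    g.add_nodes_from(nodes)
    for comm in communities:
        m = len(comm)
        if m < 2:
            continue
        iu, ju = np.triu_indices(m, k=1)
        mask = rng.random(len(iu)) < net.background_edge_prob
        g.add_edges_from((comm[i], comm[j]) for i, j in zip(iu[mask], ju[mask]))

    for bridge in bridges:
        for comm in communities:
            k = max(1, math.ceil(len(comm) / 4))
            targets = rng.choice(len(comm), size=min(k, len(comm)), replace=False)
            g.add_edges_from((bridge, comm[t]) for t in targets)

    for hub in hubs:
        others = [n for n in nodes if n != hub]
        weights = np.array([g.degree(n) + 1.0 for n in others])
        probs = weights / weights.sum()
        k = min(net.hub_degree, len(others))
        targets = rng.choice(len(others), size=k, replace=False, p=probs)
        g.add_edges_from((hub, others[t]) for t in targets)

    g.remove_edges_from(nx.selfloop_edges(g))
    truth = SyntheticTruth(planted_hubs=set(hubs), planted_bridges=set(bridges))
    return g, truth
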