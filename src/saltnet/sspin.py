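"""Salt Sensitivity Protein Interaction Network (SS-PIN) assembly.

Hubs, bottlenecks and salt-sensitivity genes (SSGs) are grouped into the
HBS union; the SS-PIN is the induced subgraph of the interaction network on
that union. This module also carries the overlap arithmetic reported for
the three sets and the edge/node summary ratio.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx

from .errors import ValidationError
from .network import induced_subgraph


class GeneSetCollection(dict):
    """Named gene sets with upper-cased symbols and unique, non-empty names."""

    def __init__(self, sets: Mapping[str, Iterable[str]] | None = None):
        super().__init__()
        for name, members in (sets or {}).items():
            self[name] = members

    def __setitem__(self, name: str, members: Iterable[str]) -> None:
        if not str(name):
            raise ValidationError("gene set names must be non-empty")
        super().__setitem__(str(name), {str(g).upper() for g in members})


@dataclass(frozen=True)
class HBSReport:
    """Set sizes and overlap arithmetic for hubs (H), bottlenecks (B), SSGs (S)."""

    hubs: frozenset
    bottlenecks: frozenset
    ssgs: frozenset
    union: frozenset
    overlap_hub_bottleneck: int
    overlap_hub_ssg: int
    overlap_bottleneck_ssg: int
    overlap_all_three: int
    union_size: int
    sspin_edges: int | None = None

    def summary(self) -> str:
        lines = [
            f"hubs: {len(self.hubs)}",
            f"bottlenecks: {len(self.bottlenecks)}",
            f"salt-sensitivity genes: {len(self.ssgs)}",
            f"hub & bottleneck overlap: {self.overlap_hub_bottleneck}",
            f"hub & SSG overlap: {self.overlap_hub_ssg}",
            f"bottleneck & SSG overlap: {self.overlap_bottleneck_ssg}",
            f"triple overlap: {self.overlap_all_three}",
            f"HBS union: {self.union_size}",
        ]
        if self.sspin_edges is not None:
            lines.append(f"SS-PIN edges: {self.sspin_edges}")
        return "\n".join(lines)


def assemble_hbs(
    hubs: Iterable[str],
    bottlenecks: Iterable[str],
    ssgs: Iterable[str],
    pin: nx.Graph | None = None,
) -> HBSReport:
    """Group hubs, bottlenecks and SSGs into the HBS union with overlap counts.

    When the cleaned interaction network ``pin`` is given, the SS-PIN edge
    count (edges of the induced subgraph on the union) is included.
    """
    h = frozenset(str(g).upper() for g in hubs)
    b = frozenset(str(g).upper() for g in bottlenecks)
    s = frozenset(str(g).upper() for g in ssgs)
    union = h | b | s
    edges = extract_sspin(pin, union).number_of_edges() if pin is not None else None
    return HBSReport(
        hubs=h,
        bottlenecks=b,
        ssgs=s,
        union=union,
        overlap_hub_bottleneck=len(h & b),
        overlap_hub_ssg=len(h & s),
        overlap_bottleneck_ssg=len(b & s),
        overlap_all_three=len(h & b & s),
        union_size=len(union),
        sspin_edges=edges,
    )


def extract_sspin(pin: nx.Graph, hbs_union: Iterable[str]) -> nx.Graph:
    """Induced subgraph of the interaction network on the HBS union."""
    return induced_subgraph(pin, hbs_union)


def edge_node_ratio(network: nx.Graph) -> float:
    """``|edges| / |nodes|`` — the average connectivity summary of a network."""
    n = network.number_of_nodes()
    if n == 0:
        raise ValidationError("edge/node ratio undefined for an empty network")
    return network.number_of_edges() / n
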