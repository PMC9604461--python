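"""Confidence-filtered PPI subnetworks and MCODE-style dense-module detection.

The subnetwork keeps only interactions whose two endpoints both belong to
the feature list of interest (e.g. the up-regulated proteins of a contrast)
and whose confidence score reaches the threshold — 0.7 being the customary
"high confidence" cut for STRING-style scores.  Modules are found with the
MCODE vertex-weighting scheme: each node is weighted by the product of the
highest k-core number of its closed neighbourhood and that core's density;
modules grow outward from the highest-weight seed, admitting neighbours
whose weight stays within a percentage of the seed weight, with an optional
"haircut" that prunes singly-connected members.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .errors import FormatError

__all__ = ["Module", "build_subnetwork", "mcode_weights", "mcode_modules", "modules_frame"]


@dataclass(frozen=True)
class Module:
    members: tuple[str, ...]
    seed: str
    density: float
    score: float  # density × size

    @property
    def size(self) -> int:
        return len(self.members)


def build_subnetwork(
    edges: pd.DataFrame,
    selected: set[str],
    min_confidence: float = 0.7,
) -> nx.Graph:
    """Induced subgraph on ``selected`` keeping edges with confidence ≥ cut.

    Isolated selected nodes are not added; the result contains exactly the
    nodes incident to at least one retained edge.
    """
    graph = nx.Graph()
    for row in edges.itertuples(index=False):
        a, b, conf = row.node_a, row.node_b, float(row.confidence)
        if a == b:
            raise FormatError(f"self-loop on {a!r}")
        if a in selected and b in selected and conf >= min_confidence:
            if graph.has_edge(a, b):
                raise FormatError(f"duplicate edge {a!r}–{b!r}")
            graph.add_edge(a, b, confidence=conf)
    return graph


def _density(graph: nx.Graph) -> float:
    n = graph.number_of_nodes()
    if n < 2:
        return 0.0
    return 2.0 * graph.number_of_edges() / (n * (n - 1))


def mcode_weights(graph: nx.Graph) -> dict[str, float]:
    """MCODE vertex weights: k × density of the highest k-core of the
    closed neighbourhood of each node."""
    weights: dict[str, float] = {}
    for node in graph.nodes:
        closed = graph.subgraph([node, *graph.neighbors(node)])
        core_numbers = nx.core_number(closed)
        k = max(core_numbers.values())
        core = closed.subgraph([v for v, c in core_numbers.items() if c >= k])
        weights[node] = k * _density(core)
    return weights


def mcode_modules(
    graph: nx.Graph,
    vwp: float = 0.2,
    haircut: bool = True,
    fluff: bool = False,
    min_size: int = 3,
) -> list[Module]:
    """Grow disjoint dense modules from high-weight seeds.

    Seeds are taken in decreasing weight order (node id breaks ties, so the
    output is independent of edge insertion order).  From a seed, a
    breadth-first expansion admits unassigned neighbours whose weight is at
    least ``(1 − vwp) ×`` the seed weight.  ``haircut`` iteratively removes
    members with fewer than two connections inside the module.  Modules
    with at least ``min_size`` members are returned ranked by score
    (density × size, descending).
    """
    if not 0.0 <= vwp < 1.0:
        raise FormatError("vwp must be in [0, 1)")
    if fluff:
        raise NotImplementedError("fluff expansion is not implemented")
    weights = mcode_weights(graph)
    assigned: set[str] = set()
    modules: list[Module] = []
    for seed in sorted(graph.nodes, key=lambda v: (-weights[v], str(v))):
        if seed in assigned:
            continue
        threshold = (1.0 - vwp) * weights[seed]
        members = {seed}
        frontier = [seed]
        while frontier:
            nxt = []
            for v in frontier:
                for u in sorted(graph.neighbors(v), key=str):
                    if u in members or u in assigned:
                        continue
                    if weights[u] >= threshold:
                        members.add(u)
                        nxt.append(u)
            frontier = nxt
        if haircut:
            while True:
                sub = graph.subgraph(members)
                trim = {v for v in members if sub.degree(v) < 2}
                if not trim or len(members) - len(trim) < 2:
                    members -= trim
                    break
                members -= trim
        if len(members) < min_size:
            assigned.add(seed)  # a failed seed never seeds again
            continue
        assigned |= members
        sub = graph.subgraph(members)
        density = _density(sub)
        modules.append(
            Module(
                members=tuple(sorted(members)),
                seed=seed,
                density=density,
                score=density * len(members),
            )
        )
    return sorted(modules, key=lambda m: (-m.score, m.members))


def modules_frame(modules: list[Module]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "module": i + 1,
                "score": m.score,
                "size": m.size,
                "density": m.density,
                "seed": m.seed,
                "members": ";".join(m.members),
            }
            for i, m in enumerate(modules)
        ]
    )
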