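"""Scored undirected gene networks and their edge-list serialization."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

Pair = tuple[str, str]

METHODS = ("wgcna", "ggm", "bc3net")
DATASETS = ("raw", "fpkm", "uq", "tmm", "rle", "vst")


def pair(a: str, b: str) -> Pair:
    """Canonical unordered gene pair (lexicographically sorted)."""
    if a == b:
        raise ValueError(f"self-loop on {a!r}")
    return (a, b) if a < b else (b, a)


@dataclass
class ScoredNetwork:
    """An undirected network of gene pairs with non-negative confidence scores.

    ``provenance`` carries (method, dataset) tags for initial networks and
    free-form tags (e.g. ``("consensus", "final")``) downstream. ``support``
    optionally counts contributing source networks per edge after voting.
    """

    edges: dict[Pair, float]
    node_universe: set[str]
    provenance: tuple[str, str] = ("", "")
    support: dict[Pair, int] | None = None

    def __post_init__(self) -> None:
        for (a, b), s in self.edges.items():
            if a >= b:
                raise ValueError(f"pair ({a!r}, {b!r}) not in canonical order")
            if a not in self.node_universe or b not in self.node_universe:
                raise ValueError(f"edge endpoint outside node universe: {(a, b)}")
            if not np.isfinite(s):
                raise ValueError(f"non-finite score on {(a, b)}")

    def __len__(self) -> int:
        return len(self.edges)

    def __contains__(self, p: Pair) -> bool:
        return p in self.edges

    @property
    def pairs(self) -> set[Pair]:
        return set(self.edges)

    def nodes_with_edges(self) -> set[str]:
        out: set[str] = set()
        for a, b in self.edges:
            out.add(a)
            out.add(b)
        return out

    def top(self, k: int) -> list[tuple[Pair, float]]:
        """Top-k edges by descending score, ties broken by pair id."""
        return sorted(self.edges.items(), key=lambda kv: (-kv[1], kv[0]))[:k]

    def to_graph(self):
        import networkx as nx

        g = nx.Graph()
        for (a, b), s in self.edges.items():
            g.add_edge(a, b, weight=s)
        return g


def from_score_matrix(
    scores: np.ndarray,
    gene_ids: list[str],
    provenance: tuple[str, str],
    threshold: float = 0.0,
) -> ScoredNetwork:
    """Build a network from a symmetric score matrix, keeping scores >= threshold."""
    n = len(gene_ids)
    iu, ju = np.triu_indices(n, k=1)
    keep = scores[iu, ju] >= threshold
    edges = {
        pair(gene_ids[i], gene_ids[j]): float(scores[i, j])
        for i, j in zip(iu[keep], ju[keep])
    }
    return ScoredNetwork(edges=edges, node_universe=set(gene_ids), provenance=provenance)


def write_edge_list(net: ScoredNetwork, path: str | Path) -> None:
    """Tab-separated ``geneA geneB score [support]`` with a provenance header.

    geneA < geneB lexicographically; rows sorted by descending score then pair.
    """
    with open(path, "w") as fh:
        fh.write(f"# method={net.provenance[0]}\tdataset={net.provenance[1]}\n")
        rows = sorted(net.edges.items(), key=lambda kv: (-kv[1], kv[0]))
        for (a, b), s in rows:
            if net.support is not None:
                fh.write(f"{a}\t{b}\t{s:.10g}\t{net.support.get((a, b), 0)}\n")
            else:
                fh.write(f"{a}\t{b}\t{s:.10g}\n")


def read_edge_list(path: str | Path, node_universe: set[str] | None = None) -> ScoredNetwork:
    """Read a two- or three-column edge list (third column = score, default 1)."""
    edges: dict[Pair, float] = {}
    support: dict[Pair, int] = {}
    provenance = ("", "")
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                fields = dict(
                    f.split("=", 1) for f in line[1:].strip().split("\t") if "=" in f
                )
                provenance = (fields.get("method", ""), fields.get("dataset", ""))
                continue
            parts = line.split("\t")
            p = pair(parts[0], parts[1])
            edges[p] = float(parts[2]) if len(parts) > 2 else 1.0
            if len(parts) > 3:
                support[p] = int(parts[3])
    universe = node_universe or {g for p in edges for g in p}
    return ScoredNetwork(
        edges=edges,
        node_universe=universe,
        provenance=provenance,
        support=support or None,
    )
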