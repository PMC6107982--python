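"""Edge-list / partition file formats, network summaries, run manifests.

The edge-list dialect is one undirected edge per line,
``nodeA<whitespace>nodeB[<whitespace>weight]``, with ``#`` comment lines;
node identifiers are arbitrary strings (gene symbols, integers, ...).
Self-loops are dropped with a warning, duplicate edges have their weights
summed, and a missing weight defaults to 1.0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict
from typing import Optional, Sequence

import networkx as nx

from .model import Layer, Partition

logger = logging.getLogger(__name__)

__all__ = [
    "read_edge_list",
    "write_edge_list",
    "read_partition",
    "write_partition",
    "NetworkSummary",
    "network_summary",
    "density_from_counts",
    "format_density",
    "RunManifest",
]


def read_edge_list(path, name: Optional[str] = None) -> Layer:
    """Read one layer from an edge-list file (dialect above).

    Malformed lines raise :class:`ValueError` naming the file and line
    number.  Zero-weight edges are treated as absent; negative weights are
    rejected.
    """
    g = nx.Graph()
    n_loops = 0
    n_dups = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) not in (2, 3):
                raise ValueError(f"{path}:{lineno}: expected 2 or 3 fields, "
                                 f"got {len(fields)}: {line!r}")
            u, v = fields[0], fields[1]
            if len(fields) == 3:
                try:
                    w = float(fields[2])
                except ValueError:
                    raise ValueError(f"{path}:{lineno}: invalid weight "
                                     f"{fields[2]!r}") from None
            else:
                w = 1.0
            if u == v:
                n_loops += 1
                continue
            if w < 0:
                raise ValueError(f"{path}:{lineno}: negative weight {w}")
            if w == 0:
                continue
            if g.has_edge(u, v):
                g[u][v]["weight"] += w
                n_dups += 1
            else:
                g.add_edge(u, v, weight=w)
    if n_loops:
        logger.warning("%s: dropped %d self-loop line(s)", path, n_loops)
    if n_dups:
        logger.warning("%s: summed weights of %d duplicate edge line(s)",
                       path, n_dups)
    return Layer(g, name=name if name is not None else str(path))


def write_edge_list(layer: Layer, path) -> None:
    """Write a layer as ``u<TAB>v<TAB>weight`` lines, sorted for determinism."""
    rows = sorted(
        (str(u), str(v), layer.graph[u][v].get("weight", 1.0))
        for u, v in layer.graph.edges
    )
    with open(path, "w") as fh:
        for u, v, w in rows:
            fh.write(f"{u}\t{v}\t{w:g}\n")


def read_partition(path) -> Partition:
    """Read ``vertex<TAB>community`` lines into a Partition."""
    assignment = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 fields, "
                                 f"got {len(fields)}")
            assignment[fields[0]] = fields[1]
    if not assignment:
        raise ValueError(f"{path}: empty partition file")
    return Partition(assignment)


def write_partition(part: Partition, path) -> None:
    """Write ``vertex<TAB>communityID`` lines (vertices sorted as strings)."""
    with open(path, "w") as fh:
        for v in sorted(part.vertices(), key=str):
            fh.write(f"{v}\t{part[v]}\n")


@dataclass(frozen=True)
class NetworkSummary:
    """Vertex count, count of distinct positive-weight edges, and density."""

    n_nodes: int
    n_edges: int
    density: float


def density_from_counts(n_nodes: int, n_edges: int) -> float:
    """Edge density ``E / (N (N-1) / 2)`` of an undirected simple graph."""
    if n_nodes < 2:
        logger.warning("density undefined for fewer than 2 nodes; reporting 0")
        return 0.0
    return n_edges / (n_nodes * (n_nodes - 1) / 2)


def network_summary(layer: Layer) -> NetworkSummary:
    """Node count, distinct-edge count and density of one layer."""
    g = layer.graph
    n_nodes = g.number_of_nodes()
    n_edges = sum(1 for u, v in g.edges if u != v)
    return NetworkSummary(n_nodes=n_nodes, n_edges=n_edges,
                          density=density_from_counts(n_nodes, n_edges))


def format_density(x: float) -> str:
    """Render a density with 3 significant digits in scientific notation."""
    return f"{x:.2e}"


@dataclass(frozen=True)
class RunManifest:
    """Everything needed to reproduce a clustering run byte-for-byte."""

    version: str
    layer_files: tuple
    layer_names: tuple
    layer_weights: tuple
    gamma: float
    n_runs: int
    seed: Optional[int]
    recursive: bool
    max_size: int
    filter_min: int
    filter_max: int
    score: float
    n_communities: int

    def write(self, path) -> None:
        with open(path, "w") as fh:
            for key, value in asdict(self).items():
                if isinstance(value, tuple):
                    value = ",".join(str(x) for x in value)
                fh.write(f"{key}={value}\n")

    @classmethod
    def read(cls, path) -> "RunManifest":
        raw = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                key, _, value = line.partition("=")
                raw[key] = value
        split = lambda s: tuple(s.split(",")) if s else ()
        return cls(
            version=raw["version"],
            layer_files=split(raw["layer_files"]),
            layer_names=split(raw["layer_names"]),
            layer_weights=tuple(float(x) for x in split(raw["layer_weights"])),
            gamma=float(raw["gamma"]),
            n_runs=int(raw["n_runs"]),
            seed=None if raw["seed"] == "None" else int(raw["seed"]),
            recursive=raw["recursive"] == "True",
            max_size=int(raw["max_size"]),
            filter_min=int(raw["filter_min"]),
            filter_max=int(raw["filter_max"]),
            score=float(raw["score"]),
            n_communities=int(raw["n_communities"]),
        )
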