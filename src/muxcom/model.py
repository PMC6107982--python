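"""Core data model for multiplex networks and the multiplex modularity score.

A *multiplex network* is an ordered collection of undirected, weighted graph
layers sharing one vertex universe (the union of the layers' vertex sets);
there are no inter-layer edges.  Communities are scored by the multiplex
modularity

    Q(P) = sum_g  w_g / (2 m_g) *
           sum_{unordered pairs {i,j}, i != j, c_i = c_j}
               ( X_ij^g  -  gamma * S_i^g S_j^g / (2 m_g) )

where, per layer g, ``X_ij^g`` is the edge weight, ``m_g`` the total edge
weight, ``S_i^g`` the (weighted) vertex strength, ``w_g`` a user-defined
nonnegative layer weight, and ``gamma`` the resolution parameter (larger
gamma favours smaller communities).  A vertex absent from a layer simply has
strength 0 there; an empty layer (m_g = 0) contributes 0.

The score is the per-layer Newman-Girvan null-model comparison summed over
layers, written over unordered vertex pairs excluding i = j.  Self-loops
(which arise when communities are contracted to super-vertices) are excluded
from the pair sum but do count toward m_g and the strengths, keeping
``sum_i S_i = 2 m`` true throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Hashable, Iterable, Mapping, Sequence

import networkx as nx

logger = logging.getLogger(__name__)

Vertex = Hashable

__all__ = [
    "Layer",
    "LayerStats",
    "LayerWeights",
    "MultiplexNetwork",
    "Partition",
    "layer_stats",
    "modularity_gain",
    "multiplex_modularity",
    "subnetwork",
]


class Layer:
    """One undirected weighted layer, backed by a :class:`networkx.Graph`.

    Edge weights default to 1.0 when the ``weight`` attribute is missing.
    Weights must be positive; zero-weight edges are treated as absent and
    negative weights are rejected.  Self-loops are permitted here (community
    contraction produces them) but are dropped by the edge-list reader.
    """

    __slots__ = ("graph", "name")

    def __init__(self, graph: nx.Graph | None = None, name: str | None = None,
                 validate: bool = False):
        self.graph = nx.Graph() if graph is None else graph
        self.name = name
        if validate:
            self._validate()

    def _validate(self) -> None:
        g = self.graph
        drop = []
        for u, v, w in g.edges(data="weight", default=1.0):
            if w < 0:
                raise ValueError(f"negative edge weight {w!r} on ({u!r}, {v!r})")
            if w == 0:
                drop.append((u, v))
        if drop:
            logger.warning("dropping %d zero-weight edges", len(drop))
            g.remove_edges_from(drop)

    @classmethod
    def from_edges(cls, edges: Iterable[tuple], name: str | None = None) -> "Layer":
        """Build a layer from ``(u, v)`` or ``(u, v, weight)`` tuples.

        Duplicate edges have their weights summed; self-loops are dropped
        with a warning; missing weights default to 1.0.
        """
        g = nx.Graph()
        n_loops = 0
        for e in edges:
            if len(e) == 2:
                u, v = e
                w = 1.0
            else:
                u, v, w = e
                w = float(w)
            if u == v:
                n_loops += 1
                continue
            if w < 0:
                raise ValueError(f"negative edge weight {w!r} on ({u!r}, {v!r})")
            if w == 0:
                continue
            if g.has_edge(u, v):
                g[u][v]["weight"] += w
            else:
                g.add_edge(u, v, weight=w)
        if n_loops:
            logger.warning("dropped %d self-loop(s)%s", n_loops,
                           f" in layer {name!r}" if name else "")
        return cls(g, name=name)

    @property
    def vertex_set(self) -> set:
        return set(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def weight(self, u: Vertex, v: Vertex) -> float:
        """Weight of edge {u, v}, 0.0 if absent (symmetric by construction)."""
        data = self.graph.get_edge_data(u, v)
        return 0.0 if data is None else data.get("weight", 1.0)

    def copy(self) -> "Layer":
        return Layer(self.graph.copy(), name=self.name)

    def __repr__(self) -> str:  # pragma: no cover
        return (f"Layer(name={self.name!r}, n={self.graph.number_of_nodes()}, "
                f"edges={self.graph.number_of_edges()})")


@dataclass(frozen=True)
class LayerStats:
    """Total edge weight ``m`` and per-vertex strengths of one layer."""

    m: float
    strength: Mapping[Vertex, float]


def layer_stats(layer: Layer) -> LayerStats:
    """Compute ``m`` (sum of edge weights) and vertex strengths.

    A self-loop counts once in ``m`` and twice in its vertex's strength, so
    ``sum(strength) == 2 m`` always holds.  An empty layer gives m = 0.
    """
    g = layer.graph
    m = g.size(weight="weight")
    strength = dict(g.degree(weight="weight"))
    return LayerStats(m=float(m), strength=strength)


class LayerWeights(tuple):
    """Nonnegative per-layer weights w_g; at least one must be positive."""

    def __new__(cls, values: Iterable[float]) -> "LayerWeights":
        vals = tuple(float(v) for v in values)
        if not vals:
            raise ValueError("layer weights must be non-empty")
        if any(v < 0 for v in vals):
            raise ValueError("layer weights must be nonnegative")
        if not any(v > 0 for v in vals):
            raise ValueError("at least one layer weight must be positive")
        return super().__new__(cls, vals)


class MultiplexNetwork:
    """Ordered list of layers over the union of their vertex sets.

    The universe order is first-appearance order (layer by layer), which
    fixes the deterministic sweep order of the optimizer.
    """

    __slots__ = ("layers", "layer_names", "universe", "_index")

    def __init__(self, layers: Sequence[Layer],
                 layer_names: Sequence[str] | None = None):
        layers = list(layers)
        if not layers:
            raise ValueError("a multiplex network needs at least one layer")
        if layer_names is None:
            layer_names = [lay.name or f"layer{i + 1}" for i, lay in enumerate(layers)]
        layer_names = [str(s) for s in layer_names]
        if len(layer_names) != len(layers):
            raise ValueError("layer_names length must match the number of layers")
        universe: dict = {}
        for lay in layers:
            for v in lay.graph.nodes:
                universe.setdefault(v, None)
        self.layers = layers
        self.layer_names = layer_names
        self.universe = tuple(universe)
        self._index = {v: i for i, v in enumerate(self.universe)}

    @classmethod
    def from_graphs(cls, graphs: Sequence[nx.Graph],
                    layer_names: Sequence[str] | None = None) -> "MultiplexNetwork":
        return cls([Layer(g) for g in graphs], layer_names)

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    @property
    def n_vertices(self) -> int:
        return len(self.universe)

    def index(self, vertex: Vertex) -> int:
        return self._index[vertex]

    def __repr__(self) -> str:  # pragma: no cover
        return (f"MultiplexNetwork(layers={self.layer_names}, "
                f"n_vertices={self.n_vertices})")


class Partition:
    """Total, non-overlapping assignment of vertices to communities.

    Labels are canonicalized to consecutive integers in first-seen order of
    the vertices, so two equal partitions compare (and hash) equal whatever
    labels they were built with.
    """

    __slots__ = ("assignment", "_communities", "_hash")

    def __init__(self, assignment: Mapping[Vertex, Hashable],
                 universe: Sequence[Vertex] | None = None):
        order = universe if universe is not None else assignment.keys()
        canon: dict = {}
        relabel: dict = {}
        for v in order:
            lab = assignment[v]
            if lab not in relabel:
                relabel[lab] = len(relabel)
            canon[v] = relabel[lab]
        if universe is not None and len(canon) != len(assignment):
            extra = set(assignment) - set(canon)
            raise ValueError(f"assignment has vertices outside the universe: "
                             f"{sorted(map(repr, extra))[:5]}")
        self.assignment = canon
        self._communities = None
        self._hash = None

    @classmethod
    def from_communities(cls, communities: Iterable[Iterable[Vertex]]) -> "Partition":
        assignment: dict = {}
        for lab, comm in enumerate(communities):
            members = list(comm)
            if not members:
                raise ValueError("communities must be non-empty")
            for v in members:
                if v in assignment:
                    raise ValueError(f"vertex {v!r} appears in two communities")
                assignment[v] = lab
        return cls(assignment)

    @classmethod
    def singletons(cls, vertices: Iterable[Vertex]) -> "Partition":
        return cls({v: i for i, v in enumerate(vertices)})

    @property
    def communities(self) -> dict:
        """Mapping label -> frozenset of member vertices (cached)."""
        if self._communities is None:
            groups: dict = {}
            for v, lab in self.assignment.items():
                groups.setdefault(lab, []).append(v)
            self._communities = {lab: frozenset(ms) for lab, ms in groups.items()}
        return self._communities

    @property
    def n_communities(self) -> int:
        return len(self.communities)

    def vertices(self):
        return self.assignment.keys()

    def restrict(self, vertices: Iterable[Vertex]) -> "Partition":
        """Partition induced on a vertex subset (labels re-canonicalized)."""
        sub = {v: self.assignment[v] for v in vertices if v in self.assignment}
        if not sub:
            raise ValueError("restriction to an empty vertex set")
        return Partition(sub)

    def __getitem__(self, vertex: Vertex):
        return self.assignment[vertex]

    def __contains__(self, vertex: Vertex) -> bool:
        return vertex in self.assignment

    def __len__(self) -> int:
        return len(self.assignment)

    def __eq__(self, other) -> bool:
        if not isinstance(other, Partition):
            return NotImplemented
        return self.assignment == other.assignment

    def __hash__(self) -> int:
        if self._hash is None:
            self._hash = hash(frozenset(self.assignment.items()))
        return self._hash

    def __repr__(self) -> str:  # pragma: no cover
        return f"Partition(n={len(self)}, communities={self.n_communities})"


def _resolve_weights(net: MultiplexNetwork,
                     layer_weights: Sequence[float] | None) -> tuple:
    if layer_weights is None:
        return tuple([1.0] * net.n_layers)
    lw = tuple(float(v) for v in layer_weights)
    if any(v < 0 for v in lw):
        raise ValueError("layer weights must be nonnegative")
    if len(lw) != net.n_layers:
        raise ValueError(f"{len(lw)} layer weights given for "
                         f"{net.n_layers} layers")
    return lw


def _check_coverage(net: MultiplexNetwork, part: Partition) -> None:
    missing = [v for v in net.universe if v not in part]
    if missing:
        raise ValueError(f"partition does not cover the universe; e.g. missing "
                         f"{missing[:5]!r}")


def multiplex_modularity(net: MultiplexNetwork, part: Partition,
                         gamma: float = 1.0,
                         layer_weights: Sequence[float] | None = None) -> float:
    """Multiplex modularity of a partition (see module docstring).

    Layers with zero total weight or zero layer weight contribute 0.
    Deterministic for fixed inputs.
    """
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    lw = _resolve_weights(net, layer_weights)
    _check_coverage(net, part)
    score = 0.0
    for layer, w in zip(net.layers, lw):
        if w == 0:
            continue
        g = layer.graph
        m = g.size(weight="weight")
        if m == 0:
            continue
        assignment = part.assignment
        intra = 0.0
        for u, v, wt in g.edges(data="weight", default=1.0):
            if u != v and assignment[u] == assignment[v]:
                intra += wt
        deg = dict(g.degree(weight="weight"))
        null = 0.0
        for members in part.communities.values():
            s1 = 0.0
            s2 = 0.0
            for v in members:
                d = deg.get(v, 0.0)
                s1 += d
                s2 += d * d
            null += (s1 * s1 - s2) / 2.0
        score += w / (2.0 * m) * (intra - gamma * null / (2.0 * m))
    return score


def modularity_gain(net: MultiplexNetwork, part: Partition, vertex: Vertex,
                    target: Hashable | None, gamma: float = 1.0,
                    layer_weights: Sequence[float] | None = None,
                    stats: Sequence[LayerStats] | None = None) -> float:
    """Incremental change in multiplex modularity from moving one vertex.

    ``target`` is an existing community label of ``part`` or ``None`` for
    "detach into a new singleton".  Matches the difference of two full
    score evaluations to ~1e-12 (it is the same sum, cancelled analytically).

    Per layer the move of vertex v from community a to community b changes
    the score by  w/(2m) * [ (k_{v->b} - k_{v->a\\{v}})
                              - gamma * S_v (T_b - T_{a\\{v}}) / (2m) ]
    where k_{v->C} is the weight from v to C and T_C the strength total of C.
    """
    lw = _resolve_weights(net, layer_weights)
    _check_coverage(net, part)
    if vertex not in part:
        raise ValueError(f"unknown vertex {vertex!r}")
    current = part[vertex]
    if target is not None and target not in part.communities:
        raise ValueError(f"unknown target community {target!r}")
    if target == current:
        return 0.0
    if stats is None:
        stats = [layer_stats(lay) for lay in net.layers]
    assignment = part.assignment
    target_members = part.communities[target] if target is not None else frozenset()
    delta = 0.0
    for layer, w, st in zip(net.layers, lw, stats):
        if w == 0 or st.m == 0:
            continue
        g = layer.graph
        sv = st.strength.get(vertex, 0.0)
        k_cur = 0.0
        k_tgt = 0.0
        if vertex in g:
            for u, data in g[vertex].items():
                if u == vertex:
                    continue
                wt = data.get("weight", 1.0)
                lab = assignment[u]
                if lab == current:
                    k_cur += wt
                if target is not None and lab == target:
                    k_tgt += wt
        t_cur = sum(st.strength.get(u, 0.0)
                    for u in part.communities[current]) - sv
        t_tgt = sum(st.strength.get(u, 0.0) for u in target_members)
        delta += w / (2.0 * st.m) * (
            (k_tgt - k_cur) - gamma * sv * (t_tgt - t_cur) / (2.0 * st.m))
    return delta


def subnetwork(net: MultiplexNetwork, vertices: Iterable[Vertex]) -> MultiplexNetwork:
    """Restrict every layer to the induced subgraph on ``vertices``.

    The result's universe is exactly the given subset, in original universe
    order; vertices outside the subset (and edges touching them) are gone.
    """
    subset = set(vertices)
    if not subset:
        raise ValueError("vertex subset must be non-empty")
    unknown = subset - set(net.universe)
    if unknown:
        raise ValueError(f"vertices not in universe: {sorted(map(repr, unknown))[:5]}")
    ordered = [v for v in net.universe if v in subset]
    layers = []
    for lay in net.layers:
        keep = [v for v in ordered if v in lay.graph]
        sg = nx.Graph()
        sg.add_nodes_from(keep)
        for u, v, wt in lay.graph.edges(data="weight", default=1.0):
            if u in subset and v in subset:
                sg.add_edge(u, v, weight=wt)
        layers.append(Layer(sg, name=lay.name))
    return MultiplexNetwork(layers, net.layer_names)
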