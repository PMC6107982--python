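"""Stochastic-block-model simulator for multiplex networks.

Generates planted-partition multiplexes for validating community detection:
``n`` vertices in ``k`` balanced blocks; each layer is an independent SBM
draw in which a pair of vertices is joined (unit weight) with probability
``p_in`` inside a block and ``p_out`` between blocks.  Two canonical
regimes are provided — sparse (0.1, 0.01) and dense (0.5, 0.2) — plus a
mixed mode that samples each layer's regime uniformly between the two.

Missing data is emulated by deleting vertices (with their incident edges):
either independently per layer with a fixed probability (default; a vertex
can survive in some layers and not others) or globally, removing exactly
half of the vertices from every layer at once.  The planted partition is
always kept on the original vertex set; evaluation restricts to survivors.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence, Tuple

import networkx as nx
import numpy as np

from .model import Layer, MultiplexNetwork, Partition

__all__ = [
    "SPARSE",
    "DENSE",
    "SBMSpec",
    "PlantedInstance",
    "simulate",
    "simulate_block_matrix",
    "apply_missing",
    "write_instance",
]

SPARSE: Tuple[float, float] = (0.1, 0.01)
DENSE: Tuple[float, float] = (0.5, 0.2)


@dataclass(frozen=True)
class SBMSpec:
    """Planted-partition simulation parameters.

    regimes
        Optional explicit per-layer ``(p_in, p_out)`` pairs (length
        ``n_layers``); overrides ``regime``/``mixed``.
    regime
        The single ``(p_in, p_out)`` pair used for every layer when
        ``regimes`` is not given (default sparse).
    mixed
        Sample each layer's pair uniformly from {sparse, dense}.
    missing_mode
        ``"per_layer"``: each vertex removed from each layer independently
        with probability ``missing_prob``; ``"global"``: exactly
        ``floor(n * missing_prob)`` vertices removed from all layers.
    """

    n: int = 1000
    k: int = 20
    n_layers: int = 2
    regime: Tuple[float, float] = SPARSE
    regimes: Optional[Sequence[Tuple[float, float]]] = None
    mixed: bool = False
    missing_prob: float = 0.0
    missing_mode: str = "per_layer"
    seed: Optional[int] = None

    def __post_init__(self):
        if self.n < 2 or self.k < 1 or self.k > self.n:
            raise ValueError("need n >= 2 and 1 <= k <= n")
        if self.n_layers < 1:
            raise ValueError("n_layers must be >= 1")
        if not 0.0 <= self.missing_prob < 1.0:
            raise ValueError("missing_prob must be in [0, 1)")
        if self.missing_mode not in ("per_layer", "global"):
            raise ValueError("missing_mode must be 'per_layer' or 'global'")
        pairs = self.regimes if self.regimes is not None else [self.regime]
        for p_in, p_out in pairs:
            if not (0.0 <= p_out <= p_in <= 1.0):
                raise ValueError(f"need 0 <= p_out <= p_in <= 1, "
                                 f"got ({p_in}, {p_out})")
        if self.regimes is not None and len(self.regimes) != self.n_layers:
            raise ValueError("regimes length must equal n_layers")


@dataclass(frozen=True)
class PlantedInstance:
    """A simulated multiplex plus the partition it was generated from."""

    network: MultiplexNetwork
    planted: Partition
    spec: Optional[SBMSpec] = None


def _block_sizes(n: int, k: int) -> list:
    """Balanced block sizes (differing by at most 1 when k does not divide n)."""
    base, extra = divmod(n, k)
    return [base + (1 if i < extra else 0) for i in range(k)]


def _child_seeds(seed, count):
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2 ** 31) for s in ss.generate_state(count, dtype=np.uint64)]


def simulate_block_matrix(sizes: Sequence[int], p: Sequence[Sequence[float]],
                          n_layers: int = 1, seed: Optional[int] = None,
                          spec: Optional[SBMSpec] = None) -> PlantedInstance:
    """Draw a multiplex from an explicit block-probability matrix.

    Every layer is an independent draw from the same block model; vertices
    are 0..n-1 (all present in every layer, including isolated ones) and the
    planted partition is the block structure.
    """
    seeds = _child_seeds(seed, n_layers)
    layers = []
    for g in range(n_layers):
        graph = nx.stochastic_block_model(list(sizes), [list(r) for r in p],
                                          seed=seeds[g])
        del graph.graph["partition"]
        layers.append(Layer(graph, name=f"layer{g + 1}"))
    assignment = {}
    v = 0
    for b, size in enumerate(sizes):
        for _ in range(size):
            assignment[v] = b
            v += 1
    planted = Partition(assignment)
    net = MultiplexNetwork(layers)
    return PlantedInstance(network=net, planted=planted, spec=spec)


def simulate(spec: SBMSpec, seed: Optional[int] = None) -> PlantedInstance:
    """Draw a planted-partition multiplex according to ``spec``.

    ``seed`` overrides ``spec.seed`` when given.  Layers are independent;
    missing data (if requested) is applied after the draw, with its own
    substream, so the planted partition always covers the original
    n vertices while the network universe may be smaller.
    """
    base = seed if seed is not None else spec.seed
    ss = np.random.SeedSequence(base)
    regime_ss, layers_ss, missing_ss = ss.spawn(3)
    if spec.regimes is not None:
        pairs = list(spec.regimes)
    elif spec.mixed:
        rng = np.random.default_rng(regime_ss)
        picks = rng.integers(0, 2, size=spec.n_layers)
        pairs = [SPARSE if c == 0 else DENSE for c in picks]
    else:
        pairs = [spec.regime] * spec.n_layers
    sizes = _block_sizes(spec.n, spec.k)
    layer_seeds = [int(s) % (2 ** 31)
                   for s in layers_ss.generate_state(spec.n_layers,
                                                     dtype=np.uint64)]
    layers = []
    for g, (p_in, p_out) in enumerate(pairs):
        p = [[p_in if i == j else p_out for j in range(spec.k)]
             for i in range(spec.k)]
        graph = nx.stochastic_block_model(sizes, p, seed=layer_seeds[g])
        del graph.graph["partition"]
        layers.append(Layer(graph, name=f"layer{g + 1}"))
    assignment = {}
    v = 0
    for b, size in enumerate(sizes):
        for _ in range(size):
            assignment[v] = b
            v += 1
    instance = PlantedInstance(network=MultiplexNetwork(layers),
                               planted=Partition(assignment), spec=spec)
    if spec.missing_prob > 0:
        instance = apply_missing(instance, spec.missing_prob,
                                 np.random.default_rng(missing_ss),
                                 mode=spec.missing_mode)
    return instance


def apply_missing(instance: PlantedInstance, missing_prob: float, rng,
                  mode: str = "per_layer") -> PlantedInstance:
    """Remove vertices (and their incident edges) to emulate missing data.

    ``per_layer``: each vertex is removed from each layer independently
    with probability ``missing_prob`` — removal in one layer leaves its
    edges in other layers untouched.  ``global``: one sample of exactly
    ``floor(n * missing_prob)`` vertices is removed from every layer.
    The planted partition is retained on the original vertex set.
    """
    if not 0.0 <= missing_prob < 1.0:
        raise ValueError("missing_prob must be in [0, 1)")
    if missing_prob == 0.0:
        return instance
    net = instance.network
    verts = list(net.universe)
    n = len(verts)
    new_layers = []
    if mode == "global":
        n_remove = int(np.floor(n * missing_prob))
        removed = {verts[int(i)]
                   for i in rng.choice(n, size=n_remove, replace=False)}
        for lay in net.layers:
            g = lay.graph.copy()
            g.remove_nodes_from([v for v in g.nodes if v in removed])
            new_layers.append(Layer(g, name=lay.name))
    elif mode == "per_layer":
        for lay in net.layers:
            mask = rng.random(n) < missing_prob
            removed = {verts[i] for i in range(n) if mask[i]}
            g = lay.graph.copy()
            g.remove_nodes_from([v for v in g.nodes if v in removed])
            new_layers.append(Layer(g, name=lay.name))
    else:
        raise ValueError("mode must be 'per_layer' or 'global'")
    return PlantedInstance(network=MultiplexNetwork(new_layers, net.layer_names),
                           planted=instance.planted, spec=instance.spec)


def write_instance(instance: PlantedInstance, prefix: str) -> list:
    """Write one edge-list file per layer plus the planted partition.

    Files are ``<prefix>.layer<i>.tsv`` (``u TAB v TAB weight``) and
    ``<prefix>.planted.tsv`` (``vertex TAB community``); both dialects are
    the ones the package readers consume.  Returns the paths written.
    """
    from .io import write_edge_list, write_partition  # avoid import cycle

    paths = []
    for i, lay in enumerate(instance.network.layers, start=1):
        path = f"{prefix}.layer{i}.tsv"
        write_edge_list(lay, path)
        paths.append(path)
    ppath = f"{prefix}.planted.tsv"
    write_partition(instance.planted, ppath)
    paths.append(ppath)
    return paths
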