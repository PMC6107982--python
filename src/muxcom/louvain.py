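"""Multiplex-adapted Louvain optimization of the multiplex modularity.

The algorithm starts from the all-singletons partition and alternates two
phases: a local-move phase that relocates single vertices between
communities as long as some move increases the score, and a contraction
phase that replaces each community by a super-vertex (intra-community weight
becomes a self-loop) and restarts the local moves on the smaller graph.

Two move policies are available:

* ``deterministic`` — classic Louvain: each vertex takes the move with the
  largest positive gain (ties keep the current community, then the
  lowest-labelled target).
* ``randomized`` — at each vertex a move is drawn uniformly at random among
  *all* strictly improving moves.  Different runs then usually end in
  different local optima; running the procedure N times and keeping the
  best-scoring partition ("best-of-N") is the recommended mode, and is
  what makes dense, noisy multiplexes tractable.

Internally the optimizer maximizes the aggregation-invariant (ordered-pair,
diagonal-included) form of the score, which differs from the reported
unordered-pair score only by a partition-independent offset per layer, so
both have the same argmax.  The reported score is always recomputed on the
original (uncontracted) network with :func:`muxcom.model.multiplex_modularity`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx
import numpy as np

from .model import (Layer, MultiplexNetwork, Partition, _check_coverage,
                    _resolve_weights, multiplex_modularity)

logger = logging.getLogger(__name__)

__all__ = [
    "OptimizerConfig",
    "ClusteringResult",
    "louvain_pass",
    "aggregate",
    "internal_modularity",
    "run_louvain",
]

_NEW = -1  # sentinel label: detach into a new singleton community


@dataclass(frozen=True)
class OptimizerConfig:
    """Parameters of the (randomized) Louvain optimizer.

    gamma
        Resolution parameter (> 0); larger values favour smaller communities.
    n_runs
        0 = a single deterministic run (classic Louvain); N >= 1 = N
        randomized runs, keeping the best-scoring partition.
    seed
        Base seed; run i uses an RNG seeded with ``(seed + i) % 2**31``.
        ``None`` draws a fresh base seed (recorded in the result).
    improvement_tolerance
        A move must improve the internal score by more than this to be
        accepted; guards against infinite loops from rounding noise.
    max_outer_iterations
        Safety cap on the number of move/contract levels per run.
    shuffle_sweep
        Extension flag: also shuffle the vertex visiting order each sweep in
        randomized mode (off by default; randomness then lies only in the
        move choice).
    """

    gamma: float = 1.0
    n_runs: int = 10
    seed: Optional[int] = None
    improvement_tolerance: float = 1e-10
    max_outer_iterations: int = 100
    shuffle_sweep: bool = False

    def __post_init__(self):
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.n_runs < 0:
            raise ValueError("n_runs must be >= 0")
        if self.improvement_tolerance <= 0:
            raise ValueError("improvement_tolerance must be positive")
        if self.max_outer_iterations < 1:
            raise ValueError("max_outer_iterations must be >= 1")


@dataclass(frozen=True)
class ClusteringResult:
    """Best partition found, its reported score, and run metadata."""

    partition: Partition
    score: float
    runs_performed: int
    best_run_index: int
    seed_used: Optional[int]
    run_scores: tuple = ()
    gamma: float = 1.0


class _Flat:
    """Integer-indexed view of the effective layers (w > 0 and m > 0)."""

    __slots__ = ("n", "vertices", "adj", "S", "a", "b", "L")

    def __init__(self, net: MultiplexNetwork, gamma: float,
                 lw: Sequence[float]):
        self.vertices = net.universe
        self.n = len(self.vertices)
        index = {v: i for i, v in enumerate(self.vertices)}
        self.adj = []
        self.S = []
        self.a = []  # w_g / m_g          (edge term scale)
        self.b = []  # w_g * gamma / (2 m_g^2)   (null term scale)
        for layer, w in zip(net.layers, lw):
            if w == 0:
                continue
            g = layer.graph
            m = g.size(weight="weight")
            if m == 0:
                continue
            rows = [dict() for _ in range(self.n)]
            for u, v, wt in g.edges(data="weight", default=1.0):
                iu, iv = index[u], index[v]
                if iu == iv:
                    rows[iu][iu] = rows[iu].get(iu, 0.0) + wt
                else:
                    rows[iu][iv] = wt
                    rows[iv][iu] = wt
            deg = dict(g.degree(weight="weight"))
            self.adj.append(rows)
            self.S.append([float(deg.get(v, 0.0)) for v in self.vertices])
            self.a.append(w / m)
            self.b.append(w * gamma / (2.0 * m * m))
        self.L = len(self.adj)


def _move_phase(adj, S, a, b, comm, csize, free, tol, randomized, rng,
                shuffle_sweep):
    """Local-move phase; mutates comm/csize/free, returns number of moves.

    Insertion scores are on the internal scale (2x the reported per-move
    gain), which preserves ordering and sign.
    """
    L = len(adj)
    n = len(comm)
    gs = range(L)
    tot = []
    for g in gs:
        t = [0.0] * n
        sg = S[g]
        for v in range(n):
            t[comm[v]] += sg[v]
        tot.append(t)
    total_moves = 0
    base_order = list(range(n))
    while True:
        sweep_moves = 0
        if shuffle_sweep and randomized:
            order = [int(x) for x in rng.permutation(n)]
        else:
            order = base_order
        for v in order:
            c = comm[v]
            links = {}
            for g in gs:
                row = adj[g][v]
                if not row:
                    continue
                ag = a[g]
                for u, wt in row.items():
                    if u == v:
                        continue
                    d = comm[u]
                    if d in links:
                        links[d] += ag * wt
                    else:
                        links[d] = ag * wt
            sv = [S[g][v] for g in gs]
            for g in gs:
                tot[g][c] -= sv[g]
            # insertion score of community d (relative, internal scale)
            fc = links.get(c, 0.0)
            for g in gs:
                fc -= b[g] * sv[g] * tot[g][c]
            dest = c
            if randomized:
                thresh = fc + tol
                improving = []
                for d, lk in links.items():
                    if d == c:
                        continue
                    fd = lk
                    for g in gs:
                        fd -= b[g] * sv[g] * tot[g][d]
                    if fd > thresh:
                        improving.append(d)
                if 0.0 > thresh and csize[c] > 1:
                    improving.append(_NEW)
                if improving:
                    dest = improving[rng.integers(len(improving))]
            else:
                best_f = fc
                for d in sorted(links):
                    if d == c:
                        continue
                    fd = links[d]
                    for g in gs:
                        fd -= b[g] * sv[g] * tot[g][d]
                    if fd > best_f:
                        best_f, dest = fd, d
                if csize[c] > 1 and 0.0 > best_f:
                    best_f, dest = 0.0, _NEW
                if dest != c and not best_f > fc + tol:
                    dest = c
            if dest == c:
                for g in gs:
                    tot[g][c] += sv[g]
            else:
                csize[c] -= 1
                if csize[c] == 0:
                    free.append(c)
                if dest == _NEW:
                    dest = free.pop()
                comm[v] = dest
                csize[dest] += 1
                for g in gs:
                    tot[g][dest] += sv[g]
                sweep_moves += 1
        total_moves += sweep_moves
        if sweep_moves == 0:
            return total_moves


def _contract(adj, S, comm):
    """Contract communities to super-vertices; returns (adj', S', relabel)."""
    labels = sorted(set(comm))
    newid = {lab: i for i, lab in enumerate(labels)}
    K = len(labels)
    L = len(adj)
    n = len(comm)
    cid = [newid[comm[v]] for v in range(n)]
    new_adj = []
    new_S = []
    for g in range(L):
        rows = [dict() for _ in range(K)]
        sg = [0.0] * K
        adjg = adj[g]
        Sg = S[g]
        for v in range(n):
            cv = cid[v]
            sg[cv] += Sg[v]
            for u, wt in adjg[v].items():
                if u < v:
                    continue
                if u == v:
                    rows[cv][cv] = rows[cv].get(cv, 0.0) + wt
                else:
                    cu = cid[u]
                    if cu == cv:
                        rows[cv][cv] = rows[cv].get(cv, 0.0) + wt
                    else:
                        rows[cv][cu] = rows[cv].get(cu, 0.0) + wt
                        rows[cu][cv] = rows[cu].get(cv, 0.0) + wt
        new_adj.append(rows)
        new_S.append(sg)
    return new_adj, new_S, cid


def _one_run(flat: _Flat, randomized: bool, rng, tol: float, max_levels: int,
             shuffle_sweep: bool):
    """One full Louvain run; returns original-vertex -> community label list."""
    adj, S = flat.adj, flat.S
    a, b = flat.a, flat.b
    n = flat.n
    assignment = list(range(n))  # original vertex -> current-level node
    for _level in range(max_levels):
        ncur = len(adj[0]) if adj else 0
        comm = list(range(ncur))
        csize = [1] * ncur
        free: list[int] = []
        moves = _move_phase(adj, S, a, b, comm, csize, free, tol, randomized,
                            rng, shuffle_sweep)
        if moves == 0:
            return assignment
        adj, S, cid = _contract(adj, S, comm)
        assignment = [cid[assignment[i]] for i in range(n)]
        if len(adj[0]) == 1:
            return assignment
    raise RuntimeError(
        "Louvain did not converge within max_outer_iterations levels; "
        "this indicates a bug (the score is bounded and strictly increasing)")


def run_louvain(net: MultiplexNetwork, config: OptimizerConfig | None = None,
                layer_weights: Sequence[float] | None = None) -> ClusteringResult:
    """Cluster a multiplex network by (randomized) Louvain.

    With ``config.n_runs == 0`` a single deterministic run is performed;
    with ``n_runs >= 1`` that many randomized runs are performed with
    independent RNG streams and the highest-scoring partition is returned
    (ties break to the lowest run index).  The reported ``score`` is the
    multiplex modularity of the returned partition on the original network.
    """
    if config is None:
        config = OptimizerConfig()
    lw = _resolve_weights(net, layer_weights)
    flat = _Flat(net, config.gamma, lw)
    tol = config.improvement_tolerance

    if config.seed is not None:
        seed_used = int(config.seed) % (2 ** 31)
    else:
        seed_used = int(np.random.SeedSequence().entropy % (2 ** 31))

    if flat.L == 0:
        part = Partition.singletons(net.universe)
        return ClusteringResult(partition=part, score=0.0, runs_performed=0,
                                best_run_index=0, seed_used=seed_used,
                                run_scores=(), gamma=config.gamma)

    partitions = []
    if config.n_runs == 0:
        rng = np.random.default_rng(seed_used)  # unused in deterministic mode
        assignment = _one_run(flat, False, rng, tol,
                              config.max_outer_iterations, False)
        partitions.append(assignment)
    else:
        for i in range(config.n_runs):
            rng = np.random.default_rng((seed_used + i) % (2 ** 31))
            partitions.append(_one_run(flat, True, rng, tol,
                                       config.max_outer_iterations,
                                       config.shuffle_sweep))

    verts = net.universe
    scores = []
    parts = []
    for assignment in partitions:
        part = Partition({v: assignment[i] for i, v in enumerate(verts)},
                         universe=verts)
        parts.append(part)
        scores.append(multiplex_modularity(net, part, config.gamma, lw))
    best = max(range(len(scores)), key=lambda i: (scores[i], -i))
    return ClusteringResult(partition=parts[best], score=scores[best],
                            runs_performed=len(parts), best_run_index=best,
                            seed_used=seed_used, run_scores=tuple(scores),
                            gamma=config.gamma)


def louvain_pass(net: MultiplexNetwork, part: Partition, gamma: float = 1.0,
                 layer_weights: Sequence[float] | None = None,
                 mode: str = "deterministic", rng=None) -> Partition:
    """One local-move phase starting from ``part`` (no contraction).

    Sweeps vertices in universe order, applying single-vertex moves until a
    full sweep changes nothing; the score is non-decreasing throughout.
    """
    if mode not in ("deterministic", "randomized"):
        raise ValueError("mode must be 'deterministic' or 'randomized'")
    lw = _resolve_weights(net, layer_weights)
    _check_coverage(net, part)
    flat = _Flat(net, gamma, lw)
    if flat.L == 0:
        return part
    n = flat.n
    comm = [part[v] for v in flat.vertices]
    csize = [0] * n
    for c in comm:
        csize[c] += 1
    free = [c for c in range(n - 1, -1, -1) if csize[c] == 0]
    randomized = mode == "randomized"
    if randomized and rng is None:
        rng = np.random.default_rng()
    _move_phase(flat.adj, flat.S, flat.a, flat.b, comm, csize, free,
                1e-10, randomized, rng, False)
    return Partition({v: comm[i] for i, v in enumerate(flat.vertices)},
                     universe=flat.vertices)


def aggregate(net: MultiplexNetwork, part: Partition) -> MultiplexNetwork:
    """Contract each community to a super-vertex, per layer.

    Inter-community weights sum onto a single edge; intra-community weight
    (plus any existing self-loop weight) becomes the super-vertex's
    self-loop.  Under this bookkeeping the internal (aggregation-invariant)
    modularity of the contracted network under a coarser partition equals
    that of the original network under the corresponding refinement.
    """
    _check_coverage(net, part)
    assignment = part.assignment
    labels = sorted(part.communities)
    layers = []
    for lay in net.layers:
        g = nx.Graph()
        g.add_nodes_from(labels)
        for u, v, wt in lay.graph.edges(data="weight", default=1.0):
            cu, cv = assignment[u], assignment[v]
            if g.has_edge(cu, cv):
                g[cu][cv]["weight"] += wt
            else:
                g.add_edge(cu, cv, weight=wt)
        layers.append(Layer(g, name=lay.name))
    return MultiplexNetwork(layers, net.layer_names)


def internal_modularity(net: MultiplexNetwork, part: Partition,
                        gamma: float = 1.0,
                        layer_weights: Sequence[float] | None = None) -> float:
    """Aggregation-invariant (ordered-pair) form of the multiplex score.

    Per layer:  w_g * [ W_intra / m  -  gamma * sum_c T_c^2 / (4 m^2) ]
    with W_intra the intra-community weight (self-loops counted once) and
    T_c the community strength total.  Equals twice the reported score plus
    a partition-independent offset per layer; invariant under
    :func:`aggregate`, hence what the optimizer tracks across levels.
    """
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
            if assignment[u] == assignment[v]:
                intra += wt
        deg = dict(g.degree(weight="weight"))
        null = 0.0
        for members in part.communities.values():
            t = 0.0
            for v in members:
                t += deg.get(v, 0.0)
            null += t * t
        score += w * (intra / m - gamma * null / (4.0 * m * m))
    return score
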