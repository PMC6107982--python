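"""Recursive re-clustering of oversized communities and size filtering.

Very large networks often yield a few huge communities at the default
resolution.  Rather than raising gamma, each community larger than
``max_size`` is extracted as an induced sub-multiplex and re-clustered with
the same optimizer settings, recursively, until every community fits or a
community cannot be split (the optimizer returns it whole — e.g. a large
clique, whose modularity optimum is the single community).  A size-range
post-filter then keeps only communities within ``[min_size, max_size]``,
the shape required for downstream module analyses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

from .louvain import OptimizerConfig, run_louvain
from .model import MultiplexNetwork, Partition, subnetwork

logger = logging.getLogger(__name__)

__all__ = [
    "RecursionConfig",
    "RecursionResult",
    "ModuleSet",
    "recursive_cluster",
    "filter_by_size",
    "write_module_set",
]


@dataclass(frozen=True)
class RecursionConfig:
    """Size cap triggering recursion plus the post-filter size range.

    ``max_size`` (inclusive) is both the recursion trigger and the filter
    ceiling; communities of 7–100 vertices are the default keep range.
    """

    max_size: int = 100
    min_size_filter: int = 7
    max_size_filter: int = 100
    optimizer: OptimizerConfig = field(default_factory=OptimizerConfig)

    def __post_init__(self):
        if self.max_size < 2:
            raise ValueError("max_size must be >= 2")
        if self.min_size_filter > self.max_size_filter:
            raise ValueError("min_size_filter must be <= max_size_filter")
        if self.min_size_filter < 1:
            raise ValueError("min_size_filter must be >= 1")


@dataclass(frozen=True)
class RecursionResult:
    """Pre-filter partition plus bookkeeping of the recursion.

    ``unsplittable`` lists communities larger than ``max_size`` that the
    optimizer returned whole at some depth; ``depth`` maps each final
    community label to the recursion depth at which it stabilized.
    """

    partition: Partition
    unsplittable: tuple
    depth: dict


def _child_seed(base: Optional[int], counter: int) -> Optional[int]:
    if base is None:
        return None
    return (int(base) + 10007 * (counter + 1)) % (2 ** 31)


def recursive_cluster(net: MultiplexNetwork,
                      config: RecursionConfig | None = None,
                      layer_weights: Sequence[float] | None = None
                      ) -> RecursionResult:
    """Cluster, then recursively re-cluster communities above ``max_size``.

    The same optimizer settings (gamma, n_runs) are reused at every depth,
    on the induced sub-multiplex of each oversized community; per-depth
    seeds are derived deterministically from the base seed.  The returned
    partition covers the full universe; every community either satisfies
    the size cap or is flagged unsplittable.
    """
    if config is None:
        config = RecursionConfig()
    counter = 0
    base_seed = config.optimizer.seed
    opt = replace(config.optimizer, seed=_child_seed(base_seed, counter))
    counter += 1
    top = run_louvain(net, opt, layer_weights)

    final: list[frozenset] = []
    depths: list[int] = []
    unsplittable: list[frozenset] = []
    stack = [(members, 0) for _, members in sorted(top.partition.communities.items())]
    while stack:
        members, depth = stack.pop(0)
        if len(members) <= config.max_size:
            final.append(members)
            depths.append(depth)
            continue
        sub = subnetwork(net, members)
        opt = replace(config.optimizer, seed=_child_seed(base_seed, counter))
        counter += 1
        res = run_louvain(sub, opt, layer_weights)
        comms = sorted(res.partition.communities.items())
        if len(comms) <= 1:
            logger.warning("community of %d vertices at depth %d cannot be "
                           "split; flagged unsplittable", len(members), depth)
            unsplittable.append(members)
            final.append(members)
            depths.append(depth)
            continue
        for _, sub_members in comms:
            stack.append((sub_members, depth + 1))

    part = Partition.from_communities(final)
    # map canonical labels back to depths via membership
    label_of = {next(iter(ms)): d for ms, d in zip(final, depths)}
    depth_map = {part[v]: d for v, d in label_of.items()}
    return RecursionResult(partition=part, unsplittable=tuple(unsplittable),
                           depth=depth_map)


@dataclass(frozen=True)
class ModuleSet:
    """Size-filtered modules plus the classes the filter discarded."""

    modules: tuple
    dropped_small: tuple
    dropped_large: tuple
    unsplittable: tuple = ()

    @property
    def n_modules(self) -> int:
        return len(self.modules)


def filter_by_size(part: Partition, min_size: int = 7, max_size: int = 100,
                   unsplittable: Sequence[frozenset] = ()) -> ModuleSet:
    """Keep exactly the communities with ``min_size <= |C| <= max_size``.

    Both bounds are inclusive.  Dropped classes are returned so that kept
    modules plus dropped classes still partition the vertex set.
    """
    if min_size > max_size:
        raise ValueError("min_size must be <= max_size")
    kept, small, large = [], [], []
    for _, members in sorted(part.communities.items()):
        if len(members) < min_size:
            small.append(members)
        elif len(members) > max_size:
            large.append(members)
        else:
            kept.append(members)
    return ModuleSet(modules=tuple(kept), dropped_small=tuple(small),
                     dropped_large=tuple(large),
                     unsplittable=tuple(unsplittable))


def _vertex_key(v):
    return str(v)


def write_module_set(ms: ModuleSet, path, log_path=None) -> None:
    """Write one module per line: ``M<i><TAB>node1<TAB>node2...``.

    A companion log (``<path>.log`` by default) records the dropped and
    unsplittable classes.
    """
    with open(path, "w") as fh:
        for i, members in enumerate(ms.modules, start=1):
            fh.write("M%d\t%s\n" % (i, "\t".join(
                str(v) for v in sorted(members, key=_vertex_key))))
    if log_path is None:
        log_path = str(path) + ".log"
    with open(log_path, "w") as fh:
        fh.write(f"modules_kept\t{len(ms.modules)}\n")
        fh.write(f"classes_dropped_small\t{len(ms.dropped_small)}\n")
        fh.write(f"classes_dropped_large\t{len(ms.dropped_large)}\n")
        fh.write(f"communities_unsplittable\t{len(ms.unsplittable)}\n")
        for tag, group in (("small", ms.dropped_small),
                           ("large", ms.dropped_large),
                           ("unsplittable", ms.unsplittable)):
            for members in group:
                fh.write("%s\t%s\n" % (tag, "\t".join(
                    str(v) for v in sorted(members, key=_vertex_key))))
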