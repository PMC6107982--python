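"""Independent oracles used by the tests.

These deliberately avoid the implementation paths they check: the
modularity oracle sums the score term by term over all vertex pairs, the
ARI oracle classifies every vertex pair, and small argmax checks enumerate
every set partition (via sympy).
"""

from __future__ import annotations

from itertools import combinations

from sympy.utilities.iterables import multiset_partitions

from muxcom import Partition, layer_stats


def eq1_brute(net, part, gamma=1.0, layer_weights=None):
    """Term-by-term multiplex modularity over all unordered pairs i != j."""
    lw = layer_weights if layer_weights is not None else [1.0] * net.n_layers
    score = 0.0
    for layer, w in zip(net.layers, lw):
        if w == 0:
            continue
        st = layer_stats(layer)
        if st.m == 0:
            continue
        for i, j in combinations(net.universe, 2):
            if part[i] != part[j]:
                continue
            x = layer.weight(i, j)
            si = st.strength.get(i, 0.0)
            sj = st.strength.get(j, 0.0)
            score += w / (2 * st.m) * (x - gamma * si * sj / (2 * st.m))
    return score


def pair_count_ari(p_a, p_b):
    """ARI from an exhaustive classification of all vertex pairs.

    Counts pairs co-clustered in both (n11), in neither (n00), and in
    exactly one (n10, n01), then applies the closed form
    2 (n00 n11 - n01 n10) / ((n00+n01)(n01+n11) + (n00+n10)(n10+n11)).
    """
    aa = p_a.assignment if isinstance(p_a, Partition) else dict(p_a)
    ab = p_b.assignment if isinstance(p_b, Partition) else dict(p_b)
    assert set(aa) == set(ab)
    n11 = n00 = n10 = n01 = 0
    for i, j in combinations(sorted(aa, key=str), 2):
        sa = aa[i] == aa[j]
        sb = ab[i] == ab[j]
        if sa and sb:
            n11 += 1
        elif sa:
            n10 += 1
        elif sb:
            n01 += 1
        else:
            n00 += 1
    den = (n00 + n01) * (n01 + n11) + (n00 + n10) * (n10 + n11)
    if den == 0:
        return 1.0 if all(
            (aa[i] == aa[j]) == (ab[i] == ab[j])
            for i, j in combinations(aa, 2)) else 0.0
    return 2.0 * (n00 * n11 - n01 * n10) / den


def all_partitions(items):
    """Every set partition of ``items`` as a Partition (Bell(n) of them)."""
    items = list(items)
    if len(items) == 1:
        yield Partition({items[0]: 0})
        return
    for blocks in multiset_partitions(items):
        yield Partition.from_communities(blocks)


def exhaustive_argmax(net, gamma=1.0, layer_weights=None):
    """Best score and the set of maximizing partitions, by enumeration."""
    best = None
    argmax = []
    for part in all_partitions(net.universe):
        q = eq1_brute(net, part, gamma, layer_weights)
        if best is None or q > best + 1e-12:
            best, argmax = q, [part]
        elif abs(q - best) <= 1e-12:
            argmax.append(part)
    return best, argmax
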