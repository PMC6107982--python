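"""Partition comparison by the adjusted Rand index (ARI).

The ARI is the pair-counting Rand index corrected for chance under the
permutation model: 1 for identical partitions, about 0 for independent
ones, negative for worse-than-chance agreement.  All combinatorial sums
are carried out in exact integer arithmetic before the final division.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np

from .model import Partition

__all__ = ["contingency_table", "adjusted_rand_index", "ari_on_overlap"]


def _assignment(p) -> Mapping:
    if isinstance(p, Partition):
        return p.assignment
    return dict(p)


def contingency_table(p_a, p_b):
    """Cross-tabulation of two partitions of the same vertex set.

    Returns ``(counts, a, b)``: the |A| x |B| matrix of intersection sizes
    and its row/column marginals, as numpy integer arrays.
    """
    aa, ab = _assignment(p_a), _assignment(p_b)
    if set(aa) != set(ab):
        raise ValueError("partitions are not defined on the same vertex set")
    rows = {lab: i for i, lab in enumerate(dict.fromkeys(aa.values()))}
    cols = {lab: i for i, lab in enumerate(dict.fromkeys(ab.values()))}
    counts = np.zeros((len(rows), len(cols)), dtype=np.int64)
    for v, la in aa.items():
        counts[rows[la], cols[ab[v]]] += 1
    return counts, counts.sum(axis=1), counts.sum(axis=0)


def _comb2(x: int) -> int:
    return x * (x - 1) // 2


def adjusted_rand_index(p_a, p_b) -> float:
    """Adjusted Rand index between two partitions of the same vertex set.

    Symmetric and label-permutation invariant; returns exactly 1.0 when the
    chance-correction denominator vanishes and the partitions are equal
    (e.g. both all-singletons), 0.0 when it vanishes otherwise.
    """
    counts, a, b = contingency_table(p_a, p_b)
    n = int(counts.sum())
    cn2 = _comb2(n)
    sum_ij = int(sum(_comb2(int(x)) for x in counts.flat))
    sum_a = int(sum(_comb2(int(x)) for x in a))
    sum_b = int(sum(_comb2(int(x)) for x in b))
    # ARI = (sum_ij - sum_a sum_b / C(n,2)) /
    #       ((sum_a + sum_b)/2 - sum_a sum_b / C(n,2)), cleared of fractions
    num = 2 * (cn2 * sum_ij - sum_a * sum_b)
    den = cn2 * (sum_a + sum_b) - 2 * sum_a * sum_b
    if den == 0:
        aa, ab = _assignment(p_a), _assignment(p_b)
        same = Partition(aa) == Partition(ab)
        return 1.0 if same else 0.0
    return num / den


def ari_on_overlap(p_detected, p_planted,
                   missing_as_singletons: bool = False) -> float:
    """ARI between partitions whose vertex sets need not coincide.

    By default both partitions are restricted to the intersection of their
    domains (the natural choice when missing-data simulations leave some
    planted vertices undetectable).  With ``missing_as_singletons`` the
    detected partition is instead extended to the planted domain, placing
    each absent vertex in its own fresh community.
    """
    ad = dict(_assignment(p_detected))
    ap = dict(_assignment(p_planted))
    common = set(ad) & set(ap)
    if not common:
        raise ValueError("partitions have no vertices in common")
    if missing_as_singletons:
        fresh = 0
        labels = set(ad.values())
        for v in set(ap) - set(ad):
            while ("_missing", fresh) in labels:  # pragma: no cover
                fresh += 1
            ad[v] = ("_missing", fresh)
            fresh += 1
        return adjusted_rand_index(ad, ap)
    return adjusted_rand_index({v: ad[v] for v in common},
                               {v: ap[v] for v in common})
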