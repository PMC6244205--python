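"""Independent brute-force reference implementations used only by tests."""

from itertools import combinations

import numpy as np


def enumerate_8cm(seq, bounds):
    """All increasing cysteine 8-tuples satisfying the CC/CXC anchors and
    gap bounds, by exhaustive enumeration over cysteine combinations."""
    cys = [i for i, r in enumerate(seq) if r == "C"]
    (l1, h1), (l2, h2), (l3, h3), (l4, h4), (l5, h5) = bounds.as_tuple()
    out = []
    for tup in combinations(cys, 8):
        p1, p2, p3, p4, p5, p6, p7, p8 = tup
        if p4 != p3 + 1 or p6 != p5 + 2:
            continue
        gaps = (p2 - p1 - 1, p3 - p2 - 1, p5 - p4 - 1, p7 - p6 - 1, p8 - p7 - 1)
        if (
            l1 <= gaps[0] <= h1 and l2 <= gaps[1] <= h2 and l3 <= gaps[2] <= h3
            and l4 <= gaps[3] <= h4 and l5 <= gaps[4] <= h5
        ):
            out.append(tup)
    return sorted(out, key=lambda p: (p[0], p[7] - p[0], p))


def resolve_overlaps(tuples):
    """The leftmost-start, smallest-span greedy resolution, re-implemented."""
    chosen, last_end = [], -1
    for p in tuples:
        if p[0] > last_end:
            chosen.append(p)
            last_end = p[7]
    return chosen


def naive_upgma(ids, matrix):
    """O(n^3) UPGMA recomputing every cluster distance from the original
    leaf-pair matrix; returns (frozenset-of-leaves -> height) per node and
    the nested-tuple topology keyed by sorted leaf labels."""
    idx = {name: i for i, name in enumerate(ids)}
    clusters = {name: frozenset([name]) for name in ids}
    heights = {frozenset([name]): 0.0 for name in ids}
    topology = {name: name for name in ids}

    def cdist(a, b):
        return float(
            np.mean([[matrix[idx[x], idx[y]] for y in clusters[b]] for x in clusters[a]])
        )

    while len(clusters) > 1:
        keys = sorted(clusters)
        best = None
        for i, a in enumerate(keys):
            for b in keys[i + 1 :]:
                cand = (cdist(a, b), a, b)
                if best is None or cand < best:
                    best = cand
        d, a, b = best
        new_key = min(a, b)
        merged = clusters[a] | clusters[b]
        heights[merged] = d / 2
        topology[new_key] = (topology[a], topology[b])
        clusters[new_key] = merged
        for k in (a, b):
            if k != new_key:
                del clusters[k], topology[k]
    return heights, topology[next(iter(clusters))]


def tree_to_heights(root):
    """frozenset-of-leaves -> height for every internal node of a TreeNode."""
    out = {}
    for node in root.walk():
        if not node.is_leaf:
            out[node.leaf_names()] = node.height
    return out


def hypergeom_tail(a, n_pos, b, n_neg):
    """One-sided Fisher p as an explicit hypergeometric tail sum."""
    from math import comb

    N = n_pos + n_neg
    K = a + b
    denom = comb(N, n_pos)
    total = 0
    for x in range(a, min(K, n_pos) + 1):
        if K - x <= n_neg:
            total += comb(K, x) * comb(N - K, n_pos - x)
    return total / denom


def naive_motif_count(seq, motif, iupac, revcomp):
    """Position-by-position occurrence count on both strands."""
    def count_one(s, m):
        c = 0
        for i in range(len(s) - len(m) + 1):
            if all(s[i + j] in iupac[m[j]] for j in range(len(m))):
                c += 1
        return c

    rc = revcomp(motif)
    n = count_one(seq, motif)
    if rc != motif:
        n += count_one(seq, rc)
    return n
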