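"""Pairwise mature-protein distances, UPGMA trees and clade composition.

Distances are 1 - identity from global BLOSUM62 alignment (identity over
aligned columns excluding terminal gaps). UPGMA iteratively merges the
closest pair of clusters, averaging distances with cluster-size weights
(the arithmetic mean over all member pairs) and placing each merge node at
height d/2; ties are broken by the lexicographically smallest leaf-label
pair so trees are reproducible byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .align import protein_identity


@dataclass
class DistanceMatrix:
    ids: list[str]
    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(m, m.T) or np.any(np.diag(m) != 0) or np.any(m < 0):
            raise ValueError("distance matrix must be symmetric, non-negative, zero-diagonal")
        self.matrix = m

    def to_phylip(self) -> str:
        lines = [str(len(self.ids))]
        for i, name in enumerate(self.ids):
            lines.append(name + "  " + "  ".join(f"{v:.6f}" for v in self.matrix[i]))
        return "\n".join(lines) + "\n"


@dataclass
class TreeNode:
    """Node of an ultrametric (UPGMA) tree; leaves sit at height 0."""

    name: str | None = None
    height: float = 0.0
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_names(self) -> frozenset:
        return frozenset(l.name for l in self.leaves())

    def walk(self):
        yield self
        for c in self.children:
            yield from c.walk()

    def to_newick(self, _parent_height: float | None = None) -> str:
        length = (
            "" if _parent_height is None
            else f":{_parent_height - self.height:.10g}"
        )
        if self.is_leaf:
            return f"{self.name}{length}"
        inner = ",".join(c.to_newick(self.height) for c in self.children)
        return f"({inner}){length}"


def write_newick(root: TreeNode) -> str:
    return root.to_newick() + ";"


def parse_newick(text: str) -> TreeNode:
    """Parse a Newick string with branch lengths into a TreeNode tree.

    Heights are reconstructed from branch lengths assuming an ultrametric
    tree (leaves at height 0).
    """
    text = text.strip()
    if not text.endswith(";"):
        raise ValueError("Newick must end with ';'")
    pos = 0

    def parse_clade():
        nonlocal pos
        node = TreeNode()
        if text[pos] == "(":
            pos += 1
            while True:
                node.children.append(parse_clade())
                if text[pos] == ",":
                    pos += 1
                    continue
                if text[pos] == ")":
                    pos += 1
                    break
        start = pos
        while pos < len(text) and text[pos] not in ":,();":
            pos += 1
        label = text[start:pos]
        if label:
            node.name = label
        length = 0.0
        if pos < len(text) and text[pos] == ":":
            pos += 1
            start = pos
            while pos < len(text) and text[pos] not in ",();":
                pos += 1
            length = float(text[start:pos])
        node._branch = length  # type: ignore[attr-defined]
        return node

    root = parse_clade()

    def set_heights(node):
        if node.is_leaf:
            node.height = 0.0
            return 0.0
        h = max(set_heights(c) + getattr(c, "_branch", 0.0) for c in node.children)
        node.height = h
        return h

    set_heights(root)
    return root


def pairwise_distance_matrix(sequences: dict[str, str]) -> DistanceMatrix:
    """1 - alignment identity over all pairs of mature proteins."""
    ids = sorted(sequences)
    if len(ids) < 2:
        raise ValueError("need at least two sequences")
    n = len(ids)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = 1.0 - protein_identity(sequences[ids[i]], sequences[ids[j]])
            m[i, j] = m[j, i] = d
    return DistanceMatrix(ids, m)


def upgma(dm: DistanceMatrix) -> TreeNode:
    """Build the UPGMA tree with deterministic tie-breaking."""
    n = len(dm.ids)
    if n < 2:
        raise ValueError("need at least two leaves")
    # cluster key = lexicographically smallest leaf label in the cluster
    clusters: dict[str, TreeNode] = {name: TreeNode(name=name) for name in dm.ids}
    sizes: dict[str, int] = {name: 1 for name in dm.ids}
    dist: dict[frozenset, float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[frozenset((dm.ids[i], dm.ids[j]))] = dm.matrix[i, j]

    while len(clusters) > 1:
        keys = sorted(clusters)
        best = None
        for i, a in enumerate(keys):
            for b in keys[i + 1 :]:
                d = dist[frozenset((a, b))]
                cand = (d, a, b)
                if best is None or cand < best:
                    best = cand
        d, a, b = best
        node = TreeNode(height=d / 2, children=[clusters[a], clusters[b]])
        na, nb = sizes[a], sizes[b]
        new_key = min(a, b)
        for other in keys:
            if other in (a, b):
                continue
            da = dist.pop(frozenset((a, other)))
            db = dist.pop(frozenset((b, other)))
            dist[frozenset((new_key, other))] = (na * da + nb * db) / (na + nb)
        dist.pop(frozenset((a, b)))
        del clusters[a], clusters[b], sizes[a], sizes[b]
        clusters[new_key] = node
        sizes[new_key] = na + nb
    return next(iter(clusters.values()))


@dataclass
class CladeComposition:
    node: TreeNode
    counts: dict[str, int]

    def bracket(self, species_order: list[str]) -> str:
        return "[" + "-".join(str(self.counts.get(s, 0)) for s in species_order) + "]"


def clade_species_composition(
    root: TreeNode,
    leaf_species: dict[str, str],
    leaf_type: dict[str, str] | None = None,
):
    """Per-internal-node species counts plus per-type monophyly report.

    A type is monophyletic iff some node's leaf set equals exactly that
    type's leaf set; species-specific clades are internal nodes whose
    leaves all come from one species.
    """
    unmapped = root.leaf_names() - set(leaf_species)
    if unmapped:
        raise KeyError(f"leaves without species mapping: {sorted(unmapped)}")
    comps = []
    node_leafsets = []
    for node in root.walk():
        if node.is_leaf:
            continue
        counts: dict[str, int] = {}
        for leaf in node.leaves():
            sp = leaf_species[leaf.name]
            counts[sp] = counts.get(sp, 0) + 1
        comps.append(CladeComposition(node, counts))
        node_leafsets.append(node.leaf_names())

    monophyly = {}
    if leaf_type:
        node_leafsets.append(root.leaf_names())
        by_type: dict[str, set] = {}
        for leaf, t in leaf_type.items():
            by_type.setdefault(t, set()).add(leaf)
        for t, leaves in by_type.items():
            fs = frozenset(leaves)
            monophyly[t] = len(leaves) == 1 or any(fs == s for s in node_leafsets)

    species_specific = [c for c in comps if len(c.counts) == 1]
    return {"compositions": comps, "monophyly": monophyly,
            "species_specific": species_specific}
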