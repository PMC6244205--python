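"""FPKM matrix handling: log transform, profile clustering, enrichment calls.

Genes are clustered on log2(FPKM+1) profiles with average-linkage
agglomeration on correlation distance (1 - Pearson r across samples), the
tree cut to exactly k clusters. "Anther-enriched" and "not expressed" are
operational calls: the tissue rule (mean FPKM in the target tissue at least
``min_fpkm`` and at least ``fold`` times the best other tissue mean) and an
everywhere-below-threshold rule respectively.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform


@dataclass
class ExpressionMatrix:
    """Gene x sample FPKM table with tissue (and optional stage) labels."""

    fpkm: pd.DataFrame  # rows = genes, columns = samples
    sample_tissue: dict[str, str]
    sample_stage: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if (self.fpkm.values < 0).any():
            raise ValueError("FPKM values must be non-negative")
        missing = set(self.fpkm.columns) - set(self.sample_tissue)
        if missing:
            raise ValueError(f"samples without tissue label: {sorted(missing)}")

    @property
    def tissues(self) -> list[str]:
        return sorted(set(self.sample_tissue.values()))

    def tissue_means(self) -> pd.DataFrame:
        """Per-gene mean FPKM per tissue."""
        groups: dict[str, list[str]] = {}
        for s, t in self.sample_tissue.items():
            if s in self.fpkm.columns:
                groups.setdefault(t, []).append(s)
        return pd.DataFrame(
            {t: self.fpkm[cols].mean(axis=1) for t, cols in sorted(groups.items())}
        )

    def to_tsv(self) -> str:
        buf = io.StringIO()
        self.fpkm.rename_axis("gene_id").to_csv(buf, sep="\t")
        return buf.getvalue()

    def sample_map_tsv(self) -> str:
        lines = ["sample\ttissue\tstage"]
        for s in self.fpkm.columns:
            lines.append(f"{s}\t{self.sample_tissue[s]}\t{self.sample_stage.get(s, '')}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_tsv(cls, fpkm_text: str, sample_map_text: str) -> "ExpressionMatrix":
        fpkm = pd.read_csv(io.StringIO(fpkm_text), sep="\t", index_col=0, comment="#")
        tissue, stage = {}, {}
        for line in sample_map_text.splitlines()[1:]:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            tissue[parts[0]] = parts[1]
            stage[parts[0]] = parts[2] if len(parts) > 2 else ""
        return cls(fpkm, tissue, stage)


@dataclass
class EnrichmentCall:
    gene_id: str
    status: str  # anther_enriched | not_expressed | other
    tissue_mean: float
    max_other_mean: float
    fold: float


def log_transform(matrix: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    if (matrix.values < 0).any():
        raise ValueError("negative FPKM")
    return np.log2(matrix + pseudocount)


def hierarchical_cluster_genes(
    transformed: pd.DataFrame, k: int = 10, metric: str = "correlation"
):
    """Average-linkage clustering of gene profiles cut to exactly k clusters.

    Constant-profile genes (undefined correlation) are clustered separately
    with a Euclidean fallback: each is assigned to the nearest resulting
    cluster centroid. Rows are ordered by gene id first so the outcome is
    independent of input row order. Returns (assignment, linkage, ids).
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    df = transformed.sort_index()
    values = df.values.astype(float)
    variable = values.std(axis=1) > 0
    var_ids = list(df.index[variable])
    if len(var_ids) < k:
        raise ValueError(f"need at least k={k} genes with non-constant profiles")
    vmat = values[variable]
    if metric == "correlation":
        corr = np.corrcoef(vmat)
        dist = 1.0 - corr
        np.fill_diagonal(dist, 0.0)
        dist = np.clip((dist + dist.T) / 2, 0.0, None)
        condensed = squareform(dist, checks=False)
    else:
        from scipy.spatial.distance import pdist

        condensed = pdist(vmat, metric=metric)
    Z = hierarchy.linkage(condensed, method="average")
    labels = hierarchy.cut_tree(Z, n_clusters=k).ravel() + 1
    assignment = dict(zip(var_ids, (int(l) for l in labels)))

    if (~variable).any():
        centroids = {
            lab: vmat[labels == lab].mean(axis=0) for lab in sorted(set(labels))
        }
        for gid, row in zip(df.index[~variable], values[~variable]):
            best = min(
                centroids, key=lambda lab: (np.linalg.norm(row - centroids[lab]), lab)
            )
            assignment[gid] = int(best)
    return assignment, Z, var_ids


def dendrogram_newick(Z: np.ndarray, ids: list[str]) -> str:
    """Render a scipy linkage as a Newick string with merge-height branch lengths."""
    tree = hierarchy.to_tree(Z)

    def render(node, parent_dist):
        length = parent_dist - node.dist
        if node.is_leaf():
            return f"{ids[node.id]}:{length:.10g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length:.10g}"

    return f"({render(tree.left, tree.dist)},{render(tree.right, tree.dist)});"


def call_tissue_enriched(
    em: ExpressionMatrix,
    tissue: str = "anther",
    min_fpkm: float = 2.0,
    fold: float = 4.0,
    not_expressed_max: float = 0.5,
) -> list[EnrichmentCall]:
    """Per-gene enrichment status for one tissue.

    A gene is ``anther_enriched`` (for the default tissue) when its mean
    FPKM over that tissue's samples is >= min_fpkm and >= fold times the
    maximum other-tissue mean; ``not_expressed`` when every sample is below
    ``not_expressed_max``; otherwise ``other``. Statuses are mutually
    exclusive, with not_expressed taking precedence.
    """
    if tissue not in set(em.sample_tissue.values()):
        raise KeyError(f"tissue {tissue!r} not in sample map")
    means = em.tissue_means()
    others = [t for t in means.columns if t != tissue]
    not_expr = call_not_expressed(em, not_expressed_max)
    calls = []
    for gid in em.fpkm.index:
        tmean = float(means.at[gid, tissue])
        omax = float(means.loc[gid, others].max()) if others else 0.0
        ratio = tmean / omax if omax > 0 else float("inf")
        if gid in not_expr:
            status = "not_expressed"
        elif tmean >= min_fpkm and tmean >= fold * omax:
            status = f"{tissue}_enriched"
        else:
            status = "other"
        calls.append(EnrichmentCall(gid, status, tmean, omax, ratio))
    return calls


def call_not_expressed(em: ExpressionMatrix, max_fpkm: float = 0.5) -> set[str]:
    """Genes whose FPKM is below ``max_fpkm`` in every sample."""
    mask = (em.fpkm < max_fpkm).all(axis=1)
    return set(em.fpkm.index[mask])
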