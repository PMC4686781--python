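"""Exploratory layer: variance-ranked genes, sample clustering, PCA, heat maps.

Counts are put on a log2(normalized + 1) scale, the top-k most variable
genes are selected, and samples are summarized two ways: an average-
linkage dendrogram on correlation distance (1 - Pearson between sample
profiles), and a gene-centered PCA with per-component variance fractions.
Heat-map exports are min-max scaled per gene so each row spans [0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from skbio.tree import TreeNode
from sklearn.decomposition import PCA

from .io import CountMatrix

logger = logging.getLogger(__name__)


def transform_counts(matrix: CountMatrix, size_factors: pd.Series) -> pd.DataFrame:
    """log2(count / size_factor + 1), genes x samples."""
    s = size_factors.loc[matrix.data.columns].to_numpy(dtype=float)
    if (s <= 0).any():
        raise ValueError("size factors must be positive")
    return np.log2(matrix.data / s + 1.0)


def top_variance_genes(transformed: pd.DataFrame, k: int) -> list[str]:
    """The k genes with the largest across-sample variance.

    Ties are broken by lexicographic gene id so the selection is
    deterministic; k larger than the gene count returns all genes.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(transformed):
        logger.warning("k=%d exceeds %d genes; returning all", k, len(transformed))
        k = len(transformed)
    variances = transformed.var(axis=1, ddof=1)
    order = sorted(transformed.index, key=lambda g: (-variances[g], g))
    return order[:k]


@dataclass(frozen=True)
class Dendrogram:
    """Average-linkage merge tree over samples (scipy linkage encoding)."""

    linkage: np.ndarray
    sample_ids: tuple[str, ...]

    def to_newick(self) -> str:
        tree = TreeNode.from_linkage_matrix(self.linkage, list(self.sample_ids))
        return str(tree).strip() + ("\n" if not str(tree).endswith("\n") else "")

    def leaf_sets(self) -> list[frozenset[str]]:
        """Leaf-name set below every internal node."""
        root = hierarchy.to_tree(self.linkage)
        sets: list[frozenset[str]] = []

        def walk(node) -> frozenset[str]:
            if node.is_leaf():
                return frozenset([self.sample_ids[node.id]])
            leaves = walk(node.left) | walk(node.right)
            sets.append(leaves)
            return leaves

        walk(root)
        return sets

    def is_clade(self, samples) -> bool:
        """True if ``samples`` form one monophyletic group in the tree."""
        target = frozenset(samples)
        full = frozenset(self.sample_ids)
        if target == full:
            return True
        return target in self.leaf_sets() or (full - target) in self.leaf_sets()


def correlation_distances(transformed: pd.DataFrame) -> np.ndarray:
    """Condensed 1 - Pearson distance between sample columns.

    Zero-variance profiles have undefined correlations; these are set to
    0 (distance 1) with a logged warning.
    """
    x = transformed.to_numpy(dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("transformed matrix must be finite")
    sd = x.std(axis=0)
    if (sd == 0).any():
        logger.warning("%d zero-variance sample profiles; correlations set to 0",
                       int((sd == 0).sum()))
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = np.corrcoef(x, rowvar=False)
    corr = np.nan_to_num(corr, nan=0.0)
    np.fill_diagonal(corr, 1.0)
    dist = 1.0 - corr
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    return squareform(dist, checks=False)


def cluster_samples(transformed: pd.DataFrame) -> Dendrogram:
    """Agglomerative average-linkage clustering on correlation distance."""
    if transformed.shape[1] < 2:
        raise ValueError("clustering needs >= 2 samples")
    condensed = correlation_distances(transformed)
    linkage = hierarchy.linkage(condensed, method="average")
    return Dendrogram(linkage=linkage, sample_ids=tuple(transformed.columns))


@dataclass(frozen=True)
class PCAResult:
    """Per-sample component scores and per-component variance fractions."""

    scores: pd.DataFrame
    variance_fractions: np.ndarray


def pca_samples(transformed: pd.DataFrame, n_components: int = 2) -> PCAResult:
    """Gene-centered PCA of samples.

    Samples are observations, genes features; each gene is centered
    across samples.  Requested components beyond the data's rank are
    truncated with a warning.
    """
    if transformed.shape[1] < 2:
        raise ValueError("PCA needs >= 2 samples")
    x = transformed.to_numpy(dtype=float).T  # samples x genes
    max_rank = min(x.shape[0] - 1, x.shape[1])
    if n_components > max_rank:
        logger.warning("truncating PCA components from %d to rank %d", n_components, max_rank)
        n_components = max_rank
    model = PCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(x)
    cols = [f"PC{i + 1}" for i in range(n_components)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=transformed.columns, columns=cols),
        variance_fractions=model.explained_variance_ratio_.copy(),
    )


def export_heatmap_table(
    transformed: pd.DataFrame,
    gene_subset,
    sample_order=None,
    path=None,
) -> pd.DataFrame:
    """Row-wise min-max scaled expression in [0, 1], heat-map ready.

    A constant row carries no contrast and maps to 0.5 everywhere (logged).
    Written tab-separated when ``path`` is given.
    """
    genes = list(gene_subset)
    if not genes:
        raise ValueError("gene subset must be non-empty")
    samples = list(sample_order) if sample_order is not None else list(transformed.columns)
    sub = transformed.loc[genes, samples]
    lo = sub.min(axis=1)
    span = sub.max(axis=1) - lo
    constant = span == 0
    if constant.any():
        logger.warning("%d constant rows set to 0.5", int(constant.sum()))
    scaled = sub.sub(lo, axis=0).div(span.where(~constant, 1.0), axis=0)
    scaled[constant] = 0.5
    if path is not None:
        scaled.rename_axis("gene_id").to_csv(path, sep="\t")
    return scaled


def render_heatmap(scaled: pd.DataFrame, path) -> None:
    """Optional PNG/SVG rendering (blue = low, red = high per row)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(max(4, scaled.shape[1] * 0.5),
                                    max(4, scaled.shape[0] * 0.05)))
    ax.imshow(scaled.to_numpy(), aspect="auto", cmap="coolwarm", vmin=0, vmax=1)
    ax.set_xticks(range(scaled.shape[1]), scaled.columns, rotation=90, fontsize=6)
    ax.set_yticks([])
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
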