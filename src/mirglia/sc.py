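"""Single-cell QC, clustering, and DAM subclustering.

Disease-associated microglia (DAM) are a transcriptional state surrounding
amyloid pathology.  This module reproduces the desk analysis that splits
the DAM cluster by a phagocytic miRNA-target gene signature:

* :func:`qc_filter` — remove genes seen in fewer than 3 cells, cells with
  fewer than 200 detected genes, and cells with more than 5% mitochondrial
  counts, in that order;
* :func:`normalize_and_project` — library-size normalization, log1p,
  selection of the 2000 most variable genes, per-gene scaling, and PCA
  (20 components);
* :func:`cluster_cells` — graph-based (Leiden) or k-means clustering of the
  embedding;
* :func:`signature_score` / :func:`annotate_clusters` — per-cell mean
  z-score over a gene set, with clusters labeled by their best-scoring set;
* :class:`DAMSubclusterer` — two-way split of the DAM cells in the PC space
  of the signature genes, the higher-scoring subcluster labeled
  ``phagocytic_dam``;
* :func:`de_between_subclusters` / :func:`exclude_shared` — rank-sum DE
  between the subclusters with BH correction, then removal of the DAM
  markers the two subpopulations share.

Count matrices travel as :class:`anndata.AnnData` (cells × genes, raw
integer counts in ``X``); scanpy performs the standard preprocessing steps.
"""

from __future__ import annotations

import logging

import anndata as ad
import numpy as np
import pandas as pd
import scanpy as scpy
from scipy import sparse, stats
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from mirglia.exceptions import ConfigurationError, ParameterError

logger = logging.getLogger(__name__)

PHAGOCYTIC_LABEL = "phagocytic_dam"
NONPHAGOCYTIC_LABEL = "nonphagocytic_dam"


def _dense(X) -> np.ndarray:
    return np.asarray(X.todense()) if sparse.issparse(X) else np.asarray(X)


def qc_filter(
    adata: ad.AnnData,
    min_cells_per_gene: int = 3,
    min_genes_per_cell: int = 200,
    max_mito_fraction: float = 0.05,
    mito_prefix: str = "mt-",
) -> ad.AnnData:
    """Standard QC: gene support, detected genes per cell, mito fraction.

    Filters are applied in order: genes expressed in at least
    ``min_cells_per_gene`` cells are kept; then cells expressing at least
    ``min_genes_per_cell`` genes; then cells whose mitochondrial fraction
    (computed on the surviving genes) exceeds ``max_mito_fraction`` are
    removed — the keep thresholds are inclusive, the mito cut strict, so a
    cell at exactly the cap survives.  Mitochondrial genes are taken from a
    boolean ``var['mito']`` column when present, else by name prefix
    (case-insensitive).
    """
    out = adata.copy()
    scpy.pp.filter_genes(out, min_cells=min_cells_per_gene)
    scpy.pp.filter_cells(out, min_genes=min_genes_per_cell)
    if "mito" in out.var.columns:
        mito = out.var["mito"].to_numpy(dtype=bool)
    else:
        mito = np.asarray(out.var_names.str.lower().str.startswith(mito_prefix.lower()))
    totals = np.ravel(_dense(out.X).sum(axis=1))
    mito_counts = np.ravel(_dense(out.X[:, mito]).sum(axis=1)) if mito.any() else np.zeros_like(totals)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(totals > 0, mito_counts / totals, 0.0)
    out.obs["mito_fraction"] = frac
    out = out[frac <= max_mito_fraction].copy()
    if out.n_obs == 0 or out.n_vars == 0:
        logger.warning("qc_filter removed every cell or gene")
    return out


def normalize_and_project(
    adata: ad.AnnData,
    n_components: int = 20,
    n_top_genes: int = 2000,
    target_sum: float = 1e4,
    random_state: int = 0,
) -> ad.AnnData:
    """Normalize, log-transform, and project to principal components.

    Library sizes are scaled to a common total, counts log1p-transformed,
    the ``n_top_genes`` most variable genes selected (Seurat flavor),
    standardized per gene, and projected onto ``n_components`` PCs.  The
    embedding lands in ``.obsm['X_pca']``; the log-normalized expression is
    kept in ``.layers['lognorm']``.
    """
    out = adata.copy()
    scpy.pp.normalize_total(out, target_sum=target_sum)
    scpy.pp.log1p(out)
    out.layers["lognorm"] = out.X.copy()
    max_rank = int(min(out.n_obs - 1, out.n_vars))
    if n_components > max_rank:
        logger.warning("n_components reduced from %d to matrix rank %d", n_components, max_rank)
        n_components = max_rank
    n_hvg = min(n_top_genes, out.n_vars)
    if out.n_vars > n_hvg:
        scpy.pp.highly_variable_genes(out, n_top_genes=n_hvg, flavor="seurat")
        hvg = out.var["highly_variable"].to_numpy()
    else:
        hvg = np.ones(out.n_vars, dtype=bool)
    X = _dense(out.X)[:, hvg].astype(np.float64)
    mu, sd = X.mean(axis=0), X.std(axis=0)
    Xs = (X - mu) / np.where(sd > 0, sd, 1.0)
    pca = PCA(n_components=n_components, svd_solver="full", random_state=random_state)
    out.obsm["X_pca"] = pca.fit_transform(Xs)
    out.uns["pca_variance_ratio"] = pca.explained_variance_ratio_
    return out


def cluster_cells(
    adata: ad.AnnData,
    method: str = "leiden",
    resolution: float = 0.2,
    n_clusters: int | None = None,
    random_state: int = 0,
) -> np.ndarray:
    """Cluster cells on their PCA embedding.

    ``leiden`` runs a k-NN graph + Leiden partition at the given resolution
    (a granularity knob; the cluster count is data-dependent); ``kmeans``
    fixes ``n_clusters``.  Deterministic under a fixed ``random_state``.
    """
    if "X_pca" not in adata.obsm:
        raise ParameterError("run normalize_and_project first")
    emb = adata.obsm["X_pca"]
    if np.allclose(emb.std(axis=0), 0):
        logger.warning("degenerate embedding; returning a single cluster")
        return np.zeros(adata.n_obs, dtype=int)
    if method == "kmeans":
        if n_clusters is None:
            raise ParameterError("kmeans requires n_clusters")
        km = KMeans(n_clusters=n_clusters, n_init=10, random_state=random_state)
        return km.fit_predict(emb)
    if method != "leiden":
        raise ParameterError("method must be 'leiden' or 'kmeans'")
    scpy.pp.neighbors(adata, use_rep="X_pca", random_state=random_state)
    scpy.tl.leiden(
        adata,
        resolution=resolution,
        random_state=random_state,
        flavor="igraph",
        n_iterations=2,
        directed=False,
    )
    return adata.obs["leiden"].astype(int).to_numpy()


def _lognorm_z(adata: ad.AnnData, genes: list[str]) -> np.ndarray:
    """Per-gene z-scored log-normalized expression for the given genes."""
    if "lognorm" in adata.layers:
        X = _dense(adata[:, genes].layers["lognorm"])
    else:
        X = np.log1p(_dense(adata[:, genes].X))
    mu, sd = X.mean(axis=0), X.std(axis=0)
    return (X - mu) / np.where(sd > 0, sd, 1.0)


def signature_score(adata: ad.AnnData, gene_set) -> np.ndarray:
    """Per-cell mean z-score of a gene set on log-normalized expression.

    A one-gene set reduces to that gene's z-score.  Raises when no
    signature gene survives QC.
    """
    present = [g for g in gene_set if g in adata.var_names]
    if not present:
        raise ConfigurationError("no signature gene present in the matrix")
    if len(present) < len(list(gene_set)):
        logger.warning("%d signature gene(s) absent from matrix", len(list(gene_set)) - len(present))
    return _lognorm_z(adata, present).mean(axis=1)


def annotate_clusters(adata: ad.AnnData, labels, gene_sets: dict) -> dict:
    """Assign each cluster the gene set with the highest mean signature score."""
    labels = np.asarray(labels)
    scores = {name: signature_score(adata, genes) for name, genes in gene_sets.items()}
    annotation = {}
    for cl in np.unique(labels):
        mask = labels == cl
        annotation[cl] = max(scores, key=lambda name: scores[name][mask].mean())
    return annotation


class DAMSubclusterer(ClusterMixin, BaseEstimator):
    """Two-way split of DAM cells by their phagocytic signature.

    PCA is recomputed on the signature genes only, restricted to the DAM
    cells, and the cells are partitioned with 2-means.  The subcluster with
    the higher mean signature score is labeled ``phagocytic_dam``, the
    other ``nonphagocytic_dam`` — the orientation is part of the contract,
    not an arbitrary cluster index.

    Parameters
    ----------
    signature_genes : list of str
        The phagocytic miRNA-target panel.
    n_components : int, default=10
        PCs retained from the signature-gene expression (capped at the
        available rank).
    min_cluster_size : int, default=10
        Fitting aborts when fewer than ``2 * min_cluster_size`` DAM cells
        are supplied.
    random_state : int, default=0

    Attributes
    ----------
    labels_ : ndarray of str
        ``phagocytic_dam`` / ``nonphagocytic_dam`` per cell.
    score_ : ndarray
        Per-cell mean z-score of the signature.
    embedding_ : ndarray
        The signature-gene PC coordinates used for clustering.
    """

    def __init__(
        self,
        signature_genes=(),
        n_components: int = 10,
        min_cluster_size: int = 10,
        random_state: int = 0,
    ) -> None:
        self.signature_genes = signature_genes
        self.n_components = n_components
        self.min_cluster_size = min_cluster_size
        self.random_state = random_state

    def fit(self, X, y=None):
        adata = X if isinstance(X, ad.AnnData) else ad.AnnData(np.asarray(X))
        if adata.n_obs < 2 * self.min_cluster_size:
            raise ParameterError(
                f"need at least {2 * self.min_cluster_size} DAM cells, got {adata.n_obs}"
            )
        present = [g for g in self.signature_genes if g in adata.var_names]
        if not present:
            raise ConfigurationError("no signature gene present in the DAM matrix")
        Z = _lognorm_z(adata, present)
        n_comp = int(min(self.n_components, Z.shape[1], adata.n_obs - 1))
        pca = PCA(n_components=n_comp, svd_solver="full", random_state=self.random_state)
        emb = pca.fit_transform(Z)
        km = KMeans(n_clusters=2, n_init=10, random_state=self.random_state)
        raw = km.fit_predict(emb)
        score = Z.mean(axis=1)
        hi = int(score[raw == 1].mean() > score[raw == 0].mean())
        self.labels_ = np.where(raw == hi, PHAGOCYTIC_LABEL, NONPHAGOCYTIC_LABEL)
        self.score_ = score
        self.embedding_ = emb
        self.signature_genes_used_ = present
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X, y).labels_


def subcluster_dam(adata: ad.AnnData, dam_mask, signature_genes, **kwargs) -> pd.Series:
    """Label the DAM cells of ``adata`` as phagocytic / non-phagocytic.

    Thin wrapper over :class:`DAMSubclusterer`; returns a Series indexed by
    the DAM cell names.
    """
    dam_mask = np.asarray(dam_mask, dtype=bool)
    sub = adata[dam_mask].copy()
    labels = DAMSubclusterer(signature_genes=signature_genes, **kwargs).fit_predict(sub)
    return pd.Series(labels, index=sub.obs_names, name="dam_subcluster")


def de_between_subclusters(
    adata: ad.AnnData,
    labels,
    alpha: float = 0.05,
    target_sum: float = 1e4,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Rank-sum DE between the two DAM subclusters.

    Per gene: two-sided Wilcoxon rank-sum on library-size-normalized
    counts, BH correction across genes, and log2 fold change of the
    normalized group means (with a small pseudocount).  Returns the
    significant markers up in each subcluster,
    ``(de_phagocytic, de_nonphagocytic)``.
    """
    labels = np.asarray(labels)
    levels = np.unique(labels)
    if len(levels) != 2:
        raise ParameterError("labels must contain exactly two subclusters")
    a_name = PHAGOCYTIC_LABEL if PHAGOCYTIC_LABEL in levels else levels[0]
    b_name = [lv for lv in levels if lv != a_name][0]
    X = _dense(adata.X).astype(float)
    sizes = X.sum(axis=1, keepdims=True)
    norm = X / np.where(sizes > 0, sizes, 1.0) * target_sum
    a, b = norm[labels == a_name], norm[labels == b_name]
    eps = 1e-9
    lfc = np.log2((a.mean(axis=0) + eps) / (b.mean(axis=0) + eps))
    pvals = np.ones(adata.n_vars)
    for j in range(adata.n_vars):
        if np.ptp(norm[:, j]) > 0:
            pvals[j] = stats.mannwhitneyu(a[:, j], b[:, j], alternative="two-sided").pvalue
    padj = multipletests(pvals, method="fdr_bh")[1]
    table = pd.DataFrame(
        {
            "feature_id": adata.var_names,
            "log2fc": lfc,
            "p_value": pvals,
            "fdr": padj,
        }
    )
    sig = table.loc[table["fdr"] < alpha]
    de_a = sig.loc[sig["log2fc"] > 0].reset_index(drop=True)
    de_b = sig.loc[sig["log2fc"] < 0].reset_index(drop=True)
    return de_a, de_b


def exclude_shared(de_lists: tuple[pd.DataFrame, pd.DataFrame], dam_markers) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop shared DAM markers from both subcluster DE lists.

    An empty marker list is the identity (with a warning) so downstream
    tables are always defined.
    """
    markers = set(dam_markers)
    if not markers:
        logger.warning("empty DAM marker list; exclusion is the identity")
        return de_lists
    return tuple(
        df.loc[~df["feature_id"].isin(markers)].reset_index(drop=True) for df in de_lists
    )
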