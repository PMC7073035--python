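"""Minimal single-cell processing chain: QC filtering, normalization, HVG
selection, PCA, kNN graph, modularity clustering, marker ranking and
marker-overlap cluster annotation.

Cells live in an :class:`anndata.AnnData` with raw integer UMI counts in
``.X``, per-cell metadata in ``.obs`` (``batch``, ``total_counts``,
``n_genes``, ``mito_frac``, ``cluster``, ``pseudotime``) and the normalized
log layer in ``.layers["lognorm"]``. Raw counts are never mutated — pathway
scoring reads them directly.

Batch correction (MNN) and batch-balanced neighbor graphs are deliberately
not re-implemented here; the graph is built on pooled PCA coordinates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
from anndata import AnnData
from scipy import sparse
from scipy import stats as sps
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .genesets import GeneSet

__all__ = [
    "QCThresholds",
    "QC_PRESETS",
    "compute_qc_metrics",
    "filter_cells",
    "normalize_log",
    "select_common_hvg",
    "embed_pca",
    "knn_graph",
    "cluster_graph",
    "rank_markers_ttest",
    "annotate_clusters_overlap",
]

log = logging.getLogger(__name__)

LOGNORM_LAYER = "lognorm"


@dataclass(frozen=True)
class QCThresholds:
    """Cell-level QC gates. ``min_umi`` and the two maxima are exclusive
    ("more than" / "fewer than"); the gene-count window is inclusive."""

    min_umi: int = 0
    min_genes: int = 0
    max_genes: int = 10 ** 9
    max_umi: int | None = None
    max_mito_fraction: float | None = None

    def __post_init__(self) -> None:
        if self.min_genes > self.max_genes:
            raise ValueError("min_genes > max_genes")
        if min(self.min_umi, self.min_genes) < 0:
            raise ValueError("thresholds must be >= 0")


#: Presets mirroring the two published analyses: embryonic-day-15 mouse retina
#: (UMIs > 2000, 400–3500 genes) and human retinal organoids (500–7000 genes,
#: < 20,000 UMIs, mitochondrial fraction < 0.001). The organoid mitochondrial
#: cut is implemented exactly as printed (0.1%, unusually strict) but is an
#: ordinary parameter and can be overridden.
QC_PRESETS: dict[str, QCThresholds] = {
    "e15_mouse": QCThresholds(min_umi=2000, min_genes=400, max_genes=3500),
    "organoid": QCThresholds(min_genes=500, max_genes=7000, max_umi=20_000,
                             max_mito_fraction=0.001),
}


def compute_qc_metrics(adata: AnnData, mito_prefixes: tuple[str, ...] = ("MT-", "mt-")) -> AnnData:
    """Fill ``total_counts``, ``n_genes`` and ``mito_frac`` in ``adata.obs``.

    ``mito_frac`` is the fraction of a cell's UMIs falling on genes whose
    symbol starts with one of ``mito_prefixes``; cells with zero total UMIs
    get ``mito_frac = 0`` and are flagged in ``obs["zero_count_cell"]``.
    """
    x = adata.X
    if sparse.issparse(x):
        totals = np.asarray(x.sum(axis=1)).ravel()
        n_genes = np.asarray((x > 0).sum(axis=1)).ravel()
    else:
        totals = np.asarray(x).sum(axis=1)
        n_genes = (np.asarray(x) > 0).sum(axis=1)
    mito_mask = np.array([any(g.startswith(p) for p in mito_prefixes)
                          for g in adata.var_names])
    if mito_mask.any():
        xm = x[:, mito_mask]
        mito = np.asarray(xm.sum(axis=1)).ravel() if sparse.issparse(xm) else np.asarray(xm).sum(axis=1)
    else:
        mito = np.zeros(adata.n_obs)
    zero = totals == 0
    frac = np.divide(mito, totals, out=np.zeros_like(mito, dtype=float), where=~zero)
    adata.obs["total_counts"] = totals
    adata.obs["n_genes"] = n_genes
    adata.obs["mito_frac"] = frac
    adata.obs["zero_count_cell"] = zero
    return adata


def filter_cells(adata: AnnData, t: QCThresholds) -> AnnData:
    """Return the subset of cells passing all QC gates; gene axis unchanged.

    Logs a per-criterion removal count. An empty result is a warning, not an
    error. Idempotent: re-filtering a filtered matrix removes nothing.
    """
    obs = adata.obs
    for col in ("total_counts", "n_genes", "mito_frac"):
        if col not in obs:
            raise ValueError("run compute_qc_metrics first")
    umi = obs["total_counts"].to_numpy()
    ng = obs["n_genes"].to_numpy()
    keep = umi > t.min_umi
    removed = {"min_umi": int((~keep).sum())}
    m = (ng >= t.min_genes) & (ng <= t.max_genes)
    removed["gene_window"] = int((keep & ~m).sum())
    keep &= m
    if t.max_umi is not None:
        m = umi < t.max_umi
        removed["max_umi"] = int((keep & ~m).sum())
        keep &= m
    if t.max_mito_fraction is not None:
        m = obs["mito_frac"].to_numpy() < t.max_mito_fraction
        removed["mito"] = int((keep & ~m).sum())
        keep &= m
    log.info("filter_cells: kept %d/%d cells; removed per criterion %s",
             int(keep.sum()), adata.n_obs, removed)
    if not keep.any():
        log.warning("filter_cells: no cells pass QC thresholds %s", t)
    return adata[keep].copy()


def normalize_log(adata: AnnData, target_sum: float = 1e4) -> AnnData:
    """Add a ``lognorm`` layer: per-cell scaling to ``target_sum`` total
    counts followed by natural log1p. Raw counts are left untouched (pathway
    scores use them); all-zero cells stay all-zero and are flagged."""
    x = adata.X
    totals = np.asarray(x.sum(axis=1)).ravel()
    zero = totals == 0
    if zero.any():
        log.warning("normalize_log: %d zero-count cells left all-zero", int(zero.sum()))
    scale = np.divide(target_sum, totals, out=np.zeros_like(totals, dtype=float), where=~zero)
    if sparse.issparse(x):
        layer = x.tocsr().astype(float).multiply(scale[:, None]).tocsr()
        layer.data = np.log1p(layer.data)
    else:
        layer = np.log1p(np.asarray(x, dtype=float) * scale[:, None])
    adata.layers[LOGNORM_LAYER] = layer
    return adata


def _dense_layer(adata: AnnData) -> np.ndarray:
    if LOGNORM_LAYER not in adata.layers:
        raise ValueError("run normalize_log first")
    layer = adata.layers[LOGNORM_LAYER]
    return layer.toarray() if sparse.issparse(layer) else np.asarray(layer)


def _normalized_dispersion(x: np.ndarray, n_bins: int = 20) -> np.ndarray:
    """Dispersion (var/mean of the log layer) standardized within mean bins.

    Standardization uses the bin median and median absolute deviation, so a
    handful of genuinely variable genes cannot inflate their own bin's scale.
    """
    mean = x.mean(axis=0)
    var = x.var(axis=0, ddof=1) if x.shape[0] > 1 else np.zeros(x.shape[1])
    disp = np.divide(var, mean, out=np.zeros_like(var), where=mean > 0)
    order = np.argsort(mean)
    z = np.zeros_like(disp)
    # equal-count mean bins; small panels get fewer bins so each holds
    # enough genes to estimate a scale
    n_bins = min(n_bins, max(1, x.shape[1] // 10))
    for chunk in np.array_split(order, n_bins):
        d = disp[chunk]
        med = np.median(d)
        mad = np.median(np.abs(d - med))
        scale = 1.4826 * mad if mad > 0 else (d.std() or 1.0)
        z[chunk] = (d - med) / scale
    return z


def select_common_hvg(adata: AnnData, n_per_batch: int = 1000,
                      batch_key: str = "batch", n_genes: int | None = None) -> list[str]:
    """Highly variable genes shared across batches.

    Per batch, genes are ranked by normalized dispersion (variance/mean of the
    log layer, standardized within 20 mean bins). Returns the intersection of
    per-batch top-``n_per_batch`` lists; with ``n_genes`` set, returns instead
    the ``n_genes`` genes with the best (smallest) worst-case rank across
    batches. A single batch reduces to a plain top list.
    """
    x = _dense_layer(adata)
    batches = (adata.obs[batch_key] if batch_key in adata.obs
               else pd.Series("all", index=adata.obs_names))
    ranks = []
    for _, idx in batches.groupby(batches, observed=True).groups.items():
        z = _normalized_dispersion(x[adata.obs_names.get_indexer(idx)])
        # rank 0 = most variable
        r = np.empty(z.size, dtype=int)
        r[np.argsort(-z, kind="stable")] = np.arange(z.size)
        ranks.append(r)
    ranks = np.vstack(ranks)
    worst = ranks.max(axis=0)
    if n_genes is not None:
        order = np.argsort(worst, kind="stable")[:n_genes]
        return list(adata.var_names[np.sort(order)])
    keep = (ranks < n_per_batch).all(axis=0)
    return list(adata.var_names[keep])


def embed_pca(adata: AnnData, genes: list[str] | None = None,
              n_pcs: int = 40, seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Centered PCA of the log layer on the given genes.

    Returns ``(coords, explained_variance_ratio)`` with components ordered by
    decreasing explained variance. ``n_pcs`` larger than the data rank is
    clipped with a warning.
    """
    x = _dense_layer(adata)
    if genes is not None:
        missing = set(genes) - set(adata.var_names)
        if missing:
            raise KeyError(f"genes not in panel: {sorted(missing)[:5]}...")
        x = x[:, adata.var_names.get_indexer(genes)]
    max_pcs = min(x.shape[0] - 1, x.shape[1])
    if n_pcs > max_pcs:
        log.warning("embed_pca: clipping n_pcs %d -> %d", n_pcs, max_pcs)
        n_pcs = max_pcs
    pca = PCA(n_components=n_pcs, svd_solver="full" if min(x.shape) < 500 else "randomized",
              random_state=seed)
    coords = pca.fit_transform(x)
    return coords, pca.explained_variance_ratio_


def knn_graph(coords: np.ndarray, k: int = 15) -> sparse.csr_matrix:
    """Symmetric kNN graph on Euclidean distances.

    Each cell is linked to its k nearest neighbors (ties broken by cell
    index), the edge set is symmetrized by union, and weights are the
    similarity ``1/(1+distance)``. Returned as a sparse adjacency matrix.
    """
    n = coords.shape[0]
    if k >= n:
        raise ValueError("k must be smaller than the number of cells")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(coords)
    dist, idx = nn.kneighbors(coords)
    rows = np.repeat(np.arange(n), k)
    cols = idx[:, 1:].ravel()  # drop self
    sim = 1.0 / (1.0 + dist[:, 1:].ravel())
    a = sparse.csr_matrix((sim, (rows, cols)), shape=(n, n))
    return a.maximum(a.T)


def _adjacency_to_igraph(adj: sparse.csr_matrix) -> ig.Graph:
    coo = sparse.triu(adj, k=1).tocoo()
    g = ig.Graph(n=adj.shape[0], edges=list(zip(coo.row.tolist(), coo.col.tolist())))
    g.es["weight"] = coo.data.tolist()
    return g


def cluster_graph(adj: sparse.csr_matrix, resolution: float = 1.0, seed: int = 0,
                  algorithm: str = "leiden") -> np.ndarray:
    """Modularity-optimizing community detection on a weighted graph.

    ``algorithm`` selects Leiden (default) or the Louvain-style multilevel
    method; both are deterministic given ``seed``. Returns an integer cluster
    id per cell.
    """
    g = _adjacency_to_igraph(adj)
    if algorithm == "leiden":
        part = leidenalg.find_partition(
            g, leidenalg.RBConfigurationVertexPartition,
            weights="weight", resolution_parameter=resolution, seed=seed,
            n_iterations=2,
        )
        labels = np.array(part.membership)
    elif algorithm == "louvain":
        import random
        random.seed(seed)
        part = g.community_multilevel(weights="weight", resolution=resolution)
        labels = np.array(part.membership)
    else:
        raise ValueError(f"unknown algorithm {algorithm!r}")
    return labels


def rank_markers_ttest(adata: AnnData, cluster_key: str = "cluster",
                       top_n: int = 100) -> dict[str, pd.DataFrame]:
    """Welch t-test of each cluster against all other cells, per gene.

    Computed on the log layer; per cluster the ``top_n`` genes with largest
    positive t-statistic (upregulated only) are returned ordered by
    decreasing t. Clusters with fewer than 3 cells are skipped with a warning.
    """
    x = _dense_layer(adata)
    labels = adata.obs[cluster_key]
    out: dict[str, pd.DataFrame] = {}
    for cl in labels.astype(str).unique():
        mask = (labels.astype(str) == cl).to_numpy()
        n1, n2 = int(mask.sum()), int((~mask).sum())
        if n1 < 3 or n2 < 3:
            log.warning("rank_markers_ttest: cluster %s has <3 cells, skipped", cl)
            continue
        m1, m2 = x[mask].mean(axis=0), x[~mask].mean(axis=0)
        v1, v2 = x[mask].var(axis=0, ddof=1), x[~mask].var(axis=0, ddof=1)
        se2 = v1 / n1 + v2 / n2
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se2 > 0, (m1 - m2) / np.sqrt(se2), 0.0)
            df = np.where(se2 > 0,
                          se2 ** 2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1) + 1e-300),
                          1.0)
        p = 2 * sps.t.sf(np.abs(t), df)
        pos = np.where(t > 0)[0]
        order = pos[np.argsort(-t[pos], kind="stable")][:top_n]
        out[cl] = pd.DataFrame({
            "gene": adata.var_names[order],
            "t": t[order],
            "p": p[order],
        }).reset_index(drop=True)
    return out


def annotate_clusters_overlap(markers: dict[str, pd.DataFrame],
                              reference: list[GeneSet]) -> dict[str, dict]:
    """Label clusters by overlap of their top markers with reference sets.

    The overlap coefficient is ``|markers ∩ ref| / min(|markers|, |ref|)``.
    The label is the argmax reference set; ties break by larger raw
    intersection, then lexical label order. Clusters with all-zero overlap
    get label ``"unassigned"``. Returns per cluster a dict with ``label``,
    ``score``, ``runner_up`` and ``runner_up_score``.
    """
    if not reference:
        raise ValueError("reference marker sets are empty")
    out = {}
    for cl, tab in markers.items():
        top = set(tab["gene"])
        scored = []
        for gs in reference:
            inter = len(top & set(gs.symbols))
            denom = min(len(top), len(gs)) or 1
            scored.append((inter / denom, inter, gs.name))
        # sort: score desc, raw intersection desc, label asc
        scored.sort(key=lambda s: (-s[0], -s[1], s[2]))
        best, second = scored[0], (scored[1] if len(scored) > 1 else (0.0, 0, ""))
        if best[0] == 0:
            out[cl] = {"label": "unassigned", "score": 0.0,
                       "runner_up": "", "runner_up_score": 0.0}
        else:
            out[cl] = {"label": best[2], "score": float(best[0]),
                       "runner_up": second[2], "runner_up_score": float(second[0])}
    return out
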