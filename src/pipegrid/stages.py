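"""Reference implementations of the scRNA-seq processing steps.

These are deliberately plain, self-contained versions of the standard
stages — log-normalization, covariate regression and unit-variance
scaling, feature ranking (mean / variance / trend-standardized variance /
binomial deviance), PCA embedding with optional variance weighting,
k-nearest-neighbor and shared-nearest-neighbor graphs, and pluggable
graph community detection — so the benchmarking engine can run complete
pipelines end-to-end and alternative subroutines can be swapped per step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .data import CountDataset

logger = logging.getLogger(__name__)

__all__ = [
    "NormalizedMatrix",
    "Embedding",
    "FeatureRanking",
    "lognormalize",
    "scale_features",
    "rank_features",
    "filter_features_by_type",
    "pca_embed",
    "build_neighbor_graph",
    "cluster_graph",
    "quick_cluster",
]


@dataclass
class NormalizedMatrix:
    """Gene x cell normalized expression with the per-cell size factors."""

    values: np.ndarray  # dense genes x cells
    size_factors: np.ndarray
    transform: str = "lognorm"


@dataclass
class Embedding:
    """Cell x component coordinates with per-component variances (descending)."""

    coords: np.ndarray
    variances: np.ndarray
    weighted: bool = True

    def __post_init__(self) -> None:
        if np.any(np.diff(self.variances) > 1e-9 * max(self.variances[0], 1e-30)):
            raise ValueError("component variances must be non-increasing")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("embedding coordinates must be finite")


@dataclass
class FeatureRanking:
    """Genes ordered by a selection criterion (descending, stable ties)."""

    order: np.ndarray  # gene indices, best first
    values: np.ndarray  # criterion value per gene (original order)
    method: str


def lognormalize(counts, scale_target: float = 1e4) -> NormalizedMatrix:
    """Library-size normalization followed by log1p.

    Each cell's counts are divided by its total, multiplied by
    ``scale_target`` (default 10,000) and log1p-transformed.
    """
    dense = counts.toarray() if sp.issparse(counts) else np.asarray(counts, float)
    totals = dense.sum(axis=0)
    if np.any(totals <= 0):
        raise ValueError("cells with zero total counts must be filtered first")
    sf = totals / scale_target
    return NormalizedMatrix(np.log1p(dense / sf), size_factors=sf)


def scale_features(
    norm: NormalizedMatrix | np.ndarray,
    covariates: pd.DataFrame | np.ndarray | None = None,
    clip: float | None = None,
) -> np.ndarray:
    """Per-gene centering and unit-variance scaling, optionally after
    regressing out cell-level covariates.

    When ``covariates`` is given, each gene is first replaced by the
    residuals of an ordinary least-squares fit on the covariates (with
    intercept). Zero-variance genes become all-zero rows. ``clip`` bounds
    the absolute scaled values if set.
    """
    X = norm.values if isinstance(norm, NormalizedMatrix) else np.asarray(norm, float)
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        if C.shape[0] != X.shape[1]:
            raise ValueError("covariate rows must match number of cells")
        D = np.column_stack([np.ones(C.shape[0]), C])
        beta, *_ = np.linalg.lstsq(D, X.T, rcond=None)
        X = X - (D @ beta).T
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    # rows whose spread is numerical noise (e.g. perfect covariate fits)
    # count as constant, not as unit-variance signal
    tiny = sd <= 1e-10 * max(np.abs(X).max(), 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        Z = np.where(~tiny, (X - mu) / np.where(tiny, 1.0, sd), 0.0)
    if clip is not None:
        Z = np.clip(Z, -clip, clip)
    return Z


def _fit_mean_var_trend(log_mean: np.ndarray, log_var: np.ndarray) -> np.ndarray:
    """Local (kernel-weighted) regression of log variance on log mean."""
    span = 0.3
    n = len(log_mean)
    order = np.argsort(log_mean)
    fitted = np.empty(n)
    x, y = log_mean[order], log_var[order]
    h = max(span * (x[-1] - x[0]), 1e-6)
    for i in range(n):
        w = np.exp(-0.5 * ((x - x[i]) / h) ** 2)
        W = w.sum()
        xm = (w * x).sum() / W
        ym = (w * y).sum() / W
        sxx = (w * (x - xm) ** 2).sum()
        slope = (w * (x - xm) * (y - ym)).sum() / sxx if sxx > 0 else 0.0
        fitted[i] = ym + slope * (x[i] - xm)
    out = np.empty(n)
    out[order] = fitted
    return out


def binomial_deviance(counts) -> np.ndarray:
    """Per-gene binomial deviance under a constant-proportion null.

    With per-cell totals ``n_i`` and gene counts ``y_gi``, the null says
    each gene takes a constant share ``pi_g`` of every cell's library.
    D_g = 2 sum_i [ y ln(y / (n pi)) + (n - y) ln((n - y) / (n (1 - pi))) ],
    with 0 ln 0 = 0. Large deviance marks genes whose share varies across
    cells — the count-based analogue of a highly variable gene.
    """
    Y = counts.toarray() if sp.issparse(counts) else np.asarray(counts, float)
    n = Y.sum(axis=0)
    pi = Y.sum(axis=1) / n.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        mu = np.outer(pi, n)
        t1 = Y * np.log(Y / mu)
        t1[Y == 0] = 0.0
        r = n[None, :] - Y
        t2 = r * np.log(r / (n[None, :] * (1 - pi[:, None])))
        t2[r == 0] = 0.0
    t1 = np.nan_to_num(t1, nan=0.0, posinf=0.0)
    t2 = np.nan_to_num(t2, nan=0.0, posinf=0.0)
    return 2.0 * (t1 + t2).sum(axis=1)


def rank_features(data, method: str = "variance") -> FeatureRanking:
    """Rank genes for feature selection.

    ``mean_expression`` / ``variance``: moments of the normalized values.
    ``standardized_variance``: variance of values standardized by a fitted
    mean-variance trend (clipped at sqrt(n)), so selection is not driven by
    expression level. ``deviance``: binomial deviance on raw counts.
    Ties break by gene index (stable sort on the negated criterion).
    """
    if method == "deviance":
        values = binomial_deviance(
            data.counts if isinstance(data, CountDataset) else data
        )
    else:
        X = data.values if isinstance(data, NormalizedMatrix) else np.asarray(data, float)
        if method == "mean_expression":
            values = X.mean(axis=1)
        elif method == "variance":
            values = X.var(axis=1, ddof=1)
        elif method == "standardized_variance":
            mean = X.mean(axis=1)
            var = X.var(axis=1, ddof=1)
            pos = var > 0
            values = np.zeros(X.shape[0])
            if pos.sum() >= 3:
                lm = np.log10(np.maximum(mean[pos], 1e-12))
                lv = np.log10(var[pos])
                fitted_sd = np.sqrt(10 ** _fit_mean_var_trend(lm, lv))
                Z = (X[pos] - mean[pos, None]) / fitted_sd[:, None]
                Z = np.clip(Z, -np.sqrt(X.shape[1]), np.sqrt(X.shape[1]))
                values[pos] = Z.var(axis=1, ddof=1)
        else:
            raise ValueError(f"unknown ranking method {method!r}")
    order = np.argsort(-values, kind="stable")
    return FeatureRanking(order=order, values=values, method=method)


def filter_features_by_type(ds: CountDataset, exclude=()) -> CountDataset:
    """Drop genes by annotation category.

    ``exclude`` is a subset of {"mito", "ribo", "noncoding"}.
    """
    exclude = set(exclude)
    unknown = exclude - {"mito", "ribo", "noncoding"}
    if unknown:
        raise ValueError(f"unknown feature categories: {sorted(unknown)}")
    drop = np.zeros(ds.n_genes, dtype=bool)
    if "mito" in exclude:
        drop |= ds.gene_meta["is_mito"].to_numpy(dtype=bool)
    if "ribo" in exclude:
        drop |= ds.gene_meta["is_ribo"].to_numpy(dtype=bool)
    if "noncoding" in exclude:
        drop |= ~ds.gene_meta["is_coding"].to_numpy(dtype=bool)
    if drop.all():
        raise ValueError("feature-type exclusion removes every gene")
    return ds.subset_genes(~drop)


def pca_embed(
    scaled: np.ndarray, n_components: int = 10, weight_by_variance: bool = True
) -> Embedding:
    """PCA of the gene-centered scaled matrix via truncated SVD.

    The weighted embedding (the common default) scales cell scores by each
    component's singular value, so components carry their variance;
    unweighted returns unit-variance scores. Column signs are fixed by
    making the largest-magnitude gene loading positive.
    """
    X = np.asarray(scaled, float)
    n_genes, n_cells = X.shape
    if n_components > min(n_genes, n_cells) - 1:
        raise ValueError("n_components too large for matrix size")
    Xc = X - X.mean(axis=1, keepdims=True)
    # cells are observations: SVD of the cells x genes matrix
    U, s, Vt = np.linalg.svd(Xc.T, full_matrices=False)
    U, s, Vt = U[:, :n_components], s[:n_components], Vt[:n_components]
    for j in range(n_components):
        i = np.argmax(np.abs(Vt[j]))
        if Vt[j, i] < 0:
            Vt[j] *= -1.0
            U[:, j] *= -1.0
    variances = s**2 / (n_cells - 1)
    if weight_by_variance:
        coords = U * s
    else:
        coords = U * np.sqrt(n_cells - 1)
    return Embedding(coords=coords, variances=variances, weighted=weight_by_variance)


def _knn_indices(
    coords: np.ndarray, k: int, exact: bool = True, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    n = coords.shape[0]
    if k >= n:
        raise ValueError("k must be smaller than the number of cells")
    if not exact:
        try:
            from pynndescent import NNDescent

            index = NNDescent(coords, n_neighbors=k + 1, random_state=seed)
            idx, dist = index.neighbor_graph
            return idx[:, 1 : k + 1], dist[:, 1 : k + 1]
        except ImportError:
            logger.warning("approximate search unavailable; using exact k-d tree")
    from sklearn.neighbors import NearestNeighbors

    nn = NearestNeighbors(n_neighbors=k + 1).fit(coords)
    dist, idx = nn.kneighbors(coords)
    # drop self; deterministic tie handling by index order from kneighbors
    out_i = np.empty((n, k), dtype=int)
    out_d = np.empty((n, k))
    for i in range(n):
        row = [j for j in range(k + 1) if idx[i, j] != i][:k]
        out_i[i] = idx[i, row]
        out_d[i] = dist[i, row]
    return out_i, out_d


def build_neighbor_graph(
    embedding: Embedding | np.ndarray,
    k: int = 15,
    graph_type: str = "snn_jaccard",
    exact: bool = True,
    seed: int = 0,
) -> sp.csr_matrix:
    """Weighted cell-cell graph as a symmetric sparse adjacency matrix.

    ``knn``: union-symmetrized k-nearest-neighbor edges, weight
    1 / (1 + distance). ``snn_jaccard``: kNN edges reweighted by the
    Jaccard overlap of the two endpoint neighborhoods (each including the
    point itself). ``snn_rank``: scran-flavored rank weights
    ``k - r/2`` with ``r`` the smallest rank sum over shared neighbors,
    clipped at zero.
    """
    coords = embedding.coords if isinstance(embedding, Embedding) else np.asarray(embedding)
    n = coords.shape[0]
    idx, dist = _knn_indices(coords, k, exact=exact, seed=seed)

    rows = np.repeat(np.arange(n), k)
    cols = idx.ravel()
    if graph_type == "knn":
        w = 1.0 / (1.0 + dist.ravel())
        A = sp.coo_matrix((w, (rows, cols)), shape=(n, n)).tocsr()
        A = A.maximum(A.T)
        return A
    # neighborhoods including self
    nbr_sets = [set(idx[i]) | {i} for i in range(n)]
    if graph_type == "snn_jaccard":
        data, ri, ci = [], [], []
        seen = set()
        for i in range(n):
            for j in idx[i]:
                a, b = (i, int(j)) if i < j else (int(j), i)
                if (a, b) in seen:
                    continue
                seen.add((a, b))
                inter = len(nbr_sets[a] & nbr_sets[b])
                union = len(nbr_sets[a] | nbr_sets[b])
                w = inter / union
                if w > 0:
                    ri.append(a)
                    ci.append(b)
                    data.append(w)
        A = sp.coo_matrix((data, (ri, ci)), shape=(n, n)).tocsr()
        return A.maximum(A.T)
    if graph_type == "snn_rank":
        # rank of neighbor j in i's list (self has rank 0)
        rank = {}
        for i in range(n):
            rank[(i, i)] = 0
            for r, j in enumerate(idx[i], start=1):
                rank[(i, int(j))] = r
        data, ri, ci = [], [], []
        seen = set()
        for i in range(n):
            for j in idx[i]:
                a, b = (i, int(j)) if i < j else (int(j), i)
                if (a, b) in seen:
                    continue
                seen.add((a, b))
                shared = nbr_sets[a] & nbr_sets[b]
                r = min(
                    rank.get((a, s), k + 1) + rank.get((b, s), k + 1) for s in shared
                )
                w = max(k - r / 2.0, 0.0)
                if w > 0:
                    ri.append(a)
                    ci.append(b)
                    data.append(w)
        A = sp.coo_matrix((data, (ri, ci)), shape=(n, n)).tocsr()
        return A.maximum(A.T)
    raise ValueError(f"unknown graph_type {graph_type!r}")


def _to_igraph(adj: sp.csr_matrix):
    import igraph as ig

    coo = sp.triu(adj, k=1).tocoo()
    g = ig.Graph(
        n=adj.shape[0],
        edges=list(zip(coo.row.tolist(), coo.col.tolist())),
        edge_attrs={"weight": coo.data.tolist()},
    )
    return g


def cluster_graph(
    adj: sp.csr_matrix,
    method: str = "modularity_resolution",
    resolution: float = 1.0,
    seed: int = 0,
) -> np.ndarray:
    """Community detection on a weighted cell-cell graph.

    ``modularity_resolution`` optimizes configuration-model modularity at
    the given resolution (Leiden); ``walk_based`` is random-walk community
    detection (walktrap); ``greedy_modularity`` is agglomerative modularity
    optimization. Only ``modularity_resolution`` honors ``resolution``.
    """
    if adj.shape[0] == 0:
        raise ValueError("empty graph")
    if adj.shape[0] == 1:
        return np.zeros(1, dtype=int)
    g = _to_igraph(adj)
    if method == "modularity_resolution":
        import leidenalg

        part = leidenalg.find_partition(
            g,
            leidenalg.RBConfigurationVertexPartition,
            weights="weight",
            resolution_parameter=resolution,
            seed=int(seed),
            n_iterations=2,
        )
        return np.asarray(part.membership)
    if method == "walk_based":
        dend = g.community_walktrap(weights="weight")
        return np.asarray(dend.as_clustering().membership)
    if method == "greedy_modularity":
        dend = g.community_fastgreedy(weights="weight")
        return np.asarray(dend.as_clustering().membership)
    raise ValueError(f"unknown clustering method {method!r}")


def quick_cluster(
    ds: CountDataset,
    n_hvg: int = 1000,
    n_pcs: int = 10,
    k: int = 15,
    seed: int = 0,
) -> np.ndarray:
    """Fast pre-clustering used by cluster-wise filtering and doublet
    generation: log-normalize, top variable genes, PCA, SNN graph,
    modularity clustering at resolution 1."""
    counts = ds.counts
    totals = np.asarray(counts.sum(axis=0)).ravel()
    ok = totals > 0
    if not ok.all():
        # zero-total cells form their own throwaway cluster
        labels = np.full(ds.n_cells, -1, dtype=int)
        sub = ds.subset_cells(ok)
        labels[ok] = quick_cluster(sub, n_hvg, n_pcs, k, seed)
        return labels
    norm = lognormalize(counts)
    rank = rank_features(norm, "variance")
    top = rank.order[: min(n_hvg, ds.n_genes)]
    Z = scale_features(NormalizedMatrix(norm.values[top], norm.size_factors))
    n_pcs = min(n_pcs, min(Z.shape) - 1)
    emb = pca_embed(Z, n_components=n_pcs)
    adj = build_neighbor_graph(emb, k=min(k, ds.n_cells - 1))
    return cluster_graph(adj, "modularity_resolution", resolution=1.0, seed=seed)
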