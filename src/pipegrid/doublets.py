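"""Cluster-informed artificial-doublet detection.

Real heterotypic doublets are sums of two transcript pools from different
cell types. The detector therefore pre-clusters the cells, fabricates
artificial doublets by summing the raw counts of cells drawn from
different clusters (optionally adding meta-cell-based composites that
emulate triplets), embeds real and artificial cells together, and scores
each real cell by the artificial-doublet enrichment of its k-nearest
neighborhood, normalized for the artificial:real ratio. Calls are made by
choosing a score threshold consistent with the expected doublet rate and
its uncertainty. Homotypic doublets are largely invisible to this (and
any count-based) approach, which is acceptable because they are not the
primary target of doublet removal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .data import CountDataset
from .stages import NormalizedMatrix, lognormalize, pca_embed, rank_features, scale_features

logger = logging.getLogger(__name__)

__all__ = [
    "DoubletCallParams",
    "generate_artificial_doublets",
    "score_doublets",
    "call_doublets",
    "doublet_roc",
    "find_doublets",
]


@dataclass
class DoubletCallParams:
    """Knobs of the artificial-doublet scorer and caller.

    ``n_artificial`` defaults to one artificial doublet per real cell;
    ``expected_rate`` is the anticipated doublet fraction with a tolerance
    half-width ``rate_uncertainty``; ``include_metacell_triplets`` adds
    cluster-mean + cell composites to the artificial pool.
    """

    n_artificial: int | None = None
    k_neighbors: int = 20
    expected_rate: float = 0.05
    rate_uncertainty: float = 0.02
    include_metacell_triplets: bool = False
    n_pcs: int = 10
    n_hvg: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.expected_rate < 0.5:
            raise ValueError("expected_rate must be in (0, 0.5)")
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")


def generate_artificial_doublets(
    ds: CountDataset,
    clusters: np.ndarray,
    params: DoubletCallParams,
):
    """Artificial doublet count matrix plus parent annotations.

    Each artificial doublet is the entrywise sum of two cells sampled from
    different clusters; with ``include_metacell_triplets``, an extra 25%
    are cluster meta-cell profiles (rounded per-gene means) added to a
    sampled cell from another cluster. A single cluster degrades to
    uniform random pairing (logged).
    """
    rng = np.random.default_rng(params.seed)
    clusters = np.asarray(clusters)
    n = ds.n_cells
    n_art = params.n_artificial or n
    if n_art < n / 10:
        raise ValueError("n_artificial must be at least a tenth of n_cells")
    uniq = np.unique(clusters)
    counts = sp.csc_matrix(ds.counts)
    if len(uniq) < 2:
        logger.warning("single cluster: artificial doublets from uniform pairs")
        pa = rng.integers(0, n, size=n_art)
        pb = (pa + 1 + rng.integers(0, n - 1, size=n_art)) % n
    else:
        pairs = [(a, b) for i, a in enumerate(uniq) for b in uniq[i + 1 :]]
        members = {c: np.flatnonzero(clusters == c) for c in uniq}
        pick = rng.integers(0, len(pairs), size=n_art)
        pa = np.array([rng.choice(members[pairs[p][0]]) for p in pick])
        pb = np.array([rng.choice(members[pairs[p][1]]) for p in pick])
    art = np.asarray(counts[:, pa].todense()) + np.asarray(counts[:, pb].todense())
    parents = pd.DataFrame(
        {"parent_a": pa, "parent_b": pb, "kind": "pair",
         "cluster_a": clusters[pa], "cluster_b": clusters[pb]}
    )
    if params.include_metacell_triplets and len(uniq) >= 2:
        n_tri = max(1, n_art // 4)
        metacells = {
            c: np.round(np.asarray(counts[:, members[c]].mean(axis=1)).ravel())
            for c in uniq
        }
        tri_cluster = rng.choice(uniq, size=n_tri)
        tri_cols = []
        tri_parent = []
        for c in tri_cluster:
            other = rng.choice(uniq[uniq != c])
            cell = rng.choice(members[other])
            tri_cols.append(metacells[c] + np.asarray(counts[:, cell].todense()).ravel())
            tri_parent.append((int(cell), c))
        art = np.hstack([art, np.column_stack(tri_cols)])
        tri_df = pd.DataFrame(
            {
                "parent_a": [p for p, _ in tri_parent],
                "parent_b": -1,
                "kind": "metacell_triplet",
                "cluster_a": [c for _, c in tri_parent],
                "cluster_b": tri_cluster,
            }
        )
        parents = pd.concat([parents, tri_df], ignore_index=True)
    return art, parents


def score_doublets(
    ds: CountDataset,
    artificial: np.ndarray,
    params: DoubletCallParams,
) -> np.ndarray:
    """Neighborhood artificial-doublet enrichment score per real cell.

    Real and artificial cells are embedded jointly (log-normalize, top
    variable genes, PCA); a cell's raw score is the artificial proportion
    among its k nearest neighbors, ratio-normalized so that 0.5 means the
    neighborhood matches the global artificial:real composition:
    score = (p/r) / (p/r + (1-p)/(1-r)) with r the realized artificial
    fraction. Scores are in [0, 1].
    """
    real = np.asarray(
        ds.counts.todense() if sp.issparse(ds.counts) else ds.counts, dtype=float
    )
    combined = np.hstack([real, np.asarray(artificial, dtype=float)])
    n_real = real.shape[1]
    n_art = combined.shape[1] - n_real
    norm = lognormalize(combined)
    ranking = rank_features(norm, "variance")
    top = ranking.order[: min(params.n_hvg, combined.shape[0])]
    Z = scale_features(NormalizedMatrix(norm.values[top], norm.size_factors))
    n_pcs = min(params.n_pcs, min(Z.shape) - 1)
    emb = pca_embed(Z, n_components=n_pcs)

    from sklearn.neighbors import NearestNeighbors

    k = params.k_neighbors
    if k >= combined.shape[1]:
        logger.warning("k=%d clipped to population size", k)
        k = combined.shape[1] - 1
    nn = NearestNeighbors(n_neighbors=k + 1).fit(emb.coords)
    _, idx = nn.kneighbors(emb.coords[:n_real])
    is_art = idx >= n_real
    # drop self-neighbors (always a real cell at distance 0)
    p = is_art[:, 1:].mean(axis=1)
    r = n_art / (n_real + n_art)
    with np.errstate(divide="ignore", invalid="ignore"):
        odds = (p / r) / np.where(1 - p > 0, (1 - p) / (1 - r), np.inf)
        score = np.where(p >= 1.0, 1.0, odds / (1.0 + odds))
    return np.clip(score, 0.0, 1.0)


def call_doublets(scores: np.ndarray, params: DoubletCallParams) -> pd.DataFrame:
    """Threshold scores into doublet calls near the expected rate.

    The admissible call counts span expected_rate +/- rate_uncertainty
    (times n); within that band the threshold is placed at the largest
    drop between consecutive sorted scores, balancing the expected count
    against the score distribution's separation. Zero uncertainty reduces
    to calling exactly round(expected_rate * n) top-scoring cells;
    constant scores degrade to the same count taken in index order.
    """
    scores = np.asarray(scores, dtype=float)
    n = len(scores)
    target = params.expected_rate * n
    lo = int(np.floor(max(0.0, (params.expected_rate - params.rate_uncertainty) * n)))
    hi = int(np.ceil(min(1.0, params.expected_rate + params.rate_uncertainty) * n))
    hi = min(hi, n)
    order = np.argsort(-scores, kind="stable")
    s_sorted = scores[order]
    if np.ptp(scores) == 0:
        logger.warning("constant scores: calling round(expected_rate*n) by index")
        n_call = int(round(target))
        call = np.zeros(n, dtype=bool)
        call[:n_call] = True
        threshold = float(scores[0]) if n else 0.5
    elif lo >= hi or params.rate_uncertainty == 0:
        n_call = int(round(target))
        call = np.zeros(n, dtype=bool)
        call[order[:n_call]] = True
        threshold = float(s_sorted[n_call - 1]) if n_call else float("inf")
    else:
        counts = np.arange(max(lo, 1), hi + 1)
        gaps = np.array(
            [s_sorted[c - 1] - (s_sorted[c] if c < n else 0.0) for c in counts]
        )
        n_call = int(counts[int(np.argmax(gaps))])
        call = np.zeros(n, dtype=bool)
        call[order[:n_call]] = True
        upper = s_sorted[n_call - 1]
        lower = s_sorted[n_call] if n_call < n else 0.0
        threshold = float((upper + lower) / 2.0)
    return pd.DataFrame({"score": scores, "call": call}).assign(threshold=threshold)


def doublet_roc(scores, truth) -> tuple[pd.DataFrame, float]:
    """ROC curve and trapezoidal AUROC of scores against truth flags."""
    from sklearn.metrics import roc_curve

    truth = np.asarray(truth, dtype=bool)
    if truth.all() or not truth.any():
        raise ValueError("truth must contain both classes")
    fpr, tpr, thr = roc_curve(truth, np.asarray(scores, float))
    auroc = float(np.trapezoid(tpr, fpr))
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr}), auroc


def find_doublets(
    ds: CountDataset,
    params: DoubletCallParams | None = None,
    clusters: np.ndarray | None = None,
) -> pd.DataFrame:
    """Full score-and-call path: pre-cluster, fabricate artificial
    doublets, score neighborhoods, threshold at the expected rate."""
    params = params or DoubletCallParams()
    if clusters is None:
        from .stages import quick_cluster

        clusters = quick_cluster(ds, seed=params.seed)
    art, _ = generate_artificial_doublets(ds, clusters, params)
    scores = score_doublets(ds, art, params)
    calls = call_doublets(scores, params)
    calls.index = ds.barcodes
    return calls
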