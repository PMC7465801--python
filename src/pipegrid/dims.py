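"""Estimating how many principal components to keep.

Three estimators: the automated elbow rule (farthest point from the chord
of the scree curve), a permutation-based significance test on gene
loadings with the same farthest-point rule applied to the log10 p-values,
and molecular cross-validation — each raw count is split binomially into
two pseudo-replicates, PCA is fitted on one half and scored by the
reconstruction error of the other, and the component count minimizing
that error is returned. Because of the 50-50 split, molecular
cross-validation tends to underestimate slightly.
"""

from __future__ import annotations

import logging

import numpy as np
import scipy.sparse as sp

from .stages import Embedding, lognormalize

logger = logging.getLogger(__name__)

__all__ = [
    "farthest_point",
    "elbow_dims",
    "jackstraw_pvalues",
    "jackstraw_dims",
    "mcv_split",
    "mcv_dims",
]


def farthest_point(curve) -> int:
    """1-based index of the curve point farthest from the first-last chord.

    Distances are perpendicular point-to-line distances on the (index,
    value) plane; ties (e.g. an exactly linear curve) return the smallest
    index. Invariant to jointly rescaling both axes.
    """
    y = np.asarray(curve, dtype=float)
    m = len(y)
    if m < 2:
        raise ValueError("curve needs at least two points")
    if m == 2:
        logger.warning("two-point curve: farthest point defaults to 1")
        return 1
    x = np.arange(1, m + 1, dtype=float)
    dx, dy = x[-1] - x[0], y[-1] - y[0]
    norm = np.hypot(dx, dy)
    d = np.abs(dy * (x - x[0]) - dx * (y - y[0])) / norm
    # ties (within floating noise, scaled with the chord so the rule stays
    # invariant to joint rescaling) resolve to the smallest index
    atol = 1e-9 * norm
    return int(np.argmax(d >= d.max() - atol)) + 1


def elbow_dims(embedding: Embedding | np.ndarray, max_components: int = 50) -> int:
    """Elbow rule on the variance-explained scree curve.

    Applies :func:`farthest_point` to the variances of the first
    ``max_components`` components (or all, if fewer).
    """
    var = embedding.variances if isinstance(embedding, Embedding) else np.asarray(embedding)
    return farthest_point(var[: min(max_components, len(var))])


def jackstraw_pvalues(
    scaled: np.ndarray,
    n_components: int = 20,
    n_perm: int = 100,
    perm_fraction: float = 0.01,
    seed: int = 0,
) -> np.ndarray:
    """Permutation p-values for each principal component.

    Per permutation, a random ``perm_fraction`` of genes have their values
    shuffled across cells and the PCA is recomputed; the shuffled genes'
    absolute loadings form the per-component null. Each component's
    p-value is a one-sided rank test (Mann-Whitney, greater) of the
    observed absolute gene loadings against that null — small p-values
    mean real structure. Components are judged by the farthest-point rule
    on log10 p-values rather than a hard threshold.
    """
    from scipy.stats import mannwhitneyu

    if n_perm < 20:
        raise ValueError("n_perm must be at least 20")
    rng = np.random.default_rng(seed)
    X = np.asarray(scaled, dtype=float)
    n_genes, n_cells = X.shape
    n_components = min(n_components, min(n_genes, n_cells) - 1)
    n_shuf = max(1, int(round(perm_fraction * n_genes)))

    def loadings(M: np.ndarray) -> np.ndarray:
        Mc = M - M.mean(axis=1, keepdims=True)
        _, _, Vt = np.linalg.svd(Mc.T, full_matrices=False)
        # gene loadings: rows genes x components
        return Vt[:n_components].T

    obs = np.abs(loadings(X))
    null = [[] for _ in range(n_components)]
    for _ in range(n_perm):
        idx = rng.choice(n_genes, size=n_shuf, replace=False)
        Xp = X.copy()
        for g in idx:
            Xp[g] = Xp[g, rng.permutation(n_cells)]
        lp = np.abs(loadings(Xp))
        for c in range(n_components):
            null[c].extend(lp[idx, c])
    pvals = np.empty(n_components)
    for c in range(n_components):
        nc = np.asarray(null[c])
        if nc.std() == 0 and obs[:, c].std() == 0:
            pvals[c] = 1.0
            continue
        pvals[c] = mannwhitneyu(obs[:, c], nc, alternative="greater").pvalue
    return np.clip(pvals, 1e-300, 1.0)


def jackstraw_dims(
    scaled: np.ndarray,
    n_components: int = 20,
    n_perm: int = 100,
    perm_fraction: float = 0.01,
    seed: int = 0,
) -> int:
    """Farthest point on the log10 jackstraw p-value curve (drop in
    significance rather than a p-value threshold)."""
    p = jackstraw_pvalues(scaled, n_components, n_perm, perm_fraction, seed)
    return farthest_point(np.log10(p))


def mcv_split(counts, proportion: float = 0.5, seed: int = 0):
    """Split each count binomially into two pseudo-replicates.

    Entry y becomes A ~ Binomial(y, proportion) and B = y - A, so A + B
    reproduces the input exactly. Non-integer counts are rounded up first.
    """
    rng = np.random.default_rng(seed)
    dense = counts.toarray() if sp.issparse(counts) else np.asarray(counts)
    if not np.issubdtype(dense.dtype, np.integer):
        if not np.allclose(dense, np.round(dense)):
            dense = np.ceil(dense)
        dense = dense.astype(np.int64)
    A = rng.binomial(dense, proportion)
    B = dense - A
    return A, B


def mcv_dims(
    counts,
    k_grid=None,
    seed: int = 0,
    scale_target: float = 1e4,
    n_splits: int = 1,
):
    """Choose the PCA dimensionality by molecular cross-validation.

    The counts are split 50-50; both halves are log-normalized
    identically; PCA bases of increasing size are fitted on half A (genes
    centered on A's means) and half B's normalized matrix is projected and
    reconstructed through them. Returns the ``k`` minimizing the mean
    squared reconstruction error and the full MSE curve (averaged over
    ``n_splits`` independent splits).
    """
    dense = counts.toarray() if sp.issparse(counts) else np.asarray(counts)
    n_genes, n_cells = dense.shape
    if k_grid is None:
        k_grid = list(range(1, min(50, min(n_genes, n_cells) - 1) + 1))
    k_grid = sorted(int(k) for k in k_grid)
    kmax = k_grid[-1]
    if kmax >= min(n_genes, n_cells):
        raise ValueError("k grid exceeds matrix rank")
    curves = []
    for split in range(n_splits):
        A, B = mcv_split(dense, 0.5, seed=seed + split)
        # guard against zero-total cells in either half
        ok = (A.sum(axis=0) > 0) & (B.sum(axis=0) > 0)
        An = lognormalize(A[:, ok], scale_target).values
        Bn = lognormalize(B[:, ok], scale_target).values
        mu = An.mean(axis=1, keepdims=True)
        Ac = An - mu
        Bc = Bn - mu  # centered on A's means: pure prediction convention
        _, _, Vt = np.linalg.svd(Ac.T, full_matrices=False)
        V = Vt[:kmax].T  # genes x kmax basis
        # rank-k model is fitted entirely on half A (its basis and scores);
        # half B only scores the reconstruction, so A's noise components
        # raise rather than lower the error
        proj = V.T @ Ac
        mse = []
        for k in k_grid:
            recon = V[:, :k] @ proj[:k]
            mse.append(float(((Bc - recon) ** 2).mean()))
        curves.append(mse)
    curve = np.mean(curves, axis=0)
    best = k_grid[int(np.argmin(curve))]
    return best, dict(zip(k_grid, curve))
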