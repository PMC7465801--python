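"""Ground-truth intermediate metrics: variance and deviance explained by
subpopulations, covariate-association diagnostics, and truth-based
dimensionality.

These metrics score intermediate pipeline outputs directly against the
known subpopulation labels, instead of waiting for the final clustering:
a good normalization should leave principal components uncorrelated with
library size once subpopulation differences are accounted for, a good
feature ranking should capture most of the variance/deviance explained by
the subpopulations, and the informative dimensionality of an embedding is
the number of leading components the subpopulations explain.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "variance_explained",
    "deviance_explained",
    "covariate_correlation_adjusted",
    "cumulative_explained_topk",
    "true_dimensionality",
]


def _one_hot(labels) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels)
    classes = np.unique(labels)
    return (labels[:, None] == classes[None, :]).astype(float), classes


def variance_explained(values, labels) -> np.ndarray:
    """Per-row R-squared of a one-way fit on the subpopulation factor.

    ``values`` is rows x cells (rows are genes or principal components).
    R^2 = between-group SS / total SS; zero-variance rows get 0.
    """
    X = np.atleast_2d(np.asarray(values, dtype=float))
    labels = np.asarray(labels)
    classes, inv = np.unique(labels, return_inverse=True)
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    counts = np.bincount(inv).astype(float)
    grand = X.mean(axis=1, keepdims=True)
    group_sums = np.zeros((X.shape[0], len(classes)))
    for c in range(len(classes)):
        group_sums[:, c] = X[:, inv == c].sum(axis=1)
    group_means = group_sums / counts
    ss_between = (counts * (group_means - grand) ** 2).sum(axis=1)
    ss_total = ((X - grand) ** 2).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(ss_total > 0, ss_between / ss_total, 0.0)
    return np.clip(r2, 0.0, 1.0)


def _nb_alpha_mle(y: np.ndarray, mu: np.ndarray) -> float:
    """ML dispersion (alpha) of NB counts with fixed means."""
    from scipy.optimize import minimize_scalar
    from scipy.stats import nbinom

    def nll(log_alpha: float) -> float:
        alpha = np.exp(log_alpha)
        size = 1.0 / alpha
        p = size / (size + mu)
        return -nbinom.logpmf(y, size, p).sum()

    res = minimize_scalar(nll, bounds=(-10.0, 5.0), method="bounded")
    return float(np.exp(res.x))


def deviance_explained(
    counts,
    labels,
    lib_size: np.ndarray | None = None,
    offset_model: bool = True,
) -> np.ndarray:
    """Per-gene fraction of NB deviance explained by the subpopulation.

    For each gene two negative-binomial GLMs (log link) are fitted: a
    reduced model with library size only and a full model adding the
    subpopulation factor. Library size enters as a log offset by default
    (``offset_model=False`` uses it as a free covariate instead). The
    dispersion is estimated once per gene on the reduced model and held
    fixed for both fits, guaranteeing the models are nested. Returns
    (dev_reduced - dev_full) / dev_reduced clipped to >= 0; genes whose NB
    fit fails fall back to Poisson.
    """
    import scipy.sparse as sp
    import statsmodels.api as sm

    Y = counts.toarray() if sp.issparse(counts) else np.asarray(counts, float)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("need at least two classes")
    if lib_size is None:
        lib_size = Y.sum(axis=0)
    lib_size = np.asarray(lib_size, dtype=float)
    if np.any(lib_size <= 0):
        raise ValueError("library sizes must be positive")
    H, _ = _one_hot(labels)
    X_red = np.ones((Y.shape[1], 1))
    X_full = np.column_stack([np.ones(Y.shape[1]), H[:, 1:]])
    offset = np.log(lib_size)
    if not offset_model:
        X_red = np.column_stack([X_red, offset])
        X_full = np.column_stack([X_full, offset])
        offset = None

    out = np.zeros(Y.shape[0])
    for g in range(Y.shape[0]):
        y = Y[g]
        try:
            pois = sm.families.Poisson()
            fit0 = sm.GLM(y, X_red, family=pois, offset=offset).fit()
            alpha = _nb_alpha_mle(y, fit0.mu)
            fam = sm.families.NegativeBinomial(alpha=max(alpha, 1e-8))
            dev_r = sm.GLM(y, X_red, family=fam, offset=offset).fit().deviance
            dev_f = sm.GLM(y, X_full, family=fam, offset=offset).fit().deviance
        except Exception as exc:  # noqa: BLE001 - per-gene Poisson fallback
            logger.warning("NB fit failed for gene %d (%s); Poisson fallback", g, exc)
            fam = sm.families.Poisson()
            dev_r = sm.GLM(y, X_red, family=fam, offset=offset).fit().deviance
            dev_f = sm.GLM(y, X_full, family=fam, offset=offset).fit().deviance
        out[g] = max(0.0, (dev_r - dev_f) / dev_r) if dev_r > 0 else 0.0
    return np.clip(out, 0.0, 1.0)


def covariate_correlation_adjusted(component, covariate, labels) -> float:
    """Correlation of a component with a covariate after removing
    subpopulation differences.

    The component is regressed on the subpopulation factor and the
    residuals are Pearson-correlated with the covariate; the squared value
    is the covariate-explained variance net of subpopulations. Constant
    residuals give 0.
    """
    y = np.asarray(component, dtype=float)
    z = np.asarray(covariate, dtype=float)
    H, _ = _one_hot(labels)
    beta, *_ = np.linalg.lstsq(H, y, rcond=None)
    resid = y - H @ beta
    if resid.std() < 1e-12 * max(np.abs(y).max(), 1.0) or z.std() == 0:
        return 0.0
    return float(np.corrcoef(resid, z)[0, 1])


def cumulative_explained_topk(
    ranking_order, explained: np.ndarray, k_grid
) -> pd.DataFrame:
    """Fraction of the best-achievable cumulative explained metric
    retrieved by a ranking's top-k genes, for each k.

    The denominator at each k is the metric summed over the oracle
    ranking's own top-k (ranking by the metric itself), so the curve lies
    in [0, 1] and hits 1 when the ranking is metric-optimal.
    """
    order = np.asarray(ranking_order)
    explained = np.asarray(explained, dtype=float)
    if len(order) != len(explained):
        raise ValueError("ranking and explained table cover different genes")
    oracle = np.sort(explained)[::-1]
    oracle_cum = np.cumsum(oracle)
    rank_cum = np.cumsum(explained[order])
    rows = []
    for k in k_grid:
        kk = min(int(k), len(order))
        denom = oracle_cum[kk - 1]
        frac = rank_cum[kk - 1] / denom if denom > 0 else 1.0
        rows.append({"k": kk, "fraction_explained": float(frac)})
    return pd.DataFrame(rows)


def true_dimensionality(embedding, labels, threshold: float = 0.05) -> int:
    """Number of leading components explained by the subpopulations.

    Per-component R^2 on the subpopulation factor is computed; counting
    stops at the first component below ``threshold`` (contiguity rule), so
    isolated deep components above threshold do not inflate the estimate.
    """
    coords = getattr(embedding, "coords", embedding)
    r2 = variance_explained(np.asarray(coords).T, labels)
    below = np.flatnonzero(r2 < threshold)
    return int(below[0]) if len(below) else len(r2)
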