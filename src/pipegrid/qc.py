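"""Per-cell quality-control metrics and cell-filtering strategies.

Five QC covariates are computed per cell: log10 total counts, log10
detected features (count > 0), the fraction of counts falling in the cell's
20 (and 50) highest-count genes, the residual of log10 features from the
dataset-wide trend on log10 counts (``featcount_dist``), and the
mitochondrial count fraction. Filter sets combine robust per-metric outlier
calls (MADs from the median) under different strictness rules; cluster-wise
filtering applies a set within pre-clusters so that genuine subpopulations
with shifted QC profiles are not wiped out; a multivariate alternative
flags outliers by robust Mahalanobis distance on the QC covariates.

Fraction-valued metrics are stored as fractions in [0, 1]; the absolute
mitochondrial threshold of 0.08 therefore means 8%.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import chi2

from .data import CountDataset

logger = logging.getLogger(__name__)

__all__ = [
    "compute_cell_qc",
    "mad_outlier",
    "apply_filter_set",
    "clusterwise_filter",
    "pca_outlier_filter",
    "FILTER_SETS",
]

#: consistency constant making the MAD estimate the sd under normality
MAD_CONSTANT = 1.4826


def compute_cell_qc(ds: CountDataset, robust_trend: bool = False) -> pd.DataFrame:
    """Compute the per-cell QC table.

    ``featcount_dist`` is the residual of an ordinary least-squares fit of
    log10 detected features on log10 total counts over all cells (a
    Theil-Sen robust fit is used when ``robust_trend``). Cells with zero
    total counts get ``-inf`` log metrics so any filter can drop them.
    """
    counts = sp.csc_matrix(ds.counts)
    total = np.asarray(counts.sum(axis=0)).ravel().astype(float)
    n_feats = np.asarray((counts > 0).sum(axis=0)).ravel().astype(float)
    with np.errstate(divide="ignore"):
        log_total = np.log10(total)
        log_feats = np.log10(n_feats)

    def pct_top(k: int) -> np.ndarray:
        out = np.zeros(counts.shape[1])
        for j in range(counts.shape[1]):
            col = counts.data[counts.indptr[j] : counts.indptr[j + 1]]
            if total[j] > 0:
                top = np.sort(col)[::-1][:k]
                out[j] = top.sum() / total[j]
        return out

    mito = np.asarray(ds.gene_meta["is_mito"], dtype=bool)
    if mito.any():
        mito_counts = np.asarray(counts[mito].sum(axis=0)).ravel()
        with np.errstate(invalid="ignore", divide="ignore"):
            pct_mt = np.where(total > 0, mito_counts / np.maximum(total, 1), 0.0)
    else:
        pct_mt = np.full(counts.shape[1], np.nan)

    ok = total > 0
    x, y = log_total[ok], log_feats[ok]
    featcount_dist = np.full(counts.shape[1], -np.inf)
    if ok.sum() >= 2 and np.ptp(x) > 0:
        if robust_trend:
            from scipy.stats import theilslopes

            slope, intercept, *_ = theilslopes(y, x)
        else:
            slope, intercept = np.polyfit(x, y, 1)
        featcount_dist[ok] = y - (intercept + slope * x)
    elif ok.sum() >= 2:
        featcount_dist[ok] = y - y.mean()

    qc = pd.DataFrame(
        {
            "log10_total_counts": log_total,
            "log10_total_features": log_feats,
            "pct_counts_in_top_20_features": pct_top(20),
            "pct_counts_in_top_50_features": pct_top(50),
            "featcount_dist": featcount_dist,
            "pct_counts_Mt": pct_mt,
        },
        index=ds.barcodes,
    )
    return qc


def mad_outlier(
    values: np.ndarray,
    nmads_lower: float = np.inf,
    nmads_upper: float = np.inf,
    log: bool = False,
) -> np.ndarray:
    """Robust outlier mask: value beyond n MADs from the median.

    The MAD is scaled by 1.4826. A zero MAD disables both sides (no value is
    an outlier there) unless a value differs from the median by more than
    an epsilon of 1e-12 times the median magnitude, in which case only
    those values are flagged — this keeps constant vectors outlier-free
    while still catching a lone extreme point among ties.
    """
    v = np.asarray(values, dtype=float)
    if log:
        v = np.log2(v + 1)
    finite = np.isfinite(v)
    if finite.sum() < 2:
        raise ValueError("need at least two finite values")
    med = np.median(v[finite])
    mad = MAD_CONSTANT * np.median(np.abs(v[finite] - med))
    mask = np.zeros(len(v), dtype=bool)
    mask[~finite] = True  # -inf / nan sentinel values are always outliers
    mask[np.isnan(v)] = False
    if mad == 0:
        eps = 1e-12 * max(abs(med), 1.0)
        dev = v[finite] - med
        out = np.zeros(finite.sum(), dtype=bool)
        if np.isfinite(nmads_lower):
            out |= dev < -eps
        if np.isfinite(nmads_upper):
            out |= dev > eps
        mask[finite] = out
        return mask
    lo = med - nmads_lower * mad if np.isfinite(nmads_lower) else -np.inf
    hi = med + nmads_upper * mad if np.isfinite(nmads_upper) else np.inf
    mask[finite] = (v[finite] < lo) | (v[finite] > hi)
    return mask


def _outlier_calls(qc: pd.DataFrame, set_name: str) -> pd.DataFrame:
    """Per-metric outlier calls underlying each filter set."""
    inf = np.inf
    has_mt = "pct_counts_Mt" in qc and np.isfinite(qc["pct_counts_Mt"]).any()
    if not has_mt:
        logger.warning("no mitochondrial annotation: Mt criterion skipped")

    def call(col: str, lower: float, upper: float) -> np.ndarray:
        return mad_outlier(qc[col].to_numpy(), lower, upper)

    if set_name in ("default", "stringent"):
        crit = {
            "log10_total_counts": call("log10_total_counts", 5, 2.5),
            "log10_total_features": call("log10_total_features", 5, 2.5),
            "pct_counts_in_top_20_features": call(
                "pct_counts_in_top_20_features", 5, 5
            ),
            "featcount_dist": call("featcount_dist", 5, 5),
        }
        if has_mt:
            crit["pct_counts_Mt"] = call("pct_counts_Mt", inf, 2.5) & (
                qc["pct_counts_Mt"].to_numpy() > 0.08
            )
    elif set_name == "lenient":
        crit = {
            "log10_total_counts": call("log10_total_counts", 5, 5),
            "log10_total_features": call("log10_total_features", 5, 5),
            "pct_counts_in_top_20_features": call(
                "pct_counts_in_top_20_features", 5, 5
            ),
            "featcount_dist": call("featcount_dist", 5, 5),
        }
        if has_mt:
            crit["pct_counts_Mt"] = call("pct_counts_Mt", inf, 3) & (
                qc["pct_counts_Mt"].to_numpy() > 0.08
            )
    elif set_name == "veryStringent":
        crit = {
            "log10_total_counts": call("log10_total_counts", 2, 2),
            "log10_total_features": call("log10_total_features", 2, 2),
            "pct_counts_in_top_20_features": call(
                "pct_counts_in_top_20_features", 2, 2
            ),
        }
        if has_mt:
            crit["pct_counts_Mt"] = call("pct_counts_Mt", 2, 2)
    else:
        raise ValueError(f"unknown filter set {set_name!r}")
    return pd.DataFrame(crit, index=qc.index)


#: minimum number of per-metric outlier calls that excludes a cell
FILTER_SETS = {
    "default": 2,
    "lenient": 2,
    "stringent": 1,
    "veryStringent": 1,
}


def apply_filter_set(qc: pd.DataFrame, set_name: str = "default") -> np.ndarray:
    """Boolean *keep* mask for one of the named filter sets.

    ``default``: excluded when an outlier on >= 2 of {log10 counts (upper
    2.5 / lower 5 MADs), log10 features (2.5 / 5), % in top-20 (5 / 5),
    featcount_dist (5 / 5), mito fraction (> 2.5 MADs AND > 0.08)}.
    ``stringent``: same calls, one suffices. ``lenient``: >= 2 calls at 5
    MADs (mito: > 3 MADs AND > 0.08). ``veryStringent``: any single
    two-sided 2-MAD call on counts, features, mito or top-20.
    """
    if set_name not in FILTER_SETS:
        raise ValueError(f"unknown filter set {set_name!r}")
    calls = _outlier_calls(qc, set_name)
    n_out = calls.to_numpy().sum(axis=1)
    return n_out < FILTER_SETS[set_name]


def clusterwise_filter(
    ds: CountDataset,
    set_name: str = "default",
    qc: pd.DataFrame | None = None,
    clusters: np.ndarray | None = None,
    min_cluster_size: int = 3,
    seed: int = 0,
) -> np.ndarray:
    """Apply a filter set within pre-clusters; union the exclusions.

    Clusters smaller than ``min_cluster_size`` are left unfiltered (the MAD
    is meaningless there). Pre-clustering defaults to the shared routine in
    :mod:`pipegrid.stages` (log-normalize, top variable genes, PCA, shared
    nearest-neighbor graph, modularity clustering).
    """
    if qc is None:
        qc = compute_cell_qc(ds)
    if clusters is None:
        from .stages import quick_cluster

        clusters = quick_cluster(ds, seed=seed)
    clusters = np.asarray(clusters)
    keep = np.ones(ds.n_cells, dtype=bool)
    for cl in np.unique(clusters):
        idx = np.flatnonzero(clusters == cl)
        if len(idx) < min_cluster_size:
            continue
        keep[idx] = apply_filter_set(qc.iloc[idx], set_name)
    return keep


def pca_outlier_filter(
    qc: pd.DataFrame,
    covariates: str = "all",
    quantile: float = 0.999,
    seed: int = 0,
) -> np.ndarray:
    """Multivariate QC outlier removal; returns a *keep* mask.

    Outlyingness is the robust Mahalanobis distance of the standardized
    covariates under a minimum-covariance-determinant estimate; cells
    beyond the chi-squared ``quantile`` are excluded. ``covariates="all"``
    uses every QC column; ``"selected"`` uses log10 counts, log10 features,
    the mitochondrial fraction and the top-50-features fraction. A singular
    covariance falls back to the union of per-axis 3.5-MAD calls.
    """
    if covariates == "all":
        cols = list(qc.columns)
    elif covariates == "selected":
        cols = [
            "log10_total_counts",
            "log10_total_features",
            "pct_counts_Mt",
            "pct_counts_in_top_50_features",
        ]
        cols = [c for c in cols if c in qc.columns]
    else:
        raise ValueError("covariates must be 'all' or 'selected'")
    X = qc[cols].to_numpy(dtype=float)
    finite_rows = np.isfinite(X).all(axis=1)
    if finite_rows.sum() < 10:
        raise ValueError("need at least 10 cells with finite QC values")
    Xf = X[finite_rows]
    Xf = Xf[:, Xf.std(axis=0) > 0] if (Xf.std(axis=0) > 0).any() else Xf
    Xs = (Xf - np.median(Xf, axis=0)) / np.maximum(
        MAD_CONSTANT * np.median(np.abs(Xf - np.median(Xf, axis=0)), axis=0), 1e-12
    )
    keep = np.zeros(len(qc), dtype=bool)
    try:
        from sklearn.covariance import MinCovDet

        mcd = MinCovDet(random_state=seed).fit(Xs)
        if np.linalg.cond(mcd.covariance_) > 1e12:
            raise np.linalg.LinAlgError("near-singular robust covariance")
        d2 = mcd.mahalanobis(Xs)
        cutoff = chi2.ppf(quantile, df=Xs.shape[1])
        keep[finite_rows] = d2 <= cutoff
    except (np.linalg.LinAlgError, ValueError) as exc:
        logger.warning("robust covariance failed (%s); per-axis MAD fallback", exc)
        out = np.zeros(Xs.shape[0], dtype=bool)
        for j in range(Xs.shape[1]):
            out |= mad_outlier(Xs[:, j], 3.5, 3.5)
        keep[finite_rows] = ~out
    return keep
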