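"""Clustering-evaluation metrics against ground-truth subpopulations.

All metrics operate on the contingency table of true class versus
predicted cluster: the adjusted Rand index (Hubert-Arabie form), mutual
information (natural-log units, unnormalized), Hungarian-matched
per-class precision/recall/F1, ARI restricted to sweep members that hit
the true number of clusters, per-subpopulation silhouette widths in an
embedding, and subpopulation-adjusted per-cell misclassification rates
across many clusterings.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.special import comb

__all__ = [
    "contingency",
    "ari",
    "mutual_information",
    "normalized_mutual_information",
    "match_and_score",
    "ari_at_true_k",
    "silhouette_per_subpop",
    "misclassification_rates",
    "evaluate_clustering",
]


def contingency(truth, predicted) -> pd.DataFrame:
    """Cross-tabulation of true classes (rows) by predicted clusters (columns)."""
    truth = np.asarray(truth)
    predicted = np.asarray(predicted)
    if len(truth) != len(predicted):
        raise ValueError("label vectors must have equal length")
    if len(truth) == 0:
        raise ValueError("need at least one cell")
    return pd.crosstab(pd.Series(truth, name="truth"), pd.Series(predicted, name="cluster"))


def _as_table(table) -> np.ndarray:
    t = table.to_numpy() if isinstance(table, pd.DataFrame) else np.asarray(table)
    return t.astype(np.int64)


def ari(table) -> float:
    """Adjusted Rand index from a contingency table.

    (Index - E[Index]) / (Max - E[Index]) on pair counts; 1 for identical
    partitions, ~0 for independent ones, possibly negative.
    """
    t = _as_table(table)
    n = t.sum()
    if n < 2:
        raise ValueError("ARI needs at least two cells")
    sum_cells = comb(t, 2).sum()
    a = comb(t.sum(axis=1), 2).sum()
    b = comb(t.sum(axis=0), 2).sum()
    total = comb(n, 2)
    expected = a * b / total
    max_index = (a + b) / 2.0
    if max_index == expected:  # both partitions trivial
        return 1.0
    return float((sum_cells - expected) / (max_index - expected))


def mutual_information(table) -> float:
    """Mutual information of the empirical joint distribution, in nats."""
    t = _as_table(table).astype(float)
    n = t.sum()
    if n < 2:
        raise ValueError("MI needs at least two cells")
    p = t / n
    pr = p.sum(axis=1, keepdims=True)
    pc = p.sum(axis=0, keepdims=True)
    nz = p > 0
    return float((p[nz] * np.log(p[nz] / (pr @ pc)[nz])).sum())


def normalized_mutual_information(table) -> float:
    """MI normalized by the arithmetic mean of the marginal entropies."""
    t = _as_table(table).astype(float)
    p = t / t.sum()
    pr = p.sum(axis=1)
    pc = p.sum(axis=0)
    hr = -(pr[pr > 0] * np.log(pr[pr > 0])).sum()
    hc = -(pc[pc > 0] * np.log(pc[pc > 0])).sum()
    denom = (hr + hc) / 2.0
    return float(mutual_information(t) / denom) if denom > 0 else 0.0


def match_and_score(table) -> pd.DataFrame:
    """Hungarian one-to-one matching of clusters to true classes.

    The assignment maximizes the total number of matched cells; when there
    are fewer clusters than classes (or vice versa) the rectangle is padded
    with zero-overlap dummies, so unmatched classes score F1 = 0. Returns a
    per-class table with precision, recall and F1, plus the matched cluster
    (-1 when unmatched); the unweighted mean over classes is ``mean_F1``.
    """
    df = table if isinstance(table, pd.DataFrame) else pd.DataFrame(np.asarray(table))
    t = _as_table(df)
    n_class, n_clust = t.shape
    size = max(n_class, n_clust)
    padded = np.zeros((size, size), dtype=np.int64)
    padded[:n_class, :n_clust] = t
    row_ind, col_ind = linear_sum_assignment(padded, maximize=True)
    match = {r: c for r, c in zip(row_ind, col_ind)}
    rows = []
    class_sizes = t.sum(axis=1)
    clust_sizes = t.sum(axis=0)
    for i in range(n_class):
        c = match[i]
        if c >= n_clust or t[i, c] == 0:
            rows.append({"class": df.index[i], "cluster": -1, "precision": 0.0,
                         "recall": 0.0, "F1": 0.0})
            continue
        overlap = t[i, c]
        prec = overlap / clust_sizes[c]
        rec = overlap / class_sizes[i] if class_sizes[i] > 0 else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec > 0 else 0.0
        rows.append({"class": df.index[i], "cluster": df.columns[c],
                     "precision": float(prec), "recall": float(rec), "F1": float(f1)})
    return pd.DataFrame(rows).set_index("class")


def ari_at_true_k(sweep: pd.DataFrame, true_k: int) -> float:
    """ARI among sweep members whose cluster count equals the true one.

    ``sweep`` needs columns ``n_clusters`` and ``ari``. Returns the maximum
    matching ARI, or NaN when no sweep member reaches ``true_k`` (rendered
    as a gray cell in heatmaps).
    """
    if len(sweep) == 0:
        raise ValueError("empty sweep")
    hits = sweep[sweep["n_clusters"] == true_k]
    if hits.empty:
        return float("nan")
    return float(hits["ari"].max())


def silhouette_per_subpop(embedding, truth) -> pd.Series:
    """Mean silhouette width per true subpopulation (Euclidean metric).

    Cells in singleton classes get silhouette 0 by convention.
    """
    from sklearn.metrics import silhouette_samples

    coords = getattr(embedding, "coords", embedding)
    truth = np.asarray(truth)
    if len(np.unique(truth)) < 2:
        raise ValueError("need at least two classes")
    s = silhouette_samples(np.asarray(coords), truth)
    return pd.Series(s).groupby(truth).mean().rename("mean_silhouette")


def misclassification_rates(clusterings, truth) -> pd.DataFrame:
    """Per-cell misclassification rate across many clusterings, adjusted by
    the median rate of the cell's true subpopulation.

    A cell is misclassified in one clustering when its cluster's
    Hungarian-matched class differs from its true class (cells in unmatched
    clusters count as misclassified). The adjusted rate subtracts the
    median raw rate within the cell's subpopulation, isolating cells that
    fail more often than their subpopulation does.
    """
    clusterings = [np.asarray(c) for c in clusterings]
    truth = np.asarray(truth)
    if len(clusterings) < 2:
        raise ValueError("need at least two clustering outcomes")
    n = len(truth)
    for c in clusterings:
        if len(c) != n:
            raise ValueError("clustering outcomes cover different cell sets")
    mis = np.zeros(n)
    for labels in clusterings:
        tab = contingency(truth, labels)
        scored = match_and_score(tab)
        clust_to_class = {
            row["cluster"]: cls
            for cls, row in scored.iterrows()
            if row["cluster"] != -1
        }
        assigned = np.array([clust_to_class.get(c, None) for c in labels], dtype=object)
        mis += (assigned != truth).astype(float)
    rate = mis / len(clusterings)
    med = pd.Series(rate).groupby(truth).transform("median").to_numpy()
    return pd.DataFrame(
        {"truth": truth, "rate": rate, "adjusted_rate": rate - med}
    )


def evaluate_clustering(truth, predicted) -> dict:
    """Standard evaluator payload: ARI, MI, NMI, cluster count, and
    Hungarian-matched F1 summaries with per-class precision/recall."""
    tab = contingency(truth, predicted)
    scored = match_and_score(tab)
    payload = {
        "ari": ari(tab),
        "mi": mutual_information(tab),
        "nmi": normalized_mutual_information(tab),
        "n_clusters": int(len(np.unique(np.asarray(predicted)))),
        "mean_F1": float(scored["F1"].mean()),
        "min_precision": float(scored["precision"].min()),
        "min_recall": float(scored["recall"].min()),
    }
    for cls, row in scored.iterrows():
        payload[f"pr_{cls}"] = float(row["precision"])
        payload[f"re_{cls}"] = float(row["recall"])
    return payload
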