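"""Cross-dataset comparable result transformation and export.

Raw metric values live on different scales in different datasets, so the
heatmap transform maps each entry to the signed square root of its number
of matrix-wise median absolute deviations from its column (dataset)
median: differences in color then carry the same meaning across datasets,
while the raw values are kept alongside for printing in the cells.
"""

from __future__ import annotations

import logging
import os

import numpy as np
import pandas as pd

from .qc import MAD_CONSTANT

logger = logging.getLogger(__name__)

__all__ = ["mad_center_transform", "sqrt_silhouette_transform", "export_report"]


def mad_center_transform(m: pd.DataFrame | np.ndarray):
    """Signed-sqrt MAD-centered transform of a variants x datasets matrix.

    Entries are centered on their column median; the scale is the single
    MAD of all centered deviations pooled over the whole matrix (constant
    1.4826); the transform is sign(d) * sqrt(|d| / MAD). Missing entries
    stay missing. A zero pooled MAD yields an all-zero matrix (logged).
    """
    df = pd.DataFrame(m).astype(float)
    d = df - df.median(axis=0, skipna=True)
    pooled = d.to_numpy().ravel()
    pooled = pooled[np.isfinite(pooled)]
    if len(pooled) == 0:
        raise ValueError("no finite entries to scale")
    s = MAD_CONSTANT * np.median(np.abs(pooled - np.median(pooled)))
    if s == 0:
        logger.warning("pooled MAD is zero; transform collapses to zeros")
        out = d * 0.0
    else:
        out = np.sign(d) * np.sqrt(d.abs() / s)
    return out if isinstance(m, pd.DataFrame) else out.to_numpy()


def sqrt_silhouette_transform(values):
    """Sign-preserving square root for silhouette color mapping."""
    v = np.asarray(values, dtype=float)
    if np.nanmax(np.abs(v)) > 1 + 1e-9:
        raise ValueError("silhouette values must lie in [-1, 1]")
    out = np.sign(v) * np.sqrt(np.abs(v))
    if np.isscalar(values) or np.ndim(values) == 0:
        return float(out)
    return out


def export_report(results, out_dir: str, metrics=("ari", "mi", "mean_F1")) -> None:
    """Write per-step long tables, per-metric variant x dataset matrices
    (raw and MAD-transformed), timings and errors as CSV."""
    os.makedirs(out_dir, exist_ok=True)
    tables = results.aggregate()
    for step, table in tables.items():
        table.to_csv(os.path.join(out_dir, f"{step}.csv"), index=False)
        if table.empty:
            continue
        param_cols = [
            c for c in table.columns
            if c not in ("dataset", "combination", "status", "elapsed")
            and c in set(results.pipeline.param_names)
        ]
        for metric in metrics:
            if metric not in table.columns:
                continue
            wide = table.pivot_table(
                index=param_cols, columns="dataset", values=metric, aggfunc="max"
            )
            if wide.empty or not np.isfinite(wide.to_numpy(dtype=float)).any():
                continue
            wide.to_csv(os.path.join(out_dir, f"{step}_{metric}_raw.csv"))
            mad_center_transform(wide).to_csv(
                os.path.join(out_dir, f"{step}_{metric}_scaled.csv")
            )
    results.timings().to_csv(os.path.join(out_dir, "timings.csv"), index=False)
    results.errors().to_csv(os.path.join(out_dir, "errors.csv"), index=False)
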