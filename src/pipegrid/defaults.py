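"""The shipped scRNA-seq pipeline: step operations, evaluators, registry.

The default pipeline has six steps — doublet identification, cell
filtering, normalization, feature selection, dimensionality reduction and
graph clustering — each owning its parameters (``doubletmethod``,
``filt``, ``norm``, ``sel``/``n_features``, ``dr``/``dims``,
``clustmethod``/``k_nn``/``graph_type``/``resolution``). Subroutine
alternatives are plain strings resolved through a user-extensible
registry, so external methods can be benchmarked by registering a wrapper
under a new name. The default parameter grid selects 2000 features and
sweeps dimensions {5, 10, 15, 20, 30, 50} and sixteen clustering
resolutions from 0.005 to 4.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import dims as dimmod
from . import metrics, qc, stages
from .data import CountDataset, read_dataset
from .doublets import DoubletCallParams, find_doublets
from .pipeline import PipelineDefinition, StepSpec

__all__ = [
    "ScState",
    "build_scrna_pipeline",
    "default_alternatives",
    "default_grid",
    "register_method",
    "get_method",
    "register_pipeline",
    "get_pipeline",
    "PIPELINES",
]

#: registry of named subroutines, keyed by (step, name)
METHODS: dict = {}
#: registry of named pipeline factories
PIPELINES: dict = {}


def register_method(step: str, name: str, fn) -> None:
    METHODS[(step, name)] = fn


def get_method(step: str, name: str):
    return METHODS.get((step, name))


def register_pipeline(name: str, factory) -> None:
    PIPELINES[name] = factory


def get_pipeline(name: str) -> PipelineDefinition:
    try:
        return PIPELINES[name]()
    except KeyError:
        raise KeyError(f"unknown pipeline {name!r}; known: {sorted(PIPELINES)}")


@dataclass
class ScState:
    """Mutable state threaded through the scRNA-seq pipeline steps."""

    ds: CountDataset
    qc_table: pd.DataFrame | None = None
    norm: stages.NormalizedMatrix | None = None
    selected: np.ndarray | None = None
    scaled: np.ndarray | None = None
    embedding: stages.Embedding | None = None
    clusters: np.ndarray | None = None
    dims_used: int | None = None

    @property
    def truth(self) -> np.ndarray:
        return self.ds.cell_meta["phenoid"].to_numpy()


def _initiator(raw) -> ScState:
    if isinstance(raw, ScState):
        return raw
    if isinstance(raw, CountDataset):
        return ScState(ds=raw)
    if isinstance(raw, str):
        return ScState(ds=read_dataset(raw))
    raise TypeError(f"cannot initiate pipeline from {type(raw)}")


# --- step operations -------------------------------------------------------


def step_doublets(state: ScState, doubletmethod: str, seed: int = 0) -> ScState:
    custom = get_method("doublets", doubletmethod)
    if custom is not None:
        return custom(state, seed=seed)
    if doubletmethod == "none":
        return state
    if doubletmethod == "dblfinder":
        params = DoubletCallParams(seed=seed)
        calls = find_doublets(state.ds, params)
        keep = ~calls["call"].to_numpy()
        return replace(state, ds=state.ds.subset_cells(keep))
    raise ValueError(f"unknown doublet method {doubletmethod!r}")


def eval_doublets(state: ScState) -> dict:
    meta = state.ds.cell_meta
    payload = {"n_cells": int(state.ds.n_cells)}
    if "is_doublet" in meta:
        payload["doublets_remaining"] = int(meta["is_doublet"].sum())
    return payload


def step_filter(state: ScState, filt: str, seed: int = 0) -> ScState:
    custom = get_method("filtering", filt)
    qc_table = qc.compute_cell_qc(state.ds)
    totals_ok = np.isfinite(qc_table["log10_total_counts"].to_numpy())
    if custom is not None:
        keep = custom(state, qc_table, seed=seed)
    elif filt == "none":
        keep = np.ones(state.ds.n_cells, dtype=bool)
    elif filt in qc.FILTER_SETS:
        keep = qc.apply_filter_set(qc_table, filt)
    elif filt.endswith(".cluster") and filt[: -len(".cluster")] in qc.FILTER_SETS:
        keep = qc.clusterwise_filter(
            state.ds, filt[: -len(".cluster")], qc=qc_table, seed=seed
        )
    elif filt in ("pca.all", "pca.sel"):
        keep = qc.pca_outlier_filter(
            qc_table, "all" if filt == "pca.all" else "selected", seed=seed
        )
    else:
        raise ValueError(f"unknown filter {filt!r}")
    keep = keep & totals_ok  # zero-count cells can never proceed
    return replace(
        state, ds=state.ds.subset_cells(keep), qc_table=qc_table.loc[keep]
    )


def eval_filter(state: ScState) -> dict:
    meta = state.ds.cell_meta
    payload = {"n_cells": int(state.ds.n_cells)}
    if "is_lowq" in meta:
        payload["lowq_remaining"] = int(meta["is_lowq"].sum())
    if "is_doublet" in meta:
        payload["doublets_remaining"] = int(meta["is_doublet"].sum())
    return payload


def step_norm(state: ScState, norm: str) -> ScState:
    custom = get_method("normalization", norm)
    if custom is not None:
        return custom(state)
    if norm == "lognorm":
        return replace(state, norm=stages.lognormalize(state.ds.counts))
    raise ValueError(f"unknown normalization {norm!r}")


def step_select(state: ScState, sel: str, n_features: int) -> ScState:
    custom = get_method("selection", sel)
    if custom is not None:
        return custom(state, n_features)
    data = state.ds if sel == "deviance" else state.norm
    ranking = stages.rank_features(data, sel)
    top = ranking.order[: min(int(n_features), state.ds.n_genes)]
    return replace(state, selected=np.asarray(top))


def step_dimred(state: ScState, dr: str, dims, seed: int = 0) -> ScState:
    custom = get_method("dimreduction", dr)
    if custom is not None:
        return custom(state, dims, seed=seed)
    if dr not in ("pca", "pca_unweighted"):
        raise ValueError(f"unknown dimensionality reduction {dr!r}")
    sub = stages.NormalizedMatrix(
        state.norm.values[state.selected], state.norm.size_factors
    )
    scaled = stages.scale_features(sub)
    max_rank = min(scaled.shape) - 1
    if isinstance(dims, str):
        if dims == "elbow":
            probe = stages.pca_embed(scaled, min(50, max_rank))
            k = dimmod.elbow_dims(probe)
        elif dims == "jackstraw":
            k = dimmod.jackstraw_dims(scaled, min(20, max_rank), n_perm=30, seed=seed)
        elif dims == "mcv":
            counts_sub = state.ds.counts[state.selected]
            grid = range(1, min(30, max_rank) + 1)
            k, _ = dimmod.mcv_dims(counts_sub, grid, seed=seed)
        else:
            raise ValueError(f"unknown dimensionality estimator {dims!r}")
    else:
        k = min(int(dims), max_rank)
    emb = stages.pca_embed(scaled, k, weight_by_variance=(dr == "pca"))
    return replace(state, scaled=scaled, embedding=emb, dims_used=int(k))


def eval_dimred(state: ScState) -> dict:
    from .truth import (
        covariate_correlation_adjusted,
        true_dimensionality,
        variance_explained,
    )

    payload = {"dims_used": state.dims_used}
    truth = state.truth
    if len(np.unique(truth)) >= 2:
        r2 = variance_explained(state.embedding.coords.T, truth)
        payload["r2_pc1"] = float(r2[0])
        payload["true_dims"] = int(true_dimensionality(state.embedding, truth))
        libsize = state.ds.counts.sum(axis=0)
        payload["pc1_libsize_cor"] = covariate_correlation_adjusted(
            state.embedding.coords[:, 0], np.asarray(libsize).ravel(), truth
        )
    return payload


def step_cluster(
    state: ScState,
    clustmethod: str,
    k_nn: int,
    graph_type: str,
    resolution: float,
    seed: int = 0,
) -> ScState:
    custom = get_method("clustering", clustmethod)
    if custom is not None:
        return custom(state, k_nn, graph_type, resolution, seed=seed)
    adj = stages.build_neighbor_graph(
        state.embedding, k=min(int(k_nn), state.ds.n_cells - 1),
        graph_type=graph_type, seed=seed,
    )
    labels = stages.cluster_graph(adj, clustmethod, resolution=resolution, seed=seed)
    return replace(state, clusters=labels)


def eval_cluster(state: ScState) -> dict:
    return metrics.evaluate_clustering(state.truth, state.clusters)


def build_scrna_pipeline() -> PipelineDefinition:
    """The six-step default single-cell pipeline with truth-based evaluators."""
    return PipelineDefinition(
        [
            StepSpec("doublets", step_doublets, ("doubletmethod",), eval_doublets),
            StepSpec("filtering", step_filter, ("filt",), eval_filter),
            StepSpec("normalization", step_norm, ("norm",)),
            StepSpec("selection", step_select, ("sel", "n_features")),
            StepSpec("dimreduction", step_dimred, ("dr", "dims"), eval_dimred),
            StepSpec(
                "clustering",
                step_cluster,
                ("clustmethod", "k_nn", "graph_type", "resolution"),
                eval_cluster,
            ),
        ],
        initiator=_initiator,
    )


register_pipeline("scrna_default", build_scrna_pipeline)

#: the sixteen clustering resolutions of the default sweep
RESOLUTIONS = (
    0.005, 0.01, 0.02, 0.05, 0.1, 0.15, 0.2, 0.3,
    0.4, 0.5, 0.8, 1, 1.2, 1.5, 2, 4,
)


def default_alternatives() -> dict:
    """A single default value per parameter (resolution sweep included)."""
    return {
        "doubletmethod": ["dblfinder"],
        "filt": ["default"],
        "norm": ["lognorm"],
        "sel": ["variance"],
        "n_features": [2000],
        "dr": ["pca"],
        "dims": [10],
        "clustmethod": ["modularity_resolution"],
        "k_nn": [15],
        "graph_type": ["snn_jaccard"],
        "resolution": list(RESOLUTIONS),
    }


def default_grid() -> dict:
    """The full default grid: six dimension choices and sixteen resolutions."""
    alts = default_alternatives()
    alts["dims"] = [5, 10, 15, 20, 30, 50]
    return alts
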