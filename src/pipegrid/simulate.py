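"""Seeded synthetic scRNA-seq count data with known ground truth.

The generator emulates the structure of droplet scRNA-seq data that the
evaluation suite needs: several subpopulations with negative-binomial
counts and per-subpopulation log-fold-change structure, lognormal
library-size variation, a flagged mitochondrial gene set, injected
low-quality (degraded) cells with inflated mitochondrial content, and
injected heterotypic doublets formed by summing two cells from different
subpopulations. Every cell and gene carries its truth annotation so that
filters, doublet callers and clustering metrics can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .data import CountDataset

__all__ = ["SimParams", "simulate_dataset"]


@dataclass
class SimParams:
    """Parameters of the synthetic dataset generator.

    Counts for a singlet are NB distributed with mean
    ``libfactor * mu[gene, subpop]`` and a dispersion shared across genes
    (size = 1 / ``nb_dispersion``). Subpopulation means start from a common
    baseline (log-mean uniform over ``baseline_logmean_range``, natural
    log); each subpopulation then receives log-fold changes drawn uniformly
    from ``de_logfc_range`` (random sign) on its own random
    ``frac_de_genes`` subset of genes.

    Doublets are entrywise sums of two freshly drawn singlets from distinct
    subpopulations (heterotypic only). Low-quality cells have their
    non-mitochondrial counts binomially thinned with keep probability
    ``1 / lowq_mito_inflation``, which both shrinks the library and
    inflates the mitochondrial fraction — the degradation signature QC
    filters are meant to catch.
    """

    n_genes: int = 1000
    n_cells: int = 1000
    n_subpops: int = 3
    subpop_proportions: tuple | None = None  # default: uniform
    baseline_logmean_range: tuple = (-1.0, 2.0)
    frac_de_genes: float = 0.1
    de_logfc_range: tuple = (1.0, 2.0)
    nb_dispersion: float = 0.4
    libsize_lognormal_sd: float = 0.35
    frac_mito_genes: float = 0.03
    frac_ribo_genes: float = 0.05
    frac_coding_genes: float = 0.9
    doublet_rate: float = 0.0
    lowq_rate: float = 0.0
    lowq_mito_inflation: float = 4.0
    hierarchical: bool = False
    homotypic_doublets: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.subpop_proportions is None:
            self.subpop_proportions = tuple([1.0 / self.n_subpops] * self.n_subpops)
        props = np.asarray(self.subpop_proportions, dtype=float)
        if len(props) != self.n_subpops or not np.isclose(props.sum(), 1.0):
            raise ValueError("subpop_proportions must sum to 1 and match n_subpops")
        if (props <= 0).any():
            raise ValueError("degenerate subpopulation proportions")
        for frac in (
            self.frac_de_genes,
            self.frac_mito_genes,
            self.doublet_rate,
            self.lowq_rate,
        ):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if self.n_subpops > self.n_cells:
            raise ValueError("more subpopulations than cells")


def _subpop_means(params: SimParams, rng: np.random.Generator) -> np.ndarray:
    """Gene x subpop matrix of NB means."""
    lo, hi = params.baseline_logmean_range
    base = rng.uniform(lo, hi, size=params.n_genes)
    logmu = np.tile(base[:, None], (1, params.n_subpops))
    n_de = int(round(params.frac_de_genes * params.n_genes))
    flo, fhi = params.de_logfc_range
    if params.hierarchical:
        # random bifurcating structure: each new subpopulation branches off an
        # existing one, so some pairs stay close while others diverge
        for s in range(1, params.n_subpops):
            parent = int(rng.integers(0, s))
            logmu[:, s] = logmu[:, parent]
            idx = rng.choice(params.n_genes, size=n_de, replace=False)
            lfc = rng.uniform(flo, fhi, size=n_de) * rng.choice([-1.0, 1.0], size=n_de)
            logmu[idx, s] += lfc
    else:
        for s in range(params.n_subpops):
            idx = rng.choice(params.n_genes, size=n_de, replace=False)
            lfc = rng.uniform(flo, fhi, size=n_de) * rng.choice([-1.0, 1.0], size=n_de)
            logmu[idx, s] += lfc
    return np.exp(logmu)


def _nb_counts(
    mean: np.ndarray, dispersion: float, rng: np.random.Generator
) -> np.ndarray:
    """NB(mean, size=1/dispersion) via the gamma-Poisson mixture."""
    size = 1.0 / dispersion
    lam = rng.gamma(shape=size, scale=mean / size)
    return rng.poisson(lam)


def simulate_dataset(params: SimParams) -> CountDataset:
    """Generate a seeded synthetic count dataset with full truth annotation.

    Returns a :class:`CountDataset` whose ``cell_meta`` records the truth
    label ``phenoid`` (doublets carry both parent labels joined by ``+``),
    ``is_doublet``, ``is_lowq`` and the true library factor, and whose
    ``gene_meta`` records mito/ribo/coding flags and the per-subpopulation
    true means.
    """
    rng = np.random.default_rng(params.seed)
    mu = _subpop_means(params, rng)  # genes x subpops
    subpop_names = [f"subpop{s + 1}" for s in range(params.n_subpops)]

    n_doublets = int(round(params.doublet_rate * params.n_cells))
    n_singlets = params.n_cells - n_doublets
    if n_singlets < params.n_subpops:
        raise ValueError("not enough singlets to populate all subpopulations")

    props = np.asarray(params.subpop_proportions)
    labels = rng.choice(params.n_subpops, size=n_singlets, p=props)
    libf = rng.lognormal(mean=0.0, sigma=params.libsize_lognormal_sd, size=n_singlets)
    counts = _nb_counts(libf[None, :] * mu[:, labels], params.nb_dispersion, rng)

    phenoid = [subpop_names[s] for s in labels]
    is_doublet = [False] * n_singlets
    lib_factor = list(libf)

    if n_doublets:
        if params.homotypic_doublets:
            pa = rng.choice(params.n_subpops, size=n_doublets, p=props)
            pb = pa.copy()
        else:
            pa = rng.choice(params.n_subpops, size=n_doublets, p=props)
            pb = np.array(
                [
                    rng.choice([s for s in range(params.n_subpops) if s != a])
                    for a in pa
                ]
            )
        lfa = rng.lognormal(0.0, params.libsize_lognormal_sd, size=n_doublets)
        lfb = rng.lognormal(0.0, params.libsize_lognormal_sd, size=n_doublets)
        ca = _nb_counts(lfa[None, :] * mu[:, pa], params.nb_dispersion, rng)
        cb = _nb_counts(lfb[None, :] * mu[:, pb], params.nb_dispersion, rng)
        counts = np.hstack([counts, ca + cb])
        for a, b in zip(pa, pb):
            phenoid.append("+".join(sorted((subpop_names[a], subpop_names[b]))))
        is_doublet += [True] * n_doublets
        lib_factor += list(lfa + lfb)
        parent_totals = np.full((params.n_cells, 2), np.nan)
        parent_totals[n_singlets:, 0] = ca.sum(axis=0)
        parent_totals[n_singlets:, 1] = cb.sum(axis=0)
    else:
        parent_totals = np.full((params.n_cells, 2), np.nan)

    n_mito = int(round(params.frac_mito_genes * params.n_genes))
    n_ribo = int(round(params.frac_ribo_genes * params.n_genes))
    is_mito = np.zeros(params.n_genes, dtype=bool)
    is_mito[:n_mito] = True
    is_ribo = np.zeros(params.n_genes, dtype=bool)
    is_ribo[n_mito : n_mito + n_ribo] = True
    is_coding = rng.random(params.n_genes) < params.frac_coding_genes
    is_coding[is_mito | is_ribo] = True

    is_lowq = np.zeros(params.n_cells, dtype=bool)
    n_lowq = int(round(params.lowq_rate * n_singlets))
    if n_lowq:
        lowq_idx = rng.choice(n_singlets, size=n_lowq, replace=False)
        is_lowq[lowq_idx] = True
        keep_p = 1.0 / params.lowq_mito_inflation
        nonmito = ~is_mito
        sub = counts[np.ix_(nonmito, lowq_idx)]
        counts[np.ix_(nonmito, lowq_idx)] = rng.binomial(sub, keep_p)

    gene_names = [
        ("MT-g%d" % (i + 1)) if is_mito[i] else ("RP-g%d" % (i + 1)) if is_ribo[i] else ("g%d" % (i + 1))
        for i in range(params.n_genes)
    ]
    gene_meta = pd.DataFrame(
        {"is_mito": is_mito, "is_ribo": is_ribo, "is_coding": is_coding},
        index=pd.Index(gene_names, name="gene_id"),
    )
    for s, name in enumerate(subpop_names):
        gene_meta[f"true_mean_{name}"] = mu[:, s]

    cell_meta = pd.DataFrame(
        {
            "phenoid": phenoid,
            "is_doublet": is_doublet,
            "is_lowq": is_lowq,
            "lib_factor": lib_factor,
            "parent_a_total": parent_totals[:, 0],
            "parent_b_total": parent_totals[:, 1],
        },
        index=pd.Index([f"cell{i + 1}" for i in range(params.n_cells)], name="barcode"),
    )
    return CountDataset(sp.csr_matrix(counts), cell_meta, gene_meta)
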