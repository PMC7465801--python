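"""QC metrics and filter-set semantics, checked against direct
rule-by-rule oracles and robust-statistics hand computations."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from hypothesis import given, settings
from hypothesis import strategies as st

from pipegrid.data import CountDataset
from pipegrid.qc import (
    MAD_CONSTANT,
    apply_filter_set,
    clusterwise_filter,
    compute_cell_qc,
    mad_outlier,
    pca_outlier_filter,
)
from pipegrid.simulate import SimParams, simulate_dataset


def tiny_dataset(counts, n_mito=0):
    counts = np.asarray(counts)
    g, c = counts.shape
    gene_meta = pd.DataFrame(
        {
            "is_mito": [i < n_mito for i in range(g)],
            "is_ribo": [False] * g,
            "is_coding": [True] * g,
        },
        index=pd.Index([f"g{i}" for i in range(g)], name="gene_id"),
    )
    cell_meta = pd.DataFrame(
        {"phenoid": ["p"] * c},
        index=pd.Index([f"c{i}" for i in range(c)], name="barcode"),
    )
    return CountDataset(sp.csr_matrix(counts), cell_meta, gene_meta)


class TestCellQC:
    def test_two_gene_cell_arithmetic(self):
        # one cell with counts 9 and 1: total 10, two detected genes
        ds = tiny_dataset(np.array([[9, 5], [1, 5]]))
        qc = compute_cell_qc(ds)
        assert qc["log10_total_counts"].iloc[0] == pytest.approx(1.0)
        assert qc["log10_total_features"].iloc[0] == pytest.approx(np.log10(2))
        assert qc["pct_counts_in_top_20_features"].iloc[0] == pytest.approx(1.0)

    def test_scalar_multiple_profiles_have_zero_featcount_dist(self):
        base = np.array([5, 3, 2, 1, 1])
        counts = np.column_stack([base * m for m in (1, 2, 4, 8, 16)])
        qc = compute_cell_qc(tiny_dataset(counts))
        # all cells detect the same genes: features constant, residuals ~0
        assert np.allclose(qc["featcount_dist"], 0.0, atol=1e-9)

    def test_all_counts_in_mito_genes(self):
        ds = tiny_dataset(np.array([[10, 20], [0, 0]]), n_mito=1)
        qc = compute_cell_qc(ds)
        assert np.allclose(qc["pct_counts_Mt"], 1.0)

    def test_zero_count_cell_flagged_with_neg_inf(self):
        ds = tiny_dataset(np.array([[5, 0], [3, 0]]))
        qc = compute_cell_qc(ds)
        assert qc["log10_total_counts"].iloc[1] == -np.inf

    def test_qc_median_featcount_dist_near_zero(self, sim3):
        qc = compute_cell_qc(sim3)
        assert abs(np.median(qc["featcount_dist"])) < 0.02


class TestMadOutlier:
    def test_single_extreme_value_flagged(self):
        # median 6, MAD = 3 * 1.4826, upper bound ~17.1: only 100 is out
        v = np.array([1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 100], dtype=float)
        mask = mad_outlier(v, 2.5, 2.5)
        med = np.median(v)
        mad = MAD_CONSTANT * np.median(np.abs(v - med))
        expected = (v < med - 2.5 * mad) | (v > med + 2.5 * mad)
        assert np.array_equal(mask, expected)
        assert mask.sum() == 1 and mask[-1]

    def test_constant_vector_has_no_outliers(self):
        assert not mad_outlier(np.full(10, 3.3), 2, 2).any()

    def test_zero_mad_with_one_deviant_still_flags_it(self):
        v = np.array([5.0] * 20 + [50.0])
        assert mad_outlier(v, 2, 2).sum() == 1

    def test_one_sided_disabling(self):
        v = np.array([1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 100], dtype=float)
        assert not mad_outlier(v, 2.5, np.inf).any()

    @given(
        a=st.floats(0.1, 10),
        b=st.floats(-5, 5),
        seed=st.integers(0, 50),
    )
    @settings(max_examples=25, deadline=None)
    def test_affine_invariance(self, a, b, seed):
        rng = np.random.default_rng(seed)
        v = rng.normal(size=30)
        assert np.array_equal(
            mad_outlier(v, 2, 2), mad_outlier(a * v + b, 2, 2)
        )


def rule_oracle(qc, set_name):
    """Direct rule-by-rule evaluation of the filter-set definitions."""

    def out(col, lower, upper):
        v = qc[col].to_numpy()
        med = np.median(v)
        mad = MAD_CONSTANT * np.median(np.abs(v - med))
        lo = med - lower * mad if np.isfinite(lower) else -np.inf
        hi = med + upper * mad if np.isfinite(upper) else np.inf
        return (v < lo) | (v > hi)

    mt = qc["pct_counts_Mt"].to_numpy()
    if set_name in ("default", "stringent"):
        calls = [
            out("log10_total_counts", 5, 2.5),
            out("log10_total_features", 5, 2.5),
            out("pct_counts_in_top_20_features", 5, 5),
            out("featcount_dist", 5, 5),
            out("pct_counts_Mt", np.inf, 2.5) & (mt > 0.08),
        ]
        need = 2 if set_name == "default" else 1
    elif set_name == "lenient":
        calls = [
            out("log10_total_counts", 5, 5),
            out("log10_total_features", 5, 5),
            out("pct_counts_in_top_20_features", 5, 5),
            out("featcount_dist", 5, 5),
            out("pct_counts_Mt", np.inf, 3) & (mt > 0.08),
        ]
        need = 2
    else:  # veryStringent
        calls = [
            out("log10_total_counts", 2, 2),
            out("log10_total_features", 2, 2),
            out("pct_counts_in_top_20_features", 2, 2),
            out("pct_counts_Mt", 2, 2),
        ]
        need = 1
    return np.vstack(calls).sum(axis=0) < need


def random_qc_table(seed, n=200):
    rng = np.random.default_rng(seed)
    qc = pd.DataFrame(
        {
            "log10_total_counts": rng.normal(3.5, 0.2, n),
            "log10_total_features": rng.normal(2.8, 0.15, n),
            "pct_counts_in_top_20_features": rng.beta(4, 8, n),
            "pct_counts_in_top_50_features": rng.beta(6, 5, n),
            "featcount_dist": rng.normal(0, 0.05, n),
            "pct_counts_Mt": rng.beta(2, 30, n),
        }
    )
    # hand-plant outliers of several kinds
    qc.loc[0, "log10_total_counts"] = 5.5
    qc.loc[1, ["log10_total_counts", "log10_total_features"]] = [2.0, 1.5]
    qc.loc[2, "pct_counts_Mt"] = 0.5
    qc.loc[3, ["pct_counts_Mt", "featcount_dist"]] = [0.4, -0.6]
    return qc


class TestFilterSets:
    @pytest.mark.parametrize(
        "set_name", ["default", "lenient", "stringent", "veryStringent"]
    )
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_masks_equal_rule_by_rule_oracle(self, set_name, seed):
        qc = random_qc_table(seed)
        assert np.array_equal(
            apply_filter_set(qc, set_name), rule_oracle(qc, set_name)
        )

    def test_single_metric_outlier_kept_by_default_removed_by_stringent(self):
        qc = random_qc_table(7)
        # cell 0 is a counts-only outlier in this table
        calls_needed = rule_oracle(qc, "stringent")
        assert not calls_needed[0]  # excluded by stringent
        assert apply_filter_set(qc, "default")[0]
        assert not apply_filter_set(qc, "stringent")[0]

    def test_mito_criterion_requires_absolute_floor(self):
        qc = random_qc_table(8)
        qc["pct_counts_Mt"] = np.full(len(qc), 0.01)
        qc.loc[5, "pct_counts_Mt"] = 0.05  # many MADs high but below 0.08
        assert apply_filter_set(qc, "stringent")[5]

    def test_no_outliers_all_kept(self):
        rng = np.random.default_rng(0)
        n = 100
        qc = pd.DataFrame(
            {
                c: rng.uniform(0.45, 0.55, n)
                for c in random_qc_table(0).columns
            }
        )
        for s in ["default", "lenient", "stringent", "veryStringent"]:
            assert apply_filter_set(qc, s).all()

    @pytest.mark.parametrize("seed", range(10))
    def test_default_exclusions_subset_of_stringent(self, seed):
        qc = random_qc_table(seed, n=300)
        d = ~apply_filter_set(qc, "default")
        s = ~apply_filter_set(qc, "stringent")
        assert not (d & ~s).any()

    def test_default_recall_of_injected_lowq_at_least_lenient(self):
        ds = simulate_dataset(
            SimParams(n_genes=600, n_cells=2000, lowq_rate=0.05, seed=13)
        )
        qc = compute_cell_qc(ds)
        lowq = ds.cell_meta["is_lowq"].to_numpy()
        rec_d = (~apply_filter_set(qc, "default"))[lowq].mean()
        rec_l = (~apply_filter_set(qc, "lenient"))[lowq].mean()
        assert rec_d >= rec_l

    def test_unknown_set_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            apply_filter_set(random_qc_table(0), "nonsense")

    def test_filter_is_pure_function_of_table(self):
        qc = random_qc_table(3)
        a = apply_filter_set(qc, "default")
        b = apply_filter_set(qc.copy(), "default")
        assert np.array_equal(a, b)


class TestClusterwise:
    def test_bimodal_dataset_spared_by_clusterwise_filtering(self):
        dsA = simulate_dataset(
            SimParams(
                n_genes=400, n_cells=60, n_subpops=1,
                baseline_logmean_range=(-2.2, -0.3),
                libsize_lognormal_sd=0.2, seed=4,
            )
        )
        dsB = simulate_dataset(
            SimParams(
                n_genes=400, n_cells=340, n_subpops=1,
                baseline_logmean_range=(2.0, 4.0),
                libsize_lognormal_sd=0.2, seed=5,
            )
        )
        cmA = dsA.cell_meta.copy()
        cmB = dsB.cell_meta.copy()
        cmB.index = pd.Index([f"x{i}" for i in range(len(cmB))], name="barcode")
        cmB["phenoid"] = "subpopB"
        comb = CountDataset(
            sp.hstack([dsA.counts, dsB.counts]).tocsr(),
            pd.concat([cmA, cmB]),
            dsA.gene_meta,
        )
        qc = compute_cell_qc(comb)
        global_removed = ~apply_filter_set(qc, "default")
        clusters = np.array([0] * 60 + [1] * 340)
        cw_removed = ~clusterwise_filter(comb, "default", qc=qc, clusters=clusters)
        assert global_removed[:60].sum() > 30  # small-library subpop wiped out
        assert cw_removed.sum() <= 2  # cluster-wise spares it

    def test_single_cluster_reduces_to_plain_filter(self, sim3):
        qc = compute_cell_qc(sim3)
        plain = apply_filter_set(qc, "default")
        cw = clusterwise_filter(
            sim3, "default", qc=qc, clusters=np.zeros(sim3.n_cells, dtype=int)
        )
        assert np.array_equal(plain, cw)

    def test_tiny_clusters_left_unfiltered(self, sim3):
        qc = compute_cell_qc(sim3)
        clusters = np.zeros(sim3.n_cells, dtype=int)
        clusters[:2] = 1  # below min size
        cw = clusterwise_filter(sim3, "default", qc=qc, clusters=clusters)
        assert cw[:2].all()


class TestPcaOutlier:
    def test_injected_multivariate_outlier_flagged(self):
        rng = np.random.default_rng(1)
        qc = pd.DataFrame(
            rng.normal(size=(500, 5)), columns=list(random_qc_table(0).columns[:5])
        )
        qc.iloc[0] = 8.0
        keep = pca_outlier_filter(qc, "all")
        assert not keep[0]

    def test_clean_gaussian_flags_few(self):
        rng = np.random.default_rng(2)
        qc = pd.DataFrame(
            rng.normal(size=(1000, 5)), columns=list(random_qc_table(0).columns[:5])
        )
        keep = pca_outlier_filter(qc, "all")
        assert (~keep).mean() <= 0.005 + 0.01  # chi2 0.999 tail plus MCD slack

    def test_duplicate_columns_trigger_fallback_and_continue(self):
        rng = np.random.default_rng(3)
        base = rng.normal(size=(200, 1))
        qc = pd.DataFrame(
            np.hstack([base] * 5), columns=list(random_qc_table(0).columns[:5])
        )
        keep = pca_outlier_filter(qc, "all")
        assert keep.shape == (200,)
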