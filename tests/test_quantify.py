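import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import nnls

from nasdeconv.genome_io import CoverageTrack, GenomicInterval, MatureIsoform
from nasdeconv.quantify import (
    QuantifyConfig,
    aggregate_genes,
    estimate_abundance,
    filter_by_expression_rank,
    gene_union_regions,
    normalize,
    quantify,
    rcb_estimate,
)


def _random_instance(rng, m_max=50, n_max=6):
    while True:
        m = int(rng.integers(4, m_max + 1))
        n = int(rng.integers(1, n_max + 1))
        X = np.zeros((m, n))
        for j in range(n):
            s = int(rng.integers(0, m - 1))
            e = int(rng.integers(s + 1, m + 1))
            X[s:e, j] = rng.uniform(0.3, 2.0) if rng.random() < 0.5 else 1.0
        # full column rank keeps the constrained optimum unique
        if np.linalg.matrix_rank(X) == n:
            break
    beta = rng.uniform(0, 10, size=n)
    Y = rng.poisson(np.maximum(X @ beta, 0.1)).astype(float)
    return X, Y


class TestEstimator:
    def test_single_isoform_exact_fit(self):
        X = np.ones((5, 1))
        Y = np.full(5, 4.0)
        assert estimate_abundance(X, Y)[0] == pytest.approx(4.0, abs=1e-9)

    def test_nested_mixture_recovered(self):
        # long isoform over 10 bins, short over the first 5:
        # Y = 5 on shared bins, 2 on long-only bins -> (long, short) = (2, 3)
        X = np.zeros((10, 2))
        X[:, 0] = 1.0
        X[:5, 1] = 1.0
        Y = np.array([5.0] * 5 + [2.0] * 5)
        beta = estimate_abundance(X, Y)
        np.testing.assert_allclose(beta, [2.0, 3.0], atol=1e-9)

    def test_all_zero_counts_give_zero_weights(self):
        X = np.ones((6, 2))
        beta = estimate_abundance(X, np.zeros(6))
        np.testing.assert_array_equal(beta, np.zeros(2))

    def test_lbfgsb_route_matches_nnls(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            X, Y = _random_instance(rng)
            rows = X.sum(axis=1) > 0
            oracle, _ = nnls(X[rows], Y[rows])
            est = estimate_abundance(X, Y, solver="lbfgsb")
            np.testing.assert_allclose(est, oracle, atol=1e-6)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_noiseless_recovery(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 5))
        m = 10 + 4 * n
        # staggered full-column-rank design
        X = np.zeros((m, n))
        for j in range(n):
            X[4 * j : m, j] = 1.0
        beta_true = rng.uniform(0.0, 20.0, size=n)
        Y = X @ beta_true
        beta = estimate_abundance(X, Y)
        np.testing.assert_allclose(beta, beta_true, atol=1e-6)

    def test_log_mode_noiseless_recovery(self):
        X = np.zeros((20, 2))
        X[:, 0] = 1.0
        X[:10, 1] = 1.0
        beta_true = np.array([30.0, 70.0])
        beta = estimate_abundance(X, X @ beta_true, log_space=True)
        np.testing.assert_allclose(beta, beta_true, rtol=1e-4)

    def test_scale_equivariance_linear(self):
        rng = np.random.default_rng(5)
        X, Y = _random_instance(rng)
        b1 = estimate_abundance(X, Y)
        b2 = estimate_abundance(X, 7.5 * Y)
        np.testing.assert_allclose(b2, 7.5 * b1, rtol=1e-9, atol=1e-9)

    def test_masked_rows_excluded_from_objective(self):
        # an all-zero row with a huge count must not influence the fit
        X = np.ones((5, 1))
        X = np.vstack([X, np.zeros((1, 1))])
        Y = np.array([4.0] * 5 + [1e6])
        assert estimate_abundance(X, Y)[0] == pytest.approx(4.0, abs=1e-9)

    def test_empty_design_errors(self):
        with pytest.raises(ValueError):
            estimate_abundance(np.zeros((5, 0)), np.zeros(5))
        with pytest.raises(ValueError):
            estimate_abundance(np.ones((5, 1)), np.zeros(3))


class TestNormalization:
    @pytest.mark.parametrize(
        "beta,depth,expected", [(2.0, 1e6, 2.0), (2.0, 2e6, 1.0), (0.0, 1e6, 0.0)]
    )
    def test_per_million(self, beta, depth, expected):
        assert normalize(np.array([beta]), depth)[0] == pytest.approx(expected)

    def test_non_positive_depth_errors(self):
        with pytest.raises(ValueError):
            normalize(np.array([1.0]), 0.0)


def _toy_table():
    return pd.DataFrame(
        {
            "gene_id": ["G1", "G1", "G2"],
            "pre_rna_isoform_id": ["G1:a", "G1:b", "G2:a"],
            "length": [10000, 5000, 2000],
            "tss": [0, 0, 0],
            "raw_beta": [3.0, 1.0, 2.0],
            "normalized_abundance": [3.0, 1.0, 2.0],
        }
    )


class TestGeneAggregation:
    def test_sum_and_dominant(self):
        out = aggregate_genes(_toy_table()).set_index("gene_id")
        assert out.loc["G1", "raw_beta"] == 4.0
        assert out.loc["G1", "dominant_isoform_id"] == "G1:a"

    def test_tie_broken_by_length(self):
        t = _toy_table()
        t.loc[1, "raw_beta"] = 3.0
        out = aggregate_genes(t).set_index("gene_id")
        assert out.loc["G1", "dominant_isoform_id"] == "G1:a"  # longer wins

    def test_conservation(self):
        t = _toy_table()
        out = aggregate_genes(t)
        assert out["raw_beta"].sum() == pytest.approx(t["raw_beta"].sum())


class TestRCB:
    def _track(self):
        track = CoverageTrack()
        track.add_counts("chr1", "+", 0, np.full(1000, 0.1))     # 100 reads / 1 kb
        track.add_counts("chr1", "+", 10000, np.full(3000, 0.1))  # 300 reads / 3 kb
        return track

    def test_two_gene_hand_example(self):
        regions = [
            {"id": "A", "chrom": "chr1", "strand": "+", "intervals": [(0, 1000)]},
            {"id": "B", "chrom": "chr1", "strand": "+", "intervals": [(10000, 13000)]},
        ]
        out = rcb_estimate(regions, self._track(), mode="gene").set_index("id")
        assert out.loc["A", "abundance"] == pytest.approx(5e5)
        assert out.loc["B", "abundance"] == pytest.approx(5e5)

    def test_single_gene_self_normalizes_to_one_million(self):
        regions = [{"id": "A", "chrom": "chr1", "strand": "+", "intervals": [(0, 1000)]}]
        out = rcb_estimate(regions, self._track(), mode="gene")
        assert out["abundance"].iloc[0] == pytest.approx(1e6)

    def test_isoform_mode_trims_region(self):
        regions = [
            {"id": "I", "chrom": "chr1", "strand": "+", "start": 0, "end": 10000}
        ]
        out = rcb_estimate(regions, self._track(), mode="isoform", T=1.0)
        assert out["length"].iloc[0] == 10000 - 250 - 1000

    def test_zero_length_region_errors(self):
        regions = [{"id": "I", "chrom": "chr1", "strand": "+", "start": 0, "end": 1000}]
        with pytest.raises(ValueError):
            rcb_estimate(regions, self._track(), mode="isoform")

    def test_gene_union_regions_merges_overlaps(self):
        isos = [
            MatureIsoform("a", "G", GenomicInterval("chr1", 0, 1000, "+")),
            MatureIsoform("b", "G", GenomicInterval("chr1", 500, 2000, "+")),
        ]
        (reg,) = gene_union_regions(isos)
        out = rcb_estimate([reg], self._track(), mode="gene")
        assert out["length"].iloc[0] == 2000


class TestExpressionFilter:
    def test_top_75_of_100(self):
        t = pd.DataFrame({"normalized_abundance": np.arange(1.0, 101.0)})
        assert len(filter_by_expression_rank(t)) == 75

    def test_all_zero_empty(self):
        t = pd.DataFrame({"normalized_abundance": np.zeros(10)})
        assert filter_by_expression_rank(t).empty

    def test_fraction_one_keeps_all_expressed(self):
        t = pd.DataFrame({"normalized_abundance": [0.0, 1.0, 2.0]})
        assert len(filter_by_expression_rank(t, top_fraction=1.0)) == 2


class TestPipeline:
    def test_quantify_writes_all_isoforms_with_nonnegative_beta(self, small_dataset):
        table = quantify(
            small_dataset.isoforms,
            small_dataset.coverage,
            QuantifyConfig(use_tss=False, use_shape=False, log_space=False),
        )
        assert (table["raw_beta"] >= 0).all()
        assert table.groupby("gene_id")["is_dominant"].sum().eq(1).all()

    def test_user_inactive_list_forces_zero(self, small_dataset):
        config = QuantifyConfig(use_tss=False, use_shape=False, log_space=False)
        base = quantify(small_dataset.isoforms, small_dataset.coverage, config)
        expressed = base[base["raw_beta"] > 0].iloc[0]
        banned = set(expressed["member_transcript_ids"].split(","))
        table = quantify(
            small_dataset.isoforms, small_dataset.coverage, config, user_inactive=banned
        )
        row = table[table["pre_rna_isoform_id"] == expressed["pre_rna_isoform_id"]]
        assert row["raw_beta"].iloc[0] == 0.0
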