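import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from scipy.special import gammaln

import smad4sig as s
from smad4sig import _nb
from smad4sig.diffexpr import CountMatrix, DesignError


def _cm(counts, genotype=None, time=None):
    counts = np.atleast_2d(np.asarray(counts))
    n = counts.shape[1]
    sids = [f"s{i}" for i in range(n)]
    meta = pd.DataFrame(
        {
            "genotype": genotype or ["WT"] * n,
            "time": time if time is not None else [0] * n,
            "replicate": list(range(n)),
        },
        index=pd.Index(sids, name="sample_id"),
    )
    df = pd.DataFrame(counts, index=[f"g{i}" for i in range(counts.shape[0])], columns=sids)
    return CountMatrix(df, meta)


class TestFilterLowCounts:
    def test_gene_with_three_samples_at_threshold_is_retained(self):
        row = [5, 5, 5] + [0] * 15
        m = s.filter_low_counts(_cm([row, [10] * 18]))
        assert "g0" in m.gene_ids

    def test_gene_below_threshold_everywhere_is_removed(self):
        m = s.filter_low_counts(_cm([[4] * 18, [10] * 18]))
        assert list(m.gene_ids) == ["g1"]

    def test_all_zero_matrix_warns_and_empties(self):
        with pytest.warns(UserWarning):
            m = s.filter_low_counts(_cm(np.zeros((3, 6), dtype=int)))
        assert len(m.gene_ids) == 0


class TestSizeFactors:
    def test_identical_samples_get_unit_factors(self):
        sf = s.estimate_size_factors(_cm([[10, 10], [3, 3]]))
        assert np.allclose(sf, [1.0, 1.0])

    def test_doubled_sample_hand_computation(self):
        # sample2 = 2 x sample1: median of ratios gives (1/sqrt2, sqrt2)
        sf = s.estimate_size_factors(_cm([[10, 20], [4, 8], [7, 14]]))
        assert np.allclose(sf, [1 / np.sqrt(2), np.sqrt(2)])

    def test_invariant_to_gene_order(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(30, (40, 6)) + 1
        sf1 = s.estimate_size_factors(_cm(counts))
        sf2 = s.estimate_size_factors(_cm(counts[::-1]))
        assert np.allclose(sf1, sf2)

    def test_error_when_no_gene_covers_all_samples(self):
        with pytest.raises(ValueError):
            s.estimate_size_factors(_cm([[0, 5], [5, 0]]))


class TestBHAdjust:
    def test_hand_computation(self):
        assert np.allclose(s.bh_adjust([0.01, 0.02, 0.04]), [0.03, 0.03, 0.04])

    def test_single_p_unchanged(self):
        assert s.bh_adjust([0.3])[0] == pytest.approx(0.3)

    def test_nan_propagates_without_counting(self):
        out = s.bh_adjust([0.01, np.nan, 0.02])
        assert np.isnan(out[1])
        assert np.allclose(out[[0, 2]], s.bh_adjust([0.01, 0.02]))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_never_decreases_and_stays_in_unit_interval(self, p):
        out = s.bh_adjust(p)
        assert (out >= np.asarray(p) - 1e-12).all()
        assert (out <= 1.0).all() and (out >= 0.0).all()


class TestWaldTest:
    def test_contrast_swap_negates_lfc_and_keeps_p(self, bulk_sim):
        _, cm, _ = bulk_sim
        a = s.wald_test(cm, "time", 1, 0, subset={"genotype": "WT"})
        b = s.wald_test(cm, "time", 0, 1, subset={"genotype": "WT"})
        assert np.allclose(a["log2fc"], -b["log2fc"])
        assert np.allclose(a["pvalue"], b["pvalue"])

    def test_recovers_planted_fold_change(self):
        # pure 3v3: mean 100 vs 800 (log2fc 3), dispersion 0.1, unit factors
        rng = np.random.default_rng(4)
        r = 10.0
        mu = np.hstack([np.full((500, 3), 100.0), np.full((500, 3), 800.0)])
        counts = rng.negative_binomial(r, r / (r + mu))
        cm = _cm(counts, time=[0, 0, 0, 1, 1, 1])
        ones = pd.Series(np.ones(6), index=cm.sample_ids)
        res = s.wald_test(cm, "time", 1, 0, size_factors=ones)
        # the estimator is unbiased; its asymptotic sd is
        # sqrt(2 * (alpha + 1/mu) / n_rep) / ln2 ~= 0.39 log2 units here,
        # so +-0.5 should cover ~2*Phi(0.5/0.39)-1 ~= 0.80 of genes
        sd = np.sqrt(2 * (0.1 + 1 / 100.0) / 3) / np.log(2)
        expected_cov = 2 * stats.norm.cdf(0.5 / sd) - 1
        within = (res["log2fc"].sub(3.0).abs() <= 0.5).mean()
        assert res["log2fc"].median() == pytest.approx(3.0, abs=0.1)
        assert within == pytest.approx(expected_cov, abs=0.06)

    def test_tiny_dispersion_limit_matches_mean_ratio(self):
        # with unit size factors the Wald log2fc approaches the log2 mean ratio
        rng = np.random.default_rng(0)
        filler = rng.poisson(200, (29, 6))
        counts = np.vstack([[1000, 1010, 990, 4000, 4040, 3960], filler])
        cm = _cm(counts, time=[0, 0, 0, 1, 1, 1])
        ones = pd.Series(np.ones(6), index=cm.sample_ids)
        res = s.wald_test(cm, "time", 1, 0, size_factors=ones)
        assert res["log2fc"].iloc[0] == pytest.approx(2.0, abs=0.02)

    def test_all_zero_gene_flagged_neutral(self):
        counts = np.vstack([np.zeros(6, dtype=int), np.full(6, 50)])
        res = s.wald_test(_cm(counts, time=[0, 0, 0, 1, 1, 1]), "time", 1, 0)
        assert res.loc[0, "pvalue"] == 1.0 and res.loc[0, "log2fc"] == 0.0
        assert "g0" in res.attrs["zero_in_both_groups"]

    def test_requires_two_samples_per_group(self):
        with pytest.raises(DesignError):
            s.wald_test(_cm([[5, 6, 7]], time=[0, 1, 1]), "time", 1, 0)

    def test_normalization_equivariance_under_sample_scaling(self):
        cfg = s.BulkSimConfig(n_genes=300, seed=2)
        cm, _ = s.simulate_bulk_counts(cfg)
        r1 = s.wald_test(cm, "time", 1, 0, subset={"genotype": "WT"})
        scaled = cm.counts.copy()
        scaled.iloc[:, 1] = scaled.iloc[:, 1] * 3
        r2 = s.wald_test(CountMatrix(scaled, cm.sample_meta), "time", 1, 0,
                         subset={"genotype": "WT"})
        dlfc = (r1["log2fc"] - r2["log2fc"]).abs()
        assert dlfc.median() < 0.05
        assert (dlfc < 0.3).mean() > 0.95


class TestSingleGeneOracle:
    def test_grid_search_maximum_matches_fit(self):
        """Dense grid over (mu_A, mu_B, alpha) agrees with the Newton fit."""
        y = np.array([[12, 19, 15, 45, 38, 52]], dtype=float)
        sf = np.ones(6)
        codes = np.array([0, 0, 0, 1, 1, 1])

        def ll(qa, qb, alpha):
            mu = np.where(codes == 0, qa, qb)
            r = 1 / alpha
            return float(np.sum(gammaln(y[0] + r) - gammaln(r) - gammaln(y[0] + 1)
                                + r * np.log(r / (r + mu)) + y[0] * np.log(mu / (r + mu))))

        qa_grid = np.linspace(5, 40, 120)
        qb_grid = np.linspace(20, 80, 120)
        a_grid = np.geomspace(1e-4, 2, 80)
        best = max(
            ((ll(qa, qb, a), qa, qb, a) for a in a_grid for qa in qa_grid for qb in qb_grid),
        )
        alpha_hat = _nb.estimate_dispersion(y, sf, codes, 2, cr_adjust=False, moderate=False)
        beta, _ = _nb.fit_group_means(y, sf, codes, 2, alpha_hat)
        assert np.exp(beta[0, 0]) == pytest.approx(best[1], rel=0.02)
        assert np.exp(beta[0, 1]) == pytest.approx(best[2], rel=0.02)
        assert alpha_hat[0] == pytest.approx(best[3], rel=0.25, abs=0.01)

    def test_irls_matches_statsmodels_glm(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(1)
        X = np.column_stack([np.ones(12), np.repeat([0, 1], 6), np.tile([0, 1], 6)])
        mu = np.exp(3 + 0.8 * X[:, 1] - 0.5 * X[:, 2])
        y = rng.negative_binomial(10, 10 / (10 + mu)).astype(float)
        alpha = 0.1
        beta, ll = _nb.fit_nb_glm(y[None, :], X, np.ones(12), np.array([alpha]))
        glm = sm.GLM(y, X, family=sm.families.NegativeBinomial(alpha=alpha)).fit()
        assert np.allclose(beta[0], glm.params, atol=1e-4)


class TestLRT:
    def test_identical_designs_give_null_result(self, bulk_sim):
        _, cm, _ = bulk_sim
        res = s.lrt_time_series(cm, full=("genotype", "time"), reduced=("genotype", "time"))
        assert (res["stat"] == 0).all() and (res["pvalue"] == 1).all()

    def test_statistic_never_negative_and_planted_genes_rank_first(self, bulk_sim):
        _, cm, truth = bulk_sim
        res = s.lrt_time_series(s.filter_low_counts(cm))
        assert (res["stat"] >= 0).all()
        m = res.merge(truth, on="gene_id")
        planted = m["class"].isin(["early_up", "early_down", "smad4_dependent",
                                   "late_up", "late_down"])
        assert m.loc[planted, "pvalue"].median() < m.loc[m["class"] == "null", "pvalue"].median()

    def test_non_nested_designs_rejected(self, bulk_sim):
        _, cm, _ = bulk_sim
        with pytest.raises(DesignError):
            s.lrt_time_series(cm, full=("genotype",), reduced=("time",))


class TestCallDeg:
    @pytest.mark.parametrize(
        "log2fc,padj,expected",
        [
            (1.5, 0.01, "up"),      # fold-change boundary is inclusive
            (2.0, 0.06, None),      # FDR boundary is strict
            (-1.6, 0.001, "down"),
            (1.49, 0.001, None),
        ],
    )
    def test_threshold_rules(self, log2fc, padj, expected):
        import conftest

        res = conftest.make_de(["g"], [log2fc], [padj])
        called = s.call_deg(res)
        if expected is None:
            assert called.empty
        else:
            assert called["direction"].iloc[0] == expected
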