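import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cerebstat.continuity import (
    LogisticFit,
    TrajectoryOrdering,
    compare_pair,
    continuity_m,
    ecdf,
    fit_logistic_gene,
    order_cells,
    rank_trajectory_genes,
    scale_expression,
    wilcoxon_de_genes,
)
from cerebstat.core import NormalizedMatrix, ValidationError
from cerebstat.simulate import TrajectorySimConfig, simulate_trajectory_pair


def grid_ordering(n: int) -> TrajectoryOrdering:
    return TrajectoryOrdering(
        cell_ids=np.array([f"c{i}" for i in range(n)], dtype=object),
        rank=np.arange(1, n + 1), source="external")


def logistic(x, a, d, b, x0):
    return a + (d - a) / (1.0 + np.exp(-b * (x - x0)))


class TestOrdering:
    def test_ranks_follow_supplied_pseudotime(self):
        n = 24
        rng = np.random.default_rng(0)
        pt = rng.permutation(n) / n
        mat = NormalizedMatrix(rng.normal(size=(5, n)),
                               [f"g{i}" for i in range(5)],
                               [f"c{i}" for i in range(n)])
        o = order_cells(mat, pseudotime=pt)
        assert np.array_equal(o.rank, stats.rankdata(pt, method="ordinal"))
        assert o.source == "external"

    def test_internal_axis_recovers_monotone_trend(self):
        cfg = TrajectorySimConfig(n_cells=400, n_genes=30, steepness=6.0,
                                  noise_sd=0.25, seed=1)
        mat, t, _ = simulate_trajectory_pair(cfg)
        o = order_cells(mat)
        rho = stats.spearmanr(o.rank, t).statistic
        assert abs(rho) > 0.9

    def test_noise_free_monotone_map_gives_perfect_rho(self):
        n = 50
        t = np.linspace(0.01, 1, n)
        mat = NormalizedMatrix(np.vstack([t, t ** 2, np.exp(t)]),
                               ["g1", "g2", "g3"], [f"c{i}" for i in range(n)])
        o = order_cells(mat)
        assert abs(stats.spearmanr(o.rank, t).statistic) == pytest.approx(1.0)

    def test_constant_matrix_rejected(self):
        mat = NormalizedMatrix(np.ones((3, 30)), ["g1", "g2", "g3"],
                               [f"c{i}" for i in range(30)])
        with pytest.raises(ValidationError):
            order_cells(mat)

    def test_too_few_cells_rejected(self):
        mat = NormalizedMatrix(np.random.default_rng(0).normal(size=(3, 5)),
                               ["g1", "g2", "g3"], [f"c{i}" for i in range(5)])
        with pytest.raises(ValidationError):
            order_cells(mat)


class TestScaleExpression:
    def test_zero_mean_unit_sd(self):
        rng = np.random.default_rng(2)
        mat = NormalizedMatrix(rng.uniform(1, 5, size=(4, 40)),
                               [f"g{i}" for i in range(4)],
                               [f"c{i}" for i in range(40)])
        z = scale_expression(mat).dense()
        assert np.allclose(z.mean(axis=1), 0.0, atol=1e-9)
        assert np.allclose(z.std(axis=1, ddof=1), 1.0, atol=1e-9)

    def test_extreme_outlier_clipped(self):
        n = 701
        values = np.zeros((1, n))
        values[0, -1] = 100.0  # z-score ~ sqrt(n) >> 10
        mat = NormalizedMatrix(values, ["g"], [f"c{i}" for i in range(n)])
        z = scale_expression(mat).dense()
        assert z.max() == pytest.approx(10.0)

    def test_zero_variance_gene_excluded(self):
        mat = NormalizedMatrix(np.vstack([np.ones(30), np.arange(30.0)]),
                               ["flat", "ramp"], [f"c{i}" for i in range(30)])
        out = scale_expression(mat)
        assert out.gene_ids.tolist() == ["ramp"]


class TestLogisticFit:
    @pytest.mark.parametrize("b", [1.0, 2.0, 4.0, 8.0, 16.0, 32.0])
    def test_noise_free_recovery_within_one_percent(self, b):
        n = 400
        o = grid_ordering(n)
        y = logistic(o.x, 0.0, 1.0, b, 0.5)
        fit = fit_logistic_gene(y, o)
        assert fit.converged
        assert continuity_m(fit) == pytest.approx(b / 4.0, rel=0.01)

    def test_reversal_symmetry(self):
        n = 300
        o = grid_ordering(n)
        y = logistic(o.x, 0.0, 1.0, 8.0, 0.3)
        fwd = fit_logistic_gene(y, o)
        rev = fit_logistic_gene(y[::-1], o)
        assert rev.x0 == pytest.approx(1.0 - fwd.x0, abs=0.02)
        assert rev.b == pytest.approx(fwd.b, rel=0.02)

    def test_decreasing_gene_normalized_to_d_ge_a(self):
        o = grid_ordering(200)
        y = logistic(o.x, 1.0, 0.0, 10.0, 0.5)  # falling curve
        fit = fit_logistic_gene(y, o)
        assert fit.d >= fit.a
        assert fit.b > 0

    def test_pure_noise_small_dynamic_range_or_slope(self):
        rng = np.random.default_rng(3)
        o = grid_ordering(500)
        fit = fit_logistic_gene(rng.normal(size=500), o)
        assert fit.converged
        # flat genes: fitted step is tiny and/or slope uninformative
        assert fit.dynamic_range < 1.0 or fit.b < 5.0

    def test_non_finite_input_rejected(self):
        o = grid_ordering(30)
        y = np.zeros(30)
        y[0] = np.nan
        with pytest.raises(ValidationError):
            fit_logistic_gene(y, o)

    def test_step_gene_hits_cap_with_finite_m(self):
        n = 100
        o = grid_ordering(n)
        y = (o.x > 0.5).astype(float)
        fit = fit_logistic_gene(y, o)
        assert fit.converged and np.isfinite(continuity_m(fit))
        assert fit.b <= 4.0 * n + 1e-6


class TestContinuityM:
    def test_closed_form(self):
        fit = LogisticFit(a=0.0, d=1.0, b=8.0, x0=0.5, converged=True, rss=0.0)
        assert continuity_m(fit) == pytest.approx(2.0)
        assert np.log10(continuity_m(fit)) == pytest.approx(0.30103, abs=1e-4)

    def test_affine_invariance(self):
        o = grid_ordering(300)
        y = logistic(o.x, 0.0, 1.0, 12.0, 0.5)
        m1 = continuity_m(fit_logistic_gene(y, o))
        m2 = continuity_m(fit_logistic_gene(3.0 * y + 5.0, o))
        assert m2 == pytest.approx(m1, rel=1e-3)

    def test_cell_duplication_invariance(self):
        n = 200
        o = grid_ordering(n)
        y = logistic(o.x, 0.0, 1.0, 8.0, 0.5)
        m1 = continuity_m(fit_logistic_gene(y, o))
        o2 = grid_ordering(2 * n)
        y2 = logistic(o2.x, 0.0, 1.0, 8.0, 0.5)
        m2 = continuity_m(fit_logistic_gene(y2, o2))
        assert m2 == pytest.approx(m1, rel=1e-3)

    def test_unconverged_fit_propagates_nan(self):
        fit = LogisticFit(np.nan, np.nan, np.nan, np.nan, converged=False, rss=np.nan)
        assert np.isnan(continuity_m(fit))


class TestGeneRanking:
    def test_monotone_gene_first_flat_gene_last(self):
        n = 60
        o = grid_ordering(n)
        rng = np.random.default_rng(4)
        values = np.vstack([o.x + rng.normal(0, 1e-6, n),
                            rng.normal(size=n)])
        mat = NormalizedMatrix(values, ["ramp", "noise"],
                               [f"c{i}" for i in range(n)])
        ranked = rank_trajectory_genes(mat, o, n_top=2)
        assert ranked["gene_id"].tolist() == ["ramp", "noise"]
        assert ranked["spearman_rho"].iloc[0] == pytest.approx(1.0, abs=1e-6)

    def test_n_top_larger_than_genes_returns_all(self):
        o = grid_ordering(30)
        mat = NormalizedMatrix(np.random.default_rng(5).normal(size=(3, 30)),
                               ["a", "b", "c"], [f"c{i}" for i in range(30)])
        assert len(rank_trajectory_genes(mat, o, n_top=99)) == 3


class TestComparePair:
    def _pair(self, steepness, n_cells=600, n_genes=40, seed=0, noise_sd=0.4):
        cfg = TrajectorySimConfig(n_cells=n_cells, n_genes=n_genes,
                                  steepness=steepness, noise_sd=noise_sd, seed=seed)
        mat, t, _ = simulate_trajectory_pair(cfg)
        split = t < np.median(t)
        a = NormalizedMatrix(mat.dense()[:, split], mat.gene_ids,
                             mat.cell_ids[split])
        b = NormalizedMatrix(mat.dense()[:, ~split], mat.gene_ids,
                             mat.cell_ids[~split])
        return a, b

    def test_identical_populations_yield_empty_status(self):
        rng = np.random.default_rng(6)
        values = rng.normal(size=(10, 100))
        a = NormalizedMatrix(values[:, :50], [f"g{i}" for i in range(10)],
                             [f"a{i}" for i in range(50)])
        b = NormalizedMatrix(values[:, 50:], [f"g{i}" for i in range(10)],
                             [f"b{i}" for i in range(50)])
        res, curve = compare_pair(a, b, n_top=5, seed=0)
        assert res.empty
        assert res.attrs["status"] == "no-de-genes"
        assert curve.empty

    def test_discrete_pair_has_larger_m_than_continuous(self):
        a_hi, b_hi = self._pair(steepness=50.0, seed=7)
        a_lo, b_lo = self._pair(steepness=2.0, seed=8)
        res_hi, _ = compare_pair(a_hi, b_hi, n_top=20, seed=1)
        res_lo, _ = compare_pair(a_lo, b_lo, n_top=20, seed=1)
        assert res_hi["log10_m"].median() - res_lo["log10_m"].median() > 0.5

    def test_deterministic_given_seed(self):
        a, b = self._pair(steepness=10.0, seed=9)
        res1, curve1 = compare_pair(a, b, n_top=10, max_cells=400, seed=5)
        res2, curve2 = compare_pair(a, b, n_top=10, max_cells=400, seed=5)
        pd.testing.assert_frame_equal(res1, res2)
        pd.testing.assert_frame_equal(curve1, curve2)

    def test_mismatched_gene_space_rejected(self):
        rng = np.random.default_rng(10)
        a = NormalizedMatrix(rng.normal(size=(3, 30)), ["g1", "g2", "g3"],
                             [f"a{i}" for i in range(30)])
        b = NormalizedMatrix(rng.normal(size=(3, 30)), ["g1", "g2", "zz"],
                             [f"b{i}" for i in range(30)])
        with pytest.raises(ValidationError):
            compare_pair(a, b)


class TestEcdf:
    def test_endpoints_and_monotone(self):
        curve = ecdf([3.0, 1.0, 2.0])
        assert curve["cdf"].iloc[-1] == 1.0
        assert (np.diff(curve["value"]) >= 0).all()
        assert (np.diff(curve["cdf"]) > 0).all()
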