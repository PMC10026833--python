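import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from scstalt import (
    ExpressionMatrix,
    build_kernel,
    fit_gene_trend,
    fit_gene_trends,
    log_normalize,
    normalize_pseudotime,
    select_dynamic_genes,
)
from scstalt.errors import (
    DegenerateTrajectoryError,
    EmptyKernelError,
    FitError,
    ValidationError,
)

GRID = np.linspace(0.0, 1.0, 25)


class TestNormalizePseudotime:
    def test_affine_map(self):
        np.testing.assert_allclose(normalize_pseudotime([2, 4, 6]), [0, 0.5, 1])

    def test_degenerate_trajectory_rejected(self):
        with pytest.raises(DegenerateTrajectoryError):
            normalize_pseudotime([5, 5, 5])

    @given(
        st.lists(
            st.floats(min_value=-1e6, max_value=1e6, allow_nan=False),
            min_size=2,
            max_size=30,
            unique=True,
        )
    )
    def test_idempotent_and_rank_preserving(self, raw):
        t = normalize_pseudotime(raw)
        assert t.min() == 0.0 and t.max() == 1.0
        np.testing.assert_allclose(normalize_pseudotime(t), t, atol=1e-12)
        # order is preserved (non-strictly: far-apart magnitudes may collapse
        # to equal floats after rescaling)
        raw_arr = np.asarray(raw)
        order = np.argsort(raw_arr, kind="stable")
        assert np.all(np.diff(t[order]) >= 0)


class TestLogNormalize:
    def test_formula(self):
        counts = ExpressionMatrix(np.array([[5.0], [0.0]]), ["g1", "g2"], ["c1"])
        out = log_normalize(counts)
        assert out.layer == "lognorm"
        # single expressed gene carries the whole library: ln(1 + 1e4)
        np.testing.assert_allclose(out.values[:, 0], [np.log1p(1e4), 0.0])

    def test_depth_invariance_per_cell(self, rng):
        raw = rng.integers(0, 20, size=(30, 4)).astype(float)
        raw[0] += 1  # no zero-total cells
        doubled = raw.copy()
        doubled[:, 2] *= 2
        a = log_normalize(ExpressionMatrix(raw, [f"g{i}" for i in range(30)], list("abcd")))
        b = log_normalize(ExpressionMatrix(doubled, [f"g{i}" for i in range(30)], list("abcd")))
        np.testing.assert_allclose(a.values, b.values, atol=1e-12)

    def test_zero_total_cell_rejected_with_ids(self):
        counts = ExpressionMatrix(np.array([[1.0, 0.0]]), ["g"], ["ok", "empty"])
        with pytest.raises(ValidationError, match="empty"):
            log_normalize(counts)

    def test_requires_counts_layer(self, small_lognorm):
        with pytest.raises(ValidationError):
            log_normalize(small_lognorm)


class TestGeneTrendFit:
    def test_constant_gene_flat_curve_zero_F(self):
        t = np.linspace(0, 1, 40)
        trend = fit_gene_trend(np.full(40, 3.7), t, GRID)
        np.testing.assert_allclose(trend.grid_values, 3.7, atol=1e-8)
        assert trend.fit_statistic == pytest.approx(0.0, abs=1e-8)
        assert trend.p_value == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "poly",
        [
            lambda t: 2 * t,
            lambda t: 1 - 3 * t + 0.5 * t**2,
            lambda t: t**3 - 2 * t**2 + 0.25,
        ],
        ids=["linear", "quadratic", "cubic"],
    )
    def test_noiseless_polynomials_reproduced_exactly(self, poly):
        # a cubic spline basis with df >= 4 contains every cubic polynomial
        t = np.linspace(0, 1, 60)
        trend = fit_gene_trend(poly(t), t, GRID, df=6)
        np.testing.assert_allclose(trend.grid_values, poly(GRID), atol=1e-6)
        assert trend.p_value < 1e-10

    def test_grid_values_length_matches_grid(self, rng):
        t = np.sort(rng.random(30))
        trend = fit_gene_trend(rng.normal(size=30), normalize_pseudotime(t), GRID)
        assert trend.grid_values.shape == (len(GRID),)

    def test_f_statistic_matches_statsmodels_ols(self, rng):
        """Dual route: the vectorized F must equal statsmodels' OLS F-test."""
        import statsmodels.api as sm

        from scstalt.kernel import _spline_design

        t = normalize_pseudotime(np.sort(rng.random(80)))
        y = np.sin(2 * np.pi * t) + rng.normal(0, 0.3, size=80)
        _, F, p = fit_gene_trends(y.reshape(-1, 1), t, GRID, df=6)
        X, _ = _spline_design(t, 6)
        fit = sm.OLS(y, X).fit()
        # spline basis spans the constant, so the OLS overall F is the same test
        assert F[0] == pytest.approx(fit.fvalue, rel=1e-8)
        assert p[0] == pytest.approx(fit.f_pvalue, rel=1e-6)

    def test_too_few_distinct_pseudotimes_raise(self):
        t = np.array([0.0, 0.0, 0.5, 0.5, 1.0, 1.0, 1.0, 0.0, 0.5, 1.0])
        with pytest.raises(FitError):
            fit_gene_trend(np.arange(10.0), t, GRID, df=6)

    def test_too_few_cells_raise(self):
        with pytest.raises(FitError):
            fit_gene_trend(np.arange(5.0), np.linspace(0, 1, 5), GRID, df=6)


def _lognorm_matrix(values, t=None):
    g = [f"g{i}" for i in range(values.shape[0])]
    c = [f"c{i}" for i in range(values.shape[1])]
    return ExpressionMatrix(values, g, c, layer="lognorm")


class TestDynamicGeneSelection:
    def test_null_false_positive_rate_controlled(self, rng):
        n_cells, n_genes = 200, 1000
        t = normalize_pseudotime(np.sort(rng.random(n_cells)))
        noise = rng.normal(size=(n_genes, n_cells))
        genes, table = select_dynamic_genes(_lognorm_matrix(noise), t, fdr=0.05)
        se = np.sqrt(0.05 * 0.95 / n_genes)
        assert len(genes) / n_genes <= 0.05 + 3 * se
        # raw p-values are calibrated under the Gaussian null
        raw_frac = float((table["p_value"] < 0.05).mean())
        assert raw_frac == pytest.approx(0.05, abs=3 * se)

    def test_planted_signal_gene_is_found(self, rng):
        n_cells = 150
        t = normalize_pseudotime(np.sort(rng.random(n_cells)))
        mat = rng.normal(size=(50, n_cells))
        mat[17] = 2 * t  # noiseless trend among pure-noise genes
        genes, table = select_dynamic_genes(_lognorm_matrix(mat), t, fdr=0.05)
        assert "g17" in set(genes)
        assert genes[0] == "g17"  # diverging F sorts it first
        assert table.loc[17, "q_value"] >= table.loc[17, "p_value"]

    @pytest.mark.parametrize("fdr", [0.0, 1.0, -0.1])
    def test_fdr_bounds(self, small_lognorm, fdr):
        with pytest.raises(ValidationError):
            select_dynamic_genes(small_lognorm, np.linspace(0, 1, small_lognorm.n_cells), fdr=fdr)


class TestBuildKernel:
    def test_noiseless_linear_genes_m4(self, rng):
        t = np.linspace(0, 1, 40)
        slopes = np.array([1.0, -2.0, 0.5, 3.0, -1.5])
        intercepts = np.array([0.0, 5.0, 1.0, 2.0, 4.0])
        mat = intercepts[:, None] + slopes[:, None] * t
        kernel, _ = build_kernel(_lognorm_matrix(mat), t, m=4, fdr=0.05)
        assert kernel.R.shape == (5, 4)
        np.testing.assert_allclose(kernel.stage_grid, [0, 1 / 3, 2 / 3, 1])
        by_gene = dict(zip(kernel.genes, kernel.R))
        for i in range(5):
            np.testing.assert_allclose(by_gene[f"g{i}"][0], intercepts[i], atol=1e-6)

    def test_single_stage_rejected(self, small_lognorm):
        with pytest.raises(ValidationError):
            build_kernel(small_lognorm, np.linspace(0, 1, small_lognorm.n_cells), m=1)

    def test_empty_kernel_error(self, rng):
        t = normalize_pseudotime(np.sort(rng.random(60)))
        noise = rng.normal(size=(20, 60))
        with pytest.raises(EmptyKernelError, match="laxer"):
            build_kernel(_lognorm_matrix(noise), t, m=10, fdr=1e-6)

    def test_invariant_to_cell_ordering(self, small_sim, small_lognorm):
        t = small_sim.true_pseudotime
        kernel, _ = build_kernel(small_lognorm, t, m=20)
        perm = np.random.default_rng(5).permutation(small_lognorm.n_cells)
        shuffled = ExpressionMatrix(
            small_lognorm.values[:, perm],
            small_lognorm.gene_ids,
            small_lognorm.cell_ids[perm],
            layer="lognorm",
        )
        kernel2, _ = build_kernel(shuffled, t[perm], m=20)
        assert list(kernel.genes) == list(kernel2.genes)
        np.testing.assert_allclose(kernel.R, kernel2.R, atol=1e-8)
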