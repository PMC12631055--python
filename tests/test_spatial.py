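import numpy as np
import pandas as pd
import pytest

from alfadiv import geno, spatial, synthetic


def _identity_grm(n):
    return geno.GenomicRelationship(
        G=np.eye(n), n_scale=1.0, marker_freqs=np.array([]), m=0,
        accession_ids=[f"a{i}" for i in range(n)],
    )


def _cox_de_boor(x, t, i, k):
    """Textbook recursive B-spline evaluation (independent oracle)."""
    if k == 0:
        return 1.0 if t[i] <= x < t[i + 1] else 0.0
    left = 0.0
    if t[i + k] > t[i]:
        left = (x - t[i]) / (t[i + k] - t[i]) * _cox_de_boor(x, t, i, k - 1)
    right = 0.0
    if t[i + k + 1] > t[i + 1]:
        right = ((t[i + k + 1] - x) / (t[i + k + 1] - t[i + 1])
                 * _cox_de_boor(x, t, i + 1, k - 1))
    return left + right


class TestBasis:
    @pytest.mark.parametrize("n_knots,degree", [(4, 3), (6, 2), (3, 1)])
    def test_partition_of_unity(self, n_knots, degree):
        x = np.linspace(0.0, 10.0, 37)
        B = spatial.bspline_basis(x, n_knots, degree)
        assert B.shape == (37, n_knots + degree - 1)
        np.testing.assert_allclose(B.sum(axis=1), 1.0, atol=1e-10)

    def test_degree_zero_is_indicator(self):
        x = np.array([0.5, 1.5, 2.5])
        B = spatial.bspline_basis(x, 4, degree=0, span=(0.0, 3.0))
        np.testing.assert_allclose(B, np.eye(3), atol=1e-12)

    def test_matches_recursive_oracle(self):
        n_knots, degree = 5, 3
        lo, hi = 0.0, 8.0
        breaks = np.linspace(lo, hi, n_knots)
        t = np.concatenate([[lo] * degree, breaks, [hi] * degree])
        xs = (breaks[:-1] + breaks[1:]) / 2        # interval midpoints
        B = spatial.bspline_basis(xs, n_knots, degree, span=(lo, hi))
        for r, x in enumerate(xs):
            for i in range(B.shape[1]):
                assert B[r, i] == pytest.approx(
                    _cox_de_boor(x, t, i, degree), abs=1e-12)

    def test_outside_span_rejected(self):
        with pytest.raises(ValueError, match="span"):
            spatial.bspline_basis(np.array([5.0]), 4, span=(0.0, 4.0))


class TestTensorDesign:
    def test_brute_force_3x3(self):
        rb = np.random.default_rng(0).uniform(size=(9, 3))
        cb = np.random.default_rng(1).uniform(size=(9, 4))
        W = spatial.tensor_design(rb, cb)
        for i in range(9):
            for a in range(3):
                for b in range(4):
                    assert W[i, a * 4 + b] == rb[i, a] * cb[i, b]

    def test_row_sums_one_for_bspline_bases(self):
        x = np.linspace(1, 10, 30)
        rb = spatial.bspline_basis(x, 4)
        cb = spatial.bspline_basis(x, 5)
        W = spatial.tensor_design(rb, cb)
        np.testing.assert_allclose(W.sum(axis=1), 1.0, atol=1e-10)

    def test_degree_zero_one_hot(self):
        layout = synthetic.simulate_trial(3, 3, [f"a{i}" for i in range(9)],
                                          seed=0)
        W, _ = spatial.build_spatial_design(layout, (4, 4), degree=0)
        np.testing.assert_allclose(W.sum(axis=1), 1.0)
        assert ((W == 0) | (W == 1)).all()


class TestReml:
    def test_constant_response(self, balanced_layout):
        grm = _identity_grm(20)
        y = np.full(len(balanced_layout), 3.25)
        fit = spatial.fit_spatial_gblup(y, balanced_layout, grm, knots=(3, 3))
        assert fit.mu == pytest.approx(3.25)
        assert fit.var_additive == fit.var_spatial == fit.var_residual == 0.0
        np.testing.assert_array_equal(fit.u_hat.to_numpy(), 0.0)

    def test_matches_balanced_anova_closed_form(self):
        rng = np.random.default_rng(7)
        n_acc, reps = 20, 5
        u = rng.normal(scale=np.sqrt(2.0), size=n_acc)
        y = np.repeat(u, reps) + rng.normal(size=n_acc * reps) + 5.0
        layout = pd.DataFrame({
            "plot_id": [f"p{i}" for i in range(n_acc * reps)],
            "trial_id": "T1", "row": 1,
            "column": np.arange(n_acc * reps) + 1, "block": "B1",
            "accession": np.repeat([f"a{i}" for i in range(n_acc)], reps),
        })
        fit = spatial.fit_spatial_gblup(y, layout, _identity_grm(n_acc),
                                        include_spatial=False)
        ybar_i = y.reshape(n_acc, reps).mean(axis=1)
        msa = reps * ((ybar_i - y.mean()) ** 2).sum() / (n_acc - 1)
        mse = ((y.reshape(n_acc, reps) - ybar_i[:, None]) ** 2).sum() \
            / (n_acc * (reps - 1))
        assert fit.var_residual == pytest.approx(mse, rel=1e-6)
        assert fit.var_additive == pytest.approx((msa - mse) / reps, rel=1e-6)

    def test_no_spatial_signal_estimated_near_zero(self, balanced_layout):
        grm = _identity_grm(20)
        ok = 0
        for s in range(5):
            plots, _ = synthetic.simulate_phenotypes(
                grm, balanced_layout, None, 1.0, 1.0, 1, seed=s)
            y = plots["trait1"].to_numpy()
            fit = spatial.fit_spatial_gblup(y, balanced_layout, grm,
                                            knots=(3, 4))
            ok += fit.var_spatial <= 0.05 * y.var()
        assert ok >= 4

    def test_plot_order_invariance(self, balanced_layout):
        grm = _identity_grm(20)
        surf = synthetic.simulate_spatial_surface(6, 10, 3.0, 1.0, seed=0)
        plots, _ = synthetic.simulate_phenotypes(
            grm, balanced_layout, surf, 1.0, 0.5, 1, seed=1)
        y = plots["trait1"].to_numpy()
        fit = spatial.fit_spatial_gblup(y, balanced_layout, grm, knots=(3, 4))
        perm = np.random.default_rng(2).permutation(len(y))
        fit_p = spatial.fit_spatial_gblup(
            y[perm], balanced_layout.iloc[perm].reset_index(drop=True),
            grm, knots=(3, 4))
        assert fit_p.var_additive == pytest.approx(fit.var_additive, rel=1e-4)
        assert fit_p.var_spatial == pytest.approx(fit.var_spatial, rel=1e-4)
        assert fit_p.var_residual == pytest.approx(fit.var_residual, rel=1e-4)

    def test_unknown_accession_rejected(self, balanced_layout):
        grm = _identity_grm(5)          # layout has 20 accessions
        with pytest.raises(ValueError, match="absent from G"):
            spatial.fit_spatial_gblup(
                np.zeros(len(balanced_layout)), balanced_layout, grm)


class TestKnotSelection:
    def _signal(self, seed=0):
        grm = _identity_grm(20)
        acc = [f"a{i}" for i in range(20)]
        layout = synthetic.simulate_trial(
            6, 10, acc, checks_replication={a: 3 for a in acc}, seed=3)
        surf = synthetic.simulate_spatial_surface(6, 10, 3.0, 2.0, seed=seed)
        plots, _ = synthetic.simulate_phenotypes(
            grm, layout, surf, 0.5, 0.5, 1, seed=seed)
        return plots["trait1"].to_numpy(), layout, grm

    def test_single_point_grid(self):
        y, layout, grm = self._signal()
        fit = spatial.select_knots(y, layout, grm, [(3, 4)])
        assert fit.knots == (3, 4)

    def test_argmin_contract(self):
        y, layout, grm = self._signal()
        grid = [(3, 3), (4, 6)]
        fits = {kn: spatial.fit_spatial_gblup(y, layout, grm, knots=kn)
                for kn in grid}
        best = spatial.select_knots(y, layout, grm, grid)
        assert best.aic == min(f.aic for f in fits.values())

    def test_empty_grid_rejected(self):
        y, layout, grm = self._signal()
        with pytest.raises(ValueError, match="empty"):
            spatial.select_knots(y, layout, grm, [])


class TestAdjustment:
    def test_zero_surface_identity(self, balanced_layout):
        grm = _identity_grm(20)
        y = np.random.default_rng(0).normal(size=len(balanced_layout))
        fit = spatial.fit_spatial_gblup(y, balanced_layout, grm, knots=(3, 4))
        fit.s_hat[:] = 0.0
        np.testing.assert_array_equal(spatial.adjust_phenotype(fit, y), y)

    def test_aggregate_matches_groupby(self, balanced_layout):
        vals = np.random.default_rng(1).normal(size=len(balanced_layout))
        means = spatial.aggregate_accessions(vals, balanced_layout)
        brute = pd.Series(vals, index=balanced_layout["accession"].to_numpy()) \
            .groupby(level=0).mean()
        pd.testing.assert_series_equal(means, brute, check_names=False)

    def test_aggregate_two_plots(self):
        layout = pd.DataFrame({"accession": ["a", "a"]})
        out = spatial.aggregate_accessions(np.array([2.0, 4.0]), layout)
        assert out["a"] == 3.0


class TestStandardize:
    def test_simple_column(self):
        out = spatial.standardize_traits(pd.DataFrame({"t": [1.0, 2.0, 3.0]}))
        np.testing.assert_allclose(out["t"], [-1.0, 0.0, 1.0])

    def test_idempotent(self):
        df = pd.DataFrame(np.random.default_rng(0).normal(size=(30, 3)),
                          columns=list("abc"))
        once = spatial.standardize_traits(df)
        twice = spatial.standardize_traits(once)
        np.testing.assert_allclose(once.to_numpy(), twice.to_numpy(),
                                   atol=1e-12)

    def test_moments_and_constant_drop(self):
        df = pd.DataFrame({
            "x": np.random.default_rng(1).normal(2, 5, size=40),
            "const": np.ones(40),
        })
        with pytest.warns(UserWarning, match="const"):
            out = spatial.standardize_traits(df)
        assert list(out.columns) == ["x"]
        assert out["x"].mean() == pytest.approx(0.0, abs=1e-12)
        assert out["x"].std(ddof=1) == pytest.approx(1.0, abs=1e-12)
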