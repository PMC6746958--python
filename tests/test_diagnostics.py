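"""VIFs, correlation matrices, the array-wide screen, condition indices."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from collinear_ewas import (
    CELL_TYPES,
    compute_vif,
    condition_indices,
    correlation_matrix,
    high_correlation_screen,
    pct_variance_explained,
)


def _orthogonal_design(n=60, k=3, seed=0):
    """Columns mutually orthogonal and orthogonal to the intercept."""
    raw = np.random.default_rng(seed).normal(size=(n, k + 1))
    raw[:, 0] = 1.0
    q, _ = np.linalg.qr(raw)
    return pd.DataFrame(q[:, 1:], columns=[f"x{i}" for i in range(k)])


class TestVif:
    def test_orthogonal_predictors_vif_one(self):
        rep = compute_vif(_orthogonal_design())
        assert np.allclose(rep.table["vif"], 1.0, atol=1e-10)

    def test_two_predictor_closed_form(self):
        # construct exact sample correlation 0.9 from orthonormal columns
        q = _orthogonal_design(100, 2, seed=1).to_numpy()
        z1, z2 = q[:, 0], q[:, 1]
        design = pd.DataFrame({"a": z1, "b": 0.9 * z1 + np.sqrt(1 - 0.81) * z2})
        rep = compute_vif(design)
        expected = 1.0 / (1.0 - 0.81)
        assert rep.vif("a") == pytest.approx(expected, rel=1e-9)
        assert rep.vif("b") == pytest.approx(expected, rel=1e-9)

    def test_inverse_correlation_oracle(self, rng):
        X = rng.normal(size=(200, 5)) @ rng.normal(size=(5, 5))
        design = pd.DataFrame(X, columns=list("abcde"))
        rep = compute_vif(design)
        oracle = np.diag(np.linalg.inv(np.corrcoef(X, rowvar=False)))
        assert np.allclose(rep.table["vif"].to_numpy(), oracle, atol=1e-8)

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.outliers_influence import variance_inflation_factor
        import statsmodels.api as sm
        X = rng.normal(size=(150, 4))
        X[:, 3] = X[:, 0] * 0.8 + rng.normal(size=150) * 0.3
        design = pd.DataFrame(X, columns=list("wxyz"))
        rep = compute_vif(design)
        exog = sm.add_constant(design).to_numpy()
        for j, name in enumerate(design.columns):
            assert rep.vif(name) == pytest.approx(
                variance_inflation_factor(exog, j + 1), rel=1e-8)

    def test_perfect_collinearity_is_infinite_with_warning(self, rng):
        x = rng.normal(size=50)
        z = rng.normal(size=50)
        design = pd.DataFrame({"a": x, "b": z, "c": x + z})
        with pytest.warns(UserWarning, match="collinear"):
            rep = compute_vif(design)
        assert np.isinf(rep.table["vif"]).all()
        assert rep.warnings

    def test_tolerance_is_reciprocal(self, default_cohort):
        design = default_cohort[["cpg4", "age", "sex", *CELL_TYPES]]
        rep = compute_vif(design)
        prod = rep.table["tolerance"] * rep.table["vif"]
        assert np.allclose(prod, 1.0, atol=1e-12)
        expected_pct = (1 - 1 / rep.table["vif"]) * 100
        assert np.allclose(rep.table["pct_var_explained"], expected_pct, atol=1e-12)

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(scale=st.floats(0.001, 1000.0), shift=st.floats(-50, 50),
           seed=st.integers(0, 5000))
    def test_affine_invariance(self, scale, shift, seed):
        r = np.random.default_rng(seed)
        X = r.normal(size=(80, 3))
        X[:, 1] += 0.7 * X[:, 0]
        design = pd.DataFrame(X, columns=list("abc"))
        base = compute_vif(design)
        moved = compute_vif(design.assign(b=design["b"] * scale + shift))
        assert np.allclose(base.table["vif"], moved.table["vif"], rtol=1e-7)

    def test_constant_predictor_rejected(self, rng):
        design = pd.DataFrame({"a": rng.normal(size=30), "b": np.ones(30)})
        with pytest.raises(ValueError, match="constant"):
            compute_vif(design)

    def test_intercept_column_excluded_from_report(self, rng):
        design = pd.DataFrame({"const": np.ones(40),
                               "a": rng.normal(size=40),
                               "b": rng.normal(size=40)})
        rep = compute_vif(design, exclude_intercept=True)
        assert list(rep.table["name"]) == ["a", "b"]


class TestPctVarianceExplained:
    def test_vif_one_is_zero(self):
        assert pct_variance_explained(1.0) == 0.0

    def test_rule_of_thumb(self):
        assert pct_variance_explained(5.0) == pytest.approx(80.0)

    def test_below_one_rejected(self):
        with pytest.raises(ValueError):
            pct_variance_explained(0.8)


class TestCorrelationMatrix:
    def test_perfect_linear_pearson(self):
        cm = correlation_matrix(pd.DataFrame({"x": [1.0, 2, 3], "y": [2.0, 4, 6]}))
        assert cm.r("x", "y") == pytest.approx(1.0)

    def test_hand_computed_oracle(self):
        x = np.array([1.0, 4.0, 2.0, 7.0, 5.0, 3.0])
        y = np.array([2.0, 5.0, 1.0, 9.0, 4.0, 6.0])
        cm = correlation_matrix(pd.DataFrame({"x": x, "y": y}), method="pearson")
        r = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
        t = r * np.sqrt(4 / (1 - r**2))
        p = 2 * stats.t.sf(abs(t), 4)
        assert cm.r("x", "y") == pytest.approx(r, abs=1e-12)
        assert cm.p_values.loc["x", "y"] == pytest.approx(p, rel=1e-9)
        assert cm.n_pairs.loc["x", "y"] == 6

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 5000))
    def test_spearman_monotone_invariance(self, seed):
        r = np.random.default_rng(seed)
        x = r.normal(size=40)
        y = r.normal(size=40) + x
        base = correlation_matrix(pd.DataFrame({"x": x, "y": y}), "spearman")
        warped = correlation_matrix(
            pd.DataFrame({"x": np.exp(x), "y": y**3}), "spearman")
        assert warped.r("x", "y") == pytest.approx(base.r("x", "y"), abs=1e-12)

    def test_pairwise_complete_counts(self, rng):
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        x[:5] = np.nan
        cm = correlation_matrix(pd.DataFrame({"x": x, "y": y}))
        assert cm.n_pairs.loc["x", "y"] == 15

    def test_constant_column_warns_and_is_missing(self, rng):
        df = pd.DataFrame({"x": rng.normal(size=10), "c": np.ones(10)})
        with pytest.warns(UserWarning, match="constant"):
            cm = correlation_matrix(df)
        assert np.isnan(cm.r("x", "c"))

    def test_bad_method(self):
        with pytest.raises(ValueError):
            correlation_matrix(pd.DataFrame({"x": [1.0, 2, 3]}), "kendall")


@pytest.fixture(scope="module")
def planted_fixture():
    r = np.random.default_rng(99)
    n = 1000
    gran = r.normal(0.55, 0.09, size=n)
    cd8t = r.normal(0.10, 0.03, size=n)
    # 50 planted CpGs track granulocytes (population Spearman ~0.9);
    # Gaussian copula: Pearson rho = 2*sin(pi*rs/6)
    rho = 2 * np.sin(np.pi * 0.9 / 6)
    z = (gran - gran.mean()) / gran.std()
    planted = rho * z[None, :] + np.sqrt(1 - rho**2) * r.normal(size=(50, n))
    nulls = r.normal(size=(950, n))
    meth = np.vstack([planted, nulls])
    cols = [f"s{i}" for i in range(n)]
    meth_df = pd.DataFrame(meth, index=[f"cg{i:04d}" for i in range(1000)],
                           columns=cols)
    cells = pd.DataFrame({"gran": gran, "cd8t": cd8t}, index=cols)
    return meth_df, cells


class TestScreen:
    def test_planted_count_recovered(self, planted_fixture):
        meth, cells = planted_fixture
        rep = high_correlation_screen(meth, cells, threshold=0.700, top_k=5)
        assert rep.n_cpgs == 1000
        assert 48 <= rep.counts["gran"] <= 52
        assert rep.counts["cd8t"] <= 2  # independent cell type stays null
        assert len(rep.top["gran"]) == 5
        rs = rep.top["gran"]["r_s"].abs().to_numpy()
        assert np.all(np.diff(rs) <= 1e-12)  # sorted by |r_s| descending

    def test_null_screen_flags_nothing(self, rng):
        meth = pd.DataFrame(rng.normal(size=(300, 500)),
                            columns=[f"s{i}" for i in range(500)])
        cells = pd.DataFrame({"gran": rng.normal(size=500)},
                             index=[f"s{i}" for i in range(500)])
        rep = high_correlation_screen(meth, cells, threshold=0.700)
        assert rep.counts["gran"] == 0

    def test_monotone_transform_always_flagged(self, rng):
        gran = rng.normal(0.5, 0.1, size=100)
        meth = pd.DataFrame([np.exp(gran)], index=["cg1"],
                            columns=[f"s{i}" for i in range(100)])
        cells = pd.DataFrame({"gran": gran}, index=meth.columns)
        rep = high_correlation_screen(meth, cells, threshold=0.999)
        assert rep.counts["gran"] == 1
        assert rep.top["gran"]["r_s"].iloc[0] == pytest.approx(1.0)

    def test_counts_monotone_in_threshold(self, planted_fixture):
        meth, cells = planted_fixture
        counts = [high_correlation_screen(meth, cells, threshold=t).counts["gran"]
                  for t in (0.3, 0.5, 0.7, 0.9)]
        assert counts == sorted(counts, reverse=True)

    def test_zero_variance_cell_skipped(self, rng):
        meth = pd.DataFrame(rng.normal(size=(5, 50)),
                            columns=[f"s{i}" for i in range(50)])
        cells = pd.DataFrame({"gran": rng.normal(size=50), "nk": np.full(50, 0.01)},
                             index=meth.columns)
        rep = high_correlation_screen(meth, cells)
        assert rep.skipped_cells == ("nk",)
        assert "nk" not in rep.counts

    def test_no_shared_participants(self, rng):
        meth = pd.DataFrame(rng.normal(size=(5, 10)),
                            columns=[f"a{i}" for i in range(10)])
        cells = pd.DataFrame({"gran": rng.normal(size=10)},
                             index=[f"b{i}" for i in range(10)])
        with pytest.raises(ValueError, match="shared"):
            high_correlation_screen(meth, cells)

    def test_bad_threshold(self, rng):
        meth = pd.DataFrame(rng.normal(size=(2, 10)),
                            columns=[f"s{i}" for i in range(10)])
        cells = pd.DataFrame({"gran": rng.normal(size=10)}, index=meth.columns)
        with pytest.raises(ValueError):
            high_correlation_screen(meth, cells, threshold=1.5)


class TestConditionIndices:
    def test_orthonormal_all_one(self):
        assert np.allclose(condition_indices(_orthogonal_design()), 1.0, atol=1e-10)

    def test_duplicated_column_huge_index(self, rng):
        x = rng.normal(size=50)
        idx = condition_indices(pd.DataFrame({"a": x, "b": x}))
        assert idx[-1] >= 1e6

    def test_svd_oracle(self, rng):
        X = rng.normal(size=(40, 4))
        design = pd.DataFrame(X, columns=list("abcd"))
        Xs = X / np.linalg.norm(X, axis=0)
        eig = np.sqrt(np.sort(np.linalg.eigvalsh(Xs.T @ Xs))[::-1])
        oracle = np.sort(eig.max() / eig)
        assert np.allclose(condition_indices(design), oracle, atol=1e-8)

    def test_zero_column_rejected(self, rng):
        with pytest.raises(ValueError, match="zero"):
            condition_indices(pd.DataFrame({"a": rng.normal(size=10),
                                            "b": np.zeros(10)}))
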