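"""Core PLSC: standardization, SVD decomposition, scores, loadings."""

import numpy as np
import pytest
from scipy import stats as sstats

from strokelink.features import edge_index
from strokelink.plsc import (
    composite_scores,
    destandardize,
    fit_plsc,
    loadings,
    regional_importance,
    top_fraction,
    zscore_columns,
)
from .conftest import make_manual_scheme, power_iteration_top, rank1_data


class TestZscore:
    def test_basic_column(self):
        z, stats = zscore_columns(np.array([[1.0], [2.0], [3.0]]))
        assert np.allclose(z.ravel(), [-1.0, 0.0, 1.0])  # sample-SD convention

    def test_already_standardized_unchanged(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((50, 3))
        x = (x - x.mean(axis=0)) / x.std(axis=0, ddof=1)
        z, _ = zscore_columns(x)
        assert np.abs(z - x).max() < 1e-12

    def test_roundtrip(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((20, 4)) * 7 + 3
        z, stats = zscore_columns(x)
        assert np.allclose(destandardize(z, stats), x)

    def test_constant_column_named(self):
        x = np.column_stack([np.arange(5.0), np.full(5, 2.0)])
        with pytest.raises(ValueError, match="grip_strength"):
            zscore_columns(x, names=["gait", "grip_strength"])


class TestFit:
    def test_rank1_closed_form(self):
        t = np.array([-1.5, -0.5, 0.5, 1.5])
        X = np.column_stack([t, t])
        Y = np.column_stack([t, -t])
        m = fit_plsc(X, Y)
        assert np.allclose(m.singular_values, [2.0, 0.0], atol=1e-12)
        assert np.allclose(m.explained_covariance, [1.0, 0.0], atol=1e-12)
        scores = composite_scores(m, X, Y)
        assert scores.correlation(0) == pytest.approx(1.0)

    def test_top_singular_value_matches_power_iteration(self):
        rng = np.random.default_rng(42)
        for trial in range(5):
            n, p, q = 20, 15, 8
            X = rng.standard_normal((n, p))
            Y = rng.standard_normal((n, q))
            m = fit_plsc(X, Y)
            xz, _ = zscore_columns(X)
            yz, _ = zscore_columns(Y)
            r = yz.T @ xz / (n - 1)
            s_oracle, _, _ = power_iteration_top(r, seed=trial)
            assert m.singular_values[0] == pytest.approx(s_oracle, abs=1e-8)
            assert (m.singular_values ** 2).sum() == pytest.approx(
                np.linalg.norm(r, "fro") ** 2, abs=1e-10)

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((15, 6))
        Y = rng.standard_normal((15, 4))
        perm = rng.permutation(15)
        a = fit_plsc(X, Y)
        b = fit_plsc(X[perm], Y[perm])
        assert np.allclose(a.singular_values, b.singular_values)
        assert np.allclose(a.x_saliences, b.x_saliences)

    def test_column_scale_invariance(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((18, 5))
        Y = rng.standard_normal((18, 3))
        X2 = X.copy()
        X2[:, 2] *= 37.5
        a = fit_plsc(X, Y)
        b = fit_plsc(X2, Y)
        assert np.allclose(a.singular_values, b.singular_values)
        assert np.allclose(a.explained_covariance, b.explained_covariance)

    def test_sign_flip_of_columns_keeps_score_correlations(self):
        rng = np.random.default_rng(5)
        X, Y, *_ = rank1_data(20, 6, 4, seed=5, noise=0.3)
        Xf = X.copy()
        Xf[:, [0, 3]] *= -1
        a = fit_plsc(X, Y)
        b = fit_plsc(Xf, Y)
        sa = composite_scores(a, X, Y)
        sb = composite_scores(b, Xf, Y)
        for k in range(a.n_components):
            assert abs(sa.correlation(k)) == pytest.approx(abs(sb.correlation(k)), abs=1e-10)

    def test_sign_convention_largest_v_entry_positive(self):
        rng = np.random.default_rng(6)
        m = fit_plsc(rng.standard_normal((25, 7)), rng.standard_normal((25, 5)))
        for k in range(m.n_components):
            j = np.argmax(np.abs(m.y_saliences[:, k]))
            assert m.y_saliences[j, k] > 0

    def test_dimension_errors(self):
        rng = np.random.default_rng(7)
        with pytest.raises(ValueError, match="participant mismatch"):
            fit_plsc(rng.standard_normal((10, 3)), rng.standard_normal((9, 2)))


class TestScoresAndLoadings:
    def test_projection_reproduces_fit_scores_bit_identically(self):
        rng = np.random.default_rng(8)
        X = rng.standard_normal((14, 5))
        Y = rng.standard_normal((14, 3))
        m = fit_plsc(X, Y)
        s1 = composite_scores(m, X, Y)
        s2 = composite_scores(m, X, Y)
        assert (s1.x_scores == s2.x_scores).all()
        # self-standardization of the training data equals fit-time stats
        s3 = composite_scores(m, X, Y, standardize="fit")
        assert np.allclose(s1.x_scores, s3.x_scores)

    def test_score_cross_products_match_direct_oracle(self):
        rng = np.random.default_rng(9)
        X = rng.standard_normal((16, 6))
        Y = rng.standard_normal((16, 4))
        m = fit_plsc(X, Y)
        s = composite_scores(m, X, Y)
        xz, _ = zscore_columns(X)
        direct = (xz @ m.x_saliences).T @ (xz @ m.x_saliences)
        assert np.allclose(s.x_scores.T @ s.x_scores, direct, atol=1e-10)

    def test_loading_extremes_and_oracle(self):
        rng = np.random.default_rng(10)
        X, Y, *_ = rank1_data(15, 4, 3, seed=10, noise=0.2)
        m = fit_plsc(X, Y)
        s = composite_scores(m, X, Y)
        # augment X with the score itself and its negation
        X_aug = np.column_stack([X, s.x_scores[:, 0], -s.x_scores[:, 0]])
        l = loadings(composite_scores(m, X, Y), X_aug, Y)
        assert l.x_loadings[-2, 0] == pytest.approx(1.0)
        assert l.x_loadings[-1, 0] == pytest.approx(-1.0)
        for f in range(4):
            r_oracle = sstats.pearsonr(X[:, f], s.x_scores[:, 0]).statistic
            assert l.x_loadings[f, 0] == pytest.approx(r_oracle, abs=1e-12)

    def test_constant_variable_loading_is_nan(self):
        rng = np.random.default_rng(11)
        X = rng.standard_normal((12, 3))
        Y = rng.standard_normal((12, 2))
        m = fit_plsc(X, Y)
        s = composite_scores(m, X, Y)
        X_aug = np.column_stack([X, np.full(12, 3.0)])
        l = loadings(s, X_aug, Y)
        assert np.isnan(l.x_loadings[-1, 0])


class TestRegionalImportance:
    def _scheme(self):
        return make_manual_scheme(
            [[[0, 0, 0]], [[1, 0, 0]], [[5, 0, 0]]],
            ["L", "L", "R"], ["a", "b", "a"], (6, 2, 2))

    def test_example_sums(self):
        # edges in canonical order: (1,2)=0.2, (1,3)=-0.1, (2,3)=0.4
        out = regional_importance(np.array([0.2, -0.1, 0.4]), self._scheme())
        assert np.allclose(out, [0.1, 0.6, 0.3])

    def test_zero_and_double_counting(self):
        scheme = self._scheme()
        assert not regional_importance(np.zeros(3), scheme).any()
        rng = np.random.default_rng(12)
        vals = rng.standard_normal(3)
        assert regional_importance(vals, scheme).sum() == pytest.approx(2 * vals.sum())


class TestTopFraction:
    def test_counts(self):
        rng = np.random.default_rng(13)
        v = rng.standard_normal(10)
        assert top_fraction(v, 0.2).sum() == 2
        assert top_fraction(v, 1.0).all()

    def test_tie_at_cut_prefers_lower_index(self):
        v = np.array([0.5, -0.5, 0.9, 0.1])
        mask = top_fraction(v, 0.5)  # keeps 2: 0.9 plus first of the +/-0.5 tie
        assert mask.sum() == 2
        assert mask[2] and mask[0] and not mask[1]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            top_fraction(np.array([]), 0.2)
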