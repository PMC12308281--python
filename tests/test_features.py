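"""Feature construction: FC matrices, damage, SDC, vectorization, imputation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from strokelink.features import (
    EdgeVector,
    FISHER_CLIP,
    assemble_group_matrix,
    damage_vector,
    drop_zero_features,
    excluded_parcels,
    fc_matrix,
    impute_behaviour,
    matrix_from_upper,
    residualize_confounds,
    sdc_matrix,
    vectorize_upper,
)
from .conftest import lesion_from_voxels, make_manual_scheme, straight_atlas


def _series_with_corr(rho, n=40, seed=1):
    """Two series whose sample Pearson correlation is exactly rho."""
    rng = np.random.default_rng(seed)
    a = rng.standard_normal(n)
    b = rng.standard_normal(n)
    a = (a - a.mean()) / a.std()
    b = b - b.mean()
    b -= (b @ a) / (a @ a) * a  # orthogonalize
    b /= b.std()
    return a, rho * a + np.sqrt(1 - rho ** 2) * b


class TestFCMatrix:
    @pytest.mark.parametrize("rho", [0.5, -0.5])
    def test_fisher_z_matches_atanh_oracle(self, rho):
        x, y = _series_with_corr(rho)
        cm = fc_matrix(np.vstack([x, y]))
        assert cm.values[0, 1] == pytest.approx(np.arctanh(rho), abs=1e-10)
        # atanh(0.5) = 0.5493 to 4 decimals
        assert abs(cm.values[0, 1]) == pytest.approx(0.5493, abs=1e-4)

    def test_identical_series_clipped_finite(self):
        x = np.linspace(0, 1, 20)
        cm = fc_matrix(np.vstack([x, x.copy(), -x]))
        zmax = np.arctanh(1 - FISHER_CLIP)
        assert cm.values[0, 1] == pytest.approx(zmax)
        assert cm.values[0, 2] == pytest.approx(-zmax)
        assert np.isfinite(cm.values[~cm.missing_mask]).all()

    def test_symmetry_and_missing_diagonal(self):
        rng = np.random.default_rng(0)
        cm = fc_matrix(rng.standard_normal((5, 30)))
        assert np.allclose(cm.values[~cm.missing_mask],
                           cm.values.T[~cm.missing_mask.T])
        assert cm.missing_mask.diagonal().all()

    def test_excluded_parcel_rows_flagged(self):
        rng = np.random.default_rng(1)
        cm = fc_matrix(rng.standard_normal((4, 30)), excluded={2})
        assert cm.missing_mask[1, :].all() and cm.missing_mask[:, 1].all()
        assert not cm.missing_mask[0, 2]

    def test_constant_series_error_names_parcel(self):
        series = np.vstack([np.ones(10), np.arange(10.0)])
        with pytest.raises(ValueError, match="parcel 1"):
            fc_matrix(series)

    def test_too_few_timepoints(self):
        with pytest.raises(ValueError, match="time points"):
            fc_matrix(np.random.default_rng(0).standard_normal((3, 2)))


class TestDamageAndExclusion:
    def test_damage_fractions(self):
        scheme = make_manual_scheme(
            [[[0, 0, 0], [0, 0, 1], [0, 0, 2], [0, 0, 3],
              [0, 1, 0], [0, 1, 1], [0, 1, 2], [0, 1, 3],
              [0, 2, 0], [0, 2, 1]],
             [[3, 0, 0], [3, 0, 1]],
             [[7, 0, 0]]],
            ["L", "L", "R"], ["a", "b", "a"], (8, 4, 4))
        lesion = lesion_from_voxels(
            [[0, 0, 0], [0, 0, 1], [0, 0, 2], [3, 0, 0], [3, 0, 1], [7, 0, 0]],
            (8, 4, 4))
        dmg = damage_vector(lesion, scheme)
        assert dmg[0] == pytest.approx(30.0)   # 3 of 10 voxels
        assert dmg[1] == pytest.approx(100.0)  # lesion covers the parcel
        assert dmg[2] == pytest.approx(100.0)
        lesion2 = lesion_from_voxels([[5, 3, 3]], (8, 4, 4))
        assert damage_vector(lesion2, scheme).max() == 0.0  # disjoint

    def test_exclusion_rule_is_strictly_greater(self):
        dmg = np.array([50.0, 50.1, 0.0, 100.0])
        assert excluded_parcels(dmg) == {2, 4}
        assert excluded_parcels(np.zeros(5)) == set()


class TestSDC:
    def test_half_disrupted_pair(self, three_parcel_scheme):
        atlas = straight_atlas(three_parcel_scheme, {(1, 3): 4})
        # lesion on 2 of the 4 identical-geometry streamlines: duplicate lines
        # share geometry, so instead use two pairs with distinct paths
        lines = atlas.streamlines
        lines[0][:, 1] += 2.0  # push two streamlines onto a different row
        lines[1][:, 1] += 2.0
        lesion = lesion_from_voxels([[4, 2, 0], [4, 3, 0]], (8, 4, 4))
        sdc = sdc_matrix(lesion, atlas, three_parcel_scheme)
        assert sdc[0, 2] == pytest.approx(0.5)
        assert sdc[2, 0] == pytest.approx(0.5)
        assert sdc[0, 1] == 0.0

    def test_untouched_lesion_gives_zero_matrix(self, three_parcel_scheme):
        atlas = straight_atlas(three_parcel_scheme, {(1, 2): 3, (1, 3): 2})
        lesion = lesion_from_voxels([[4, 3, 3]], (8, 4, 4))
        assert not sdc_matrix(lesion, atlas, three_parcel_scheme).any()

    def test_matches_vertex_walk_oracle(self, three_parcel_scheme):
        rng = np.random.default_rng(7)
        atlas = straight_atlas(three_parcel_scheme, {(1, 2): 3, (1, 3): 5, (2, 3): 2})
        for line in atlas.streamlines:  # wiggle so paths differ
            line += rng.normal(0, 0.4, size=line.shape)
            np.clip(line, 0, np.array([7, 3, 3]), out=line)
        lesion_vox = [tuple(v) for v in rng.integers(0, (8, 4, 4), size=(9, 3))]
        lesion = lesion_from_voxels(lesion_vox, (8, 4, 4))

        # oracle: per-streamline voxel walk, dict-of-pairs counting
        hit_set = set(lesion_vox)
        totals, broken = {}, {}
        for line, (a, b) in zip(atlas.streamlines, atlas.endpoints):
            key = (min(a, b), max(a, b))
            totals[key] = totals.get(key, 0) + 1
            vox = {tuple(np.clip(np.rint(p).astype(int), 0, (7, 3, 3))) for p in line}
            if vox & hit_set:
                broken[key] = broken.get(key, 0) + 1
        sdc = sdc_matrix(lesion, atlas, three_parcel_scheme)
        for (a, b), tot in totals.items():
            assert sdc[a - 1, b - 1] == pytest.approx(broken.get((a, b), 0) / tot)

    def test_monotone_under_lesion_growth(self, three_parcel_scheme):
        rng = np.random.default_rng(11)
        atlas = straight_atlas(three_parcel_scheme, {(1, 2): 4, (1, 3): 4, (2, 3): 4})
        for line in atlas.streamlines:
            line += rng.normal(0, 0.5, size=line.shape)
            np.clip(line, 0, np.array([7, 3, 3]), out=line)
        for trial in range(20):
            small_vox = rng.integers(0, (8, 4, 4), size=(4, 3))
            extra_vox = rng.integers(0, (8, 4, 4), size=(6, 3))
            small = lesion_from_voxels(small_vox, (8, 4, 4))
            big = lesion_from_voxels(np.vstack([small_vox, extra_vox]), (8, 4, 4))
            s_small = sdc_matrix(small, atlas, three_parcel_scheme)
            s_big = sdc_matrix(big, atlas, three_parcel_scheme)
            assert (s_big >= s_small - 1e-12).all()

    def test_vertex_order_reversal_invariance(self, three_parcel_scheme):
        atlas = straight_atlas(three_parcel_scheme, {(1, 2): 2, (1, 3): 3})
        lesion = lesion_from_voxels([[0, 1, 1], [2, 1, 1]], (8, 4, 4))
        fwd = sdc_matrix(lesion, atlas, three_parcel_scheme)
        rev = straight_atlas(three_parcel_scheme, {})
        rev.streamlines = [l[::-1].copy() for l in atlas.streamlines]
        rev.endpoints = atlas.endpoints.copy()
        assert np.allclose(fwd, sdc_matrix(lesion, rev, three_parcel_scheme))


class TestVectorize:
    def test_three_by_three_order(self):
        m = np.array([[0.0, 1.0, 2.0], [1.0, 0.0, 3.0], [2.0, 3.0, 0.0]])
        ev = vectorize_upper(m)
        assert np.allclose(ev.values, [1.0, 2.0, 3.0])

    def test_full_parcellation_edge_count(self):
        rng = np.random.default_rng(0)
        a = rng.standard_normal((333, 333))
        assert vectorize_upper((a + a.T) / 2).values.shape == (55278,)

    @given(st.integers(min_value=2, max_value=12), st.integers(min_value=0, max_value=2 ** 31))
    @settings(max_examples=25, deadline=None)
    def test_roundtrip_property(self, p, seed):
        rng = np.random.default_rng(seed)
        a = rng.standard_normal((p, p))
        sym = (a + a.T) / 2
        np.fill_diagonal(sym, 0.0)
        back = matrix_from_upper(vectorize_upper(sym), p)
        assert np.allclose(back, sym)

    def test_asymmetric_rejected(self):
        m = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValueError, match="asymmetric"):
            vectorize_upper(m)


class TestGroupAssembly:
    def test_stack_without_missingness(self):
        vecs = [EdgeVector(values=np.array([1.0, 2.0]), missing_mask=np.zeros(2, bool)),
                EdgeVector(values=np.array([3.0, 4.0]), missing_mask=np.zeros(2, bool))]
        mat, kept, dropped = assemble_group_matrix(vecs)
        assert np.allclose(mat, [[1, 2], [3, 4]])
        assert dropped.size == 0

    def test_missing_cell_gets_observed_mean(self):
        vecs = [EdgeVector(np.array([1.0, 5.0]), np.array([False, False])),
                EdgeVector(np.array([3.0, 99.0]), np.array([False, True])),
                EdgeVector(np.array([5.0, 7.0]), np.array([False, False]))]
        mat, _, _ = assemble_group_matrix(vecs)
        assert mat[1, 1] == pytest.approx(6.0)
        # imputation preserves observed-cell column means exactly
        assert mat[:, 1].mean() == pytest.approx(6.0)

    def test_fully_missing_edge_dropped_and_logged(self):
        vecs = [EdgeVector(np.array([1.0, 0.0]), np.array([False, True])),
                EdgeVector(np.array([2.0, 0.0]), np.array([False, True]))]
        mat, kept, dropped = assemble_group_matrix(vecs)
        assert mat.shape == (2, 1)
        assert list(kept) == [0] and list(dropped) == [1]


class TestTables:
    def test_mean_imputation(self):
        t = pd.DataFrame({"a": [1.0, np.nan, 3.0], "b": [1.0, 2.0, 3.0]})
        out = impute_behaviour(t)
        assert out["a"].tolist() == [1.0, 2.0, 3.0]
        assert out["b"].equals(t["b"])

    def test_fully_missing_column_errors(self):
        with pytest.raises(ValueError, match="no observed value"):
            impute_behaviour(pd.DataFrame({"a": [np.nan, np.nan]}))

    def test_drop_zero_features(self):
        m = np.array([[1.0, 0.0, 2.0], [3.0, 0.0, 4.0]])
        out, kept = drop_zero_features(m)
        assert out.shape == (2, 2) and list(kept) == [0, 2]
        with pytest.raises(ValueError):
            drop_zero_features(np.zeros((3, 2)))


class TestResidualize:
    def test_self_confound_annihilates(self):
        rng = np.random.default_rng(3)
        col = rng.standard_normal(30)
        out = residualize_confounds(col[:, None], col)
        assert np.abs(out).max() < 1e-10

    def test_residuals_orthogonal_to_confounds(self):
        rng = np.random.default_rng(4)
        m = rng.standard_normal((40, 5))
        conf = rng.standard_normal((40, 2))
        out = residualize_confounds(m, conf)
        for j in range(2):
            assert np.abs(out.T @ (conf[:, j] - conf[:, j].mean())).max() < 1e-8
        assert np.abs(out.mean(axis=0)).max() < 1e-12

    def test_rank_deficient_confounds_rejected(self):
        rng = np.random.default_rng(5)
        c = rng.standard_normal(20)
        with pytest.raises(ValueError, match="rank-deficient"):
            residualize_confounds(rng.standard_normal((20, 3)),
                                  np.column_stack([c, 2 * c]))
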