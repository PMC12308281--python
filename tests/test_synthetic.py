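"""Synthetic cohort generator: geometry, determinism, calibration."""

import dataclasses

import numpy as np
import pytest

from strokelink.synthetic import (
    SyntheticConfig,
    generate_cohort,
    make_parcel_scheme,
    make_streamline_atlas,
    read_cohort,
    sample_lesions,
    write_cohort,
)


class TestParcelScheme:
    def test_one_parcel_per_network(self):
        scheme = make_parcel_scheme(13, 13, (24, 12, 12))
        assert scheme.n_parcels == 26
        for hemi in ("L", "R"):
            nets = scheme.network[scheme.hemisphere == hemi]
            assert len(set(nets)) == 13 and len(nets) == 13

    def test_balanced_networks(self):
        scheme = make_parcel_scheme(20, 4, (24, 12, 12))
        for hemi in ("L", "R"):
            nets = scheme.network[scheme.hemisphere == hemi]
            _, counts = np.unique(nets, return_counts=True)
            assert (counts == 5).all()

    def test_no_parcel_spans_hemispheres(self):
        scheme = make_parcel_scheme(8, 4, (16, 10, 10))
        for hemi, vox in zip(scheme.hemisphere, scheme.voxel_members):
            if hemi == "L":
                assert (vox[:, 0] < 8).all()
            else:
                assert (vox[:, 0] >= 8).all()

    def test_mirror_symmetry(self):
        scheme = make_parcel_scheme(6, 3, (12, 8, 8))
        left = [set(map(tuple, v)) for v, h in
                zip(scheme.voxel_members, scheme.hemisphere) if h == "L"]
        right = [set(map(tuple, v)) for v, h in
                 zip(scheme.voxel_members, scheme.hemisphere) if h == "R"]
        for lv, rv in zip(left, right):
            mirrored = {(11 - x, y, z) for x, y, z in lv}
            assert mirrored == rv

    def test_voxels_disjoint_and_cortical(self):
        scheme = make_parcel_scheme(9, 3, (18, 9, 8), cortex_fraction=0.5)
        scheme.validate()  # raises on overlap
        for vox in scheme.voxel_members:
            assert (vox[:, 2] >= 4).all()  # white matter left free below

    def test_grid_too_small(self):
        with pytest.raises(ValueError, match="too small"):
            make_parcel_scheme(100, 100, (4, 2, 2))


class TestAtlas:
    def test_streamline_count(self):
        scheme = make_parcel_scheme(2, 2, (8, 6, 6), cortex_fraction=1.0)
        # 3 parcels is awkward with mirror symmetry; 4 parcels -> 6 pairs
        atlas = make_streamline_atlas(scheme, streamlines_per_pair=4, seed=0)
        assert atlas.n_streamlines == 6 * 4

    def test_wobble_zero_is_straight_centroid_to_centroid(self):
        scheme = make_parcel_scheme(2, 1, (8, 6, 6), cortex_fraction=1.0)
        atlas = make_streamline_atlas(scheme, streamlines_per_pair=1, wobble=0.0, seed=1)
        for line, (a, b) in zip(atlas.streamlines, atlas.endpoints):
            start, end = line[0], line[-1]
            assert np.allclose(start, scheme.centroids[a - 1])
            assert np.allclose(end, scheme.centroids[b - 1])
            # collinearity: every vertex on the segment
            d = end - start
            for v in line:
                cross = np.cross(v - start, d)
                assert np.linalg.norm(cross) < 1e-9

    def test_same_seed_bit_identical(self):
        scheme = make_parcel_scheme(4, 2, (12, 8, 8))
        a = make_streamline_atlas(scheme, 3, wobble=0.7, seed=5, route_depth=True)
        b = make_streamline_atlas(scheme, 3, wobble=0.7, seed=5, route_depth=True)
        assert all((x == y).all() for x, y in zip(a.streamlines, b.streamlines))

    def test_vertex_spacing_and_endpoints_valid(self):
        scheme = make_parcel_scheme(4, 2, (12, 8, 8))
        atlas = make_streamline_atlas(scheme, 2, wobble=0.8, seed=2, route_depth=True)
        atlas.validate(scheme)  # spacing <= 1 voxel, endpoint ids in scheme


class TestLesions:
    def test_unit_radius_ball(self):
        scheme = make_parcel_scheme(2, 2, (12, 8, 8))
        cfg = SyntheticConfig(n_participants=5, lesion_radius_range=(1.0, 1.0),
                              grid_dims=(12, 8, 8))
        masks, _ = sample_lesions(scheme, cfg, seed=0)
        for m in masks:
            # radius-1 ball: center voxel plus at most 6 face neighbours
            assert 1 <= m.n_voxels <= 7

    def test_unilateral_over_many_seeds(self):
        scheme = make_parcel_scheme(2, 2, (12, 8, 8))
        cfg = SyntheticConfig(n_participants=2, lesion_radius_range=(1.0, 2.0),
                              grid_dims=(12, 8, 8))
        for seed in range(50):
            masks, _ = sample_lesions(scheme, cfg, seed=seed)
            for m in masks:
                left = m.grid[:6].any()
                right = m.grid[6:].any()
                assert left != right  # exactly one hemisphere touched

    def test_severity_zero_without_streamline_hits(self):
        scheme = make_parcel_scheme(2, 2, (12, 8, 8))
        cfg = SyntheticConfig(n_participants=3, lesion_radius_range=(1.0, 1.0),
                              grid_dims=(12, 8, 8))
        _, sev = sample_lesions(scheme, cfg, seed=1, atlas=None)
        assert (sev == 0).all()

    def test_radius_exceeding_hemisphere_rejected(self):
        scheme = make_parcel_scheme(2, 2, (12, 8, 8))
        cfg = SyntheticConfig(n_participants=2, lesion_radius_range=(1.0, 50.0),
                              grid_dims=(12, 8, 8))
        with pytest.raises(ValueError, match="radius"):
            sample_lesions(scheme, cfg, seed=0)


class TestCohort:
    def _small(self, seed=0, **kw):
        base = dict(n_participants=25, n_parcels_per_hemisphere=4,
                    n_networks_per_hemisphere=4, n_behaviour_measures=10,
                    n_domains=5, seed=seed)
        base.update(kw)
        return SyntheticConfig(**base)

    def test_same_config_same_cohort(self):
        a = generate_cohort(self._small())
        b = generate_cohort(self._small())
        assert (np.asarray(a.fc_edges) == np.asarray(b.fc_edges)).all()
        assert a.behaviour.equals(b.behaviour)
        assert (a.truth.latent_scores == b.truth.latent_scores).all()
        assert all((x.grid == y.grid).all() for x, y in zip(a.lesions, b.lesions))

    def test_planted_salience_structure(self):
        c = generate_cohort(self._small())
        u = c.truth.planted_x_salience
        assert np.linalg.norm(u) == pytest.approx(1.0)
        assert np.linalg.norm(c.truth.planted_y_salience) == pytest.approx(1.0)
        from strokelink.features import edge_index
        ii, jj = edge_index(c.scheme.n_parcels)
        hemi = c.scheme.hemisphere
        inter = hemi[ii] != hemi[jj]
        # opposite signs: interhemispheric support negative, intra positive
        assert u[inter & (u != 0)].max() < 0
        assert u[~inter & (u != 0)].min() > 0

    def test_composite_correlation_calibrated(self):
        """Monte-Carlo check of the gain calibration at large n."""
        cfg = self._small(seed=21, n_participants=500, noise_sd_x=0.05,
                          noise_sd_y=0.05, missing_rate=0.0)
        c = generate_cohort(cfg)
        x = np.asarray(c.fc_edges) @ c.truth.planted_x_salience
        y = c.behaviour.to_numpy() @ c.truth.planted_y_salience
        assert np.corrcoef(x, y)[0, 1] == pytest.approx(0.7, abs=0.05)

    def test_missingness_applied_but_columns_observable(self):
        cfg = self._small(seed=3, missing_rate=0.2)
        c = generate_cohort(cfg)
        frac = c.behaviour.isna().to_numpy().mean()
        assert 0.1 < frac < 0.3
        assert (c.behaviour.notna().sum(axis=0) >= 1).all()

    def test_degenerate_config_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            SyntheticConfig(latent_effect=0.0, noise_sd_x=0.0).validate()

    def test_shared_truth_cohorts_share_saliences_only(self):
        cfg = self._small(seed=4)
        a = generate_cohort(cfg)
        b = generate_cohort(cfg, truth=a.truth, participant_seed=cfg.seed + 999)
        assert (a.truth.planted_x_salience == b.truth.planted_x_salience).all()
        assert not np.allclose(np.asarray(a.fc_edges), np.asarray(b.fc_edges))

    def test_write_read_roundtrip(self, tmp_path):
        cfg = self._small(seed=5, n_participants=6)
        c = generate_cohort(cfg)
        write_cohort(c, tmp_path / "cohort")
        back = read_cohort(tmp_path / "cohort")
        assert np.allclose(np.asarray(back.fc_edges), np.asarray(c.fc_edges))
        assert back.behaviour.shape == c.behaviour.shape
        assert np.allclose(back.truth.planted_y_salience, c.truth.planted_y_salience)
        assert len(back.lesions) == 6
        assert (back.lesions[0].grid == c.lesions[0].grid).all()
        assert back.atlas.n_streamlines == c.atlas.n_streamlines
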