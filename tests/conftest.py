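"""Shared fixtures and oracle helpers."""

from __future__ import annotations

import numpy as np
import pytest

from strokelink.features import LesionMask, ParcelScheme, StreamlineAtlas
from strokelink.synthetic import SyntheticConfig


def rank1_data(n=12, p=3, q=2, seed=0, noise=0.0):
    """Noise-free (or noisy) rank-1 paired blocks driven by one latent t."""
    rng = np.random.default_rng(seed)
    t = rng.standard_normal(n)
    t = (t - t.mean()) / t.std(ddof=1)
    u = rng.standard_normal(p)
    u /= np.linalg.norm(u)
    v = rng.standard_normal(q)
    v /= np.linalg.norm(v)
    X = np.outer(t, u) + noise * rng.standard_normal((n, p))
    Y = np.outer(t, v) + noise * rng.standard_normal((n, q))
    return X, Y, t, u, v


def power_iteration_top(r, n_iter=5000, tol=1e-14, seed=0):
    """Independent oracle: max over unit u, v of v' R u by power iteration."""
    rng = np.random.default_rng(seed)
    u = rng.standard_normal(r.shape[1])
    u /= np.linalg.norm(u)
    s_prev = 0.0
    for _ in range(n_iter):
        v = r @ u
        v /= np.linalg.norm(v)
        u = r.T @ v
        s = np.linalg.norm(u)
        u /= s
        if abs(s - s_prev) < tol:
            break
        s_prev = s
    return float(v @ r @ u), u, v


def make_manual_scheme(voxels_per_parcel, hemis, networks, grid_dims):
    """Build a ParcelScheme directly from explicit voxel lists."""
    members = [np.asarray(v, dtype=int) for v in voxels_per_parcel]
    return ParcelScheme(
        hemisphere=np.asarray(hemis),
        network=np.asarray(networks),
        voxel_members=members,
        centroids=np.array([m.mean(axis=0) for m in members], dtype=float),
        grid_dims=tuple(grid_dims),
    )


@pytest.fixture
def three_parcel_scheme():
    """3 parcels on an 8x4x4 grid (2 left, 1 right), for SDC fixtures."""
    return make_manual_scheme(
        voxels_per_parcel=[
            [[0, 0, 0], [0, 1, 0], [1, 0, 0], [1, 1, 0]],
            [[0, 3, 3], [1, 3, 3]],
            [[7, 0, 0], [7, 1, 0], [6, 0, 0]],
        ],
        hemis=["L", "L", "R"],
        networks=["netA", "netB", "netA"],
        grid_dims=(8, 4, 4),
    )


def straight_atlas(scheme, counts):
    """Hand-built atlas: ``counts[(i, j)]`` straight streamlines per pair."""
    lines, pairs = [], []
    for (i, j), c in counts.items():
        a = scheme.centroids[i - 1]
        b = scheme.centroids[j - 1]
        n_seg = max(1, int(np.ceil(np.linalg.norm(b - a))))
        base = np.linspace(a, b, n_seg + 1)
        for _ in range(c):
            lines.append(base.copy())
            pairs.append((i, j))
    return StreamlineAtlas(streamlines=lines, endpoints=np.asarray(pairs, dtype=int))


def lesion_from_voxels(voxels, grid_dims):
    grid = np.zeros(grid_dims, dtype=bool)
    for v in voxels:
        grid[tuple(v)] = True
    return LesionMask(grid=grid)


def recovery_config(seed, n=100, latent_effect=0.7):
    """Desk-scale parameter-recovery study conditions (see docs/methods.md)."""
    return SyntheticConfig(
        n_participants=n,
        n_parcels_per_hemisphere=4,
        n_networks_per_hemisphere=4,
        n_behaviour_measures=20,
        n_domains=5,
        latent_effect=latent_effect,
        seed=seed,
    )
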