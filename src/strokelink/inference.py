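"""Resampling inference for PLSC components.

Resampled decompositions are only identified up to per-component sign,
order, and (for near-equal singular values) rotation.  Before comparing a
permuted or bootstrapped fit to the original solution, its components are
therefore Procrustes-rotated onto the reference: with N = V_ref' V_target
and SVD N = P diag(d) Q', the orthogonal rotation Q P' maps the target's
component basis onto the reference's.  Aligned singular values are read off
as column norms of the rotated, singular-value-weighted saliences.

Component significance comes from a permutation test (rows of Y shuffled,
exceedance counting with +1 smoothing, BH-FDR across components); loading
stability from participant-level bootstrap (z = loading / bootstrap SD,
with FC edge loadings averaged within network-pair blocks before inference
to limit multiple comparisons).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats
from statsmodels.stats.multitest import multipletests

from .features import ParcelScheme, edge_index
from .plsc import (
    CompositeScores,
    LatentModel,
    _corr_columns,
    _cross_block,
    _svd_components,
    _zscore_safe,
    fit_plsc,
    loadings,
)

__all__ = [
    "ProcrustesAlignment",
    "PermutationReport",
    "BootstrapReport",
    "procrustes_align",
    "permutation_test",
    "bootstrap_loadings",
    "bh_fdr",
]


@dataclass
class ProcrustesAlignment:
    rotation: np.ndarray
    aligned_singular_values: np.ndarray


@dataclass
class PermutationReport:
    null_singular_values: np.ndarray  # (n_perm, k)
    p_values: np.ndarray
    q_values: np.ndarray
    n_permutations: int
    seed: int


@dataclass
class BootstrapReport:
    """Bootstrap dispersion of loadings.

    X-side inference is at the network-block level by default: per bootstrap
    draw the edge loadings are averaged within and between hemisphere-
    qualified network blocks *before* the SD is taken.  ``x_labels`` names
    each X-side unit (block pair, or edge in edge-level mode).
    """

    x_mean_loading: np.ndarray        # (n_units, k) observed (block) loadings
    x_loading_sd: np.ndarray
    x_z: np.ndarray
    x_p: np.ndarray
    x_q: np.ndarray
    x_labels: list
    y_loading_sd: np.ndarray          # (q, k)
    y_z: np.ndarray
    y_p: np.ndarray
    y_q: np.ndarray
    n_bootstraps: int
    seed: int
    n_redrawn: int
    block_index: np.ndarray | None = None   # per-edge unit index (block mode)
    block_names: list | None = None         # block (hemi:network) names

    def block_matrix(self, component: int = 0, stat: str = "mean") -> np.ndarray:
        """Square block x block matrix of a chosen statistic for one LC."""
        if self.block_names is None:
            raise ValueError("block matrix only available in block-level mode")
        b = len(self.block_names)
        source = {"mean": self.x_mean_loading, "z": self.x_z,
                  "p": self.x_p, "q": self.x_q}[stat]
        out = np.full((b, b), np.nan)
        pos = 0
        for i in range(b):
            for j in range(i, b):
                out[i, j] = out[j, i] = source[pos, component]
                pos += 1
        return out


# ---------------------------------------------------------------------------
# Procrustes rotation
# ---------------------------------------------------------------------------


def _rotation_to(reference: np.ndarray, target: np.ndarray) -> np.ndarray:
    n = reference.T @ target
    p, _, qt = np.linalg.svd(n)
    return qt.T @ p.T


def _aligned_values(saliences: np.ndarray, singular_values: np.ndarray,
                    rotation: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    weighted = (saliences * singular_values) @ rotation
    norms = np.linalg.norm(weighted, axis=0)
    safe = np.where(norms == 0, 1.0, norms)
    return weighted / safe, norms


def procrustes_align(reference: LatentModel, target: LatentModel,
                     block: str = "y") -> tuple[ProcrustesAlignment, LatentModel]:
    """Rotate a target model's components onto a reference model's.

    The rotation is estimated from the Y-salience (behaviour) block by
    default — the smaller, numerically better-conditioned block — and then
    applied to both blocks.  Aligned singular values are the column norms of
    the rotated singular-value-weighted Y-saliences.
    """
    if reference.y_saliences.shape != target.y_saliences.shape:
        raise ValueError("Y-salience dimensions differ between models")
    if reference.x_saliences.shape != target.x_saliences.shape:
        raise ValueError("X-salience dimensions differ between models")
    if block == "y":
        rot = _rotation_to(reference.y_saliences, target.y_saliences)
    elif block == "x":
        rot = _rotation_to(reference.x_saliences, target.x_saliences)
    else:
        raise ValueError("block must be 'x' or 'y'")
    v_al, s_al = _aligned_values(target.y_saliences, target.singular_values, rot)
    u_al, _ = _aligned_values(target.x_saliences, target.singular_values, rot)
    total = float((s_al ** 2).sum())
    aligned = LatentModel(
        x_saliences=u_al,
        y_saliences=v_al,
        singular_values=s_al,
        explained_covariance=s_al ** 2 / total if total > 0 else np.zeros_like(s_al),
        x_stats=target.x_stats,
        y_stats=target.y_stats,
        sign_flips=target.sign_flips,
        n_fit=target.n_fit,
        scale_mode=target.scale_mode,
        feature_names=target.feature_names,
        measure_names=target.measure_names,
    )
    return ProcrustesAlignment(rotation=rot, aligned_singular_values=s_al), aligned


def _aligned_null_values(v_ref: np.ndarray, v_perm: np.ndarray, s_perm: np.ndarray) -> np.ndarray:
    """Fast path: aligned singular values without building a LatentModel."""
    rot = _rotation_to(v_ref, v_perm)
    return np.linalg.norm((v_perm * s_perm) @ rot, axis=0)


# ---------------------------------------------------------------------------
# permutation test
# ---------------------------------------------------------------------------


def permutation_test(X: np.ndarray, Y: np.ndarray, n_perm: int = 1000,
                     seed: int = 0, scale_mode: str = "correlation",
                     model: LatentModel | None = None,
                     align: bool = False) -> PermutationReport:
    """Component significance by shuffling Y rows against a fixed X.

    The p-value for component k is ``(1 + #{null_k >= s_k}) / (1 + n_perm)``
    with q-values by Benjamini-Hochberg across components.

    By default the null for component k is the k-th (sorted) singular value
    of each permuted refit — the classical behavioural-PLS test.  The
    ``align=True`` variant instead Procrustes-aligns every permuted refit to
    the observed solution and records aligned singular values; aligning null
    components to an observed reference that is itself noise spreads the
    null covariance across components and makes the exceedance test grossly
    anticonservative at desk-scale dimensions (empirical null rejection far
    above the nominal level), so alignment is reserved for the bootstrap,
    where sign/order coherence is what matters, and is off by default here.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    n = X.shape[0]
    if n < 5:
        raise ValueError("need at least 5 participants for a permutation test")
    if model is None:
        model = fit_plsc(X, Y, scale_mode=scale_mode)
    scale = scale_mode == "correlation"
    xz = _zscore_safe(X, scale=scale)
    yz = _zscore_safe(Y, scale=scale)
    v_ref = model.y_saliences
    k = model.n_components

    rng = np.random.default_rng(seed)
    null = np.empty((n_perm, k))
    for b in range(n_perm):
        perm = rng.permutation(n)
        # z-scores are permutation-equivariant: shuffling standardized rows
        # equals standardizing shuffled rows
        r = _cross_block(xz, yz[perm])
        _, s_p, v_p = _svd_components(r)
        if align:
            null[b] = _aligned_null_values(v_ref, v_p, s_p)
        else:
            null[b] = s_p

    s_obs = model.singular_values
    p = (1.0 + (null >= s_obs[None, :]).sum(axis=0)) / (1.0 + n_perm)
    q = bh_fdr(p)
    return PermutationReport(null_singular_values=null, p_values=p, q_values=q,
                             n_permutations=n_perm, seed=seed)


# ---------------------------------------------------------------------------
# bootstrap loading stability
# ---------------------------------------------------------------------------


def _edge_block_structure(scheme: ParcelScheme) -> tuple[np.ndarray, list, list]:
    """Map canonical edges to unordered network-block pairs.

    Returns (per-edge unit index, unit labels, block names).  Units are the
    upper triangle (including diagonal) of the block x block grid.
    """
    labels = scheme.block_labels()
    block_names = list(dict.fromkeys(labels))  # first-appearance order
    block_of = np.array([block_names.index(l) for l in labels])
    nb = len(block_names)
    pair_to_unit = {}
    unit_labels = []
    for i in range(nb):
        for j in range(i, nb):
            pair_to_unit[(i, j)] = len(unit_labels)
            unit_labels.append(f"{block_names[i]}|{block_names[j]}")
    ii, jj = edge_index(scheme.n_parcels)
    bi = block_of[ii]
    bj = block_of[jj]
    lo = np.minimum(bi, bj)
    hi = np.maximum(bi, bj)
    unit_idx = np.array([pair_to_unit[(a, b)] for a, b in zip(lo, hi)])
    return unit_idx, unit_labels, block_names


def _block_average(edge_vals: np.ndarray, unit_idx: np.ndarray, n_units: int) -> np.ndarray:
    """Average edge x component values within units, NaN-aware."""
    k = edge_vals.shape[1]
    sums = np.zeros((n_units, k))
    counts = np.zeros((n_units, k))
    finite = np.isfinite(edge_vals)
    vals = np.where(finite, edge_vals, 0.0)
    for c in range(k):
        np.add.at(sums[:, c], unit_idx, vals[:, c])
        np.add.at(counts[:, c], unit_idx, finite[:, c].astype(float))
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(counts > 0, sums / np.where(counts > 0, counts, 1.0), np.nan)


def bootstrap_loadings(X: np.ndarray, Y: np.ndarray, n_boot: int = 1000,
                       seed: int = 0, scheme: ParcelScheme | None = None,
                       scale_mode: str = "correlation",
                       model: LatentModel | None = None,
                       sd_floor: float = 1e-12) -> BootstrapReport:
    """Bootstrap SDs and z-scores for PLSC loadings.

    Participants are resampled with replacement; each refit is Procrustes-
    aligned to the observed model and loadings are recomputed within the
    bootstrap sample.  When a ``scheme`` is given, X-side (edge) loadings
    are averaged within and between hemisphere-qualified network blocks
    before dispersion summaries; without a scheme, inference is per edge.
    Draws with fewer than 3 distinct participants are redrawn (counted).
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    n = X.shape[0]
    if n < 10:
        raise ValueError("need at least 10 participants for bootstrap inference")
    if model is None:
        model = fit_plsc(X, Y, scale_mode=scale_mode)
    k = model.n_components
    scale = scale_mode == "correlation"

    if scheme is not None:
        unit_idx, unit_labels, block_names = _edge_block_structure(scheme)
        n_units = len(unit_labels)
    else:
        n_units = X.shape[1]
        unit_idx = None
        unit_labels = [f"edge{i}" for i in range(n_units)]
        block_names = None

    # observed loadings (and their block averages) are the z-score numerators
    obs_scores = CompositeScores(
        x_scores=_zscore_safe(X, scale=scale) @ model.x_saliences,
        y_scores=_zscore_safe(Y, scale=scale) @ model.y_saliences,
    )
    obs = loadings(obs_scores, X, Y)
    if unit_idx is not None:
        x_obs_units = _block_average(obs.x_loadings, unit_idx, n_units)
    else:
        x_obs_units = obs.x_loadings

    rng = np.random.default_rng(seed)
    x_draws = np.empty((n_boot, n_units, k))
    y_draws = np.empty((n_boot, Y.shape[1], k))
    n_redrawn = 0
    for b in range(n_boot):
        while True:
            idx = rng.integers(0, n, n)
            if np.unique(idx).size >= 3:
                break
            n_redrawn += 1
        xb = X[idx]
        yb = Y[idx]
        xbz = _zscore_safe(xb, scale=scale)
        ybz = _zscore_safe(yb, scale=scale)
        r = _cross_block(xbz, ybz)
        u_b, s_b, v_b = _svd_components(r)
        rot = _rotation_to(model.y_saliences, v_b)
        v_al, _ = _aligned_values(v_b, s_b, rot)
        u_al, _ = _aligned_values(u_b, s_b, rot)
        x_load = _corr_columns(xb, xbz @ u_al)
        y_load = _corr_columns(yb, ybz @ v_al)
        if unit_idx is not None:
            x_load = _block_average(x_load, unit_idx, n_units)
        x_draws[b] = x_load
        y_draws[b] = y_load

    import warnings

    with warnings.catch_warnings():
        # blocks with no edges (e.g. within-block pairs of singleton networks)
        # are all-NaN across draws; their SD is legitimately NaN
        warnings.filterwarnings("ignore", message="Degrees of freedom")
        x_sd = np.nanstd(x_draws, axis=0, ddof=1)
        y_sd = np.nanstd(y_draws, axis=0, ddof=1)
    x_z = x_obs_units / np.maximum(x_sd, sd_floor)
    y_z = obs.y_loadings / np.maximum(y_sd, sd_floor)
    x_p = 2.0 * sstats.norm.sf(np.abs(x_z))
    y_p = 2.0 * sstats.norm.sf(np.abs(y_z))
    x_q = np.column_stack([bh_fdr(x_p[:, c]) for c in range(k)])
    y_q = np.column_stack([bh_fdr(y_p[:, c]) for c in range(k)])
    return BootstrapReport(
        x_mean_loading=x_obs_units, x_loading_sd=x_sd, x_z=x_z, x_p=x_p, x_q=x_q,
        x_labels=unit_labels,
        y_loading_sd=y_sd, y_z=y_z, y_p=y_p, y_q=y_q,
        n_bootstraps=n_boot, seed=seed, n_redrawn=n_redrawn,
        block_index=unit_idx, block_names=block_names,
    )


def bh_fdr(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (NaN-tolerant)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out
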