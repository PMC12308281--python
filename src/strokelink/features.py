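"""Analysis-ready feature construction.

Turns raw per-participant objects (parcel time series, binary lesion masks,
a streamline atlas) into the matrices the latent-component analysis consumes:

* Fisher-z functional-connectivity (FC) edge vectors, with lesion-aware
  parcel exclusion (>50% overlap rule);
* percent grey-matter damage per parcel;
* region-based structural disconnection (SDC) matrices, i.e. per parcel
  pair the proportion of atlas streamlines passing through the lesion;
* group-matrix assembly with per-edge mean imputation, behaviour-table
  mean imputation, zero-feature removal, and confound residualization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ParcelScheme",
    "LesionMask",
    "StreamlineAtlas",
    "ConnectivityMatrix",
    "EdgeVector",
    "edge_index",
    "edge_labels",
    "fc_matrix",
    "damage_vector",
    "excluded_parcels",
    "sdc_matrix",
    "vectorize_upper",
    "matrix_from_upper",
    "assemble_group_matrix",
    "impute_behaviour",
    "drop_zero_features",
    "residualize_confounds",
]

#: Pearson r is clipped to +/- (1 - FISHER_CLIP) before atanh so that the
#: Fisher z-transform stays finite on degenerate (perfectly correlated) input.
FISHER_CLIP = 1e-7


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------


@dataclass
class ParcelScheme:
    """Parcel identities: the coordinate frame for every feature matrix.

    Parcels are numbered contiguously from 1.  Each parcel lives entirely in
    one hemisphere ('L' or 'R') and carries a network label; voxel membership
    sets are pairwise disjoint on the grid.
    """

    hemisphere: np.ndarray            # (P,) array of 'L'/'R'
    network: np.ndarray               # (P,) network label strings
    voxel_members: list               # list of (m_i, 3) int arrays
    centroids: np.ndarray             # (P, 3) float voxel coordinates
    grid_dims: tuple                  # (gx, gy, gz)

    @property
    def n_parcels(self) -> int:
        return len(self.hemisphere)

    @property
    def parcel_ids(self) -> np.ndarray:
        return np.arange(1, self.n_parcels + 1)

    @property
    def n_edges(self) -> int:
        p = self.n_parcels
        return p * (p - 1) // 2

    def block_labels(self) -> np.ndarray:
        """Hemisphere-qualified network label per parcel (e.g. 'L:visual')."""
        return np.array([f"{h}:{n}" for h, n in zip(self.hemisphere, self.network)])

    def validate(self) -> None:
        grid = np.asarray(self.grid_dims)
        seen = set()
        for pid, vox in enumerate(self.voxel_members, start=1):
            vox = np.asarray(vox)
            if vox.size == 0:
                raise ValueError(f"parcel {pid} has an empty voxel set")
            if (vox < 0).any() or (vox >= grid).any():
                raise ValueError(f"parcel {pid} has voxels outside the grid")
            keys = set(map(tuple, vox.tolist()))
            if seen & keys:
                raise ValueError(f"parcel {pid} overlaps another parcel")
            seen |= keys

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "parcel_id": self.parcel_ids,
                "hemisphere": self.hemisphere,
                "network": self.network,
                "centroid_x": self.centroids[:, 0],
                "centroid_y": self.centroids[:, 1],
                "centroid_z": self.centroids[:, 2],
            }
        )


@dataclass
class LesionMask:
    """Binary lesion mask on the analysis voxel grid."""

    grid: np.ndarray  # 3-D boolean array

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=bool)
        if self.grid.ndim != 3:
            raise ValueError("lesion mask must be a 3-D array")
        if not self.grid.any():
            raise ValueError("lesion mask has no lesioned voxel")

    @property
    def n_voxels(self) -> int:
        return int(self.grid.sum())


@dataclass
class StreamlineAtlas:
    """Streamline polylines in voxel coordinates with endpoint parcels.

    ``streamlines[i]`` is an (m_i, 3) float array with consecutive vertices
    at most one voxel apart; ``endpoints[i]`` is the unordered pair of parcel
    ids the streamline connects.
    """

    streamlines: list                 # list of (m_i, 3) float arrays
    endpoints: np.ndarray             # (S, 2) int parcel ids (1-based)
    _voxel_cache: dict = field(default_factory=dict, repr=False)

    @property
    def n_streamlines(self) -> int:
        return len(self.streamlines)

    def voxel_indices(self, grid_dims: tuple) -> list:
        """Per streamline, the unique flat voxel indices its vertices visit.

        Vertices are snapped to their nearest voxel (round-half-even) and
        clipped into the grid; the result is cached per grid shape.
        """
        key = tuple(grid_dims)
        if key not in self._voxel_cache:
            dims = np.asarray(key)
            out = []
            for line in self.streamlines:
                vox = np.rint(np.asarray(line)).astype(np.int64)
                np.clip(vox, 0, dims - 1, out=vox)
                flat = np.ravel_multi_index(vox.T, key)
                out.append(np.unique(flat))
            self._voxel_cache[key] = out
        return self._voxel_cache[key]

    def validate(self, scheme: ParcelScheme) -> None:
        if self.endpoints.shape != (self.n_streamlines, 2):
            raise ValueError("endpoints shape does not match streamline count")
        if (self.endpoints < 1).any() or (self.endpoints > scheme.n_parcels).any():
            raise ValueError("endpoint parcel ids outside the scheme")
        for i, line in enumerate(self.streamlines):
            step = np.linalg.norm(np.diff(np.asarray(line), axis=0), axis=1)
            if step.size and step.max() > 1.0 + 1e-9:
                raise ValueError(f"streamline {i} has vertex spacing > 1 voxel")


@dataclass
class ConnectivityMatrix:
    """Symmetric parcel x parcel Fisher-z matrix with a missingness mask."""

    values: np.ndarray
    missing_mask: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.values.shape != self.missing_mask.shape:
            raise ValueError("values / missing_mask shape mismatch")


@dataclass
class EdgeVector:
    """Upper-triangle (i<j, row-major) flattening of a symmetric matrix."""

    values: np.ndarray
    missing_mask: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.values.shape != self.missing_mask.shape:
            raise ValueError("values / missing_mask shape mismatch")


# ---------------------------------------------------------------------------
# edge-order helpers
# ---------------------------------------------------------------------------


def edge_index(n_parcels: int) -> tuple[np.ndarray, np.ndarray]:
    """Row/column parcel indices (0-based) of each edge in canonical order.

    Canonical order is the row-major upper triangle: (0,1), (0,2), ...,
    (0,P-1), (1,2), ...  Every participant's edge vector uses this order.
    """
    return np.triu_indices(n_parcels, k=1)


def edge_labels(scheme: ParcelScheme) -> list[str]:
    """Human-readable ``parcelA-parcelB`` labels in canonical edge order."""
    ii, jj = edge_index(scheme.n_parcels)
    return [f"p{str(i + 1).zfill(3)}-p{str(j + 1).zfill(3)}" for i, j in zip(ii, jj)]


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def fc_matrix(parcel_series: np.ndarray, excluded: Sequence[int] = ()) -> ConnectivityMatrix:
    """Fisher-z functional connectivity from parcel-average time series.

    Parameters
    ----------
    parcel_series:
        (P, T) array, one BOLD-like time series per parcel.
    excluded:
        Parcel ids (1-based) whose rows/columns are flagged missing, e.g.
        parcels with more than 50% lesion overlap.

    Pearson correlations are clipped to ``+/-(1 - 1e-7)`` before ``atanh``
    so the transform stays finite even for duplicated series.
    """
    series = np.asarray(parcel_series, dtype=float)
    if series.ndim != 2:
        raise ValueError("parcel_series must be a (parcel, time) array")
    p, t = series.shape
    if t < 3:
        raise ValueError(f"need at least 3 time points, got {t}")
    excluded = set(int(e) for e in excluded)
    included = [i for i in range(p) if (i + 1) not in excluded]
    sd = series.std(axis=1)
    for i in included:
        if sd[i] == 0:
            raise ValueError(f"parcel {i + 1} has a constant time series")

    r = np.corrcoef(series)
    # excluded parcels may be constant; silence their NaNs, they are masked out
    r = np.nan_to_num(r, nan=0.0)
    r = np.clip(r, -(1 - FISHER_CLIP), 1 - FISHER_CLIP)
    z = np.arctanh(r)

    missing = np.zeros((p, p), dtype=bool)
    np.fill_diagonal(missing, True)
    for e in excluded:
        missing[e - 1, :] = True
        missing[:, e - 1] = True
    z[missing] = np.nan
    return ConnectivityMatrix(values=z, missing_mask=missing)


def damage_vector(lesion: LesionMask, scheme: ParcelScheme) -> np.ndarray:
    """Percent of each parcel's voxels inside the lesion mask, in [0, 100]."""
    if lesion.grid.shape != tuple(scheme.grid_dims):
        raise ValueError("lesion grid does not match the parcel scheme grid")
    flat = lesion.grid.ravel()
    out = np.empty(scheme.n_parcels, dtype=float)
    for k, vox in enumerate(scheme.voxel_members):
        vox = np.asarray(vox)
        if vox.size == 0:
            raise ValueError(f"parcel {k + 1} has an empty voxel set")
        idx = np.ravel_multi_index(vox.T, lesion.grid.shape)
        out[k] = 100.0 * flat[idx].sum() / len(idx)
    return out


def excluded_parcels(damage: np.ndarray, threshold_percent: float = 50.0) -> set[int]:
    """Parcel ids with damage *strictly greater* than the threshold.

    A parcel at exactly 50.0% stays in the analysis; the exclusion rule is
    "more than 50% lesion overlap".
    """
    damage = np.asarray(damage, dtype=float)
    return set((np.nonzero(damage > threshold_percent)[0] + 1).tolist())


def streamline_disruption(lesion: LesionMask, atlas: StreamlineAtlas) -> np.ndarray:
    """Boolean per streamline: does any vertex voxel fall inside the lesion?"""
    flat = lesion.grid.ravel()
    vox = atlas.voxel_indices(lesion.grid.shape)
    return np.array([bool(flat[v].any()) for v in vox])


def sdc_matrix(lesion: LesionMask, atlas: StreamlineAtlas, scheme: ParcelScheme) -> np.ndarray:
    """Region-based structural disconnection matrix.

    Entry (A, B) is the proportion of atlas streamlines between parcels A
    and B that pass through the lesion.  A streamline is disrupted iff any
    vertex, snapped to its voxel, is lesioned.  Parcel pairs with no atlas
    streamlines get 0 (nothing there to disconnect).
    """
    if lesion.grid.shape != tuple(scheme.grid_dims):
        raise ValueError("lesion grid does not match the parcel scheme grid")
    p = scheme.n_parcels
    hit = streamline_disruption(lesion, atlas)
    total = np.zeros((p, p), dtype=float)
    broken = np.zeros((p, p), dtype=float)
    a = atlas.endpoints[:, 0] - 1
    b = atlas.endpoints[:, 1] - 1
    np.add.at(total, (a, b), 1.0)
    np.add.at(broken, (a, b), hit.astype(float))
    total = total + total.T
    broken = broken + broken.T
    with np.errstate(invalid="ignore", divide="ignore"):
        sdc = np.where(total > 0, broken / np.where(total > 0, total, 1.0), 0.0)
    np.fill_diagonal(sdc, 0.0)
    return sdc


def vectorize_upper(matrix, missing_mask: np.ndarray | None = None, atol: float = 1e-10) -> EdgeVector:
    """Flatten a symmetric matrix's upper triangle into canonical edge order."""
    if isinstance(matrix, ConnectivityMatrix):
        missing_mask = matrix.missing_mask
        matrix = matrix.values
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("input must be square")
    finite = np.isfinite(m) & np.isfinite(m.T)
    if not np.allclose(m[finite.nonzero()], m.T[finite.nonzero()], atol=atol):
        raise ValueError("input matrix is asymmetric beyond tolerance")
    ii, jj = edge_index(m.shape[0])
    vals = m[ii, jj]
    if missing_mask is None:
        miss = ~np.isfinite(vals)
    else:
        miss = np.asarray(missing_mask, dtype=bool)[ii, jj]
    return EdgeVector(values=vals, missing_mask=miss)


def matrix_from_upper(edges: EdgeVector | np.ndarray, n_parcels: int, diagonal: float = 0.0) -> np.ndarray:
    """Inverse of :func:`vectorize_upper` (missing entries become NaN)."""
    if isinstance(edges, EdgeVector):
        vals = edges.values.copy()
        vals[edges.missing_mask] = np.nan
    else:
        vals = np.asarray(edges, dtype=float)
    ii, jj = edge_index(n_parcels)
    if vals.shape != ii.shape:
        raise ValueError("edge vector length does not match parcel count")
    out = np.full((n_parcels, n_parcels), diagonal, dtype=float)
    out[ii, jj] = vals
    out[jj, ii] = vals
    return out


def assemble_group_matrix(edge_vectors: Sequence[EdgeVector]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack per-participant edge vectors into a participant x edge matrix.

    Missing cells (per-participant exclusions) are imputed with the edge's
    across-participant observed mean; edges missing for every participant
    are dropped.

    Returns
    -------
    matrix, kept_idx, dropped_idx
        ``kept_idx`` maps output columns back to canonical edge indices.
    """
    if len(edge_vectors) == 0:
        raise ValueError("no edge vectors given")
    vals = np.vstack([ev.values for ev in edge_vectors])
    miss = np.vstack([ev.missing_mask for ev in edge_vectors])
    vals = np.where(miss, np.nan, vals)
    observed = ~miss
    all_missing = ~observed.any(axis=0)
    kept_idx = np.nonzero(~all_missing)[0]
    dropped_idx = np.nonzero(all_missing)[0]
    vals = vals[:, kept_idx]
    col_mean = np.nanmean(vals, axis=0)
    fill = np.where(np.isnan(vals), col_mean[None, :], vals)
    return fill, kept_idx, dropped_idx


def impute_behaviour(table: pd.DataFrame) -> pd.DataFrame:
    """Mean-impute missing behaviour cells, column by column."""
    table = table.copy()
    for col in table.columns:
        obs = table[col].dropna()
        if obs.empty:
            raise ValueError(f"behaviour measure '{col}' has no observed value")
        table[col] = table[col].fillna(obs.mean())
    return table


def drop_zero_features(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Remove columns that are identically zero across all participants."""
    m = np.asarray(matrix, dtype=float)
    nonzero = np.nonzero((m != 0).any(axis=0))[0]
    if nonzero.size == 0:
        raise ValueError("every feature is zero across all participants")
    return m[:, nonzero], nonzero


def residualize_confounds(matrix: np.ndarray, confounds: np.ndarray) -> np.ndarray:
    """Regress confounds (plus intercept) out of every feature column."""
    m = np.asarray(matrix, dtype=float)
    c = np.asarray(confounds, dtype=float)
    if c.ndim == 1:
        c = c[:, None]
    n = m.shape[0]
    if c.shape[0] != n:
        raise ValueError("confound rows do not match participant rows")
    design = np.column_stack([np.ones(n), c])
    if n <= design.shape[1]:
        raise ValueError("need more participants than covariates + intercept")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("confound matrix is rank-deficient")
    beta, *_ = np.linalg.lstsq(design, m, rcond=None)
    return m - design @ beta
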