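"""Partial least squares correlation (PLSC).

Two participant-aligned blocks — brain features X (FC or SDC edge vectors)
and behavioural measures Y — are column-standardized and cross-correlated:

    R = Yz' Xz / (n - 1)

The SVD ``R = V diag(s) U'`` yields paired latent components (LCs): each
column of U is an X-salience, the matching column of V a Y-salience, and
``s_k^2 / sum_j s_j^2`` is the fraction of cross-block covariance the
component explains.  Composite scores are the projections ``Xz U`` and
``Yz V``; loadings are Pearson correlations between original variables and
composite scores and carry the interpretation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .features import ParcelScheme, edge_index

__all__ = [
    "LatentModel",
    "CompositeScores",
    "LoadingSet",
    "zscore_columns",
    "destandardize",
    "fit_plsc",
    "composite_scores",
    "loadings",
    "regional_importance",
    "top_fraction",
]


@dataclass
class ColumnStats:
    mean: np.ndarray
    scale: np.ndarray


@dataclass
class LatentModel:
    """Fitted PLSC decomposition.

    ``x_saliences`` (p, k) and ``y_saliences`` (q, k) have orthonormal
    columns within each block; ``singular_values`` are nonincreasing.  The
    per-column standardization statistics used at fit time are retained so
    new data can be projected with either policy.
    """

    x_saliences: np.ndarray
    y_saliences: np.ndarray
    singular_values: np.ndarray
    explained_covariance: np.ndarray
    x_stats: ColumnStats
    y_stats: ColumnStats
    sign_flips: np.ndarray
    n_fit: int
    scale_mode: str = "correlation"
    feature_names: list | None = None
    measure_names: list | None = None

    @property
    def n_components(self) -> int:
        return len(self.singular_values)

    def to_json(self, path) -> None:
        payload = {
            "x_saliences": self.x_saliences.tolist(),
            "y_saliences": self.y_saliences.tolist(),
            "singular_values": self.singular_values.tolist(),
            "explained_covariance": self.explained_covariance.tolist(),
            "x_mean": self.x_stats.mean.tolist(),
            "x_scale": self.x_stats.scale.tolist(),
            "y_mean": self.y_stats.mean.tolist(),
            "y_scale": self.y_stats.scale.tolist(),
            "sign_flips": self.sign_flips.tolist(),
            "n_fit": self.n_fit,
            "scale_mode": self.scale_mode,
            "feature_names": self.feature_names,
            "measure_names": self.measure_names,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "LatentModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            x_saliences=np.asarray(d["x_saliences"], dtype=float),
            y_saliences=np.asarray(d["y_saliences"], dtype=float),
            singular_values=np.asarray(d["singular_values"], dtype=float),
            explained_covariance=np.asarray(d["explained_covariance"], dtype=float),
            x_stats=ColumnStats(np.asarray(d["x_mean"]), np.asarray(d["x_scale"])),
            y_stats=ColumnStats(np.asarray(d["y_mean"]), np.asarray(d["y_scale"])),
            sign_flips=np.asarray(d["sign_flips"], dtype=float),
            n_fit=int(d["n_fit"]),
            scale_mode=d["scale_mode"],
            feature_names=d["feature_names"],
            measure_names=d["measure_names"],
        )


@dataclass
class CompositeScores:
    """Participant x component projections for both blocks."""

    x_scores: np.ndarray
    y_scores: np.ndarray

    def correlation(self, component: int = 0) -> float:
        """Pearson r between the two blocks' scores on one component."""
        x = self.x_scores[:, component]
        y = self.y_scores[:, component]
        return float(np.corrcoef(x, y)[0, 1])


@dataclass
class LoadingSet:
    """Variable-composite correlations; NaN marks constant variables."""

    x_loadings: np.ndarray
    y_loadings: np.ndarray


# ---------------------------------------------------------------------------
# standardization
# ---------------------------------------------------------------------------


def zscore_columns(matrix: np.ndarray, names=None, scale: bool = True) -> tuple[np.ndarray, ColumnStats]:
    """Column-standardize (mean 0, sample SD 1, ddof=1).

    Raises on a constant column, naming it.  ``scale=False`` centers only
    (covariance mode).
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2:
        raise ValueError("expected a 2-D participant x variable matrix")
    mean = m.mean(axis=0)
    if scale:
        sd = m.std(axis=0, ddof=1)
        bad = np.nonzero(sd == 0)[0]
        if bad.size:
            label = names[bad[0]] if names is not None else f"column {bad[0]}"
            raise ValueError(f"constant column cannot be standardized: {label}")
    else:
        sd = np.ones(m.shape[1])
    return (m - mean) / sd, ColumnStats(mean=mean, scale=sd)


def _zscore_safe(m: np.ndarray, scale: bool = True) -> np.ndarray:
    """Center/scale, mapping zero-variance columns to zero (resampling use)."""
    m = np.asarray(m, dtype=float)
    mean = m.mean(axis=0)
    if not scale:
        return m - mean
    sd = m.std(axis=0, ddof=1)
    sd = np.where(sd == 0, 1.0, sd)
    return (m - mean) / sd


def apply_stats(matrix: np.ndarray, stats: ColumnStats) -> np.ndarray:
    return (np.asarray(matrix, dtype=float) - stats.mean) / stats.scale


def destandardize(z: np.ndarray, stats: ColumnStats) -> np.ndarray:
    return np.asarray(z, dtype=float) * stats.scale + stats.mean


# ---------------------------------------------------------------------------
# fitting and projection
# ---------------------------------------------------------------------------


def _cross_block(xz: np.ndarray, yz: np.ndarray) -> np.ndarray:
    n = xz.shape[0]
    return yz.T @ xz / (n - 1)


def _svd_components(r: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """SVD of the cross-block matrix: returns (U_x, s, V_y), unsign-fixed."""
    w, s, zt = np.linalg.svd(r, full_matrices=False)
    return zt.T, s, w


def fit_plsc(X: np.ndarray, Y: np.ndarray, scale_mode: str = "correlation",
             feature_names=None, measure_names=None) -> LatentModel:
    """Fit the PLSC decomposition of the X/Y cross-correlation matrix.

    Components are sign-fixed so that each Y-salience column has its
    largest-magnitude entry positive (a deterministic convention; the SVD
    itself leaves each component's sign free).
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.ndim != 2 or Y.ndim != 2:
        raise ValueError("X and Y must be 2-D")
    if X.shape[0] != Y.shape[0]:
        raise ValueError(f"participant mismatch: X has {X.shape[0]}, Y has {Y.shape[0]}")
    n = X.shape[0]
    if n < 3:
        raise ValueError("need at least 3 participants")
    scale = scale_mode == "correlation"
    xz, x_stats = zscore_columns(X, names=feature_names, scale=scale)
    yz, y_stats = zscore_columns(Y, names=measure_names, scale=scale)
    r = _cross_block(xz, yz)
    u, s, v = _svd_components(r)

    flips = np.ones(len(s))
    for k in range(len(s)):
        j = int(np.argmax(np.abs(v[:, k])))
        if v[j, k] < 0:
            flips[k] = -1.0
    u = u * flips
    v = v * flips

    total = float((s ** 2).sum())
    explained = s ** 2 / total if total > 0 else np.zeros_like(s)
    return LatentModel(
        x_saliences=u,
        y_saliences=v,
        singular_values=s,
        explained_covariance=explained,
        x_stats=x_stats,
        y_stats=y_stats,
        sign_flips=flips,
        n_fit=n,
        scale_mode=scale_mode,
        feature_names=list(feature_names) if feature_names is not None else None,
        measure_names=list(measure_names) if measure_names is not None else None,
    )


def composite_scores(model: LatentModel, X: np.ndarray, Y: np.ndarray,
                     standardize: str = "self") -> CompositeScores:
    """Project (standardized) data onto the model's saliences.

    ``standardize='self'`` uses the projected cohort's own column statistics
    (the default for whole-cohort projection); ``'fit'`` reuses the fit-time
    statistics (required when projecting single participants, e.g. LOOCV).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X.shape[1] != model.x_saliences.shape[0]:
        raise ValueError("X feature dimension does not match the model")
    if Y.shape[1] != model.y_saliences.shape[0]:
        raise ValueError("Y measure dimension does not match the model")
    scale = model.scale_mode == "correlation"
    if standardize == "self":
        if X.shape[0] < 2:
            raise ValueError("own-statistics standardization needs >= 2 rows; use standardize='fit'")
        xz = _zscore_safe(X, scale=scale)
        yz = _zscore_safe(Y, scale=scale)
    elif standardize == "fit":
        xz = apply_stats(X, model.x_stats)
        yz = apply_stats(Y, model.y_stats)
    else:
        raise ValueError(f"unknown standardization policy: {standardize!r}")
    return CompositeScores(x_scores=xz @ model.x_saliences, y_scores=yz @ model.y_saliences)


def _corr_columns(data: np.ndarray, scores: np.ndarray) -> np.ndarray:
    """corr(data[:, f], scores[:, k]) for all f, k; NaN for constant columns."""
    d = data - data.mean(axis=0)
    s = scores - scores.mean(axis=0)
    dn = np.sqrt((d ** 2).sum(axis=0))
    sn = np.sqrt((s ** 2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        out = (d.T @ s) / np.outer(dn, sn)
    out[dn == 0, :] = np.nan
    return out


def loadings(scores: CompositeScores, X: np.ndarray, Y: np.ndarray) -> LoadingSet:
    """Pearson correlations between original variables and composite scores."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape[0] != scores.x_scores.shape[0] or Y.shape[0] != scores.y_scores.shape[0]:
        raise ValueError("participant mismatch between data and scores")
    return LoadingSet(
        x_loadings=_corr_columns(X, scores.x_scores),
        y_loadings=_corr_columns(Y, scores.y_scores),
    )


def regional_importance(x_loadings: np.ndarray, scheme: ParcelScheme,
                        mask: np.ndarray | None = None) -> np.ndarray:
    """Per-parcel sum of edge loadings over all incident edges.

    ``mask`` optionally restricts the sum to selected edges (e.g. the top
    20% by magnitude); default is unthresholded.
    """
    vals = np.asarray(x_loadings, dtype=float)
    p = scheme.n_parcels
    ii, jj = edge_index(p)
    if vals.shape[0] != ii.shape[0]:
        raise ValueError("loading vector length does not match the scheme's edge count")
    if mask is not None:
        vals = np.where(np.asarray(mask, dtype=bool), vals, 0.0)
    out = np.zeros(p)
    np.add.at(out, ii, vals)
    np.add.at(out, jj, vals)
    return out


def top_fraction(values: np.ndarray, fraction: float = 0.2) -> np.ndarray:
    """Mask of the ceil(fraction * m) largest-|value| entries.

    Ties at the cut are broken in favour of the lower index, keeping the
    mask size exact.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty loading vector")
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    k = int(np.ceil(fraction * v.size))
    order = np.lexsort((np.arange(v.size), -np.abs(v)))
    mask = np.zeros(v.size, dtype=bool)
    mask[order[:k]] = True
    return mask
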