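"""Replication machinery for the latent component.

Cross-cohort projection (does the salience pair learned on one cohort
generalize to another?), salience similarity between independently fitted
models, leave-one-out PLSC generalization, and split-half stability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .inference import procrustes_align
from .plsc import LatentModel, composite_scores, fit_plsc

__all__ = [
    "ProjectionResult",
    "SimilarityResult",
    "project_cohort",
    "salience_similarity",
    "loocv_plsc",
    "split_half",
    "LoocvResult",
]


@dataclass
class ProjectionResult:
    x_scores: np.ndarray
    y_scores: np.ndarray
    score_correlation: np.ndarray       # per component
    permutation_p: float | None = None  # LC1, if requested


@dataclass
class SimilarityResult:
    x_salience_correlation: float
    y_salience_correlation: float
    x_flipped: bool
    y_flipped: bool


@dataclass
class LoocvResult:
    pooled_correlation: float
    x_test_scores: np.ndarray
    y_test_scores: np.ndarray
    permutation_p: float | None


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.corrcoef(a, b)[0, 1])


def project_cohort(model: LatentModel, X_new: np.ndarray, Y_new: np.ndarray,
                   feature_names=None, measure_names=None,
                   standardize: str = "self", n_perm: int = 0,
                   seed: int = 0) -> ProjectionResult:
    """Project a new cohort onto a fitted model's saliences.

    If both the model and the call carry column names, they must match in
    order; a mismatch raises with the offending names.  With ``n_perm > 0``
    a one-sided permutation p-value for the LC1 score correlation is
    computed by shuffling the new cohort's Y rows.
    """
    for got, want, side in ((feature_names, model.feature_names, "feature"),
                            (measure_names, model.measure_names, "measure")):
        if got is not None and want is not None and list(got) != list(want):
            bad = [g for g, w in zip(got, want) if g != w]
            extra = abs(len(list(got)) - len(want))
            raise ValueError(
                f"{side} columns do not match the model "
                f"(mismatched: {bad[:5]}{'...' if len(bad) > 5 else ''}, "
                f"length difference {extra})")
    scores = composite_scores(model, X_new, Y_new, standardize=standardize)
    k = model.n_components
    corr = np.array([_pearson(scores.x_scores[:, c], scores.y_scores[:, c])
                     for c in range(k)])
    p = None
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        n = scores.x_scores.shape[0]
        obs = corr[0]
        exceed = 0
        for _ in range(n_perm):
            perm = rng.permutation(n)
            exceed += _pearson(scores.x_scores[:, 0], scores.y_scores[perm, 0]) >= obs
        p = (1.0 + exceed) / (1.0 + n_perm)
    return ProjectionResult(x_scores=scores.x_scores, y_scores=scores.y_scores,
                            score_correlation=corr, permutation_p=p)


def salience_similarity(model_a: LatentModel, model_b: LatentModel,
                        component: int = 0) -> SimilarityResult:
    """Pearson r between two models' salience vectors, sign-aligned.

    Sign indeterminacy is resolved by flipping model_b's component when the
    raw correlation is negative; the flip is recorded per block.
    """
    if model_a.x_saliences.shape[0] != model_b.x_saliences.shape[0]:
        raise ValueError("feature spaces differ between models")
    if model_a.y_saliences.shape[0] != model_b.y_saliences.shape[0]:
        raise ValueError("measure spaces differ between models")
    rx = _pearson(model_a.x_saliences[:, component], model_b.x_saliences[:, component])
    ry = _pearson(model_a.y_saliences[:, component], model_b.y_saliences[:, component])
    return SimilarityResult(
        x_salience_correlation=abs(rx) if rx < 0 else rx,
        y_salience_correlation=abs(ry) if ry < 0 else ry,
        x_flipped=rx < 0,
        y_flipped=ry < 0,
    )


def _loocv_scores(X: np.ndarray, Y: np.ndarray, reference: LatentModel,
                  scale_mode: str) -> tuple[np.ndarray, np.ndarray]:
    """Held-out LC scores: fit on n-1, align to reference, project the rest.

    Fold models are Procrustes-aligned to the full-sample reference so that
    component sign and order are coherent across folds; the held-out row is
    standardized with the training fold's statistics (a single row has no
    statistics of its own).
    """
    n = X.shape[0]
    k = reference.n_components
    xs = np.empty((n, k))
    ys = np.empty((n, k))
    for i in range(n):
        keep = np.arange(n) != i
        fold = fit_plsc(X[keep], Y[keep], scale_mode=scale_mode)
        _, aligned = procrustes_align(reference, fold)
        held = composite_scores(aligned, X[i:i + 1], Y[i:i + 1], standardize="fit")
        xs[i] = held.x_scores[0]
        ys[i] = held.y_scores[0]
    return xs, ys


def loocv_plsc(X: np.ndarray, Y: np.ndarray, n_perm: int = 1000, seed: int = 0,
               scale_mode: str = "correlation") -> LoocvResult:
    """Leave-one-out generalization test of the first latent component.

    Pools held-out composite scores across folds and correlates them;
    significance by permuting Y rows and repeating the whole LOOCV loop
    (one-sided exceedance with +1 smoothing).
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    n = X.shape[0]
    if n < 5:
        raise ValueError("need at least 5 participants")
    reference = fit_plsc(X, Y, scale_mode=scale_mode)
    xs, ys = _loocv_scores(X, Y, reference, scale_mode)
    pooled = _pearson(xs[:, 0], ys[:, 0])

    p = None
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        exceed = 0
        for _ in range(n_perm):
            perm = rng.permutation(n)
            yp = Y[perm]
            ref_p = fit_plsc(X, yp, scale_mode=scale_mode)
            xs_p, ys_p = _loocv_scores(X, yp, ref_p, scale_mode)
            exceed += _pearson(xs_p[:, 0], ys_p[:, 0]) >= pooled
        p = (1.0 + exceed) / (1.0 + n_perm)
    return LoocvResult(pooled_correlation=pooled, x_test_scores=xs,
                       y_test_scores=ys, permutation_p=p)


def split_half(X: np.ndarray, Y: np.ndarray, seed: int = 0,
               scale_mode: str = "correlation") -> tuple[LatentModel, LatentModel, SimilarityResult]:
    """Fit independent PLSC models on random disjoint near-halves.

    Sizes are ceil(n/2) and floor(n/2) (81 -> 41 + 40); returns both models
    and the LC1 salience similarity between them.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    n = X.shape[0]
    if n < 10:
        raise ValueError("need at least 10 participants to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_a = int(np.ceil(n / 2))
    a, b = order[:n_a], order[n_a:]
    model_a = fit_plsc(X[a], Y[a], scale_mode=scale_mode)
    model_b = fit_plsc(X[b], Y[b], scale_mode=scale_mode)
    sim = salience_similarity(model_a, model_b, component=0)
    return model_a, model_b, sim
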