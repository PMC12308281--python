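"""Three-variable mediation on composite scores.

Classic path model on per-participant scalars: independent x, mediator m,
outcome y.  OLS paths

    m = i1 + a x            (a)
    y = i2 + c x            (c, total effect)
    y = i3 + c' x + b m     (c', direct; b, mediator slope)

with indirect effect ab = a*b = c - c' (an exact OLS identity).  Inference
on ab is by participant-level bootstrap with the bias-corrected (BC)
percentile rule: z0 = Phi^-1(fraction of bootstrap ab below the point
estimate), CI endpoints at the Phi(2 z0 +/- z_{alpha/2}) percentiles of the
bootstrap distribution.  The mediation is called significant when the CI
excludes zero; these are statistical associations, not causal effects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats

__all__ = [
    "PathCoefficients",
    "MediationReport",
    "fit_paths",
    "bc_bootstrap_ci",
    "dual_mediation",
]


@dataclass
class PathCoefficients:
    a: float
    b: float
    c: float
    c_prime: float
    ab: float


@dataclass
class MediationReport:
    a: float
    b: float
    c: float
    c_prime: float
    ab: float
    ci_low: float
    ci_high: float
    proportion_mediated: float
    significant: bool
    n_bootstraps: int
    seed: int
    level: float
    degenerate: bool = False


def _validate(x: np.ndarray, m: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float).ravel()
    m = np.asarray(m, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if not (len(x) == len(m) == len(y)):
        raise ValueError("x, m, y must be aligned per participant")
    if len(x) < 5:
        raise ValueError("need at least 5 participants")
    if x.std() == 0 or m.std() == 0:
        raise ValueError("x and m must be nonconstant")
    r_xm = np.corrcoef(x, m)[0, 1]
    if abs(r_xm) > 1 - 1e-10:
        raise ValueError("mediator is perfectly collinear with the independent variable")
    return x, m, y


def _paths_arrays(x: np.ndarray, m: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    """(a, b, c, c_prime) by closed-form OLS with intercepts."""
    xc = x - x.mean()
    mc = m - m.mean()
    yc = y - y.mean()
    sxx = xc @ xc
    a = (xc @ mc) / sxx
    c = (xc @ yc) / sxx
    smm = mc @ mc
    sxm = xc @ mc
    det = sxx * smm - sxm ** 2
    c_prime = (smm * (xc @ yc) - sxm * (mc @ yc)) / det
    b = (sxx * (mc @ yc) - sxm * (xc @ yc)) / det
    return float(a), float(b), float(c), float(c_prime)


def fit_paths(x, m, y, standardized: bool = False) -> PathCoefficients:
    """OLS path coefficients (unstandardized by default).

    ``standardized=True`` z-scores all three variables first, yielding
    standardized path coefficients.
    """
    x, m, y = _validate(x, m, y)
    if standardized:
        x = (x - x.mean()) / x.std(ddof=1)
        m = (m - m.mean()) / m.std(ddof=1)
        y = (y - y.mean()) / y.std(ddof=1)
    a, b, c, c_prime = _paths_arrays(x, m, y)
    return PathCoefficients(a=a, b=b, c=c, c_prime=c_prime, ab=a * b)


def _bootstrap_ab(x: np.ndarray, m: np.ndarray, y: np.ndarray,
                  n_boot: int, rng: np.random.Generator) -> np.ndarray:
    """Vectorized per-draw indirect effects a*b under case resampling."""
    n = len(x)
    idx = rng.integers(0, n, size=(n_boot, n))
    xb = x[idx]
    mb = m[idx]
    yb = y[idx]
    xc = xb - xb.mean(axis=1, keepdims=True)
    mc = mb - mb.mean(axis=1, keepdims=True)
    yc = yb - yb.mean(axis=1, keepdims=True)
    sxx = np.einsum("ij,ij->i", xc, xc)
    smm = np.einsum("ij,ij->i", mc, mc)
    sxm = np.einsum("ij,ij->i", xc, mc)
    sxy = np.einsum("ij,ij->i", xc, yc)
    smy = np.einsum("ij,ij->i", mc, yc)
    det = sxx * smm - sxm ** 2
    bad = (sxx == 0) | (det == 0)
    sxx = np.where(sxx == 0, 1.0, sxx)
    det = np.where(det == 0, 1.0, det)
    a = sxm / sxx
    b = (sxx * smy - sxm * sxy) / det
    ab = a * b
    ab[bad] = np.nan
    return ab


def bc_bootstrap_ci(x, m, y, n_boot: int = 10000, seed: int = 0,
                    level: float = 0.95, standardized: bool = False) -> MediationReport:
    """Bias-corrected bootstrap CI for the indirect effect ab.

    Degenerate bootstrap distributions (all draws identical) collapse the
    CI to a point and are flagged.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    x, m, y = _validate(x, m, y)
    if standardized:
        x = (x - x.mean()) / x.std(ddof=1)
        m = (m - m.mean()) / m.std(ddof=1)
        y = (y - y.mean()) / y.std(ddof=1)
    a, b, c, c_prime = _paths_arrays(x, m, y)
    ab_hat = a * b

    rng = np.random.default_rng(seed)
    draws = _bootstrap_ab(x, m, y, n_boot, rng)
    draws = draws[np.isfinite(draws)]
    if draws.size == 0:
        raise ValueError("all bootstrap draws were degenerate")

    degenerate = bool(np.ptp(draws) == 0)
    if degenerate:
        lo = hi = float(draws[0])
    else:
        frac = np.mean(draws < ab_hat)
        # clip away 0/1 so z0 stays finite for extremely skewed distributions
        frac = min(max(frac, 1.0 / (draws.size + 1)), draws.size / (draws.size + 1.0))
        z0 = sstats.norm.ppf(frac)
        zq = sstats.norm.ppf(1 - (1 - level) / 2)
        p_lo = sstats.norm.cdf(2 * z0 - zq)
        p_hi = sstats.norm.cdf(2 * z0 + zq)
        lo = float(np.quantile(draws, p_lo))
        hi = float(np.quantile(draws, p_hi))

    significant = not (lo <= 0.0 <= hi)
    prop = ab_hat / c if c != 0 else np.nan
    return MediationReport(a=a, b=b, c=c, c_prime=c_prime, ab=ab_hat,
                           ci_low=lo, ci_high=hi,
                           proportion_mediated=float(prop),
                           significant=significant, n_bootstraps=n_boot,
                           seed=seed, level=level, degenerate=degenerate)


def dual_mediation(sdc_scores, fc_scores, behaviour_scores,
                   n_boot: int = 10000, seed: int = 0,
                   standardized: bool = False) -> dict:
    """Both mediation orientations on the three composite scores.

    model1_fc_mediator:  x = SDC composite, m = FC composite, y = behaviour.
    model2_sdc_mediator: x = FC composite,  m = SDC composite, y = behaviour.
    """
    return {
        "model1_fc_mediator": bc_bootstrap_ci(
            sdc_scores, fc_scores, behaviour_scores,
            n_boot=n_boot, seed=seed, standardized=standardized),
        "model2_sdc_mediator": bc_bootstrap_ci(
            fc_scores, sdc_scores, behaviour_scores,
            n_boot=n_boot, seed=seed + 1, standardized=standardized),
    }
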