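"""Within-array intensity-trend and between-array A-quantile normalization.

Two-colour arrays show an intensity-dependent dye bias: the log ratio M
drifts as a smooth function c(A) of spot brightness.  `loess_normalize_array`
removes that drift and returns M - c(A), where c is a *weighted robust
smooth-curve fit* of M on A: a cubic regression spline (flexibility set by
the `span` parameter; knots at quantiles of A) fitted by weighted least
squares, with Tukey-bisquare robustness weights re-estimated until the
fitted curve stabilises (at least `iterations` reweighting passes).  Spot
weights multiply into the fit, so flagged spots (weight 0.1) pull the
curve 10x less.

A regression-spline smoother is chosen over a windowed local-linear
(lowess) smoother deliberately: the subtraction step is then a weighted
*projection*, so once the robustness weights have converged the operation
is idempotent — renormalizing normalized data is a no-op to numerical
tolerance.  A windowed lowess smoother has smoothing-matrix eigenvalues
strictly between 0 and 1 and therefore always re-shrinks pure noise by a
few thousandths of a log2 unit on every application, which makes repeated
normalization slowly distort the data.  Both smoothers remove the same
smooth dye trends; only the projection has the fixed-point property.

`aquantile_normalize` then equalizes the intensity distributions across
arrays: each array's A values are replaced by the mean of the order
statistics over all arrays, rank for rank (quantile normalization of A
only; M is untouched, so between-array scale differences are removed
without disturbing the within-array ratios).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.interpolate
import scipy.stats

from .array_io import MASet
from .errors import NormalizationError

_MIN_USABLE = 10
_CURVE_TOL = 1e-11  # robustness-weight fixed point: curve change below this
_MAX_ROBUST_PASSES = 100


@dataclass(frozen=True)
class NormalizationParams:
    span: float = 0.25  # smoothness: the spline spends ~2.5/span df on the curve
    iterations: int = 2  # minimum bisquare robustifying passes after the first fit
    bisquare_c: float = 6.0  # residuals beyond c * median|r| get weight 0

    def __post_init__(self) -> None:
        if not 0.0 < self.span <= 1.0:
            raise ValueError("span must be in (0, 1]")
        if self.iterations < 0:
            raise ValueError("iterations must be >= 0")


def _spline_basis(a: np.ndarray, span: float) -> np.ndarray:
    """Cubic B-spline design matrix in A with quantile-placed interior knots."""
    n = a.size
    df = int(np.clip(round(2.5 / span), 4, max(4, n - 2)))
    n_interior = max(df - 4, 0)
    lo, hi = a.min(), a.max()
    if hi <= lo:  # all spots at one intensity: constant basis
        return np.ones((n, 1))
    if n_interior:
        qs = np.quantile(a, np.linspace(0, 1, n_interior + 2)[1:-1])
        interior = np.unique(np.clip(qs, lo + 1e-9 * (hi - lo), hi - 1e-9 * (hi - lo)))
    else:
        interior = np.array([])
    t = np.concatenate([[lo] * 4, interior, [hi] * 4])
    return scipy.interpolate.BSpline.design_matrix(
        np.clip(a, lo, hi), t, 3, extrapolate=False
    ).toarray()


def _wls_curve(B: np.ndarray, m: np.ndarray, w: np.ndarray) -> np.ndarray:
    Bw = B * w[:, None]
    G = B.T @ Bw
    b = Bw.T @ m
    coef, *_ = np.linalg.lstsq(G, b, rcond=None)
    return B @ coef


def loess_normalize_array(
    M: np.ndarray,
    A: np.ndarray,
    W: np.ndarray,
    params: NormalizationParams | None = None,
) -> np.ndarray:
    """Return M minus the fitted intensity-dependent trend c(A).

    Missing M/A values (weight 0 or NaN) pass through unchanged and do not
    influence the fit.
    """
    params = params or NormalizationParams()
    M = np.asarray(M, float)
    A = np.asarray(A, float)
    W = np.asarray(W, float)
    usable = (W > 0) & np.isfinite(M) & np.isfinite(A)
    if usable.sum() < _MIN_USABLE:
        raise NormalizationError(
            f"only {int(usable.sum())} usable spots; need at least {_MIN_USABLE}"
        )
    a, m, w = A[usable], M[usable], W[usable]
    B = _spline_basis(a, params.span)
    curve = _wls_curve(B, m, w)
    prev = curve
    for it in range(_MAX_ROBUST_PASSES if params.iterations > 0 else 0):
        r = m - curve
        s = np.median(np.abs(r))
        if s <= 0:
            break  # exact fit: nothing to robustify
        u = r / (params.bisquare_c * s)
        rob = np.square(1.0 - np.square(np.clip(u, -1.0, 1.0)))
        curve = _wls_curve(B, m, w * rob)
        delta = float(np.max(np.abs(curve - prev)))
        prev = curve
        if it + 1 >= params.iterations and delta < _CURVE_TOL:
            break
    out = M.copy()
    out[usable] = m - curve
    return out


def aquantile_normalize(A: np.ndarray, W: np.ndarray | None = None) -> np.ndarray:
    """Quantile-normalize the A matrix across arrays (columns).

    Each array's values are mapped, rank for rank, onto the mean of the
    order statistics across arrays; ties within an array receive the mean of
    their tied targets.  Missing values stay missing; arrays with missing
    entries are mapped through interpolated quantiles so that complete
    arrays end up with identical sorted values.
    """
    A = np.asarray(A, float)
    if A.ndim != 2:
        raise ValueError("A must be a probes x arrays matrix")
    n, p = A.shape
    if p < 2:
        import warnings

        warnings.warn("aquantile with a single array is the identity", stacklevel=2)
        return A.copy()
    # mean quantile function on a common grid of n probability points
    probs = (np.arange(n) + 0.5) / n
    qsum = np.zeros(n)
    for j in range(p):
        col = A[:, j]
        ok = np.isfinite(col)
        vals = np.sort(col[ok])
        if vals.size == 0:
            raise NormalizationError(f"array column {j} has no finite A values")
        pj = (np.arange(vals.size) + 0.5) / vals.size
        qsum += np.interp(probs, pj, vals)
    qmean = qsum / p
    out = np.full_like(A, np.nan)
    for j in range(p):
        col = A[:, j]
        ok = np.isfinite(col)
        nj = int(ok.sum())
        ranks = scipy.stats.rankdata(col[ok], method="average")  # 1..nj, ties averaged
        pj = (ranks - 0.5) / nj
        out[ok, j] = np.interp(pj, probs, qmean)
    return out


def normalize_maset(ma: MASet, params: NormalizationParams | None = None) -> MASet:
    """Normalize M within each array, then A-quantile across arrays."""
    params = params or NormalizationParams()
    Mn = np.column_stack(
        [
            loess_normalize_array(ma.M[:, j], ma.A[:, j], ma.W[:, j], params)
            for j in range(len(ma.arrays))
        ]
    )
    An = aquantile_normalize(ma.A, ma.W) if len(ma.arrays) >= 2 else ma.A.copy()
    return MASet(probes=list(ma.probes), arrays=list(ma.arrays), M=Mn, A=An, W=ma.W.copy())
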