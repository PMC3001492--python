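"""Temporal Hotelling T2 testing of the PE time course.

In ratio space the polynomial intercept cancels, so a second-degree
polynomial time trend b0 + b1*u + b2*u^2 of per-sample expression induces,
on an array hybridizing Cy3 time t_i against Cy5 time t_j,

    E[M] = b1*(u_j - u_i) + b2*(u_j^2 - u_i^2) + d

where u is a centred/scaled time coding and d is a constant absorbing the
dye bias.  A probe changes in time exactly when (b1, b2) != 0, which is
tested jointly with the Wald form of Hotelling's T2:

    T2 = bhat' Vhat^-1 bhat,   F = T2 / 2 ~ F(2, nu) under the null,

with Vhat the WLS covariance of (b1, b2) and nu the residual degrees of
freedom.  The F statistic depends only on the column span of the two time
columns, so any affine recoding of time gives identical p-values.
Benjamini-Hochberg correction across all testable probes at a 15% FDR is
the default significance rule.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.stats

from .array_io import MASet
from .design import DesignGraph
from .errors import DesignError


def time_coding(times: np.ndarray) -> tuple[float, float]:
    """Centre/scale constants (mean, sd with ddof 1) over the design times."""
    times = np.asarray(times, float)
    sd = float(times.std(ddof=1)) if times.size > 1 else 0.0
    return float(times.mean()), sd


def temporal_design_matrix(g: DesignGraph, coding: str = "scaled") -> np.ndarray:
    """Arrays x 3 design: [u(t_cy5) - u(t_cy3), u^2 difference, 1].

    `coding` is "scaled" (centre and divide by sd over the design's distinct
    times; the default, for conditioning), "centered", or "hours".  The
    joint test downstream is invariant to this choice.
    """
    for s in g.samples:
        if s.series != "PE" or s.time_h is None:
            raise DesignError(f"temporal design requires PE samples with times ({s.id})")
    tmap = {s.id: float(s.time_h) for s in g.samples}
    times = np.array(sorted(set(tmap.values())))
    if coding == "scaled":
        mu, sd = time_coding(times)
        sd = sd if sd > 0 else 1.0
    elif coding == "centered":
        mu, sd = float(times.mean()), 1.0
    elif coding == "hours":
        mu, sd = 0.0, 1.0
    else:
        raise ValueError(f"unknown time coding {coding!r}")
    rows = []
    for a in g.arrays:
        ui = (tmap[a.cy3_sample] - mu) / sd
        uj = (tmap[a.cy5_sample] - mu) / sd
        rows.append([uj - ui, uj**2 - ui**2, 1.0])
    return np.asarray(rows)


def hotelling_temporal_test(
    ma: MASet, X: np.ndarray, level: float = 0.15
) -> pd.DataFrame:
    """Per-probe joint Wald (Hotelling T2) test of the time coefficients.

    `ma` must be restricted to the PE arrays in the row order of `X`.
    Returns one row per probe: beta1, beta2, dye, s2, nu, T2, F, p, q,
    call (q <= level) and status.  Probes with fewer than 4 usable arrays
    or a singular time-coefficient covariance are "untestable" (excluded
    from the BH family); zero-residual probes with nonzero coefficients are
    "degenerate" with p = 0.
    """
    from .effects import _batched_wls  # shared WLS core

    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    X = np.asarray(X, float)
    if X.shape[0] != len(ma.arrays):
        raise ValueError("design matrix rows must match ma arrays")
    beta, s2, nu, ok, xtwx_inv = _batched_wls(X, ma.M, ma.W)
    n = len(ma.probes)
    ok = ok & (nu >= 1) & ((np.where(np.isfinite(ma.M), ma.W, 0) > 0).sum(axis=1) >= 4)
    bs = beta[:, :2]
    cov_s = xtwx_inv[:, :2, :2]  # multiply by s2 for Vhat
    det = cov_s[:, 0, 0] * cov_s[:, 1, 1] - cov_s[:, 0, 1] * cov_s[:, 1, 0]
    singular = ~(det > 1e-300)
    inv = np.empty_like(cov_s)
    with np.errstate(invalid="ignore", divide="ignore"):
        inv[:, 0, 0] = cov_s[:, 1, 1] / det
        inv[:, 1, 1] = cov_s[:, 0, 0] / det
        inv[:, 0, 1] = -cov_s[:, 0, 1] / det
        inv[:, 1, 0] = -cov_s[:, 1, 0] / det
        quad = np.einsum("nk,nkl,nl->n", bs, inv, bs, optimize=True)
        T2 = quad / s2
    degenerate = ok & ~singular & (s2 <= 1e-20) & (quad > 1e-12)
    testable = ok & ~singular & ~degenerate
    F = T2 / 2.0
    with np.errstate(invalid="ignore"):
        p = scipy.stats.f.sf(F, 2, np.maximum(nu, 1))
    # a probe with no signal and no noise carries no evidence of change
    null_flat = ok & ~singular & (s2 <= 1e-20) & (quad <= 1e-12)
    F = np.where(degenerate, np.inf, np.where(null_flat, 0.0, F))
    T2 = np.where(degenerate, np.inf, np.where(null_flat, 0.0, T2))
    p = np.where(degenerate, 0.0, np.where(null_flat, 1.0, p))
    p = np.where(ok & ~singular, p, np.nan)
    q, call = bh_fdr(p, level)
    status = np.full(n, "ok", dtype=object)
    status[~ok | singular] = "untestable"
    status[degenerate] = "degenerate"
    return pd.DataFrame(
        {
            "probe_id": ma.probes,
            "beta1": np.where(ok, beta[:, 0], np.nan),
            "beta2": np.where(ok, beta[:, 1], np.nan),
            "dye": np.where(ok, beta[:, 2], np.nan),
            "s2": np.where(ok, s2, np.nan),
            "nu": nu,
            "T2": T2,
            "F": F,
            "p": p,
            "q": q,
            "call": call,
            "status": status,
        }
    )


def bh_fdr(p: np.ndarray, level: float) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg linear step-up adjustment.

    q_(i) = min_{j >= i} m * p_(j) / j, clipped at 1, over the m non-missing
    p-values; calls are q <= level.  Missing p-values get missing q and no
    call.
    """
    p = np.asarray(p, float)
    q = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    m = int(ok.sum())
    if m:
        ps = p[ok]
        order = np.argsort(ps, kind="mergesort")
        ranked = ps[order] * m / np.arange(1, m + 1)
        qs = np.minimum.accumulate(ranked[::-1])[::-1]
        qv = np.empty(m)
        qv[order] = np.minimum(qs, 1.0)
        q[ok] = qv
    with np.errstate(invalid="ignore"):
        call = np.where(ok, q <= level, False).astype(bool)
    return q, call
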