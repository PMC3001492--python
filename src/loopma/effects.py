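"""Per-probe expression effects over the hybridization graph.

Every array measures a *difference* of two samples' log2 expression plus a
dye offset, so per-probe expression levels are only defined relative to a
reference sample.  With the loop + round-robin + bridge design the
sample-effect design matrix (array incidence with the reference column
dropped, plus a constant dye column) has full rank, and weighted least
squares over a probe's M values across all arrays recovers:

    e_s   log2 expression of sample s relative to the reference
    d     a constant dye offset (the polynomial intercept of M space)
    s2,nu residual variance and degrees of freedom

`fit_epi_pairwise` is the stage-wise analysis of the epicardial series: the
linear model "stage + dye" on the 12 Epi-Epi arrays, followed by t tests of
all 6 pairwise stage contrasts with Benjamini-Hochberg correction across
probes within each contrast family (default significance: adjusted p below
0.01%).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import scipy.stats

from .array_io import MASet
from .design import DesignGraph
from .errors import EstimabilityError
from .temporal import bh_fdr

_SV_TOL = 1e-8
_DEGEN_S2 = 1e-20  # below this the residual variance is numerically zero


@dataclass
class SampleEffects:
    """Per-probe log2 expression per sample, relative to a reference."""

    probes: list[str]
    samples: list[str]  # includes the reference
    reference: str
    effects: np.ndarray  # probes x samples; reference column identically 0
    dye: np.ndarray  # per-probe dye offset
    s2: np.ndarray  # per-probe residual variance
    nu: np.ndarray  # per-probe residual df
    status: np.ndarray  # "ok" | "untestable"
    cov_unscaled: np.ndarray  # samples x samples covariance factor of the
    # effect estimates under unit weights (reference row/col zero); multiply
    # by s2 for a probe's effect covariance when all its spots are usable

    def frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.effects, index=self.probes, columns=self.samples)
        df.index.name = "probe_id"
        df["dye"] = self.dye
        df["s2"] = self.s2
        df["nu"] = self.nu
        df["status"] = self.status
        return df


def _batched_wls(
    X: np.ndarray, M: np.ndarray, W: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """WLS of each probe's M row on X with per-probe weights.

    Returns (beta, s2, nu, ok, xtwx_inv) with shapes (n, p), (n,), (n,),
    (n,), (n, p, p).  Probes whose weighted design is rank deficient or
    whose usable-array count is below p + 1 get ok=False.
    """
    n_arr, p = X.shape
    Wc = np.where(np.isfinite(M), W, 0.0)
    Mc = np.where(np.isfinite(M), M, 0.0)
    usable = (Wc > 0).sum(axis=1)
    # XtWX: n x p x p, XtWy: n x p
    xtwx = np.einsum("ak,na,aj->nkj", X, Wc, X, optimize=True)
    xtwy = np.einsum("ak,na,na->nk", X, Wc, Mc, optimize=True)
    # pseudo-inverse via eigen-decomposition (xtwx symmetric PSD)
    evals, evecs = np.linalg.eigh(xtwx)
    maxev = evals[:, -1]
    good = evals > np.maximum(maxev[:, None] * _SV_TOL, 1e-300)
    inv_evals = np.where(good, 1.0 / np.where(good, evals, 1.0), 0.0)
    xtwx_inv = np.einsum("nkj,nj,nlj->nkl", evecs, inv_evals, evecs, optimize=True)
    beta = np.einsum("nkl,nl->nk", xtwx_inv, xtwy, optimize=True)
    fitted = beta @ X.T
    resid = Mc - fitted
    rss = np.einsum("na,na->n", Wc, resid**2, optimize=True)
    rank = good.sum(axis=1)
    nu = usable - rank
    ok = (rank == p) & (usable >= p + 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        s2 = np.where(nu > 0, rss / np.maximum(nu, 1), np.nan)
    s2 = np.maximum(s2, 0.0)
    return beta, s2, nu.astype(int), ok, xtwx_inv


def estimate_sample_effects(
    ma: MASet, g: DesignGraph, reference: str
) -> SampleEffects:
    """Weighted least-squares sample effects over the full design graph."""
    report_X, cols = g.effect_design_matrix(reference)
    rank = np.linalg.matrix_rank(report_X)
    if rank < report_X.shape[1]:
        raise EstimabilityError(
            "design matrix is rank deficient "
            f"(rank {rank} < {report_X.shape[1]}); see validate_design"
        )
    order = [ma.arrays.index(a.array_id) for a in g.arrays]
    M = ma.M[:, order]
    W = ma.W[:, order]
    beta, s2, nu, ok, _ = _batched_wls(report_X, M, W)
    n = len(ma.probes)
    samples = g.sample_ids
    effects = np.zeros((n, len(samples)))
    for j, sid in enumerate(samples):
        if sid == reference:
            continue
        effects[:, j] = beta[:, cols.index(sid)]
    dye = beta[:, cols.index("dye")]
    status = np.where(ok, "ok", "untestable")
    effects[~ok] = np.nan
    effects[:, samples.index(reference)] = 0.0
    # unit-weight covariance factor of the effect estimates, for downstream
    # null calibration; embed into the full sample order with zero ref row/col
    xtx_inv = np.linalg.inv(report_X.T @ report_X)
    cov = np.zeros((len(samples), len(samples)))
    eff_idx = [cols.index(s) for s in samples if s != reference]
    sub = [j for j, s in enumerate(samples) if s != reference]
    cov[np.ix_(sub, sub)] = xtx_inv[np.ix_(eff_idx, eff_idx)]
    return SampleEffects(
        probes=list(ma.probes),
        samples=list(samples),
        reference=reference,
        effects=effects,
        dye=np.where(ok, dye, np.nan),
        s2=np.where(ok, s2, np.nan),
        nu=nu,
        status=status,
        cov_unscaled=cov,
    )


def epi_stage_design(g_epi: DesignGraph) -> tuple[np.ndarray, list[str]]:
    """Stage-difference design (reference = first stage) plus dye column."""
    stages = [s.id for s in g_epi.samples]
    return g_epi.effect_design_matrix(stages[0])


def fit_epi_pairwise(
    ma: MASet, g: DesignGraph, alpha: float = 0.0001
) -> pd.DataFrame:
    """Stage+dye linear model on Epi-Epi arrays; all pairwise stage contrasts.

    Returns a long table with one row per probe per stage pair: contrast
    estimate (log2), t statistic, two-sided p, BH-adjusted q within the
    contrast family, and the significance call q < alpha.  Probes with zero
    residual variance but a nonzero contrast are flagged "degenerate" with
    p = 0; probes with too few usable arrays are "untestable" and excluded
    from the BH families.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    g_epi = g.subgraph("EPI")
    stages = g_epi.sample_ids
    if len(stages) < 2:
        raise EstimabilityError("need at least 2 Epi stages")
    X, cols = epi_stage_design(g_epi)
    ma_epi = ma.subset_arrays(g_epi.array_ids)
    beta, s2, nu, ok, xtwx_inv = _batched_wls(X, ma_epi.M, ma_epi.W)
    n = len(ma.probes)
    ref = stages[0]
    # contrast vectors: effect(stage_b) - effect(stage_a) over the parameters
    pairs = list(combinations(stages, 2))
    rows = []
    for sa, sb in pairs:
        c = np.zeros(X.shape[1])
        if sb != ref:
            c[cols.index(sb)] += 1.0
        if sa != ref:
            c[cols.index(sa)] -= 1.0
        est = beta @ c
        var_c = np.einsum("k,nkl,l->n", c, xtwx_inv, c, optimize=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            se = np.sqrt(s2 * var_c)
            t = est / se
        degenerate = ok & (s2 <= _DEGEN_S2) & (np.abs(est) > 1e-8)
        t = np.where(degenerate, np.inf * np.sign(est), t)
        with np.errstate(invalid="ignore"):
            p = 2.0 * scipy.stats.t.sf(np.abs(t), df=np.maximum(nu, 1))
        p = np.where(degenerate, 0.0, p)
        p = np.where(ok & (nu >= 1), p, np.nan)
        q, call = bh_fdr(p, alpha)
        status = np.where(~ok | (nu < 1), "untestable", np.where(degenerate, "degenerate", "ok"))
        rows.append(
            pd.DataFrame(
                {
                    "probe_id": ma.probes,
                    "stage_a": sa,
                    "stage_b": sb,
                    "estimate": est,
                    "t": t,
                    "p": p,
                    "q": q,
                    "call": call,
                    "status": status,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)
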