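"""Expression-profile clustering and the divergent-template screen.

Two profile analyses run on the estimated per-sample expression levels:

* **Clustering** (temporally significant genes): profiles are z-scored per
  probe and grouped by k-means.  On unit-variance rows the squared
  Euclidean distance is an affine function of the Pearson correlation,
  1 - r(x, y) = ||x - y||^2 / (2(n-1)), so the k-means objective is
  exactly clustering on correlation distance.

* **Divergence screen** ("epicardial lock" candidates): each probe's
  12-point profile (8 PE time points ++ 4 Epi stages, z-scored per series
  segment) is correlated with a library of *discordant* templates — shapes
  whose PE and Epi trends disagree (e.g. transiently up in the
  differentiating PE explant while monotonically down during epicardial
  maturation).  The best |r| per probe is tested, BH-corrected across
  probes, and called when q < 1% and |r| > 0.6.

The default best-template p-value is calibrated against the Monte-Carlo
null distribution of the max-|r| statistic itself (null profiles drawn
with the design covariance of the effect estimates and z-scored per
segment), because a textbook per-correlation t transform ignores both the
best-of-library selection and the degrees of freedom consumed by the
segment z-scoring, and would not deliver the nominal false-discovery rate.
The t transform remains available as ``p_method="t"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.cluster import KMeans

from .design import EPI_STAGES, PE_TIMES_H
from .effects import SampleEffects
from .errors import ParameterError

_NULL_CAL_SEED = 20460  # fixed internal seed: calibration is deterministic
_NULL_CAL_DRAWS = 1_000_000


# ----------------------------------------------------------------------
# z-scoring
# ----------------------------------------------------------------------

def zscore_profiles(
    profiles: pd.DataFrame, segments: list[list[str]] | None = None
) -> tuple[pd.DataFrame, pd.Index]:
    """Z-score each probe's profile per declared segment (ddof 1).

    `segments` is a list of column groups (default: one segment spanning
    all columns).  Probes flat (zero variance) in any segment are excluded;
    their ids are returned separately.
    """
    if segments is None:
        segments = [list(profiles.columns)]
    out = profiles.copy().astype(float)
    flat = pd.Series(False, index=profiles.index)
    for cols in segments:
        block = profiles[cols].to_numpy(float)
        mu = block.mean(axis=1, keepdims=True)
        sd = block.std(axis=1, ddof=1, keepdims=True)
        zero = (sd[:, 0] <= 0) | ~np.isfinite(sd[:, 0])
        flat |= pd.Series(zero, index=profiles.index)
        with np.errstate(invalid="ignore", divide="ignore"):
            out[cols] = (block - mu) / sd
    kept = out.loc[~flat]
    return kept, profiles.index[flat]


# ----------------------------------------------------------------------
# clustering
# ----------------------------------------------------------------------

@dataclass
class ClusterModel:
    k: int
    assignments: pd.Series  # probe -> 1..k
    centroids: np.ndarray  # k x profile length, re-standardized (z-scale)
    inertia: float
    seed: int
    restarts: int


def kmeans_profiles(
    Z: pd.DataFrame,
    k: int,
    restarts: int = 50,
    seed: int = 0,
    max_iter: int = 300,
) -> ClusterModel:
    """K-means on z-scored profiles; squared-Euclidean = correlation distance.

    Best of `restarts` random initializations by inertia; deterministic
    under a fixed seed.
    """
    if k < 1:
        raise ParameterError("k must be >= 1")
    if k > len(Z):
        raise ParameterError(f"k={k} exceeds the number of profiles ({len(Z)})")
    km = KMeans(
        n_clusters=k,
        n_init=restarts,
        max_iter=max_iter,
        random_state=seed,
        algorithm="lloyd",
    ).fit(Z.to_numpy(float))
    centroids = km.cluster_centers_
    mu = centroids.mean(axis=1, keepdims=True)
    sd = centroids.std(axis=1, ddof=1, keepdims=True)
    sd[sd <= 0] = 1.0
    return ClusterModel(
        k=k,
        assignments=pd.Series(km.labels_ + 1, index=Z.index, name="cluster"),
        centroids=(centroids - mu) / sd,
        inertia=float(km.inertia_),
        seed=seed,
        restarts=restarts,
    )


# ----------------------------------------------------------------------
# divergent templates
# ----------------------------------------------------------------------

@dataclass
class TemplateLibrary:
    """Named 12-point divergent shapes: 8 PE positions ++ 4 Epi positions.

    Each series segment is z-scored (zero mean, unit sd) so correlations
    weight the two series on a common scale.
    """

    names: list[str]
    vectors: np.ndarray  # n_templates x 12
    n_pe: int = 8
    n_epi: int = 4

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, float)
        if self.vectors.shape != (len(self.names), self.n_pe + self.n_epi):
            raise ParameterError("template matrix shape does not match names/positions")

    def frame(self) -> pd.DataFrame:
        cols = [f"PE_{i}" for i in range(self.n_pe)] + [f"EPI_{i}" for i in range(self.n_epi)]
        return pd.DataFrame(self.vectors, index=self.names, columns=cols)

    def write(self, path) -> None:
        self.frame().rename_axis("template").to_csv(path, sep="\t", float_format="%.10g")

    @classmethod
    def read(cls, path, n_pe: int = 8, n_epi: int = 4) -> "TemplateLibrary":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(names=[str(i) for i in df.index], vectors=df.to_numpy(float), n_pe=n_pe, n_epi=n_epi)


def _zseg(v: np.ndarray) -> np.ndarray:
    return (v - v.mean()) / v.std(ddof=1)


def _pe_shapes(times: np.ndarray) -> dict[str, np.ndarray]:
    t = np.asarray(times, float)
    up = _zseg(np.arange(t.size, dtype=float))
    bump = np.exp(-(((t - 36.0) / 24.0) ** 2))  # transient peak in the 24-48 h window
    return {
        "PE-up": up,
        "PE-down": -up,
        "PE-transient-up": _zseg(bump),
        "PE-transient-down": _zseg(-bump),
    }


def _epi_shapes(n_stages: int) -> dict[str, np.ndarray]:
    up = _zseg(np.arange(n_stages, dtype=float))
    return {"Epi-up": up, "Epi-down": -up}


def default_templates(
    pe_times: tuple[float, ...] = PE_TIMES_H, n_epi: int = len(EPI_STAGES)
) -> TemplateLibrary:
    """Six discordant PE/Epi shape combinations.

    Monotone PE trends pair only with the opposite Epi trend; the transient
    PE shapes (no net trend) pair with both Epi directions.  Concordant
    combinations (same monotone trend in both series) are deliberately
    absent: the screen looks for genes whose behaviour *diverges* between
    cardiomyocyte differentiation and epicardial maturation.
    """
    pe = _pe_shapes(np.asarray(pe_times))
    epi = _epi_shapes(n_epi)
    combos = [
        ("PE-up", "Epi-down"),
        ("PE-down", "Epi-up"),
        ("PE-transient-up", "Epi-down"),
        ("PE-transient-up", "Epi-up"),
        ("PE-transient-down", "Epi-down"),
        ("PE-transient-down", "Epi-up"),
    ]
    names = [f"{a}/{b}" for a, b in combos]
    vectors = np.array([np.concatenate([pe[a], epi[b]]) for a, b in combos])
    return TemplateLibrary(names=names, vectors=vectors, n_pe=len(pe_times), n_epi=n_epi)


# ----------------------------------------------------------------------
# divergence screen
# ----------------------------------------------------------------------

def _profile_matrix(
    effects: SampleEffects, pe_order: list[str], epi_order: list[str]
) -> pd.DataFrame:
    df = pd.DataFrame(effects.effects, index=effects.probes, columns=effects.samples)
    df = df.loc[np.asarray(effects.status) == "ok", pe_order + epi_order]
    return df


def _correlate_all(Z: np.ndarray, templates: TemplateLibrary) -> np.ndarray:
    """Pearson r of every (segment-z-scored) profile with every template."""
    T = templates.vectors
    Zc = Z - Z.mean(axis=1, keepdims=True)
    Tc = T - T.mean(axis=1, keepdims=True)
    num = Zc @ Tc.T
    den = np.sqrt((Zc**2).sum(axis=1))[:, None] * np.sqrt((Tc**2).sum(axis=1))[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        return num / den


_null_cache: dict[tuple, np.ndarray] = {}


def _null_max_abs_r(
    templates: TemplateLibrary,
    cov: np.ndarray | None,
    n_draws: int,
    seed: int,
) -> np.ndarray:
    """Sorted Monte-Carlo null sample of max-|r| over the template library.

    Null profiles are Gaussian with covariance `cov` (the design covariance
    of the effect estimates; identity when None), z-scored per segment like
    the observed profiles.
    """
    key = (
        templates.vectors.tobytes(),
        None if cov is None else np.asarray(cov).round(12).tobytes(),
        n_draws,
        seed,
    )
    if key in _null_cache:
        return _null_cache[key]
    rng = np.random.default_rng(seed)
    n_pos = templates.n_pe + templates.n_epi
    if cov is None:
        draws = rng.standard_normal((n_draws, n_pos))
    else:
        evals, evecs = np.linalg.eigh(cov)
        evals = np.clip(evals, 0.0, None)
        L = evecs * np.sqrt(evals)
        draws = rng.standard_normal((n_draws, n_pos)) @ L.T
    for sl in (slice(0, templates.n_pe), slice(templates.n_pe, n_pos)):
        block = draws[:, sl]
        mu = block.mean(axis=1, keepdims=True)
        sd = block.std(axis=1, ddof=1, keepdims=True)
        sd[sd <= 0] = 1.0
        draws[:, sl] = (block - mu) / sd
    r = _correlate_all(draws, templates)
    out = np.sort(np.nanmax(np.abs(r), axis=1))
    _null_cache[key] = out
    return out


def divergence_screen(
    effects: SampleEffects,
    templates: TemplateLibrary | None = None,
    fdr_level: float = 0.01,
    r_min: float = 0.6,
    pe_order: list[str] | None = None,
    epi_order: list[str] | None = None,
    p_method: str = "null",
    n_null: int = _NULL_CAL_DRAWS,
) -> pd.DataFrame:
    """Screen probes for divergent PE-vs-Epi profiles by template correlation.

    Per probe: the profile (PE then Epi positions, z-scored per segment) is
    correlated with every template; the largest |r| is tested (p from the
    calibrated max-|r| null by default, or the per-correlation t transform
    with n = 12 when ``p_method="t"``); BH across probes; call when
    q < fdr_level and |r| > r_min.  Probes flat in either segment are
    excluded with status "flat".
    """
    from .temporal import bh_fdr

    templates = templates or default_templates()
    if pe_order is None:
        pe_order = [s for s in effects.samples if s.startswith("PE")]
    if epi_order is None:
        epi_order = [s for s in effects.samples if s.startswith("EPI")]
    if len(pe_order) != templates.n_pe or len(epi_order) != templates.n_epi:
        raise ParameterError("profile positions do not match the template library")
    raw = _profile_matrix(effects, pe_order, epi_order)
    Z, flat = zscore_profiles(raw, segments=[pe_order, epi_order])
    r_all = _correlate_all(Z.to_numpy(float), templates)
    best_idx = np.argmax(np.abs(r_all), axis=1)
    best_r = r_all[np.arange(len(Z)), best_idx]
    n_pos = templates.n_pe + templates.n_epi
    if p_method == "null":
        order = [effects.samples.index(s) for s in pe_order + epi_order]
        cov = effects.cov_unscaled[np.ix_(order, order)]
        null = _null_max_abs_r(templates, cov, n_null, _NULL_CAL_SEED)
        exceed = null.size - np.searchsorted(null, np.abs(best_r), side="left")
        p = (1.0 + exceed) / (1.0 + null.size)
    elif p_method == "t":
        with np.errstate(invalid="ignore", divide="ignore"):
            tstat = best_r * np.sqrt((n_pos - 2) / np.maximum(1.0 - best_r**2, 1e-300))
        p = 2.0 * scipy.stats.t.sf(np.abs(tstat), df=n_pos - 2)
    else:
        raise ParameterError(f"unknown p_method {p_method!r}")
    q, _ = bh_fdr(p, fdr_level)
    call = (q < fdr_level) & (np.abs(best_r) > r_min)
    hits = pd.DataFrame(
        {
            "probe_id": Z.index,
            "best_template": [templates.names[i] for i in best_idx],
            "r": best_r,
            "p": p,
            "q": q,
            "call": call,
            "status": "ok",
        }
    )
    if len(flat):
        excl = pd.DataFrame(
            {
                "probe_id": flat,
                "best_template": "",
                "r": np.nan,
                "p": np.nan,
                "q": np.nan,
                "call": False,
                "status": "flat",
            }
        )
        hits = pd.concat([hits, excl], ignore_index=True)
    return hits
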