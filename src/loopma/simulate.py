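"""Forward simulation of the 32-array two-colour study.

Generates GenePix-style spot tables, the design tables and a ground-truth
record for the full study layout (8-point PE loop, 4-stage Epi round robin,
2 dye-swapped bridges), so every downstream stage is testable without any
external download.  The generative model works on the log2 scale:

    per spot:  M = e[cy5] - e[cy3] + d_a + c(A) + eps,   eps ~ N(0, sigma^2)
               A = baseline_probe + shift_array + eta
    channels:  R = 2^(A + M/2),  G = 2^(A - M/2)

with a per-array constant dye offset d_a, a smooth intensity-dependent dye
trend c(A) = amp * sin(A / period) (a shape a loess fit must remove but
quantile steps must not), per-array scale shifts of A, and a configurable
fraction of flagged spots whose intensities are corrupted.  Intensities are
written at full floating precision rather than rounded to integer counts so
that noiseless runs reproduce the truth to machine accuracy.

Probe classes (fractions configurable; remainder is null):

* temporal    — PE expression follows b1*u + b2*u^2 in scaled time, with
                coefficient magnitudes calibrated to ~80% marginal power of
                the temporal test at sigma 0.3 under the BH-15% rule
* cluster     — one of four smooth PE archetype shapes (up, down,
                transient-up, transient-down), for clustering-recovery tests
* divergent   — a scaled discordant PE/Epi template from the default
                library, scaled to a target signal-to-noise ratio
* concordant  — the same monotone trend in both series (a shape the
                divergence screen must *not* call)
* epi_diff    — optional planted Epi stage differences (linear across
                stages), for the pairwise-contrast tests
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import design as design_mod
from .array_io import MASet, SpotDialect
from .design import DesignGraph
from .errors import ConfigError, InputError
from .profiles import _pe_shapes, default_templates


@dataclass(frozen=True)
class SimulationConfig:
    n_probes: int = 20460  # platform size: long-oligo probes printed in singlets
    seed: int = 0
    noise_sd: float = 0.3  # spot-level log2 noise on M
    dye_offset_sd: float = 0.1  # per-array constant dye offset
    dye_trend_amplitude: float = 0.8  # c(A) = amp * sin(A / period)
    dye_trend_period: float = 2.0
    flag_rate: float = 0.02
    baseline_mean: float = 10.0  # per-probe log2 abundance
    baseline_sd: float = 1.2
    array_shift_sd: float = 0.3  # array-scale differences in A
    a_noise_sd: float = 0.15  # spot-level noise in A
    background_level: float = 16.0  # emitted local background (counts)
    # probe-class fractions; the remainder is null
    frac_temporal: float = 0.10
    frac_cluster: float = 0.10
    frac_divergent: float = 0.05
    frac_concordant: float = 0.05
    n_epi_diff: int = 0  # planted Epi-differential probes (count, not fraction)
    epi_diff_log2: float = 4.0  # total first-to-last stage difference
    # temporal effect sizes (|b1|, |b2| uniform ranges, random signs);
    # calibrated once to ~0.8 power at sigma=0.3, BH 15%, 10% signal
    beta1_range: tuple[float, float] = (0.2, 0.4)
    beta2_range: tuple[float, float] = (0.15, 0.35)
    n_archetypes: int = 4
    archetype_log2: float = 1.0  # peak-to-sd scale of archetype shapes
    divergent_snr: float = 3.0  # per-sample signal sd / effect-estimate noise sd
    concordant_snr: float = 3.0

    def __post_init__(self) -> None:
        if self.n_probes < 100:
            raise ConfigError("n_probes must be >= 100")
        if self.noise_sd < 0 or self.flag_rate < 0 or self.flag_rate > 1:
            raise ConfigError("negative rates are not a thing")
        total = (
            self.frac_temporal
            + self.frac_cluster
            + self.frac_divergent
            + self.frac_concordant
        )
        if min(
            self.frac_temporal,
            self.frac_cluster,
            self.frac_divergent,
            self.frac_concordant,
        ) < 0 or total > 1:
            raise ConfigError("class fractions must be >= 0 and sum to <= 1")


@dataclass
class SyntheticTruth:
    """Per-probe class labels and generating parameters; per-array nuisances."""

    classes: pd.Series  # probe -> class label
    effects: pd.DataFrame  # probes x samples, absolute log2 expression offsets
    beta: pd.DataFrame  # temporal probes: true (beta1, beta2) in scaled time
    templates: pd.Series  # divergent probes -> template name
    archetypes: pd.Series  # cluster probes -> archetype label
    arrays: pd.DataFrame  # per array: dye_offset, shift

    def positives(self, cls: str) -> pd.Index:
        return self.classes.index[self.classes == cls]

    def write(self, directory) -> None:
        probe_tbl = self.effects.copy()
        probe_tbl.insert(0, "class", self.classes)
        probe_tbl["beta1"] = self.beta["beta1"].reindex(probe_tbl.index)
        probe_tbl["beta2"] = self.beta["beta2"].reindex(probe_tbl.index)
        probe_tbl["template"] = self.templates.reindex(probe_tbl.index).fillna("")
        probe_tbl["archetype"] = self.archetypes.reindex(probe_tbl.index).fillna("")
        probe_tbl.rename_axis("probe_id").to_csv(
            f"{directory}/truth_probes.tsv", sep="\t", float_format="%.10g"
        )
        self.arrays.rename_axis("array_id").to_csv(
            f"{directory}/truth_arrays.tsv", sep="\t", float_format="%.10g"
        )


@dataclass
class SyntheticStudy:
    config: SimulationConfig
    design: DesignGraph
    truth: SyntheticTruth
    probes: list[str]
    R: np.ndarray  # probes x arrays red (Cy5) foreground medians
    G: np.ndarray  # green (Cy3) foreground medians
    B_red: np.ndarray
    B_green: np.ndarray
    flags: np.ndarray  # integer flags, negative = flagged

    def maset(self, background_policy: str = "none") -> MASet:
        """M/A/W straight from the generated intensities (fast path).

        Equivalent to writing the spot tables and re-reading them through
        `array_io` (asserted in the test suite).
        """
        R, G = self.R, self.G
        if background_policy == "subtract":
            R = R - self.B_red
            G = G - self.B_green
        ok = (R > 0) & (G > 0)
        with np.errstate(invalid="ignore", divide="ignore"):
            lr = np.where(ok, np.log2(np.where(ok, R, 1.0)), np.nan)
            lg = np.where(ok, np.log2(np.where(ok, G, 1.0)), np.nan)
        M = np.where(ok, lr - lg, np.nan)
        A = np.where(ok, (lr + lg) / 2.0, np.nan)
        W = np.where(ok, np.where(self.flags < 0, 0.1, 1.0), 0.0)
        return MASet(
            probes=list(self.probes),
            arrays=self.design.array_ids,
            M=M,
            A=A,
            W=W,
        )

    def spot_table(self, array_id: str, dialect: SpotDialect | None = None) -> pd.DataFrame:
        dialect = dialect or SpotDialect()
        j = self.design.array_ids.index(array_id)
        return pd.DataFrame(
            {
                dialect.id_col: self.probes,
                dialect.flag_col: self.flags[:, j],
                dialect.f_red_col: self.R[:, j],
                dialect.b_red_col: self.B_red[:, j],
                dialect.f_green_col: self.G[:, j],
                dialect.b_green_col: self.B_green[:, j],
            }
        )

    def write(self, directory, dialect: SpotDialect | None = None) -> list[str]:
        """Write design tables, per-array spot tables and truth tables."""
        import os

        dialect = dialect or SpotDialect()
        os.makedirs(directory, exist_ok=True)
        design_mod.write_design_tables(
            self.design, f"{directory}/arrays.tsv", f"{directory}/samples.tsv"
        )
        paths = []
        for aid in self.design.array_ids:
            path = f"{directory}/spots_{aid}.tsv"
            df = self.spot_table(aid, dialect)
            with open(path, "w") as fh:
                fh.write("\t".join(df.columns) + "\n")
                flags = df[dialect.flag_col].to_numpy()
                mats = [df[c].to_numpy() for c in df.columns[2:]]
                idv = df[dialect.id_col].to_numpy()
                for i in range(len(df)):
                    fh.write(
                        f"{idv[i]}\t{flags[i]:d}\t"
                        + "\t".join(f"{m[i]:.17g}" for m in mats)
                        + "\n"
                    )
            paths.append(path)
        self.truth.write(directory)
        return paths


def _scaled_times(g_pe: DesignGraph) -> np.ndarray:
    times = np.array(sorted({float(s.time_h) for s in g_pe.samples}))
    mu, sd = times.mean(), times.std(ddof=1)
    return (times - mu) / sd


def _effect_noise_sd(g: DesignGraph, reference: str, sigma: float) -> float:
    """Typical sd of an estimated sample effect under unit spot weights."""
    X, _ = g.effect_design_matrix(reference)
    cov = np.linalg.inv(X.T @ X)
    d = np.diag(cov)[:-1]  # drop the dye column
    return float(sigma * np.sqrt(d.mean())) if sigma > 0 else 1.0


def simulate_study(config: SimulationConfig | None = None) -> SyntheticStudy:
    """Draw one synthetic study under `config` (fully reproducible by seed)."""
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    g = design_mod.study_design()
    samples = g.sample_ids
    n_samp = len(samples)
    n = config.n_probes
    probes = [f"PR{i + 1:06d}" for i in range(n)]

    pe_ids = [s.id for s in g.samples if s.series == "PE"]
    epi_ids = [s.id for s in g.samples if s.series == "EPI"]
    u = _scaled_times(g.subgraph("PE"))

    # ---- probe classes ------------------------------------------------
    counts = {
        "temporal": int(round(config.frac_temporal * n)),
        "cluster": int(round(config.frac_cluster * n)),
        "divergent": int(round(config.frac_divergent * n)),
        "concordant": int(round(config.frac_concordant * n)),
        "epi_diff": int(config.n_epi_diff),
    }
    if sum(counts.values()) > n:
        raise ConfigError("probe classes exceed n_probes")
    labels = np.array(["null"] * n, dtype=object)
    perm = rng.permutation(n)
    pos = 0
    idx_of: dict[str, np.ndarray] = {}
    for cls, cnt in counts.items():
        idx_of[cls] = perm[pos : pos + cnt]
        labels[idx_of[cls]] = cls
        pos += cnt

    effects = np.zeros((n, n_samp))
    col = {s: j for j, s in enumerate(samples)}
    pe_cols = [col[s] for s in pe_ids]
    epi_cols = [col[s] for s in epi_ids]

    beta = pd.DataFrame(columns=["beta1", "beta2"], dtype=float)
    it = idx_of["temporal"]
    if it.size:
        b1 = rng.uniform(*config.beta1_range, it.size) * rng.choice([-1.0, 1.0], it.size)
        b2 = rng.uniform(*config.beta2_range, it.size) * rng.choice([-1.0, 1.0], it.size)
        effects[np.ix_(it, pe_cols)] = np.outer(b1, u) + np.outer(b2, u**2)
        beta = pd.DataFrame(
            {"beta1": b1, "beta2": b2}, index=[probes[i] for i in it]
        )

    arch_names = list(_pe_shapes(np.array(design_mod.PE_TIMES_H)))[: config.n_archetypes]
    arch_shapes = _pe_shapes(np.array(design_mod.PE_TIMES_H))
    ic = idx_of["cluster"]
    arch_labels = pd.Series(dtype=object)
    if ic.size:
        which = rng.integers(0, len(arch_names), ic.size)
        for k, name in enumerate(arch_names):
            sel = ic[which == k]
            effects[np.ix_(sel, pe_cols)] = config.archetype_log2 * arch_shapes[name]
        arch_labels = pd.Series(
            [arch_names[w] for w in which], index=[probes[i] for i in ic]
        )

    lib = default_templates()
    eff_noise = _effect_noise_sd(g, samples[0], config.noise_sd)
    idv = idx_of["divergent"]
    tmpl_labels = pd.Series(dtype=object)
    if idv.size:
        which = rng.integers(0, len(lib.names), idv.size)
        scale = config.divergent_snr * eff_noise
        for k, name in enumerate(lib.names):
            sel = idv[which == k]
            vec = lib.vectors[k]
            effects[np.ix_(sel, pe_cols)] = scale * vec[: lib.n_pe]
            effects[np.ix_(sel, epi_cols)] = scale * vec[lib.n_pe :]
        tmpl_labels = pd.Series(
            [lib.names[w] for w in which], index=[probes[i] for i in idv]
        )

    ico = idx_of["concordant"]
    if ico.size:
        pe_up = (np.arange(len(pe_ids)) - (len(pe_ids) - 1) / 2.0)
        pe_up = pe_up / pe_up.std(ddof=1)
        epi_up = (np.arange(len(epi_ids)) - (len(epi_ids) - 1) / 2.0)
        epi_up = epi_up / epi_up.std(ddof=1)
        sign = rng.choice([-1.0, 1.0], ico.size)
        scale = config.concordant_snr * eff_noise
        effects[np.ix_(ico, pe_cols)] = np.outer(sign, scale * pe_up)
        effects[np.ix_(ico, epi_cols)] = np.outer(sign, scale * epi_up)

    ie = idx_of["epi_diff"]
    if ie.size:
        ramp = np.linspace(0.0, config.epi_diff_log2, len(epi_ids))
        effects[np.ix_(ie, epi_cols)] = ramp

    # ---- per-array nuisances and intensities --------------------------
    n_arr = len(g.arrays)
    dye_offset = rng.normal(0.0, config.dye_offset_sd, n_arr) if config.dye_offset_sd > 0 else np.zeros(n_arr)
    shift = rng.normal(0.0, config.array_shift_sd, n_arr) if config.array_shift_sd > 0 else np.zeros(n_arr)
    baseline = rng.normal(config.baseline_mean, config.baseline_sd, n)

    A = baseline[:, None] + shift[None, :]
    if config.a_noise_sd > 0:
        A = A + rng.normal(0.0, config.a_noise_sd, (n, n_arr))
    M = np.empty((n, n_arr))
    for j, arr in enumerate(g.arrays):
        M[:, j] = effects[:, col[arr.cy5_sample]] - effects[:, col[arr.cy3_sample]]
    M += dye_offset[None, :]
    if config.dye_trend_amplitude != 0:
        M += config.dye_trend_amplitude * np.sin(A / config.dye_trend_period)
    if config.noise_sd > 0:
        M += rng.normal(0.0, config.noise_sd, (n, n_arr))

    flags = np.zeros((n, n_arr), dtype=int)
    if config.flag_rate > 0:
        bad = rng.random((n, n_arr)) < config.flag_rate
        flags[bad] = -50
        M = M + np.where(bad, rng.normal(0.0, 2.0, (n, n_arr)), 0.0)
        A = A + np.where(bad, rng.normal(0.0, 1.0, (n, n_arr)), 0.0)

    R = np.exp2(A + M / 2.0)
    G = np.exp2(A - M / 2.0)
    B_red = config.background_level + np.abs(
        rng.normal(0.0, config.background_level / 8.0, (n, n_arr))
    )
    B_green = config.background_level + np.abs(
        rng.normal(0.0, config.background_level / 8.0, (n, n_arr))
    )

    truth = SyntheticTruth(
        classes=pd.Series(labels, index=probes, name="class"),
        effects=pd.DataFrame(effects, index=probes, columns=samples),
        beta=beta,
        templates=tmpl_labels,
        archetypes=arch_labels,
        arrays=pd.DataFrame(
            {"dye_offset": dye_offset, "shift": shift}, index=g.array_ids
        ),
    )
    return SyntheticStudy(
        config=config,
        design=g,
        truth=truth,
        probes=probes,
        R=R,
        G=G,
        B_red=B_red,
        B_green=B_green,
        flags=flags,
    )


# ----------------------------------------------------------------------
# evaluation against truth
# ----------------------------------------------------------------------

def evaluate_calls(calls: pd.Series, truth_positive) -> dict[str, float]:
    """False-discovery proportion and power of a boolean call vector.

    `calls` is indexed by probe id; `truth_positive` is an index/list of the
    planted-positive probe ids (must be a subset of the call index).
    """
    calls = calls.astype(bool)
    pos = pd.Index(truth_positive)
    if len(pos.intersection(calls.index)) != len(pos) or len(calls) == 0:
        raise InputError("call table and truth do not share probe ids")
    called = calls.index[calls]
    tp = len(called.intersection(pos))
    fp = len(called) - tp
    return {
        "n_calls": float(len(called)),
        "n_true": float(len(pos)),
        "fdp": fp / max(1, len(called)),
        "power": tp / len(pos) if len(pos) else float("nan"),
    }


def clustering_ari(labels: pd.Series, truth_labels: pd.Series) -> float:
    """Adjusted Rand index between a clustering and the generator's labels."""
    from sklearn.metrics import adjusted_rand_score

    common = labels.index.intersection(truth_labels.index)
    if len(common) == 0:
        raise InputError("clusterings share no probes")
    return float(adjusted_rand_score(truth_labels.loc[common], labels.loc[common]))


def beta_rmse(fit: pd.DataFrame, truth: SyntheticTruth) -> float:
    """RMSE of (beta1, beta2) over the planted temporal probes."""
    est = fit.set_index("probe_id")[["beta1", "beta2"]].reindex(truth.beta.index)
    if est.isna().all().all():
        raise InputError("no temporal probes in the fit table")
    diff = est.to_numpy(float) - truth.beta.to_numpy(float)
    return float(np.sqrt(np.nanmean(diff**2)))
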