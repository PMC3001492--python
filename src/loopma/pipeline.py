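"""End-to-end orchestration: spot tables -> calls, with a run manifest.

`run_all` executes ingestion, MA computation, normalization, sample-effect
estimation, the temporal test plus clustering of the significant probes,
the Epi pairwise contrasts, and the divergence screen plus clustering of
its hits.  Every stage writes a TSV under the output directory and logs a
stage-tagged line to stderr; the manifest records the configuration, seeds,
package versions and per-stage row counts so a run is self-describing and
reruns are byte-reproducible.
"""

from __future__ import annotations

import hashlib
import json
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .array_io import SpotDialect, maset_from_tables, read_spot_table
from .design import DesignGraph, read_design_tables
from .effects import estimate_sample_effects, fit_epi_pairwise
from .errors import ConfigError, InputError
from .normalize import NormalizationParams, normalize_maset
from .profiles import (
    TemplateLibrary,
    default_templates,
    divergence_screen,
    kmeans_profiles,
    zscore_profiles,
)
from .temporal import hotelling_temporal_test, temporal_design_matrix

@dataclass
class PipelineConfig:
    design_arrays: str = "arrays.tsv"
    design_samples: str = "samples.tsv"
    spot_dir: str = "."  # expects spots_<array_id>.tsv per array
    out_dir: str = "out"
    background_policy: str = "none"
    span: float = 0.25
    iterations: int = 2
    temporal_level: float = 0.15
    epi_alpha: float = 0.0001
    divergence_fdr: float = 0.01
    r_min: float = 0.6
    k_pe: int = 7
    k_divergence: int = 6
    restarts: int = 50
    seed: int = 0
    reference: str = "PE_000h"
    template_path: str | None = None

    def __post_init__(self) -> None:
        for name in ("temporal_level", "epi_alpha", "divergence_fdr"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ConfigError(f"{name} must be in (0, 1), got {v}")
        if self.k_pe < 1 or self.k_divergence < 1:
            raise ConfigError("cluster counts must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def _stage(name: str, msg: str) -> None:
    print(f"[{name}] {msg}", file=sys.stderr)


def _write(df: pd.DataFrame, path: Path, counts: dict, name: str) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    counts[name] = int(len(df))
    _stage(name, f"wrote {len(df)} rows -> {path}")


def load_maset(config: PipelineConfig, g: DesignGraph) -> MASet:
    dialect = SpotDialect()
    tables = {}
    for aid in g.array_ids:
        path = Path(config.spot_dir) / f"spots_{aid}.tsv"
        if not path.exists():
            raise InputError(f"missing spot table for array {aid!r}: {path}")
        try:
            tables[aid] = read_spot_table(path, dialect)
        except Exception as exc:
            raise InputError(f"ingest failed for {path}: {exc}") from exc
    return maset_from_tables(tables, g.array_ids, config.background_policy)


def run_all(config: PipelineConfig) -> dict:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}

    _stage("design", f"reading {config.design_arrays} / {config.design_samples}")
    g = read_design_tables(config.design_arrays, config.design_samples)
    from .design import validate_design

    report = validate_design(g, config.reference)
    if not report.ok:
        raise InputError(
            f"design validation failed: connected={report.connected} "
            f"rank={report.design_rank}/{report.required_rank}"
        )
    counts["arrays"] = len(g.arrays)
    counts["samples"] = len(g.samples)

    _stage("ingest", f"reading spot tables from {config.spot_dir}")
    ma = load_maset(config, g)
    counts["probes"] = len(ma.probes)

    _stage("normalize", f"span={config.span} iterations={config.iterations} + aquantile")
    params = NormalizationParams(span=config.span, iterations=config.iterations)
    man = normalize_maset(ma, params)
    man.write(out, prefix="normalized")

    _stage("effects", f"WLS sample effects, reference={config.reference}")
    eff = estimate_sample_effects(man, g, config.reference)
    eff_df = eff.frame().reset_index()
    _write(eff_df, out / "sample_effects.tsv", counts, "effects")

    _stage("temporal", f"Hotelling T2 at BH level {config.temporal_level}")
    g_pe = g.subgraph("PE")
    X = temporal_design_matrix(g_pe)
    tfit = hotelling_temporal_test(
        man.subset_arrays(g_pe.array_ids), X, config.temporal_level
    )
    _write(tfit, out / "temporal_fit.tsv", counts, "temporal")
    counts["temporal_calls"] = int(tfit["call"].sum())

    _stage("cluster", f"k-means (k={config.k_pe}) of temporally significant probes")
    sig = tfit.loc[tfit["call"], "probe_id"]
    pe_order = [s.id for s in g.samples if s.series == "PE"]
    prof = pd.DataFrame(eff.effects, index=eff.probes, columns=eff.samples)
    prof = prof.loc[prof.index.intersection(sig), pe_order]
    if len(prof) >= config.k_pe:
        Z, _flat = zscore_profiles(prof)
        model = kmeans_profiles(
            Z, config.k_pe, restarts=config.restarts, seed=config.seed
        )
        clus = model.assignments.rename_axis("probe_id").reset_index()
    else:
        _stage("cluster", f"only {len(prof)} significant probes; skipping k-means")
        clus = pd.DataFrame(columns=["probe_id", "cluster"])
    _write(clus, out / "temporal_clusters.tsv", counts, "temporal_clusters")

    _stage("epi", f"stage+dye pairwise contrasts at adjusted p < {config.epi_alpha}")
    efit = fit_epi_pairwise(man, g, config.epi_alpha)
    _write(efit, out / "epi_contrasts.tsv", counts, "epi")
    counts["epi_calls"] = int(efit["call"].sum())

    _stage("divergence", f"template screen (FDR {config.divergence_fdr}, |r|>{config.r_min})")
    templates = (
        TemplateLibrary.read(config.template_path)
        if config.template_path
        else default_templates()
    )
    hits = divergence_screen(
        eff, templates, fdr_level=config.divergence_fdr, r_min=config.r_min
    )
    _write(hits, out / "divergence_hits.tsv", counts, "divergence")
    counts["divergence_calls"] = int(hits["call"].sum())

    div_ids = hits.loc[hits["call"], "probe_id"]
    epi_order = [s.id for s in g.samples if s.series == "EPI"]
    dprof = pd.DataFrame(eff.effects, index=eff.probes, columns=eff.samples)
    dprof = dprof.loc[dprof.index.intersection(div_ids), pe_order + epi_order]
    if len(dprof) >= config.k_divergence:
        Zd, _flat = zscore_profiles(dprof, segments=[pe_order, epi_order])
        dmodel = kmeans_profiles(
            Zd, config.k_divergence, restarts=config.restarts, seed=config.seed
        )
        dclus = dmodel.assignments.rename_axis("probe_id").reset_index()
    else:
        dclus = pd.DataFrame(columns=["probe_id", "cluster"])
    _write(dclus, out / "divergence_clusters.tsv", counts, "divergence_clusters")

    config_text = yaml.safe_dump(asdict(config), sort_keys=True)
    stages = [
        "normalized",
        "sample_effects",
        "temporal_fit",
        "temporal_clusters",
        "epi_contrasts",
        "divergence_hits",
        "divergence_clusters",
    ]
    manifest = {
        "loopma_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "config": asdict(config),
        "config_sha256": hashlib.sha256(config_text.encode()).hexdigest(),
        "row_counts": counts,
        "stages": stages,
        "outputs": sorted(p.name for p in out.glob("*.tsv")),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    _stage("done", f"manifest -> {out / 'manifest.json'}")
    return manifest
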