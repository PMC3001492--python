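# loopma

Analysis pipeline for a two-colour, dye-swapped **looped microarray
time-course** comparing cardiomyocyte differentiation in proepicardial (PE)
explant cultures against epicardial (Epi) maturation in the chicken embryo,
including the screen for **"epicardial lock"** candidates — genes whose
temporal profiles diverge between the two lineages.

The study layout it implements: 8 PE samples (before explanting at HH16 =
0 h, then 14, 24, 36, 48, 60, 72 and 120 h in culture) hybridized as a
dye-swapped loop (16 arrays, 4 technical replicates per time point); 4 Epi
stages (HH25, HH29, HH32, HH37) hybridized as a dye-swapped round robin
(12 arrays, 6 replicates per stage); and two dye-swapped bridge
hybridizations (Epi HH25 and HH29 vs the PE explant at 48 h) that connect
the series — 32 arrays, ~20,460 long-oligo probes printed in singlets.

## What it computes

Each slide measures a log ratio per spot, `M = log2(R/G)`, at average log
intensity `A = (log2 R + log2 G)/2`. The pipeline:

1. **Design graph** (`loopma.design`) — samples as nodes, arrays as
   dye-directed edges; validates connectivity, per-sample dye balance and
   estimability (rank of incidence-minus-reference plus dye column).
2. **Ingestion** (`loopma.array_io`) — GenePix-style spot tables; control
   spots removed; flagged spots kept at weight 0.1.
3. **Normalization** (`loopma.normalize`) — within-array robust weighted
   smooth-curve fit of M on A (span 0.25, two-plus bisquare passes,
   idempotent projection form) and between-array quantile normalization of
   A only ("A-quantile").
4. **Sample effects** (`loopma.effects`) — per-probe weighted least squares
   over the whole graph: `E[M_a] = e[cy5(a)] − e[cy3(a)] + d`, giving log2
   expression per sample relative to a reference plus a dye offset.
5. **Temporal test** (`loopma.temporal`) — per-probe second-degree
   polynomial in (centred, scaled) time over the 16 PE arrays with a dye
   term; joint Wald/Hotelling test `T² = β̂ₛᵀ V̂ₛ⁻¹ β̂ₛ`, `F = T²/2 ~ F(2, ν)`
   of the linear+quadratic coefficients; Benjamini–Hochberg FDR at 15%.
6. **Profiles** (`loopma.profiles`) — z-scored profile k-means (squared
   Euclidean on unit-variance rows ≡ Pearson correlation distance;
   `1 − r = ‖x−y‖²/(2(n−1))`), and the divergence screen: each probe's
   12-point PE++Epi profile (z-scored per series) is correlated against a
   library of discordant templates; the best |r| is tested against the
   Monte-Carlo null of the max-|r| statistic, BH-corrected across probes,
   and called when q < 1% and |r| > 0.6.
7. **Synthetic studies** (`loopma.simulate`) — a forward model of the full
   32-array experiment (intensity-dependent dye trend, per-array dye
   offsets and scale shifts, flagged spots, planted temporal / archetype /
   divergent / concordant probe classes) with complete ground truth, so
   every stage is verifiable without any external data.

## Worked example

```sh
python analysis/01_simulate_study.py     # 32 spot tables under scratch/study/
python analysis/02_run_pipeline.py       # full pipeline -> scratch/pipeline/
python analysis/03_recovery_vs_truth.py  # score calls against ground truth
```

On the default simulated study (20,460 probes, seed 1) this prints:

```
design: 32 arrays, connected=True, dye_balanced=True, rank 12/12
pipeline call counts:
  temporal_calls: 4545
  epi_calls: 2463
  divergence_calls: 1205
temporal test: 4545 calls, FDP 0.084 vs any-PE-change truth, power 0.678
divergence screen: 1205 calls, FDP 0.164 vs planted-divergent truth ...
archetype clustering (k=4): ARI 1.000 over 2046 probes
polynomial coefficient RMSE over planted temporal probes: 0.0879
```

Reading: 30% of the simulated probes genuinely change during PE
differentiation (temporal, archetype, divergent and concordant classes),
and the temporal test recovers 68% of them with a realized false-discovery
proportion of 8% — inside its nominal 15% bound. The divergence screen
finds essentially all planted divergent probes; its FDP *against the
planted-divergent labels alone* is higher because archetype/temporal
probes with template-like PE shapes and flat Epi profiles are genuinely
divergent in shape, just not planted as such. The archetype clustering is
recovered perfectly, and the polynomial coefficients are recovered to
±0.09 on effects of size 0.2–0.4.

The same stages are scriptable through the CLI (`loopma simulate`,
`loopma normalize`, `loopma test-temporal`, `loopma test-epi`,
`loopma cluster`, `loopma divergence`, `loopma run-all --config cfg.yaml`).

## Layout

```
src/loopma/        the library (design, array_io, normalize, effects,
                   temporal, profiles, simulate, pipeline, cli)
analysis/          numbered narrative drivers over the library
tests/             pytest suite (unit, property and end-to-end checks)
scripts/           acceptance.py (operating-characteristic measurement)
docs/methods.md    models, assumptions, parameter choices, limitations
results/           small tables written by the analysis scripts
scratch/           large regenerable artifacts (not part of the deliverable)
```
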