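"""Simulate the full 32-array study and write its raw data.

Draws one synthetic study under the default conditions (20,460 probes in
singlets, 8-point PE loop + 4-stage Epi round robin + 2 dye-swapped
bridges, sigma = 0.3, intensity-dependent dye trend, 2% flagged spots,
70% null / 10% temporal / 10% archetype / 5% divergent / 5% concordant
probes) and writes the GenePix-style spot tables plus design and truth
tables under scratch/study/ (large, regenerable) and a small summary under
results/.

Run from the repository root:  python analysis/01_simulate_study.py
"""

import sys
from pathlib import Path

import pandas as pd

from loopma.design import validate_design
from loopma.simulate import SimulationConfig, simulate_study

OUT = Path("scratch/study")
RESULTS = Path("results")
SEED = 1


def main() -> None:
    cfg = SimulationConfig(seed=SEED)
    study = simulate_study(cfg)
    report = validate_design(study.design)
    print(
        f"design: {len(study.design.arrays)} arrays, "
        f"connected={report.connected}, dye_balanced={report.dye_balanced}, "
        f"rank {report.design_rank}/{report.required_rank}"
    )
    OUT.mkdir(parents=True, exist_ok=True)
    paths = study.write(OUT)
    print(f"wrote {len(paths)} spot tables ({cfg.n_probes} probes each) -> {OUT}/")

    RESULTS.mkdir(exist_ok=True)
    counts = study.truth.classes.value_counts().rename_axis("class").rename("n_probes")
    counts.to_frame().to_csv(RESULTS / "simulated_probe_classes.tsv", sep="\t")
    print("planted probe classes:")
    print(counts.to_string())
    flagged = float((study.flags < 0).mean())
    print(f"flagged spot fraction: {flagged:.4f} (target {cfg.flag_rate})")


if __name__ == "__main__":
    sys.exit(main())
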