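"""Score the pipeline's calls against the generator's ground truth.

Joins the call tables from 02_run_pipeline.py with the truth tables from
01_simulate_study.py and reports, per procedure, the realized
false-discovery proportion and power, the adjusted Rand index of the
archetype clustering, and the RMSE of the recovered polynomial
coefficients.  Note that in the full mixed simulation the archetype,
divergent and concordant classes also genuinely change in time, so they
count as true positives for the temporal test; only genuinely flat probes
count as false discoveries.

Run after 01 and 02:  python analysis/03_recovery_vs_truth.py
"""

import sys
from pathlib import Path

import pandas as pd

from loopma.profiles import zscore_profiles, kmeans_profiles
from loopma.simulate import beta_rmse, clustering_ari, evaluate_calls

STUDY = Path("scratch/study")
PIPE = Path("scratch/pipeline")
RESULTS = Path("results")


def main() -> int:
    if not (PIPE / "temporal_fit.tsv").exists():
        print("run analysis/02_run_pipeline.py first", file=sys.stderr)
        return 1
    truth = pd.read_csv(STUDY / "truth_probes.tsv", sep="\t", index_col="probe_id")
    rows = []

    tfit = pd.read_csv(PIPE / "temporal_fit.tsv", sep="\t").set_index("probe_id")
    changing = truth.index[truth["class"].isin(["temporal", "cluster", "divergent", "concordant"])]
    m = evaluate_calls(tfit["call"], changing)
    rows.append(("temporal_test_vs_any_PE_change", m["fdp"], m["power"], m["n_calls"]))
    print(
        f"temporal test: {int(m['n_calls'])} calls, FDP {m['fdp']:.3f} "
        f"vs any-PE-change truth, power {m['power']:.3f}"
    )

    hits = pd.read_csv(PIPE / "divergence_hits.tsv", sep="\t").set_index("probe_id")
    m = evaluate_calls(hits["call"], truth.index[truth["class"] == "divergent"])
    rows.append(("divergence_screen_vs_divergent", m["fdp"], m["power"], m["n_calls"]))
    print(
        f"divergence screen: {int(m['n_calls'])} calls, FDP {m['fdp']:.3f} "
        f"vs planted-divergent truth (archetype/temporal probes with "
        f"template-like PE shapes count as false here), power {m['power']:.3f}"
    )

    # archetype recovery: cluster the planted archetype probes at k = truth
    eff = pd.read_csv(PIPE / "sample_effects.tsv", sep="\t", index_col="probe_id")
    pe_cols = [c for c in eff.columns if c.startswith("PE_")]
    arch = truth.index[truth["class"] == "cluster"]
    Z, _ = zscore_profiles(eff.loc[arch, pe_cols].dropna())
    model = kmeans_profiles(Z, k=4, restarts=50, seed=0)
    ari = clustering_ari(model.assignments, truth.loc[arch, "archetype"])
    rows.append(("archetype_kmeans_ari", ari, float("nan"), len(Z)))
    print(f"archetype clustering (k=4): ARI {ari:.3f} over {len(Z)} probes")

    temporal_truth = truth.loc[truth["class"] == "temporal", ["beta1", "beta2"]]
    est = tfit.reset_index()[["probe_id", "beta1", "beta2"]]

    class _T:  # minimal truth adapter for beta_rmse
        beta = temporal_truth

    rmse = beta_rmse(est, _T)
    rows.append(("temporal_beta_rmse", rmse, float("nan"), len(temporal_truth)))
    print(f"polynomial coefficient RMSE over planted temporal probes: {rmse:.4f}")

    RESULTS.mkdir(exist_ok=True)
    pd.DataFrame(rows, columns=["metric", "value", "power", "n"]).to_csv(
        RESULTS / "recovery_vs_truth.tsv", sep="\t", index=False, float_format="%.4f"
    )
    return 0


if __name__ == "__main__":
    sys.exit(main())
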