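import numpy as np
import pandas as pd
import pytest

from loopma.effects import estimate_sample_effects
from loopma.errors import ParameterError
from loopma.profiles import (
    default_templates,
    divergence_screen,
    kmeans_profiles,
    zscore_profiles,
)
from loopma.simulate import SimulationConfig, clustering_ari, simulate_study


# ---------------------------------------------------------------------------
# z-scoring
# ---------------------------------------------------------------------------

def test_zscore_closed_form():
    df = pd.DataFrame([[1.0, 2.0, 3.0]], index=["p"], columns=list("abc"))
    Z, flat = zscore_profiles(df)
    np.testing.assert_allclose(Z.loc["p"], [-1.0, 0.0, 1.0])
    assert len(flat) == 0


def test_zscore_excludes_flat_profiles():
    df = pd.DataFrame([[1.0, 1.0, 1.0], [0.0, 1.0, 2.0]], index=["flat", "ok"])
    Z, flat = zscore_profiles(df)
    assert list(flat) == ["flat"]
    assert list(Z.index) == ["ok"]


def test_zscore_rows_standardized():
    rng = np.random.default_rng(0)
    df = pd.DataFrame(rng.normal(0, 2, (50, 12)))
    Z, _ = zscore_profiles(df)
    np.testing.assert_allclose(Z.mean(axis=1), 0.0, atol=1e-12)
    np.testing.assert_allclose(Z.std(axis=1, ddof=1), 1.0, atol=1e-12)


def test_zscore_per_segment():
    df = pd.DataFrame([[0.0, 1.0, 2.0, 10.0, 30.0]], columns=list("abcde"))
    Z, _ = zscore_profiles(df, segments=[list("abc"), list("de")])
    np.testing.assert_allclose(Z.iloc[0, :3], [-1.0, 0.0, 1.0])
    np.testing.assert_allclose(Z.iloc[0, 3:].mean(), 0.0, atol=1e-12)


# ---------------------------------------------------------------------------
# k-means on correlation distance
# ---------------------------------------------------------------------------

def test_pearson_equals_scaled_squared_euclidean():
    rng = np.random.default_rng(1)
    n = 12
    for _ in range(20):
        x, y = rng.normal(size=n), rng.normal(size=n)
        zx = (x - x.mean()) / x.std(ddof=1)
        zy = (y - y.mean()) / y.std(ddof=1)
        r = np.corrcoef(x, y)[0, 1]
        assert 1 - r == pytest.approx(np.sum((zx - zy) ** 2) / (2 * (n - 1)), abs=1e-10)


def test_kmeans_perfect_on_orthogonal_archetypes():
    arch = np.eye(4).repeat(3, axis=0)  # 3 exact copies of 4 orthogonal rows
    Z, _ = zscore_profiles(pd.DataFrame(arch))
    model = kmeans_profiles(Z, k=4, restarts=10, seed=0)
    truth = pd.Series(np.arange(12) // 3, index=Z.index)
    assert clustering_ari(model.assignments, truth) == 1.0


def test_kmeans_k1_centroid_is_mean():
    rng = np.random.default_rng(2)
    Z, _ = zscore_profiles(pd.DataFrame(rng.normal(size=(30, 8))))
    model = kmeans_profiles(Z, k=1, restarts=2, seed=0)
    assert model.assignments.nunique() == 1
    # centroids are re-standardized; compare shapes up to z-scoring
    mean = Z.mean(axis=0).to_numpy()
    mean_z = (mean - mean.mean()) / mean.std(ddof=1)
    np.testing.assert_allclose(model.centroids[0], mean_z, atol=1e-8)


def test_kmeans_k_exceeding_probes_rejected():
    Z = pd.DataFrame(np.eye(3))
    with pytest.raises(ParameterError):
        kmeans_profiles(Z, k=5)


def test_kmeans_deterministic_under_seed():
    rng = np.random.default_rng(3)
    Z, _ = zscore_profiles(pd.DataFrame(rng.normal(size=(60, 8))))
    m1 = kmeans_profiles(Z, k=3, restarts=5, seed=9)
    m2 = kmeans_profiles(Z, k=3, restarts=5, seed=9)
    assert (m1.assignments == m2.assignments).all()
    assert m1.inertia == m2.inertia


def test_kmeans_recovers_noisy_archetypes_over_seeds():
    st = simulate_study(
        SimulationConfig(
            n_probes=600,
            seed=8,
            frac_temporal=0.0,
            frac_cluster=0.5,
            frac_divergent=0.0,
            frac_concordant=0.0,
            dye_trend_amplitude=0.0,
        )
    )
    eff = estimate_sample_effects(st.maset(), st.design, reference="PE_000h")
    pe = [s for s in eff.samples if s.startswith("PE")]
    prof = pd.DataFrame(eff.effects, index=eff.probes, columns=eff.samples)
    prof = prof.loc[st.truth.positives("cluster"), pe]
    Z, _ = zscore_profiles(prof)
    aris = []
    for seed in range(10):
        model = kmeans_profiles(Z, k=4, restarts=10, seed=seed)
        aris.append(clustering_ari(model.assignments, st.truth.archetypes))
    assert min(aris) >= 0.9


# ---------------------------------------------------------------------------
# template library
# ---------------------------------------------------------------------------

def test_default_templates_segments_standardized():
    lib = default_templates()
    assert len(lib.names) == 6
    pe, epi = lib.vectors[:, :8], lib.vectors[:, 8:]
    np.testing.assert_allclose(pe.mean(axis=1), 0.0, atol=1e-12)
    np.testing.assert_allclose(pe.std(axis=1, ddof=1), 1.0, atol=1e-12)
    np.testing.assert_allclose(epi.mean(axis=1), 0.0, atol=1e-12)
    np.testing.assert_allclose(epi.std(axis=1, ddof=1), 1.0, atol=1e-12)


def test_templates_self_correlation_and_distinctness():
    lib = default_templates()
    V = lib.vectors
    C = np.corrcoef(V)
    np.testing.assert_allclose(np.diag(C), 1.0)
    # no duplicated direction (r = +1); trend-reversed pairs are exact
    # negatives of each other by construction (r = -1), which is deliberate:
    # the screen tests |r| and reports the signed direction by name
    off = C[~np.eye(len(V), dtype=bool)]
    assert np.max(off) < 1.0 - 1e-9


def test_template_tsv_round_trip(tmp_path):
    lib = default_templates()
    path = tmp_path / "templates.tsv"
    lib.write(path)
    from loopma.profiles import TemplateLibrary

    back = TemplateLibrary.read(path)
    assert back.names == lib.names
    np.testing.assert_allclose(back.vectors, lib.vectors, atol=1e-9)


# ---------------------------------------------------------------------------
# divergence screen
# ---------------------------------------------------------------------------

def _screen_study(seed, **kw):
    cfg = SimulationConfig(
        n_probes=2200,
        seed=seed,
        frac_temporal=0.0,
        frac_cluster=0.0,
        frac_divergent=200 / 2200,
        frac_concordant=500 / 2200,
        dye_trend_amplitude=0.0,
        **kw,
    )
    st = simulate_study(cfg)
    eff = estimate_sample_effects(st.maset(), st.design, reference="PE_000h")
    return st, eff


def test_exact_template_probe_called():
    st, eff = _screen_study(31)
    hits = divergence_screen(eff).set_index("probe_id")
    planted = st.truth.positives("divergent")
    sub = hits.loc[planted]
    assert sub["call"].mean() > 0.9
    assert (sub["p"] < 1e-3).mean() > 0.9
    # planted probes recover their own template shape most of the time
    # (up to sign: trend-reversed library members have identical |r|)
    lib = default_templates()
    vec = dict(zip(lib.names, lib.vectors))
    match = [
        abs(np.corrcoef(vec[b], vec[t])[0, 1]) > 0.999
        for b, t in zip(sub["best_template"], st.truth.templates.loc[planted])
    ]
    assert np.mean(match) > 0.8


def test_concordant_probes_rarely_called():
    st, eff = _screen_study(32)
    hits = divergence_screen(eff).set_index("probe_id")
    conc = hits.loc[st.truth.positives("concordant")]
    assert conc["call"].mean() < 0.05


def test_screen_fdr_and_power():
    from loopma.simulate import evaluate_calls

    fdps, powers = [], []
    for seed in range(41, 49):
        st, eff = _screen_study(seed)
        hits = divergence_screen(eff)
        m = evaluate_calls(hits.set_index("probe_id")["call"], st.truth.positives("divergent"))
        fdps.append(m["fdp"])
        powers.append(m["power"])
    mc_se = np.std(fdps, ddof=1) / np.sqrt(len(fdps))
    assert np.mean(fdps) - 2 * mc_se <= 0.01
    assert np.mean(powers) >= 0.8


def test_screen_invariant_to_affine_profile_transforms():
    st, eff = _screen_study(33)
    hits1 = divergence_screen(eff)
    import copy

    eff2 = copy.copy(eff)
    eff2.effects = eff.effects * 3.0 + 1.5
    hits2 = divergence_screen(eff2)
    np.testing.assert_allclose(hits2["r"].to_numpy(float), hits1["r"].to_numpy(float), atol=1e-9, equal_nan=True)
    assert (hits2["call"] == hits1["call"]).all()


def test_lowering_fdr_never_adds_calls():
    st, eff = _screen_study(34)
    loose = divergence_screen(eff, fdr_level=0.05).set_index("probe_id")["call"]
    strict = divergence_screen(eff, fdr_level=0.001).set_index("probe_id")["call"]
    assert not (strict & ~loose).any()


def test_t_transform_method_available():
    st, eff = _screen_study(35)
    hits = divergence_screen(eff, p_method="t")
    assert hits["p"].between(0, 1).where(hits["status"] == "ok").all()
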