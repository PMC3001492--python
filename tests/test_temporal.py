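import numpy as np
import pytest
import scipy.stats

from loopma.array_io import MASet
from loopma.design import Sample, build_pe_loop, build_round_robin
from loopma.errors import DesignError
from loopma.temporal import bh_fdr, hotelling_temporal_test, temporal_design_matrix


def _maset(g, M, W=None):
    M = np.atleast_2d(M)
    return MASet(
        probes=[f"P{i}" for i in range(M.shape[0])],
        arrays=g.array_ids,
        M=M,
        A=np.full_like(M, 10.0),
        W=np.ones_like(M) if W is None else W,
    )


def _oracle_F(y, X):
    """Independent direct least-squares F statistic for the 2 time columns."""
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    nu = len(y) - 3
    s2 = resid @ resid / nu
    V = s2 * np.linalg.inv(X.T @ X)[:2, :2]
    t2 = beta[:2] @ np.linalg.solve(V, beta[:2])
    return t2 / 2.0


# ---------------------------------------------------------------------------
# design matrix
# ---------------------------------------------------------------------------

def test_dye_swap_rows_antisymmetric(pe_loop_16, pe_design_matrix):
    g, X = pe_loop_16, pe_design_matrix
    for i, a in enumerate(g.arrays):
        j = next(
            k
            for k, b in enumerate(g.arrays)
            if (b.cy3_sample, b.cy5_sample) == (a.cy5_sample, a.cy3_sample)
        )
        np.testing.assert_allclose(X[i, :2], -X[j, :2], atol=1e-12)
        assert X[i, 2] == X[j, 2] == 1.0


def test_full_loop_design_rank(pe_design_matrix):
    assert pe_design_matrix.shape == (16, 3)
    assert np.linalg.matrix_rank(pe_design_matrix) == 3


def test_all_same_time_degenerate():
    samples = [Sample(f"s{i}", "PE", 10.0) for i in range(3)]
    # distinct ids, identical times: time columns vanish
    g = build_pe_loop(samples)
    X = temporal_design_matrix(g)
    np.testing.assert_allclose(X[:, :2], 0.0)
    assert np.linalg.matrix_rank(X) == 1
    fit = hotelling_temporal_test(_maset(g, np.ones((2, 6))), X)
    assert (fit["status"] == "untestable").all()


def test_non_pe_array_rejected():
    g = build_round_robin([Sample(f"e{i}", "EPI", stage=f"S{i}") for i in range(3)])
    with pytest.raises(DesignError):
        temporal_design_matrix(g)


# ---------------------------------------------------------------------------
# the joint test
# ---------------------------------------------------------------------------

def test_zero_m_gives_null_fit(pe_loop_16, pe_design_matrix):
    fit = hotelling_temporal_test(_maset(pe_loop_16, np.zeros((1, 16))), pe_design_matrix)
    assert fit["F"][0] == 0.0 and fit["p"][0] == 1.0 and not fit["call"][0]


def test_null_pvalues_are_uniform(null_pe_maset, pe_design_matrix):
    fit = hotelling_temporal_test(null_pe_maset, pe_design_matrix)
    stat = scipy.stats.kstest(fit["p"], "uniform")
    assert stat.pvalue > 0.01


def test_matches_independent_lstsq_oracle(pe_loop_16, pe_design_matrix):
    rng = np.random.default_rng(10)
    M = rng.normal(0, 0.4, (10, 16))
    fit = hotelling_temporal_test(_maset(pe_loop_16, M), pe_design_matrix)
    for i in range(10):
        assert fit["F"][i] == pytest.approx(_oracle_F(M[i], pe_design_matrix), rel=1e-9)


def test_p_agrees_with_permutation_oracle(pe_loop_16, pe_design_matrix):
    """The F(2, nu) tail calibrates the statistic: over Gaussian-null toy
    probes the mean difference to a 20,000-draw permutation p is within
    2 standard errors (the permutation null conditions on the data, so the
    comparison is on the mean, not probe by probe)."""
    rng = np.random.default_rng(42)
    n_probe, nperm = 20, 20000
    M = rng.normal(0, 0.5, (n_probe, 16))
    fit = hotelling_temporal_test(_maset(pe_loop_16, M), pe_design_matrix)
    X = pe_design_matrix
    prng = np.random.default_rng(7)
    diffs = []
    for i in range(n_probe):
        perms = np.argsort(prng.random((nperm, 16)), axis=1)
        f_perm = np.array([_oracle_F(M[i][p], X) for p in perms])
        p_perm = np.mean(f_perm >= fit["F"][i] - 1e-12)
        diffs.append(p_perm - fit["p"][i])
    diffs = np.asarray(diffs)
    se = diffs.std(ddof=1) / np.sqrt(n_probe)
    assert abs(diffs.mean()) < 2 * se
    # and probe-by-probe agreement at the conditional-null accuracy O(1/n)
    assert np.max(np.abs(diffs)) < 0.05


def test_time_coding_invariance(pe_loop_16):
    rng = np.random.default_rng(11)
    M = rng.normal(0, 0.4, (20, 16))
    fits = [
        hotelling_temporal_test(_maset(pe_loop_16, M), temporal_design_matrix(pe_loop_16, coding))
        for coding in ("scaled", "centered", "hours")
    ]
    for other in fits[1:]:
        np.testing.assert_allclose(other["F"], fits[0]["F"], atol=1e-8)
        np.testing.assert_allclose(other["p"], fits[0]["p"], atol=1e-8)


def test_dye_swap_consistency(pe_loop_16, pe_design_matrix):
    from loopma.design import ArrayHyb, DesignGraph

    rng = np.random.default_rng(12)
    M = rng.normal(0, 0.4, (15, 16))
    fit = hotelling_temporal_test(_maset(pe_loop_16, M), pe_design_matrix)
    flipped = DesignGraph(
        samples=pe_loop_16.samples,
        arrays=[
            ArrayHyb(a.array_id, cy3_sample=a.cy5_sample, cy5_sample=a.cy3_sample)
            for a in pe_loop_16.arrays
        ],
    )
    fit2 = hotelling_temporal_test(_maset(flipped, -M), temporal_design_matrix(flipped))
    np.testing.assert_allclose(fit2["F"], fit["F"], atol=1e-8)
    np.testing.assert_allclose(fit2["p"], fit["p"], atol=1e-8)
    assert (fit2["call"] == fit["call"]).all()


# ---------------------------------------------------------------------------
# BH-FDR
# ---------------------------------------------------------------------------

def test_bh_all_called_when_uniformly_small():
    q, call = bh_fdr(np.array([0.01, 0.02, 0.03, 0.04]), 0.05)
    assert call.all()
    np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])


def test_bh_none_called():
    _, call = bh_fdr(np.array([0.5, 0.9]), 0.15)
    assert not call.any()


def test_bh_handles_missing():
    q, call = bh_fdr(np.array([0.001, np.nan, 0.8]), 0.05)
    assert np.isnan(q[1]) and not call[1]
    assert call[0] and not call[2]


def test_bh_matches_statsmodels():
    from statsmodels.stats.multitest import multipletests

    rng = np.random.default_rng(13)
    p = rng.random(500) ** 2
    q, call = bh_fdr(p, 0.15)
    reject, q_sm, *_ = multipletests(p, alpha=0.15, method="fdr_bh")
    np.testing.assert_allclose(q, q_sm, atol=1e-12)
    assert (call == reject).all()


def test_bh_false_call_fraction_controlled():
    """Monte-Carlo check of the BH guarantee on uniform nulls."""
    rng = np.random.default_rng(14)
    fracs = []
    for _ in range(200):
        p = rng.random(1000)
        _, call = bh_fdr(p, 0.15)
        fracs.append(call.mean())  # every call is false under the global null
    # expected fraction of datasets with any false call is <= level
    assert np.mean(np.asarray(fracs) > 0) <= 0.15 + 2 * np.sqrt(0.15 * 0.85 / 200)
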