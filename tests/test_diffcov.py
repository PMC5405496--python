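"""Differential-coverage statistics: size factors vs an independent
median-of-ratios oracle, NB Wald calibration, BH adjustment, and the
compartment decision rule."""

import numpy as np
import pandas as pd
import pytest

from micmac.diffcov import (
    MAC_DESTINED,
    MIC_ONLY,
    MIC_PGM,
    NbTestResult,
    assign_compartments,
    bh_adjust,
    compartment_pipeline,
    nb_wald_test,
    size_factors,
)


def _median_of_ratios_oracle(k):
    """Literal, loop-based size factors (independent coding)."""
    k = np.asarray(k, float)
    nw, ns = k.shape
    logs = []
    for w in range(nw):
        if all(k[w, j] > 0 for j in range(ns)):
            geo = np.exp(sum(np.log(k[w, j]) for j in range(ns)) / ns)
            logs.append([k[w, j] / geo for j in range(ns)])
    logs = np.array(logs)
    return np.array([np.median(logs[:, j]) for j in range(ns)])


def test_size_factors_two_window_example():
    counts = np.array([[100, 10], [200, 20]])
    f = size_factors(counts)
    assert f == pytest.approx([np.sqrt(10), 1 / np.sqrt(10)])
    assert f[0] / f[1] == pytest.approx(10.0)


def test_size_factors_identical_samples_equal():
    rng = np.random.default_rng(1)
    col = rng.poisson(100, 300)
    counts = np.column_stack([col, col, col])
    f = size_factors(counts)
    assert np.allclose(f, f[0])


def test_size_factors_match_oracle_random_matrix():
    rng = np.random.default_rng(2)
    mu = rng.uniform(20, 400, (500, 1))
    depth = np.array([0.5, 0.8, 1.0, 1.3, 2.0, 3.0])
    counts = rng.negative_binomial(20, 20 / (20 + mu * depth))
    f = size_factors(counts)
    oracle = _median_of_ratios_oracle(counts)
    assert np.allclose(f, oracle, rtol=0.02)


def test_size_factors_fallback_warning():
    counts = np.array([[0, 5], [5, 0]])
    with pytest.warns(UserWarning):
        f = size_factors(counts)
    assert (f > 0).all()


def test_nb_wald_null_type_one_error():
    """Empirical rejection at alpha=0.05 within [0.03, 0.07] under an NB null
    with identical class means and large replicate numbers."""
    from micmac.study import null_type_one_error

    rate = null_type_one_error(seed=1, n_windows=2000)
    assert 0.03 <= rate <= 0.07


def test_nb_wald_power_tenfold_depletion():
    """10-fold depletion, 3 vs 3 replicates, mean 200 → detected >=95%."""
    rng = np.random.default_rng(4)
    n = 1 / 0.05
    a = rng.negative_binomial(n, n / (n + 200.0), size=(2000, 3))
    b = rng.negative_binomial(n, n / (n + 20.0), size=(2000, 3))
    res = nb_wald_test(np.hstack([a, b]), np.ones(6), np.arange(3), np.arange(3, 6))
    detected = (res.padj < 0.05) & (np.abs(res.log2fc) > 1)
    assert detected.mean() >= 0.95


def test_nb_wald_zero_class_capped():
    counts = np.array([[200, 210, 190, 0, 0, 0], [0, 0, 0, 0, 0, 0]])
    res = nb_wald_test(counts, np.ones(6), np.arange(3), np.arange(3, 6))
    assert res.log2fc[0] == -10.0
    assert res.pvalue[0] < 1e-10
    assert res.untestable[1] and res.pvalue[1] == 1.0 and res.log2fc[1] == 0.0


def test_nb_wald_replicate_permutation_invariance():
    rng = np.random.default_rng(5)
    counts = rng.poisson(100, (200, 6))
    res1 = nb_wald_test(counts, np.ones(6), np.array([0, 1, 2]), np.array([3, 4, 5]))
    res2 = nb_wald_test(counts[:, [2, 0, 1, 5, 3, 4]], np.ones(6), np.array([0, 1, 2]), np.array([3, 4, 5]))
    assert np.allclose(res1.pvalue, res2.pvalue)
    assert np.allclose(res1.log2fc, res2.log2fc)


def test_bh_examples_and_null():
    padj = bh_adjust(np.array([0.01, 0.02, 0.04]))
    assert padj == pytest.approx([0.03, 0.03, 0.04])
    assert bh_adjust(np.array([0.7])) == pytest.approx([0.7])
    rng = np.random.default_rng(6)
    p = rng.uniform(0, 1, 1000)
    assert (bh_adjust(p) < 0.05).mean() <= 0.005
    with pytest.raises(ValueError):
        bh_adjust(np.array([1.5]))


def _mk_res(log2fc, padj, untestable=None):
    n = len(log2fc)
    z = np.zeros(n)
    return NbTestResult(
        np.asarray(log2fc, float),
        z,
        np.asarray(padj, float),
        np.asarray(padj, float),
        np.zeros(n, bool) if untestable is None else np.asarray(untestable, bool),
        z,
    )


def _win(n):
    return pd.DataFrame({"contig": "c", "start": np.arange(n) * 1000, "end": (np.arange(n) + 1) * 1000})


def test_assign_compartments_rule():
    """MAC-depleted → MIC-limited; PGM also depleted → MIC_ONLY; else MAC."""
    mac = _mk_res([-5, -5, 0.1, -5], [1e-8, 1e-8, 0.9, 1e-8])
    pgm = _mk_res([-5, 0.0, -5, -0.5], [1e-8, 0.8, 1e-8, 1e-8])
    calls = assign_compartments(_win(4), mac, pgm)
    # window 3: PGM significant but fold-change below threshold → stays MIC_PGM
    assert calls.label.tolist() == [MIC_ONLY, MIC_PGM, MAC_DESTINED, MIC_PGM]


def test_assign_compartments_null_case_and_untestable():
    mac = _mk_res([0, 0], [1.0, 1.0], untestable=[False, True])
    pgm = _mk_res([0, 0], [1.0, 1.0])
    calls = assign_compartments(_win(2), mac, pgm)
    assert (calls.label == MAC_DESTINED).all()


def test_assign_compartments_alpha_monotone():
    """Tightening alpha never moves a window from MAC_DESTINED to a MIC class."""
    rng = np.random.default_rng(8)
    n = 200
    mac = _mk_res(rng.uniform(-6, 1, n), rng.uniform(0, 0.2, n))
    pgm = _mk_res(rng.uniform(-6, 1, n), rng.uniform(0, 0.2, n))
    loose = assign_compartments(_win(n), mac, pgm, alpha=0.05)
    tight = assign_compartments(_win(n), mac, pgm, alpha=0.001)
    moved_to_mic = (loose.label == MAC_DESTINED) & (tight.label != MAC_DESTINED)
    assert not moved_to_mic.any()


def test_compartment_pipeline_requires_replicates():
    win = _win(3)
    counts = np.ones((3, 3))
    with pytest.raises(ValueError):
        compartment_pipeline(win, counts, ["MIC", "MAC", "PGM"])
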