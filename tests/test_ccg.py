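"""Cross-correlogram oracles: exact counts, jitter null, significance rule."""

import numpy as np
import pytest

import wmintermit as wm
from wmintermit import ccg
from wmintermit.core import BinaryRaster


def brute_force_ccg_numerator(xj, xk, lag_max=100):
    """O(M N^2) direct coincidence counter (independent oracle)."""
    lags = np.arange(-lag_max, lag_max + 1)
    out = np.zeros(lags.size)
    M, N = xj.shape
    for li, tau in enumerate(lags):
        s = 0
        for i in range(M):
            for t in range(N):
                tp = t - tau
                if 0 <= tp < N:
                    s += int(xj[i, tp]) * int(xk[i, t])
        out[li] = s
    return out


def test_raw_ccg_matches_brute_force_exactly(poisson_raster):
    r = ccg.compute_ccg(poisson_raster, 0, 1)
    brute = brute_force_ccg_numerator(poisson_raster.values[0],
                                      poisson_raster.values[1])
    assert np.array_equal(r["numerator"], brute)


def test_ccg_symmetry(poisson_raster):
    a = ccg.compute_ccg(poisson_raster, 2, 3)["ccg"]
    b = ccg.compute_ccg(poisson_raster, 3, 2)["ccg"]
    np.testing.assert_allclose(a, b[::-1], atol=1e-12)


def test_self_ccg_peaks_at_one(poisson_raster):
    r = ccg.compute_ccg(poisson_raster, 1, 1)
    assert r["ccg"][100] == pytest.approx(1.0)


def test_shifted_train_peaks_at_shift():
    rng = np.random.default_rng(1)
    x = (rng.random((8, 400)) < 0.03).astype(np.uint8)
    X = np.zeros((2, 8, 400), np.uint8)
    X[0] = x
    X[1, :, 5:] = x[:, :-5]
    raster = BinaryRaster(X, np.arange(2), np.arange(8), (0.0, 400.0))
    r = ccg.compute_ccg(raster, 0, 1)
    assert r["lags"][np.argmax(r["ccg"])] == 5


def test_jitter_closed_form_matches_monte_carlo(poisson_raster):
    jit = ccg.jitter_expectation(poisson_raster, 0, 1)
    mc = ccg.jitter_monte_carlo(poisson_raster, 0, 1, n_resamples=1000,
                                seed=2)
    se = np.sqrt(np.maximum(mc["numerator"], 0.05) / 1000)
    assert np.all(np.abs(jit["numerator"] - mc["numerator"]) <= 3 * se + 1e-9)


def test_jitter_removes_slow_comodulation_keeps_fast_peak():
    """Two-timescale fixture: a shared slow (200-ms) rate envelope creates a
    broad raw pedestal; injected 2-ms-lag coincidences create a fast peak.
    Correction must remove the former and keep the latter."""
    rng = np.random.default_rng(3)
    M, N = 40, 900
    t = np.arange(N)
    env = 0.004 * (1 + np.sin(2 * np.pi * t / 400))
    X = np.zeros((2, M, N), np.uint8)
    for i in range(M):
        X[0, i] = rng.random(N) < env
        X[1, i] = rng.random(N) < env
        inj = rng.integers(0, N - 3, size=8)
        X[0, i, inj] = 1
        X[1, i, inj + 2] = 1
    raster = BinaryRaster(X, np.arange(2), np.arange(M), (500.0, 1400.0))
    raw = ccg.compute_ccg(raster, 0, 1)
    jit = ccg.jitter_expectation(raster, 0, 1)
    corr = raw["ccg"] - jit["ccg"]
    lags = raw["lags"]
    # pedestal present in raw at moderate lags; correction removes its mean
    # elevation (residual is unbiased shot noise around zero)
    mid = (np.abs(lags) > 30) & (np.abs(lags) < 100)
    assert abs(corr[mid].mean()) < 0.1 * raw["ccg"][mid].mean()
    assert lags[np.argmax(corr)] == 2


def test_corrected_ccg_near_zero_for_independent(poisson_raster):
    res = ccg.corrected_ccg(poisson_raster, 4, 5)
    inner = np.abs(res["lags"]) < 25
    base = res["ccg"][np.abs(res["lags"]) > 50]
    assert np.abs(res["ccg"][inner].mean()) < 4 * base.std()


def test_flag_rule_zero_lag_excluded():
    lags = ccg.lag_axis()
    c = np.zeros(lags.size)
    c[lags == 0] = 1.0                      # only a zero-lag peak
    rng = np.random.default_rng(4)
    c += rng.normal(0, 0.001, size=c.size)
    sig, lag, z = ccg.flag_significant_ccg(c)
    assert not sig
    c2 = np.zeros(lags.size) + rng.normal(0, 0.001, size=c.size)
    c2[lags == 3] = 1.0
    sig2, lag2, z2 = ccg.flag_significant_ccg(c2)
    assert sig2 and lag2 == 3 and z2 > 7


def test_flag_rule_respects_seven_sd():
    lags = ccg.lag_axis()
    rng = np.random.default_rng(5)
    base = rng.normal(0, 0.01, size=lags.size)
    sd = base[(np.abs(lags) > 50) & (np.abs(lags) < 100)].std(ddof=1)
    mu = base[(np.abs(lags) > 50) & (np.abs(lags) < 100)].mean()
    weak = base.copy()
    weak[lags == 5] = mu + 5 * sd
    assert not ccg.flag_significant_ccg(weak)[0]
    strong = base.copy()
    strong[lags == 5] = mu + 9 * sd
    assert ccg.flag_significant_ccg(strong)[0]


def test_state_mask_identity_and_empty(poisson_raster):
    import pandas as pd
    full = wm.StateSegments(table=pd.DataFrame(
        [(t, "On", 0.0, 1400.0) for t in range(15)],
        columns=["trial_id", "label", "t_start_ms", "t_end_ms"]))
    masked = ccg.state_restricted_raster(poisson_raster, full, "On")
    assert np.array_equal(masked.values, poisson_raster.values)
    with pytest.warns(UserWarning):
        empty = ccg.state_restricted_raster(poisson_raster, full, "Off")
    assert empty.values.sum() == 0


def test_pair_with_no_spikes_excluded():
    X = np.zeros((2, 5, 900), np.uint8)
    X[0, :, ::100] = 1
    raster = BinaryRaster(X, np.arange(2), np.arange(5), (500.0, 1400.0))
    with pytest.raises(ValueError):
        ccg.compute_ccg(raster, 0, 1)
    res = ccg.ccg_condition_edges(raster, np.ones(5, int), [(0, 1)])
    assert not res["evaluated"][0, 0]


def test_distance_dependence_directions():
    rng = np.random.default_rng(6)
    n = 40
    pos = np.linspace(0, 3000, n)
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    d = np.array([abs(pos[j] - pos[i]) for i, j in pairs])
    sig_near = rng.random(len(pairs)) < np.clip(0.3 - d / 4000, 0.01, 1)
    tab, r = ccg.distance_dependence(pairs, sig_near, pos)
    assert r < -0.05
    sig_flat = rng.random(len(pairs)) < 0.1
    _, r2 = ccg.distance_dependence(pairs, sig_flat, pos)
    assert abs(r2) < 0.05
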