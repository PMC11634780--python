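"""State labeling: z-scoring, cluster-mass correction, summaries."""

import numpy as np
import pandas as pd
import pytest

import wmintermit as wm
from wmintermit.core import ConfidenceSeries, NullConfidenceEnsemble
from wmintermit.states import (Z_OFF_ONESIDED, balanced_state_accuracy,
                               label_states, null_cluster_masses,
                               summarize_states, zscore_confidence)


def _null(values):
    T, P, S = values.shape
    return NullConfidenceEnsemble(values=values, trial_ids=np.arange(T),
                                  time_ms=np.arange(0, P * 10, 10.0))


def _conf(values):
    T, P = values.shape
    return ConfidenceSeries(values=values, accuracy=(values > .5).astype(float),
                            trial_ids=np.arange(T),
                            time_ms=np.arange(0, P * 10, 10.0))


def test_zscore_identities():
    rng = np.random.default_rng(0)
    null = _null(rng.uniform(0.3, 0.7, size=(2, 20, 50)))
    mu, sd = null.mean, null.sd
    z0 = zscore_confidence(_conf(mu), null)
    assert np.allclose(z0.z, 0.0, atol=1e-12)
    z2 = zscore_confidence(_conf(mu + 2 * sd), null)
    assert np.allclose(z2.z, 2.0, atol=1e-10)


def test_zscore_standard_normal_under_null():
    """A point drawn from the same distribution as the null replicates has
    approximately standard-normal z (t-inflation ~ 1/(2S) at S=50)."""
    rng = np.random.default_rng(1)
    vals = rng.normal(0.5, 0.05, size=(40, 50, 51))
    null = _null(vals[:, :, 1:])
    z = zscore_confidence(_conf(vals[:, :, 0]), null)
    zz = z.z.ravel()
    assert abs(zz.mean()) < 0.02
    assert zz.std() == pytest.approx(1.0, abs=0.05)


def _brute_force_masses(null_values, z_on, span_mask):
    """Independent enumeration of per-(trial, shuffle) max cluster masses."""
    T, P, S = null_values.shape
    out = []
    for t in range(T):
        for s in range(S):
            others = np.delete(null_values[t], s, axis=1)
            mu = others.mean(axis=1)
            sd = others.std(axis=1, ddof=1)
            z = (null_values[t, :, s] - mu) / sd
            z = z[span_mask]
            best, cur = 0.0, 0.0
            for v in z:
                cur = cur + v if v > z_on else 0.0
                best = max(best, cur)
            out.append(best)
    return np.asarray(out).reshape(T, S)


def test_cluster_mass_null_matches_brute_force():
    rng = np.random.default_rng(2)
    vals = rng.normal(0.5, 0.08, size=(3, 20, 12))
    null = _null(vals)
    span = (null.time_ms >= 0) & (null.time_ms < 1400)
    fast = null_cluster_masses(null, z_on=1.96)
    brute = _brute_force_masses(vals, 1.96, span)
    np.testing.assert_allclose(fast, brute, atol=1e-10)


def test_label_states_toy_series_against_oracle():
    """20-timepoint toy: a 3-point z=3 run is retained iff its mass (9)
    exceeds the 95th percentile of the null cluster masses."""
    rng = np.random.default_rng(3)
    T, P, S = 4, 20, 40
    nullv = rng.normal(0.5, 0.05, size=(T, P, S))
    null = _null(nullv)
    z = np.zeros((T, P))
    z[0, 5:8] = 3.0                      # candidate cluster, mass 9
    zs = wm.StateZSeries(z=z, trial_ids=np.arange(T), time_ms=null.time_ms)
    segs = label_states(zs, null, span=(0, 200))
    masses = _brute_force_masses(nullv, 1.96,
                                 (null.time_ms >= 0) & (null.time_ms < 200))
    thr = np.quantile(masses.ravel(), 0.95)
    on = segs.table[segs.table.label == "On"]
    if 9.0 > thr:
        assert len(on) == 1
        assert on.iloc[0].t_start_ms == 50.0 and on.iloc[0].t_end_ms == 80.0
    else:
        assert len(on) == 0
    # decision flips when we override the threshold on either side
    seg_lo = label_states(zs, null, span=(0, 200), mass_threshold=8.9)
    seg_hi = label_states(zs, null, span=(0, 200), mass_threshold=9.1)
    assert (seg_lo.table.label == "On").sum() == 1
    assert (seg_hi.table.label == "On").sum() == 0


def test_label_states_zero_z_gives_single_off_state():
    rng = np.random.default_rng(4)
    null = _null(rng.normal(0.5, 0.05, size=(1, 140, 30)))
    z = wm.StateZSeries(z=np.zeros((1, 140)), trial_ids=np.array([0]),
                        time_ms=null.time_ms)
    segs = label_states(z, null)
    tab = segs.table
    assert (tab.label == "On").sum() == 0
    off = tab[tab.label == "Off"]
    assert len(off) == 1
    assert off.iloc[0].t_start_ms == 0.0 and off.iloc[0].t_end_ms == 1400.0


def test_off_needs_five_consecutive_points():
    rng = np.random.default_rng(5)
    null = _null(rng.normal(0.5, 0.05, size=(1, 9, 30)))
    z = np.full((1, 9), 1.5)             # above off threshold (0.8416)
    z[0, :4] = 0.0                        # only 4 consecutive low points
    zs = wm.StateZSeries(z=z, trial_ids=np.array([0]), time_ms=null.time_ms)
    segs = label_states(zs, null, span=(0, 90))
    assert (segs.table.label == "Off").sum() == 0
    z[0, :5] = 0.0
    segs = label_states(wm.StateZSeries(z=z, trial_ids=np.array([0]),
                                        time_ms=null.time_ms),
                        null, span=(0, 90))
    assert (segs.table.label == "Off").sum() == 1


def test_raising_z_on_never_increases_on_duration():
    rng = np.random.default_rng(6)
    null = _null(rng.normal(0.5, 0.05, size=(6, 140, 25)))
    z = wm.StateZSeries(z=rng.normal(1.0, 1.2, size=(6, 140)),
                        trial_ids=np.arange(6), time_ms=null.time_ms)

    def total_on(z_on):
        segs = label_states(z, null, z_on=z_on, mass_threshold=5.0)
        on = segs.table[segs.table.label == "On"]
        return (on.t_end_ms - on.t_start_ms).sum()

    durations = [total_on(v) for v in (1.5, 1.96, 2.5, 3.0)]
    assert all(a >= b for a, b in zip(durations, durations[1:]))


def test_incorrect_states_mirrored():
    rng = np.random.default_rng(7)
    null = _null(rng.normal(0.5, 0.05, size=(1, 50, 30)))
    z = np.zeros((1, 50))
    z[0, 10:16] = -4.0
    segs = label_states(wm.StateZSeries(z=z, trial_ids=np.array([0]),
                                        time_ms=null.time_ms),
                        null, span=(0, 500), mass_threshold=10.0)
    inc = segs.table[segs.table.label == "incorrect"]
    assert len(inc) == 1
    assert inc.iloc[0].t_start_ms == 100.0


def test_summarize_states_counts_and_go_state():
    tab = pd.DataFrame([
        (0, "On", 0.0, 200.0), (0, "Off", 200.0, 500.0),
        (0, "On", 500.0, 1400.0), (1, "Off", 0.0, 1400.0)],
        columns=["trial_id", "label", "t_start_ms", "t_end_ms"])
    segs = wm.StateSegments(table=tab)
    trials = pd.DataFrame({"trial_id": [0, 1], "go_time_ms": [1450.0, 1450.0]})
    s = summarize_states(segs, trials)
    assert s["On"]["n"] == 2
    assert s["On"]["mean_per_trial"] == 1.0
    # the trial-1 Off state reaches the span edge (right-censored): its
    # truncated length is excluded from the duration mean, not the count
    assert s["Off"]["mean_duration_ms"] == pytest.approx(300.0)
    assert s["Off"]["mean_per_trial"] == 1.0
    assert s["state_at_go"][0] == "On" and s["state_at_go"][1] == "Off"


def test_balanced_accuracy_definition():
    det = np.array([1, 1, 0, 0, -1, 1])
    tru = np.array([1, 0, 0, 1, 1, -1])
    # evaluated points: idx 0..3 -> sens=1/2, spec=1/2
    assert balanced_state_accuracy(det, tru) == pytest.approx(0.5)
    assert np.isnan(balanced_state_accuracy(np.array([-1]), np.array([1])))
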