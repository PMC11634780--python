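"""Decoder correctness: solver agreement, chance levels, separability, leakage."""

import numpy as np
import pandas as pd
import pytest

import wmintermit as wm
from wmintermit._glm import fit_ridge_logistic, predict_proba


def test_solver_matches_sklearn_reference():
    """Dual-route check: our Newton solver vs scikit-learn's LBFGS."""
    from sklearn.linear_model import LogisticRegression
    rng = np.random.default_rng(0)
    for n, d in ((50, 6), (12, 30)):  # primal and dual paths
        X = rng.normal(size=(n, d))
        w = rng.normal(size=d)
        y = (rng.uniform(size=n) < 1 / (1 + np.exp(-(X @ w)))).astype(float)
        beta = fit_ridge_logistic(X, y, lam=2.0, tol=1e-9)
        sk = LogisticRegression(C=0.5, solver="lbfgs", max_iter=5000,
                                tol=1e-12).fit(X, y)
        np.testing.assert_allclose(beta[:-1], sk.coef_[0], atol=1e-5)
        np.testing.assert_allclose(beta[-1], sk.intercept_[0], atol=1e-5)


def test_untuned_session_decodes_at_chance():
    cfg = wm.SimConfig(n_units=24, n_trials_per_condition=6, tuning_gain=0.0,
                       evoked_gain=0.0, ensemble_pairs_per_condition=0,
                       seed=31)
    spikes, trials, _ = wm.simulate_session(cfg)
    rates = wm.preprocess.smooth_and_zscore_rates(spikes, trials)
    conf = wm.decode.loo_confidence(rates, trials, seed=0, window=(500, 1400))
    acc = conf.delay_mean_accuracy()
    # binomial CI around 0.5 for ~48 x 90 correlated samples: generous bound
    assert abs(acc - 0.5) < 0.08


def test_shuffled_labels_give_chance_and_mean_half(small_rates, small_session):
    _, _, trials, _ = small_session
    conf = wm.decode.loo_confidence(small_rates, trials, seed=0,
                                    shuffle_labels=True, window=(500, 1400))
    assert abs(conf.delay_mean_accuracy() - 0.5) < 0.08
    m = np.nanmean(conf.values)
    assert abs(m - 0.5) < 0.05


def test_separable_session_reaches_high_accuracy():
    # strong, state-blind tuning: linearly separable population patterns
    cfg = wm.SimConfig(n_units=32, n_trials_per_condition=6, tuning_gain=4.0,
                       tuning_in_off=True, ensemble_pairs_per_condition=0,
                       seed=32)
    spikes, trials, _ = wm.simulate_session(cfg)
    rates = wm.preprocess.smooth_and_zscore_rates(spikes, trials)
    conf = wm.decode.loo_confidence(rates, trials, seed=0, window=(500, 1400))
    assert conf.delay_mean_accuracy() > 0.95
    w = (conf.time_ms >= 500) & (conf.time_ms < 1400)
    # the default ridge shrinks posteriors toward 0.5; with a weak penalty
    # the separable geometry drives confidence itself toward 1
    weak = wm.decode.loo_confidence(rates, trials, seed=0, window=(500, 1400),
                                    lam=1.0)
    assert np.nanmean(weak.values[:, w]) > 0.85


def test_no_leakage_from_held_out_trial():
    """Replacing the held-out trial's features must not change other trials'
    confidences (the held-out trial never enters training)."""
    cfg = wm.SimConfig(n_units=12, n_trials_per_condition=4, seed=33)
    spikes, trials, _ = wm.simulate_session(cfg)
    rates = wm.preprocess.smooth_and_zscore_rates(spikes, trials)
    conf1 = wm.decode.loo_confidence(rates, trials, seed=5, window=(500, 600))
    # corrupt one trial's data wildly
    rates2 = wm.RateTensor(rates.values.copy(), rates.unit_ids,
                           rates.trial_ids, rates.time_ms, True)
    marker = 3
    rates2.values[:, marker, :] = 40.0
    conf2 = wm.decode.loo_confidence(rates2, trials, seed=5, window=(500, 600))
    others = np.arange(conf1.values.shape[0]) != marker
    w = (conf1.time_ms >= 500) & (conf1.time_ms < 600)
    same_cond = trials.cue_location.to_numpy() == \
        trials.cue_location.to_numpy()[marker]
    opp_cond = trials.cue_location.to_numpy() == \
        wm.core.opposite_location(trials.cue_location.to_numpy()[marker])
    unaffected = others & ~same_cond & ~opp_cond
    np.testing.assert_allclose(conf1.values[unaffected][:, w],
                               conf2.values[unaffected][:, w])


def test_state_restricted_decoding_on_vs_off(small_session, small_rates):
    from tests_helpers import ground_truth_segments
    cfg, spikes, trials, truth = small_session
    segs = ground_truth_segments(truth, small_rates.trial_ids)
    acc_on, conf_on = wm.decode.state_restricted_accuracy(
        small_rates, trials, segs, "On", seed=0)
    acc_off, conf_off = wm.decode.state_restricted_accuracy(
        small_rates, trials, segs, "Off", seed=0)
    # information exists only inside On states by construction
    assert acc_on > acc_off
    assert acc_on > 0.55
    assert abs(acc_off - 0.5) < 0.12


def test_state_restricted_requires_matching_states(small_rates, small_session):
    _, _, trials, _ = small_session
    empty = wm.StateSegments(table=pd.DataFrame(
        columns=["trial_id", "label", "t_start_ms", "t_end_ms"]))
    with pytest.raises(ValueError):
        wm.decode.state_restricted_accuracy(small_rates, trials, empty, "On")


def test_cross_temporal_stable_code_generalizes():
    cfg = wm.SimConfig(n_units=32, n_trials_per_condition=8, tuning_gain=3.0,
                       tuning_in_off=True, ensemble_pairs_per_condition=0,
                       seed=34)
    spikes, trials, _ = wm.simulate_session(cfg)
    rates = wm.preprocess.smooth_and_zscore_rates(
        spikes, trials, t_start=400, t_stop=1400, step_ms=50, boxcar_ms=100)
    acc, sig, tms = wm.decode.cross_temporal_accuracy(rates, trials, seed=0,
                                                      n_perm=0)
    P = acc.shape[0]
    offdiag = acc[np.triu_indices(P, k=3)]
    # a time-invariant code generalizes: off-diagonal accuracy far above 0.5
    assert offdiag.mean() > 0.8
    assert np.allclose(acc, acc, equal_nan=False)
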