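"""Leave-one-trial-out cue decoding with time-resolved confidence.

For each held-out trial and 10-ms timepoint, a binary ridge-logistic
classifier is trained on the remaining trials of the held-out trial's cue
condition versus the diametrically opposite condition (class counts equalized
by seeded subsampling), and the posterior probability assigned to the correct
label is recorded as the classifier's confidence. The same machinery, with
training labels permuted, produces the shuffled-label null used for state
labeling. Cross-temporal (train at t1, test at t2) and state-restricted
variants reuse the same fit.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

from ._glm import CLIP, fit_ridge_logistic, predict_proba
from .core import (DELAY_WINDOW, LABEL_ON, LABEL_OFF, ConfidenceSeries,
                   RateTensor, StateSegments, opposite_location)

__all__ = ["loo_confidence", "cross_temporal_accuracy",
           "state_restricted_accuracy"]


def _check_zscored(rates: RateTensor):
    if not rates.zscored:
        raise ValueError("decoding expects a z-scored RateTensor")


def loo_confidence(rates: RateTensor, trials, lam: float = 100.0,
                   seed: int = 0, shuffle_labels: bool = False,
                   shuffle_rep: int = 0, window=None) -> ConfidenceSeries:
    """Leave-one-trial-out confidence/accuracy series for every trial.

    ``shuffle_labels`` permutes the training labels independently per
    (test trial, timepoint); ``shuffle_rep`` separates the RNG streams of
    repeated shuffle runs. ``window`` restricts fitting to a time range
    (NaN outside). Trials whose opposite condition has fewer than 2 trials
    are skipped (NaN rows). Fits for all test trials with the same training
    size are batched through one vectorized Newton solve.
    """
    _check_zscored(rates)
    tmask = (np.ones_like(rates.time_ms, bool) if window is None
             else rates.time_mask(window))
    X = np.ascontiguousarray(rates.values[:, :, tmask].transpose(2, 1, 0))
    P, T, U = X.shape
    cues = np.asarray(trials.set_index("trial_id").loc[rates.trial_ids,
                                                       "cue_location"])
    conf = np.full((T, P), np.nan)

    # group test trials by training-set size m so their fits batch together
    groups: dict[int, list] = {}
    for i in range(T):
        c, o = cues[i], opposite_location(cues[i])
        same = np.flatnonzero((cues == c) & (np.arange(T) != i))
        opp = np.flatnonzero(cues == o)
        if same.size < 1 or opp.size < 2:
            continue
        m = min(same.size, opp.size)
        rng = np.random.default_rng(np.random.SeedSequence(
            [seed, shuffle_rep, i]))
        # one equalizing subsample (and one label permutation) per test
        # trial, shared across timepoints: per-timepoint redraws would
        # inject white noise into the confidence series and break the
        # temporal contiguity the state rules rely on
        row = np.concatenate([rng.permutation(same)[:m],
                              rng.permutation(opp)[:m]])
        idx = np.tile(row, (P, 1))
        y_row = np.concatenate([np.ones(m), np.zeros(m)])
        if shuffle_labels:
            y_row = rng.permutation(y_row)
        y = np.tile(y_row, (P, 1))
        groups.setdefault(m, []).append((i, idx, y))

    pp = np.arange(P)[None, :, None]
    for m, items in groups.items():
        tids = np.array([it[0] for it in items])
        idx = np.stack([it[1] for it in items])        # (G, P, 2m)
        y = np.stack([it[2] for it in items])
        Xg = X[pp, idx, :]                             # (G, P, 2m, U)
        beta = fit_ridge_logistic(Xg, y, lam=lam)      # (G, P, U+1)
        xt = X[:, tids, :].transpose(1, 0, 2)          # (G, P, U)
        conf[tids] = predict_proba(beta, xt)           # P(label == own cue)

    conf = np.clip(conf, CLIP, 1 - CLIP)
    acc = (conf > 0.5).astype(float)
    acc[np.isnan(conf)] = np.nan
    full_conf = np.full((T, rates.time_ms.size), np.nan)
    full_acc = np.full((T, rates.time_ms.size), np.nan)
    full_conf[:, tmask] = conf
    full_acc[:, tmask] = acc
    return ConfidenceSeries(values=full_conf, accuracy=full_acc,
                            trial_ids=rates.trial_ids, time_ms=rates.time_ms)


def cross_temporal_accuracy(rates: RateTensor, trials, lam: float = 100.0,
                            seed: int = 0, n_perm: int = 25,
                            alpha: float = 0.001):
    """Split-half cross-temporal generalization matrix.

    Classifiers for each training timepoint are fit on a random half of the
    trials of each opposite-condition pair and tested, cross-temporally, on
    the held-out half. Returns ``(accuracy, significant, time_ms)`` where
    ``accuracy`` is train x test timepoints, and ``significant`` is a
    cluster-mass-corrected above-chance mask built from ``n_perm``
    label-shuffled matrices.
    """
    _check_zscored(rates)
    acc = _split_half_matrix(rates, trials, lam, seed, shuffle=False)
    if n_perm == 0:  # accuracy matrix only, no significance mask
        return acc, np.zeros_like(acc, dtype=bool), rates.time_ms
    null_masses, null_mats = [], []
    for r in range(n_perm):
        mat = _split_half_matrix(rates, trials, lam, seed, shuffle=True,
                                 rep=r + 1)
        null_mats.append(mat)
    null_mats = np.asarray(null_mats)
    mu, sd = null_mats.mean(0), null_mats.std(0, ddof=1)
    sd = np.where(sd > 0, sd, np.inf)
    z = (acc - mu) / sd
    zcrit = 1.96
    null_z = (null_mats - mu) / sd
    for r in range(n_perm):
        null_masses.append(_max_cluster_mass_2d(null_z[r], zcrit))
    thr = np.quantile(null_masses, 1 - alpha) if n_perm >= 20 else np.inf
    significant = _clusters_above_2d(z, zcrit, thr)
    return acc, significant, rates.time_ms


def _split_half_matrix(rates, trials, lam, seed, shuffle, rep=0):
    X = np.ascontiguousarray(rates.values.transpose(2, 1, 0))
    P, T, U = X.shape
    cues = np.asarray(trials.set_index("trial_id").loc[rates.trial_ids,
                                                       "cue_location"])
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7, rep]))
    acc = np.zeros((P, P))
    n_eval = 0
    for c in range(1, 5):
        o = opposite_location(c)
        ic = rng.permutation(np.flatnonzero(cues == c))
        io = rng.permutation(np.flatnonzero(cues == o))
        m = min(ic.size, io.size)
        if m < 4:
            continue
        ic, io = ic[:m], io[:m]
        h = m // 2
        tr = np.concatenate([ic[:h], io[:h]])
        te = np.concatenate([ic[h:], io[h:]])
        y_tr = np.concatenate([np.ones(h), np.zeros(h)])
        y_te = np.concatenate([np.ones(ic[h:].size), np.zeros(io[h:].size)])
        if shuffle:
            y_tr = rng.permutation(y_tr)
        beta = fit_ridge_logistic(X[:, tr, :], y_tr, lam=lam)  # (P, U+1)
        # decision values for every (train timepoint, test timepoint, trial)
        z = (np.einsum("pu,qnu->pqn", beta[:, :-1], X[:, te, :])
             + beta[:, -1][:, None, None])
        prob = expit(z)
        acc += ((prob > 0.5) == (y_te[None, None, :] > 0.5)).mean(axis=2)
        n_eval += 1
    return acc / max(n_eval, 1)


def _max_cluster_mass_2d(z, zcrit):
    from scipy import ndimage
    above = z > zcrit
    lab, n = ndimage.label(above)
    if n == 0:
        return 0.0
    return float(max(z[lab == i].sum() for i in range(1, n + 1)))


def _clusters_above_2d(z, zcrit, thr):
    from scipy import ndimage
    above = z > zcrit
    lab, n = ndimage.label(above)
    out = np.zeros_like(above)
    for i in range(1, n + 1):
        if z[lab == i].sum() > thr:
            out[lab == i] = True
    return out


def state_restricted_accuracy(rates: RateTensor, trials,
                              segments: StateSegments, which: str,
                              lam: float = 100.0, seed: int = 0,
                              window=DELAY_WINDOW):
    """LOO decoding confined to timepoints labeled ``which`` ("On"/"Off").

    Training samples at each timepoint come only from trials labeled
    ``which`` at that timepoint; a trial is tested at a timepoint only when
    it carries the same label there. Returns (mean accuracy, mean confidence)
    over the delay window, or raises if no timepoint qualifies.
    """
    _check_zscored(rates)
    code = LABEL_ON if which == "On" else LABEL_OFF
    labels = segments.timepoint_labels(rates.trial_ids, rates.time_ms)
    X = rates.values.transpose(2, 1, 0)  # (P, T, U)
    P, T, U = X.shape
    cues = np.asarray(trials.set_index("trial_id").loc[rates.trial_ids,
                                                       "cue_location"])
    wmask = (rates.time_ms >= window[0]) & (rates.time_ms < window[1])
    confs, accs = [], []
    for p in np.flatnonzero(wmask):
        in_state = labels[:, p] == code
        for i in np.flatnonzero(in_state):
            c, o = cues[i], opposite_location(cues[i])
            same = np.flatnonzero((cues == c) & in_state & (np.arange(T) != i))
            opp = np.flatnonzero((cues == o) & in_state)
            m = min(same.size, opp.size)
            if m < 2:
                continue
            rng = np.random.default_rng(np.random.SeedSequence([seed, p, i]))
            tr = np.concatenate([rng.choice(same, m, replace=False),
                                 rng.choice(opp, m, replace=False)])
            y = np.concatenate([np.ones(m), np.zeros(m)])
            beta = fit_ridge_logistic(X[p][tr], y, lam=lam)
            pr = float(predict_proba(beta, X[p, i]))
            confs.append(pr)
            accs.append(float(pr > 0.5))
    if not confs:
        raise ValueError(f"no usable {which}-state timepoints in the window")
    return float(np.mean(accs)), float(np.mean(confs))
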