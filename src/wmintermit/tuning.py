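"""State-conditioned tuning, population-rate profiles, variance partitioning.

Split-half cross-validation avoids circularity: one half of the units labels
On/Off states, tuning is read out from the held-out half, and the halves are
then swapped so every unit receives curves. Aligning each unit's curve to its
maximum necessarily manufactures a peak at 0 degrees even from noise, so
cue-label-shuffled null curves are subtracted.
"""

from __future__ import annotations

import numpy as np

from .core import (BASELINE_WINDOW, DELAY_WINDOW, LABEL_OFF, LABEL_ON,
                   RateTensor, StateSegments)

__all__ = ["split_half_state_tuning", "state_tuning_curves",
           "population_rate_profile", "partition_rate_variance",
           "preferred_condition_from_confidence"]


def _condition_state_means(values, labels, cues, conditions, code, wmask):
    """Mean rate per (unit, condition) over delay timepoints with a given
    state label; NaN where a condition has no such samples."""
    U = values.shape[0]
    out = np.full((U, len(conditions)), np.nan)
    sel_t = labels == code  # (trials, P)
    for ci, c in enumerate(conditions):
        m = sel_t[cues == c][:, wmask]
        v = values[:, cues == c, :][:, :, wmask]
        if m.any():
            out[:, ci] = np.nansum(np.where(m[None], v, 0.0), axis=(1, 2)) \
                / m.sum()
    return out


def state_tuning_curves(rates: RateTensor, trials, segments: StateSegments,
                        unit_subset=None, n_null: int = 20, seed: int = 0,
                        window=DELAY_WINDOW):
    """Null-corrected On/Off tuning curves aligned to the preferred location.

    Returns dict with ``on``/``off`` (units x 8, null-corrected, preferred
    location at column 0), raw curves, and per-unit preferred locations
    (argmax of On + Off; ties break to the lowest condition index).
    """
    cues = np.asarray(trials.set_index("trial_id").loc[rates.trial_ids,
                                                       "cue_location"])
    conditions = np.unique(cues)
    wmask = rates.time_mask(window)
    labels = segments.timepoint_labels(rates.trial_ids, rates.time_ms)
    vals = rates.values
    if unit_subset is not None:
        vals = vals[np.asarray(unit_subset)]

    on = _condition_state_means(vals, labels, cues, conditions, LABEL_ON, wmask)
    off = _condition_state_means(vals, labels, cues, conditions, LABEL_OFF, wmask)
    pref_idx = np.nanargmax(np.nan_to_num(on, nan=-np.inf)
                            + np.nan_to_num(off, nan=-np.inf), axis=1)

    rng = np.random.default_rng(np.random.SeedSequence([seed, 23]))
    null_on = np.zeros_like(on)
    null_off = np.zeros_like(off)
    for _ in range(n_null):
        sh = rng.permutation(cues)
        n_on = _condition_state_means(vals, labels, sh, conditions, LABEL_ON,
                                      wmask)
        n_off = _condition_state_means(vals, labels, sh, conditions,
                                       LABEL_OFF, wmask)
        null_on += _align(n_on, np.nanargmax(
            np.nan_to_num(n_on, nan=-np.inf) + np.nan_to_num(n_off, nan=-np.inf),
            axis=1))
        null_off += _align(n_off, np.nanargmax(
            np.nan_to_num(n_on, nan=-np.inf) + np.nan_to_num(n_off, nan=-np.inf),
            axis=1))
    null_on /= max(n_null, 1)
    null_off /= max(n_null, 1)

    on_al, off_al = _align(on, pref_idx), _align(off, pref_idx)
    return {"on": on_al - null_on, "off": off_al - null_off,
            "on_raw": on_al, "off_raw": off_al,
            "preferred_location": conditions[pref_idx],
            "conditions": conditions}


def _align(curves, pref_idx):
    """Roll each unit's 8-vector so its preferred condition sits at index 0."""
    out = np.empty_like(curves)
    for i, p in enumerate(pref_idx):
        out[i] = np.roll(curves[i], -int(p))
    return out


def split_half_state_tuning(rates: RateTensor, trials, labeler, seed: int = 0,
                            n_null: int = 20, window=DELAY_WINDOW):
    """Split-half tuning: each half's states label the other half's units.

    ``labeler(rates_subset, trials) -> StateSegments`` runs the full
    confidence -> null -> cluster labeling pipeline on a unit subset.
    Returns curves for all units (rows ordered as ``rates.unit_ids``).
    """
    U = rates.n_units
    if U < 2:
        raise ValueError("need at least 2 units to split")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 31]))
    half_a = np.sort(rng.choice(U, U // 2, replace=False))
    half_b = np.setdiff1d(np.arange(U), half_a)

    on = np.full((U, 8), np.nan)
    off = np.full((U, 8), np.nan)
    pref = np.zeros(U, dtype=int)
    for labeling_half, heldout in ((half_a, half_b), (half_b, half_a)):
        sub = RateTensor(rates.values[labeling_half],
                         rates.unit_ids[labeling_half], rates.trial_ids,
                         rates.time_ms, rates.zscored)
        segments = labeler(sub, trials)
        res = state_tuning_curves(rates, trials, segments,
                                  unit_subset=heldout, n_null=n_null,
                                  seed=seed, window=window)
        on[heldout] = res["on"]
        off[heldout] = res["off"]
        pref[heldout] = res["preferred_location"]
    return {"on": on, "off": off, "preferred_location": pref}


def preferred_condition_from_confidence(conf, trials, window=DELAY_WINDOW):
    """Cue location with the greatest mean delay confidence (session level)."""
    cues = np.asarray(trials.set_index("trial_id").loc[conf.trial_ids,
                                                       "cue_location"])
    m = (conf.time_ms >= window[0]) & (conf.time_ms < window[1])
    means = [np.nanmean(conf.values[cues == c][:, m])
             for c in np.unique(cues)]
    return int(np.unique(cues)[int(np.nanargmax(means))])


def population_rate_profile(rates_hz: RateTensor, trials,
                            segments: StateSegments, preferred_condition,
                            baseline=BASELINE_WINDOW, window=DELAY_WINDOW):
    """Population rate in baseline SDs, with On/Off-restricted delay means.

    Averages raw (non-z-scored) rates over units and preferred-condition
    trials, normalizes by the baseline-period mean and SD of that series,
    and additionally averages delay samples restricted to On and Off labels.
    """
    if rates_hz.zscored:
        raise ValueError("population profile expects raw rates (spikes/s)")
    cues = np.asarray(trials.set_index("trial_id").loc[rates_hz.trial_ids,
                                                       "cue_location"])
    sel = cues == preferred_condition
    series = rates_hz.values[:, sel, :].mean(axis=0)    # trials x P
    profile = series.mean(axis=0)
    bmask = rates_hz.time_mask(baseline)
    mu, sd = profile[bmask].mean(), profile[bmask].std(ddof=1)
    if sd == 0:
        raise ValueError("zero baseline SD; session flagged")
    zprof = (profile - mu) / sd

    labels = segments.timepoint_labels(rates_hz.trial_ids, rates_hz.time_ms)
    wmask = rates_hz.time_mask(window)
    zser = (series - mu) / sd
    out = {"time_ms": rates_hz.time_ms, "profile_z": zprof}
    for name, code in (("on", LABEL_ON), ("off", LABEL_OFF)):
        m = (labels[sel][:, wmask] == code)
        v = zser[:, wmask]
        out[f"{name}_delay_mean_z"] = (float(v[m].mean()) if m.any()
                                       else np.nan)
    return out


def partition_rate_variance(rates_hz: RateTensor, trials,
                            segments: StateSegments, window=DELAY_WINDOW,
                            downsample: int = 10):
    """Per-unit variance partition of delay rates into cue, state, interaction.

    Rates are downsampled to 100-ms steps (mean of 10 consecutive 10-ms
    samples); each sample carries the majority state label of its span
    (samples without an On/Off majority are dropped). Within On and within
    Off samples, the cue effect is the one-way eta-squared; the interaction
    is tested per unit by the F-change of adding cue x state terms to the
    additive linear model.

    Returns DataFrame with cue_var_on, cue_var_off (fractions) and
    interaction_p per unit.
    """
    import pandas as pd
    from scipy import stats as _st

    wmask = rates_hz.time_mask(window)
    tsel = np.flatnonzero(wmask)
    n_keep = (len(tsel) // downsample) * downsample
    tsel = tsel[:n_keep]
    vals = rates_hz.values[:, :, tsel]
    U, T = vals.shape[:2]
    vals = vals.reshape(U, T, -1, downsample).mean(axis=3)   # 100-ms samples
    labels = segments.timepoint_labels(rates_hz.trial_ids, rates_hz.time_ms)
    lab = labels[:, tsel].reshape(T, -1, downsample)
    n_on = (lab == LABEL_ON).sum(axis=2)
    n_off = (lab == LABEL_OFF).sum(axis=2)
    state = np.where(n_on > downsample / 2, LABEL_ON,
                     np.where(n_off > downsample / 2, LABEL_OFF, -1))
    cues = np.asarray(trials.set_index("trial_id").loc[rates_hz.trial_ids,
                                                       "cue_location"])
    conds = np.unique(cues)
    cue_grid = np.broadcast_to(cues[:, None], state.shape)

    keep = state >= 0
    rows = []
    for u in range(U):
        y = vals[u][keep]
        s = state[keep]
        c = cue_grid[keep]
        if not ((s == LABEL_ON).any() and (s == LABEL_OFF).any()):
            continue  # unit lacks one of the states
        row = {"unit_index": u}
        for name, code in (("on", LABEL_ON), ("off", LABEL_OFF)):
            m = s == code
            row[f"cue_var_{name}"] = _eta_squared(y[m], c[m], conds)
        row["interaction_p"] = _interaction_p(y, c, s, conds)
        rows.append(row)
    return pd.DataFrame(rows)


def _eta_squared(y, groups, levels):
    gm = y.mean()
    ss_tot = ((y - gm) ** 2).sum()
    if ss_tot == 0:
        return 0.0
    ss_b = sum(len(y[groups == g]) * (y[groups == g].mean() - gm) ** 2
               for g in levels if (groups == g).any())
    return float(ss_b / ss_tot)


def _interaction_p(y, cue, state, conds):
    """F-test of the cue x state terms via nested linear models."""
    from scipy import stats as _st
    n = y.size
    cue_d = np.stack([(cue == c).astype(float) for c in conds[1:]], axis=1)
    st_d = (state == LABEL_ON).astype(float)[:, None]
    X0 = np.concatenate([np.ones((n, 1)), cue_d, st_d], axis=1)
    inter = cue_d * st_d
    X1 = np.concatenate([X0, inter], axis=1)
    rss0 = _rss(X0, y)
    rss1 = _rss(X1, y)
    df1 = inter.shape[1]
    df2 = n - np.linalg.matrix_rank(X1)
    if df2 <= 0 or rss1 <= 0:
        return np.nan
    f = ((rss0 - rss1) / df1) / (rss1 / df2)
    return float(_st.f.sf(f, df1, df2))


def _rss(X, y):
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)
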