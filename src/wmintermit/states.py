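"""On/Off state segmentation of decoder-confidence time series.

The true confidence series of each trial is z-scored against a 50-replicate
shuffled-label null. Runs of individually significant z-values (> 1.96) form
candidate On clusters; a cluster is retained when its mass (sum of z inside
the run) exceeds the 95th percentile of a null cluster-mass distribution
built from the shuffle ensemble itself (each shuffle series z-scored against
the remaining shuffles, maximal cluster mass collected, pooled across trials
of the session). Runs of at least five consecutive timepoints (50 ms) below a
conservative one-sided threshold (P > 0.20, z < 0.8416) are Off states;
retained clusters of strongly negative z are "confidently incorrect" states.
Remaining timepoints stay unlabeled.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .core import (LABEL_SPAN, ConfidenceSeries, NullConfidenceEnsemble,
                   RateTensor, StateSegments, StateZSeries)
from .decode import loo_confidence

__all__ = ["build_null_confidence", "zscore_confidence", "label_states",
           "summarize_states", "null_cluster_masses", "balanced_state_accuracy"]

#: one-sided z threshold for P > 0.20 (Off states)
Z_OFF_ONESIDED = stats.norm.ppf(0.80)
#: two-sided variant (|z| below the 0.20 two-sided bound)
Z_OFF_TWOSIDED = stats.norm.ppf(0.90)


def build_null_confidence(rates: RateTensor, trials, n_shuffles: int = 50,
                          seed: int = 0, lam: float = 100.0, window=None
                          ) -> NullConfidenceEnsemble:
    """Shuffled-label confidence replicates (the decoding null ensemble).

    ``window`` restricts the decoded time range (the labeling span suffices
    for state segmentation and saves the pre-cue fits).
    """
    if n_shuffles < 10:
        warnings.warn("fewer than 10 shuffles gives an unstable null",
                      stacklevel=2)
    reps = []
    for s in range(n_shuffles):
        c = loo_confidence(rates, trials, lam=lam, seed=seed,
                           shuffle_labels=True, shuffle_rep=s + 1,
                           window=window)
        reps.append(c.values)
    values = np.stack(reps, axis=2)
    return NullConfidenceEnsemble(values=values, trial_ids=rates.trial_ids,
                                  time_ms=rates.time_ms)


def zscore_confidence(conf: ConfidenceSeries,
                      null: NullConfidenceEnsemble) -> StateZSeries:
    """z = (confidence - null mean) / null SD, elementwise.

    Cells with zero null SD get NaN (sentinel; excluded from labeling).
    """
    if conf.values.shape != null.values.shape[:2]:
        raise ValueError("confidence and null shapes do not match")
    sd = null.sd
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (conf.values - null.mean) / sd, np.nan)
    return StateZSeries(z=z, trial_ids=conf.trial_ids, time_ms=conf.time_ms)


def _runs(mask: np.ndarray):
    """(start, stop) index pairs of maximal True runs; stop exclusive."""
    m = np.asarray(mask, bool)
    if not m.any():
        return []
    d = np.diff(np.concatenate([[0], m.astype(int), [0]]))
    starts = np.flatnonzero(d == 1)
    stops = np.flatnonzero(d == -1)
    return list(zip(starts, stops))


def null_cluster_masses(null: NullConfidenceEnsemble, z_on: float = 1.96,
                        span=LABEL_SPAN) -> np.ndarray:
    """Maximal cluster mass per (trial, shuffle) under the shuffle null.

    Each shuffle series is z-scored against the leave-one-out mean/SD of the
    remaining shuffles, and the largest supra-threshold cluster mass within
    the labeling span is collected (0 when no cluster). Pooled across trials
    these masses form the session's null cluster-mass distribution.
    """
    v = null.values  # (T, P, S)
    T, P, S = v.shape
    wmask = (null.time_ms >= span[0]) & (null.time_ms < span[1])
    tot = v.sum(axis=2, keepdims=True)
    tot2 = (v ** 2).sum(axis=2, keepdims=True)
    mu = (tot - v) / (S - 1)
    var = (tot2 - v ** 2) / (S - 1) - mu ** 2
    # ddof-1 correction for the leave-one-out sample variance
    var = np.clip(var * (S - 1) / (S - 2), 0, None)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(var > 0, (v - mu) / np.sqrt(var), np.nan)
    z = z[:, wmask, :]
    out = np.zeros((T, S))
    for t in range(T):
        for s in range(S):
            zz = z[t, :, s]
            best = 0.0
            for a, b in _runs(np.nan_to_num(zz) > z_on):
                best = max(best, float(np.nansum(zz[a:b])))
            out[t, s] = best
    return out


def label_states(z: StateZSeries, null: NullConfidenceEnsemble,
                 z_on: float = 1.96, off_p: float = 0.20,
                 min_off_pts: int = 5, span=LABEL_SPAN,
                 two_sided_off: bool = False, pooled_null: bool = True,
                 mass_threshold: float | None = None) -> StateSegments:
    """Segment each trial into On / Off / incorrect states.

    ``mass_threshold`` overrides the internally computed 95th-percentile
    null cluster-mass threshold (useful for oracles). With ``pooled_null``
    the threshold pools maxima across all trials of the session; otherwise a
    per-trial threshold is used.
    """
    wmask = (z.time_ms >= span[0]) & (z.time_ms < span[1])
    tgrid = z.time_ms[wmask]
    step = float(np.median(np.diff(tgrid))) if tgrid.size > 1 else 10.0
    zz = z.z[:, wmask]
    T = zz.shape[0]

    if mass_threshold is None:
        masses = null_cluster_masses(null, z_on=z_on, span=span)
        if pooled_null:
            thr = np.full(T, np.quantile(masses.ravel(), 0.95))
        else:
            thr = np.quantile(masses, 0.95, axis=1)
    else:
        thr = np.full(T, float(mass_threshold))

    z_off = Z_OFF_TWOSIDED if two_sided_off else stats.norm.ppf(1 - off_p)
    rows = []
    for t in range(T):
        row = np.nan_to_num(zz[t], nan=0.0)
        finite = np.isfinite(zz[t])
        for a, b in _runs((row > z_on) & finite):
            if row[a:b].sum() > thr[t]:
                rows.append((z.trial_ids[t], "On", tgrid[a], tgrid[b - 1] + step))
        for a, b in _runs((row < -z_on) & finite):
            if -row[a:b].sum() > thr[t]:
                rows.append((z.trial_ids[t], "incorrect", tgrid[a],
                             tgrid[b - 1] + step))
        off_mask = (np.abs(row) < z_off) if two_sided_off else (row < z_off)
        for a, b in _runs(off_mask & finite):
            if b - a >= min_off_pts:
                rows.append((z.trial_ids[t], "Off", tgrid[a],
                             tgrid[b - 1] + step))
    table = pd.DataFrame(rows, columns=["trial_id", "label", "t_start_ms",
                                        "t_end_ms"])
    return StateSegments(table=table, span=tuple(span), step_ms=step)


def summarize_states(segments: StateSegments, trials=None) -> dict:
    """Counts, duration statistics and (optionally) state at the go cue.

    Duration statistics exclude right-censored intervals (states still in
    progress at the end of the labeling span): their observed lengths are
    truncations of the true ones and would bias the means downward. Counts
    include them.
    """
    tab = segments.table
    span_end = segments.span[1]
    out = {}
    for label in ("On", "Off", "incorrect"):
        sub = tab[tab["label"] == label]
        complete = sub[sub["t_end_ms"] < span_end - 1e-9]
        durs = (complete["t_end_ms"] - complete["t_start_ms"]).to_numpy()
        per_trial = sub.groupby("trial_id").size()
        out[label] = {
            "n": int(len(sub)),
            "mean_per_trial": float(per_trial.reindex(
                tab["trial_id"].unique(), fill_value=0).mean()) if len(tab) else 0.0,
            "mean_duration_ms": float(durs.mean()) if durs.size else np.nan,
            "median_duration_ms": float(np.median(durs)) if durs.size else np.nan,
            "durations_ms": durs,
        }
    if trials is not None:
        go = trials.set_index("trial_id")["go_time_ms"]
        at_go = {}
        for tid, g in go.items():
            # state containing the last labeled timepoint before the go cue
            sub = tab[(tab["trial_id"] == tid) & (tab["t_start_ms"] <= g)]
            if len(sub):
                last = sub.loc[(sub["t_end_ms"] - g).abs().idxmin()]
                at_go[tid] = last["label"]
            else:
                at_go[tid] = "unlabeled"
        out["state_at_go"] = at_go
    return out


def balanced_state_accuracy(detected: np.ndarray, truth: np.ndarray) -> float:
    """Balanced accuracy of detected On(1)/Off(0) timepoint labels vs ground
    truth, over timepoints where both carry an On/Off label."""
    m = np.isin(detected, (0, 1)) & np.isin(truth, (0, 1))
    if not m.any():
        return np.nan
    d, g = detected[m], truth[m]
    sens = (d[g == 1] == 1).mean() if (g == 1).any() else np.nan
    spec = (d[g == 0] == 0).mean() if (g == 0).any() else np.nan
    return float(np.nanmean([sens, spec]))
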