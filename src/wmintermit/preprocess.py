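"""Spike-event tables to analysis-ready tensors, unit filters, QC statistics.

Rates are obtained by representing each spike as a delta function, convolving
with a 100-ms boxcar (centred by default), and sampling every 10 ms; decoding
consumes the per-(unit, timepoint) across-trial z-scored version. CCGs consume
1-ms binarized rasters (bins with >= 2 spikes clip to 1: the cross-correlogram
treats the train as an indicator).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .core import BinaryRaster, RateTensor

__all__ = ["smooth_and_zscore_rates", "bin_raster", "filter_units",
           "classify_functional_subtype", "estimate_noise_sd", "unit_meta"]


def smooth_and_zscore_rates(spikes: pd.DataFrame, trials: pd.DataFrame,
                            t_start: float = -400.0, t_stop: float = 1400.0,
                            step_ms: float = 10.0, boxcar_ms: float = 100.0,
                            zscore: bool = True, causal: bool = False,
                            unit_ids=None) -> RateTensor:
    """Boxcar-smoothed rates (spikes/s) on a uniform grid, optionally z-scored.

    The rate at sample time ``t`` is the spike count in ``[t - w/2, t + w/2)``
    (centred boxcar; ``[t - w, t)`` when ``causal``) divided by the boxcar
    width. Z-scoring is across trials per (unit, timepoint); zero-variance
    cells are imputed to 0 and flagged in ``valid``.
    """
    if boxcar_ms <= 0 or step_ms <= 0 or boxcar_ms % step_ms:
        raise ValueError("boxcar width must be a positive multiple of the step")
    unit_ids = (np.unique(spikes["unit_id"]) if unit_ids is None
                else np.asarray(unit_ids))
    if unit_ids.size == 0:
        raise ValueError("empty unit set")
    trial_ids = np.asarray(trials["trial_id"])
    time_ms = np.arange(t_start, t_stop, step_ms)

    k = int(boxcar_ms // step_ms)
    half = 0 if causal else boxcar_ms / 2.0
    # micro-bin counts covering every boxcar window, then a length-k moving sum
    lo = t_start - (boxcar_ms if causal else half)
    n_micro = int(np.ceil((t_stop - lo) / step_ms)) + k + 1
    edges_lo = lo

    uidx = {u: i for i, u in enumerate(unit_ids)}
    tidx = {t: i for i, t in enumerate(trial_ids)}
    counts = np.zeros((unit_ids.size, trial_ids.size, n_micro))
    su = spikes["unit_id"].to_numpy()
    st = spikes["trial_id"].to_numpy()
    ss = spikes["t_ms"].to_numpy()
    keep = (np.isin(su, unit_ids) & np.isin(st, trial_ids)
            & (ss >= edges_lo) & (ss < edges_lo + n_micro * step_ms))
    iu = np.fromiter((uidx[u] for u in su[keep]), int, count=int(keep.sum()))
    it = np.fromiter((tidx[t] for t in st[keep]), int, count=int(keep.sum()))
    ib = ((ss[keep] - edges_lo) // step_ms).astype(int)
    np.add.at(counts, (iu, it, ib), 1.0)

    csum = np.concatenate([np.zeros(counts.shape[:2] + (1,)),
                           np.cumsum(counts, axis=2)], axis=2)
    # sample t covers micro-bins [t - half, t - half + boxcar)
    first = ((time_ms - half) - edges_lo) / step_ms
    first = np.round(first).astype(int)
    vals = (csum[:, :, first + k] - csum[:, :, first]) / (boxcar_ms / 1000.0)

    valid = None
    if zscore:
        mu = vals.mean(axis=1, keepdims=True)
        sd = vals.std(axis=1, keepdims=True, ddof=0)
        valid = (sd[:, 0, :] > 0)
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = np.where(sd > 0, (vals - mu) / sd, 0.0)
    return RateTensor(vals, unit_ids, trial_ids, time_ms, zscored=zscore,
                      valid=valid)


def bin_raster(spikes: pd.DataFrame, window: tuple[float, float],
               trial_ids=None, unit_ids=None) -> BinaryRaster:
    """1-ms binary raster over ``[start, end)``; multi-spike bins clip to 1."""
    start, end = window
    if end <= start:
        raise ValueError("inverted window")
    unit_ids = (np.unique(spikes["unit_id"]) if unit_ids is None
                else np.asarray(unit_ids))
    trial_ids = (np.unique(spikes["trial_id"]) if trial_ids is None
                 else np.asarray(trial_ids))
    n_bins = int(round(end - start))
    x = np.zeros((unit_ids.size, trial_ids.size, n_bins), dtype=np.uint8)
    uidx = {u: i for i, u in enumerate(unit_ids)}
    tidx = {t: i for i, t in enumerate(trial_ids)}
    su = spikes["unit_id"].to_numpy()
    st = spikes["trial_id"].to_numpy()
    ss = spikes["t_ms"].to_numpy()
    keep = (np.isin(su, unit_ids) & np.isin(st, trial_ids)
            & (ss >= start) & (ss < end))
    for u, t, s in zip(su[keep], st[keep], ss[keep]):
        x[uidx[u], tidx[t], int(np.floor(s - start))] = 1
    return BinaryRaster(x, unit_ids, trial_ids, (float(start), float(end)))


def filter_units(spikes: pd.DataFrame, total_time_s: float,
                 min_total_spikes: int = 1000, min_rate_hz: float = 1.0):
    """Nested unit subsets: analysis units (spike-count floor) and CCG-eligible
    units (additionally a mean-rate floor over the recording).

    Returns ``(analysis_units, ccg_units)`` as sorted arrays of unit ids.
    """
    counts = spikes.groupby("unit_id").size()
    analysis = counts[counts >= min_total_spikes]
    rates = analysis / float(total_time_s)
    ccg = analysis[rates > min_rate_hz]
    return analysis.index.to_numpy(), ccg.index.to_numpy()


def unit_meta(spikes: pd.DataFrame, total_time_s: float) -> pd.DataFrame:
    counts = spikes.groupby("unit_id").size().rename("total_spikes")
    meta = counts.reset_index()
    meta["mean_rate_hz"] = meta["total_spikes"] / float(total_time_s)
    return meta


def _epoch_counts(spikes, trials, lo, hi, per_trial_windows=None):
    """Mean rate (Hz) per (unit, trial) within an epoch."""
    units = np.unique(spikes["unit_id"])
    tids = trials["trial_id"].to_numpy()
    uidx = {u: i for i, u in enumerate(units)}
    tidx = {t: i for i, t in enumerate(tids)}
    out = np.zeros((units.size, tids.size))
    su, st, ss = (spikes[c].to_numpy() for c in ("unit_id", "trial_id", "t_ms"))
    if per_trial_windows is None:
        dur = (hi - lo) / 1000.0
        keep = (ss >= lo) & (ss < hi)
        for u, t in zip(su[keep], st[keep]):
            if t in tidx:
                out[uidx[u], tidx[t]] += 1
        out /= dur
    else:
        win = {t: w for t, w in zip(tids, per_trial_windows)}
        for u, t, s in zip(su, st, ss):
            if t in tidx:
                a, b = win[t]
                if a <= s < b:
                    out[uidx[u], tidx[t]] += 1
        durs = np.array([(b - a) / 1000.0 for a, b in per_trial_windows])
        out /= durs[None, :]
    return units, out


def classify_functional_subtype(spikes: pd.DataFrame, trials: pd.DataFrame,
                                alpha: float = 0.05) -> pd.DataFrame:
    """Visual/memory/motor selectivity by one-way ANOVA of epoch rate on cue.

    Epochs: visual [0, 300) and memory [500, 1400) ms after cue onset; motor
    [100, 300) ms after fixation offset (the go cue). A unit is selective in
    an epoch when cue location modulates its epoch-mean rate at P < alpha;
    the subtype is the set of selective epochs.
    """
    cues = trials["cue_location"].to_numpy()
    conds = np.unique(cues)
    ok = sum((cues == c).sum() >= 2 for c in conds)
    if ok < 2:
        raise ValueError("need >= 2 conditions with >= 2 trials for the ANOVA")
    go = trials["go_time_ms"].to_numpy()
    epochs = {
        "visual": (0.0, 300.0, None),
        "memory": (500.0, 1400.0, None),
        "motor": (None, None, [(g + 100.0, g + 300.0) for g in go]),
    }
    units = np.unique(spikes["unit_id"])
    res = pd.DataFrame({"unit_id": units})
    for name, (lo, hi, win) in epochs.items():
        u_arr, rate = _epoch_counts(spikes, trials, lo, hi, win)
        assert np.array_equal(u_arr, units)
        ps = np.ones(units.size)
        groups_idx = [cues == c for c in conds]
        for i in range(units.size):
            samples = [rate[i, g] for g in groups_idx if g.sum() >= 2]
            if len(samples) < 2 or all(np.ptp(s) == 0 for s in samples):
                continue
            ps[i] = stats.f_oneway(*samples).pvalue
        res[name] = ps < alpha
        res[name + "_p"] = ps
    res["subtype"] = [
        "+".join(n for n in ("visual", "memory", "motor") if row[n]) or "none"
        for _, row in res.iterrows()]
    return res


def estimate_noise_sd(x) -> float:
    """Robust noise SD of a raw trace segment: median(|x|) / 0.6745."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty segment")
    s = float(np.median(np.abs(x)) / 0.6745)
    if s == 0.0:
        warnings.warn("all-zero segment; noise SD estimate is 0", stacklevel=2)
    return s
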