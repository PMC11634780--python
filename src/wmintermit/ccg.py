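"""Jitter-corrected cross-correlograms and the functional-connection rule.

The raw CCG between units j and k in condition c is the lag-resolved
coincidence count summed over trials, normalized by the geometric mean of the
two units' (lag-trimmed) spike counts:

    CCG(tau) = sum_i sum_t x_j^i(t - tau) x_k^i(t)
               / sqrt(sum_i sum_t x_j^i(t - tau) * sum_i sum_t x_k^i(t))

with 1-ms binary bins over the memory delay. The jitter null redistributes
each trial's spikes within fixed 25-ms windows while preserving the per-trial
window counts and the across-trial PSTH; its closed-form expectation at bin t
is n_k^i(w) PSTH_k(t) / sum_{t' in w} PSTH_k(t') (uniform within the window
when the PSTH mass is 0). Subtracting the jittered from the raw CCG removes
stimulus locking and co-modulation slower than the window. A pair is a
putative functional connection when the corrected CCG peaks within 10 ms of
zero (zero lag excluded) at more than 7 SDs above the mean of the high-lag
(50 < |tau| < 100 ms) baseline.
"""

from __future__ import annotations

import warnings

import numpy as np

from .core import DELAY_WINDOW, LABEL_ON, LABEL_OFF, BinaryRaster, StateSegments

__all__ = ["CCG_LAG_MAX", "compute_ccg", "jitter_expectation",
           "jitter_monte_carlo", "corrected_ccg", "flag_significant_ccg",
           "ccg_condition_edges", "state_restricted_raster",
           "distance_dependence", "lag_axis"]

CCG_LAG_MAX = 100           # ms, lag axis is [-100, 100]
PEAK_LAGS = 10              # significant peaks must lie within +/- 10 ms
BASELINE_RANGE = (50, 100)  # high-lag baseline: 50 < |tau| < 100
SIGMA_CRIT = 7.0
JITTER_WINDOW_MS = 25


def lag_axis() -> np.ndarray:
    return np.arange(-CCG_LAG_MAX, CCG_LAG_MAX + 1)


def _nfft(n_bins: int) -> int:
    # zero padding to n + max lag suffices: the circular wrap terms fall
    # outside the support of the linear correlation
    return 1 << int(np.ceil(np.log2(n_bins + CCG_LAG_MAX + 1)))


def _raw_numerators(X: np.ndarray, pairs_j, pairs_k) -> np.ndarray:
    """Coincidence counts per pair and lag, summed over trials.

    X: (units, trials, bins) binary. Returns (n_pairs, 201) float (integer
    valued). Lag convention: positive tau means unit k fires after unit j.
    """
    U, M, N = X.shape
    nfft = _nfft(N)
    F = np.fft.rfft(X.astype(np.float64), n=nfft, axis=2)
    S = (np.conj(F[pairs_j]) * F[pairs_k]).sum(axis=1)
    cc = np.fft.irfft(S, n=nfft, axis=1)
    lags = lag_axis()
    out = cc[:, lags % nfft]
    return np.round(out)


def _trimmed_denominator(X: np.ndarray) -> np.ndarray:
    """Per-unit spike-count sums trimmed to the lag-dependent bin ranges.

    Returns (cj_lead, ck_trail): for lag tau >= 0 the j-count over bins
    [0, N - tau) and the k-count over bins [tau, N); mirrored for tau < 0.
    Shapes (units, 201).
    """
    U, M, N = X.shape
    tot = X.sum(axis=1)                       # (U, N) summed over trials
    csum = np.concatenate([np.zeros((U, 1)), np.cumsum(tot, axis=1)], axis=1)
    total = csum[:, -1]
    a = np.abs(lag_axis())
    lead = csum[:, N - a]                     # count in [0, N - |tau|)
    trail = total[:, None] - csum[:, a]       # count in [|tau|, N)
    return lead, trail


def _denominator(X, pairs_j, pairs_k):
    lead, trail = _trimmed_denominator(X)
    lags = lag_axis()
    pos = lags >= 0
    den = np.empty((len(pairs_j), lags.size))
    # tau >= 0: x_j over leading bins, x_k over trailing bins; mirrored else
    den[:, pos] = np.sqrt(lead[pairs_j][:, pos] * trail[pairs_k][:, pos])
    den[:, ~pos] = np.sqrt(trail[pairs_j][:, ~pos] * lead[pairs_k][:, ~pos])
    return den


def compute_ccg(raster: BinaryRaster, j: int, k: int, trial_indices=None):
    """Raw geometric-mean-normalized CCG for one pair.

    ``j``/``k`` index into ``raster.unit_ids``. Returns dict with ``lags``,
    ``ccg`` (normalized), ``numerator`` (integer counts) and ``denominator``.
    Positive lag = k fires after j.
    """
    X = _select(raster, trial_indices)
    if X[j].sum() == 0 or X[k].sum() == 0:
        raise ValueError("pair-condition excluded: a unit has no spikes")
    num = _raw_numerators(X, np.array([j]), np.array([k]))[0]
    den = _denominator(X, np.array([j]), np.array([k]))[0]
    with np.errstate(invalid="ignore", divide="ignore"):
        ccg = np.where(den > 0, num / den, 0.0)
    return {"lags": lag_axis(), "ccg": ccg, "numerator": num,
            "denominator": den}


def _select(raster, trial_indices):
    X = raster.values
    if trial_indices is not None:
        X = X[:, np.asarray(trial_indices), :]
    return np.asarray(X, dtype=np.float64)


def _psth_profiles(X, window_ms):
    """Per-unit window counts and within-window PSTH profiles.

    Returns A (U, M, W) spike counts per jitter window, and Q (U, W, L)
    normalized within-window profile (PSTH / window mass; uniform when the
    window has zero PSTH mass). N must tile into windows; a final partial
    window is padded with zeros.
    """
    U, M, N = X.shape
    L = int(window_ms)
    W = int(np.ceil(N / L))
    pad = W * L - N
    if pad:
        X = np.concatenate([X, np.zeros((U, M, pad))], axis=2)
    Xw = X.reshape(U, M, W, L)
    A = Xw.sum(axis=3)
    psth = Xw.mean(axis=1)                    # (U, W, L)
    mass = psth.sum(axis=2, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        Q = np.where(mass > 0, psth / mass, 1.0 / L)
    return A, Q, W, L, pad


def _expected_jitter_trains(X, window_ms=JITTER_WINDOW_MS):
    """Expected jittered trains y (units, trials, bins): per window, the
    trial's spike count redistributed along the condition PSTH profile."""
    U, M, N = X.shape
    A, Q, W, L, pad = _psth_profiles(X, window_ms)
    y = (A[:, :, :, None] * Q[:, None, :, :]).reshape(U, M, W * L)
    return y[:, :, :N]


def _jitter_numerators(X, pairs_j, pairs_k, window_ms=JITTER_WINDOW_MS,
                       Fx=None):
    """Closed-form expected coincidence counts under jitter of the k train."""
    U, M, N = X.shape
    y = _expected_jitter_trains(X, window_ms)
    nfft = _nfft(N)
    if Fx is None:
        Fx = np.fft.rfft(X, n=nfft, axis=2)
    Fy = np.fft.rfft(y, n=nfft, axis=2)
    S = _pair_cross_spectra(Fx, Fy, pairs_j, pairs_k)
    cc = np.fft.irfft(S, n=nfft, axis=1)
    return cc[:, lag_axis() % nfft]


def jitter_expectation(raster: BinaryRaster, j: int, k: int,
                       trial_indices=None, window_ms: int = JITTER_WINDOW_MS):
    """Expected normalized CCG under the jitter null (analytic closed form).

    Only the second unit (k) is jittered; normalization reuses the raw
    denominator (jitter preserves per-trial spike counts).
    """
    if window_ms <= 1:
        raise ValueError("jitter window must exceed 1 ms")
    X = _select(raster, trial_indices)
    num = _jitter_numerators(X, np.array([j]), np.array([k]),
                             window_ms=window_ms)[0]
    den = _denominator(X, np.array([j]), np.array([k]))[0]
    with np.errstate(invalid="ignore", divide="ignore"):
        ccg = np.where(den > 0, num / den, 0.0)
    return {"lags": lag_axis(), "ccg": ccg, "numerator": num,
            "denominator": den}


def jitter_monte_carlo(raster: BinaryRaster, j: int, k: int,
                       trial_indices=None, window_ms: int = JITTER_WINDOW_MS,
                       n_resamples: int = 1000, seed: int = 0):
    """Monte-Carlo jitter: resample each trial's k-train spike positions
    i.i.d. within each window according to the PSTH profile, recompute the
    (count-valued) cross-correlation, and average. Oracle for the closed form.
    """
    X = _select(raster, trial_indices)
    U, M, N = X.shape
    A, Q, W, L, pad = _psth_profiles(X, window_ms)
    rng = np.random.default_rng(seed)
    lags = lag_axis()
    xj = X[j]
    acc = np.zeros(lags.size)
    npad = N + pad
    nfft = _nfft(N)
    Fj = np.fft.rfft(xj, n=nfft, axis=1)
    for _ in range(n_resamples):
        yk = np.zeros((M, npad))
        for w in range(W):
            q = Q[k, w]
            for i in range(M):
                n = int(A[k, i, w])
                if n == 0:
                    continue
                pos = rng.choice(L, size=n, p=q)
                np.add.at(yk[i], w * L + pos, 1.0)
        yk = yk[:, :N]
        Fk = np.fft.rfft(yk, n=nfft, axis=1)
        cc = np.fft.irfft((np.conj(Fj) * Fk).sum(axis=0), n=nfft)
        acc += cc[lags % nfft]
    num = acc / n_resamples
    den = _denominator(X, np.array([j]), np.array([k]))[0]
    with np.errstate(invalid="ignore", divide="ignore"):
        ccg = np.where(den > 0, num / den, 0.0)
    return {"lags": lags, "ccg": ccg, "numerator": num, "denominator": den}


def corrected_ccg(raster: BinaryRaster, j: int, k: int, trial_indices=None,
                  window_ms: int = JITTER_WINDOW_MS):
    raw = compute_ccg(raster, j, k, trial_indices)
    jit = jitter_expectation(raster, j, k, trial_indices, window_ms)
    return {"lags": raw["lags"], "ccg": raw["ccg"] - jit["ccg"],
            "raw": raw, "jitter": jit}


def flag_significant_ccg(corrected: np.ndarray, lags: np.ndarray | None = None):
    """Apply the 7-SD / short-lag significance rule to a corrected CCG.

    Peak is searched over 1 <= |tau| <= 10 (zero lag excluded; ties broken
    toward smaller |tau|, then negative lag); baseline mean/SD come from
    50 < |tau| < 100. Returns (significant, peak_lag, peak_z).
    """
    if lags is None:
        lags = lag_axis()
    corrected = np.asarray(corrected)
    base = (np.abs(lags) > BASELINE_RANGE[0]) & (np.abs(lags) < BASELINE_RANGE[1])
    mu = corrected[..., base].mean(-1)
    sd = corrected[..., base].std(-1, ddof=1)
    search = (np.abs(lags) >= 1) & (np.abs(lags) <= PEAK_LAGS)
    sidx = np.flatnonzero(search)
    order = sorted(sidx, key=lambda i: (abs(int(lags[i])), lags[i]))
    vals = corrected[..., order]
    best = np.argmax(vals, axis=-1)
    peak = np.max(vals, axis=-1)
    peak_lag = np.asarray(lags)[np.asarray(order)[best]]
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (peak - mu) / sd, 0.0)
    significant = (sd > 0) & (peak > mu + SIGMA_CRIT * sd)
    return significant, peak_lag, z


def make_fft_cache(raster: BinaryRaster) -> dict:
    """Per-trial spectra reused across permutation reruns of the pipeline.

    Holds complex64 FFTs of every unit x trial train plus per-trial count
    cumsums; numerators recovered from these match the float64 path after
    rounding (counts are small integers, far inside float32 precision).
    """
    X = np.asarray(raster.values, dtype=np.float32)
    U, T, N = X.shape
    nfft = _nfft(N)
    Fx = np.fft.rfft(X, n=nfft, axis=2).astype(np.complex64)
    csum = np.concatenate([np.zeros((U, T, 1), np.float32),
                           np.cumsum(X, axis=2, dtype=np.float32)], axis=2)
    return {"Fx": Fx, "csum": csum, "nfft": nfft, "n_bins": N}


def _pair_cross_spectra(Fa, Fb, pairs_j, pairs_k):
    """sum_i conj(Fa[j, i]) * Fb[k, i] for each pair; when the pair list is
    dense the all-pairs einsum beats per-pair gathers."""
    U = Fa.shape[0]
    if U * U <= 4 * len(pairs_j):
        S_all = np.einsum("uik,vik->uvk", np.conj(Fa), Fb, optimize=True)
        return S_all[pairs_j, pairs_k]
    return (np.conj(Fa[pairs_j]) * Fb[pairs_k]).sum(axis=1)


def _cached_raw_numerators(cache, idx, pairs_j, pairs_k):
    F = cache["Fx"][:, idx, :]
    S = _pair_cross_spectra(F, F, pairs_j, pairs_k)
    cc = np.fft.irfft(S, n=cache["nfft"], axis=1)
    return np.round(cc[:, lag_axis() % cache["nfft"]].astype(np.float64))


def _cached_denominator(cache, idx, pairs_j, pairs_k):
    N = cache["n_bins"]
    csum = cache["csum"][:, idx, :].sum(axis=1).astype(np.float64)
    total = csum[:, -1]
    a = np.abs(lag_axis())
    lead = csum[:, N - a]
    trail = total[:, None] - csum[:, a]
    lags = lag_axis()
    pos = lags >= 0
    den = np.empty((len(pairs_j), lags.size))
    den[:, pos] = np.sqrt(lead[pairs_j][:, pos] * trail[pairs_k][:, pos])
    den[:, ~pos] = np.sqrt(trail[pairs_j][:, ~pos] * lead[pairs_k][:, ~pos])
    return den


def ccg_condition_edges(raster: BinaryRaster, trial_conditions, pairs,
                        conditions=None, window_ms: int = JITTER_WINDOW_MS,
                        min_coverage_ms: float = 50.0,
                        labeled_ms_per_trial=None,
                        trial_subsets: dict | None = None,
                        cache: dict | None = None):
    """Significant-CCG edges for every pair in every cue condition.

    Parameters
    ----------
    trial_conditions : condition label per raster trial.
    pairs : sequence of (j, k) indices into ``raster.unit_ids``.
    labeled_ms_per_trial : for state-restricted rasters, the labeled time per
        trial (ms); conditions whose total falls below ``min_coverage_ms``
        are excluded.
    trial_subsets : optional {condition: trial index array} overriding the
        condition lookup (used by permutation nulls).

    Returns dict with ``significant`` (n_pairs, n_conditions) bool,
    ``evaluated`` mask, ``peak_lag``, ``peak_z`` arrays.
    """
    trial_conditions = np.asarray(trial_conditions)
    if conditions is None:
        conditions = np.unique(trial_conditions)
    pairs = np.asarray(pairs, dtype=int)
    pj, pk = pairs[:, 0], pairs[:, 1]
    nP, nC = len(pairs), len(conditions)
    sig = np.zeros((nP, nC), dtype=bool)
    evaluated = np.zeros((nP, nC), dtype=bool)
    peak_lag = np.zeros((nP, nC), dtype=int)
    peak_z = np.zeros((nP, nC))
    for ci, c in enumerate(conditions):
        idx = (trial_subsets[c] if trial_subsets is not None
               else np.flatnonzero(trial_conditions == c))
        if len(idx) < 2:
            continue
        if labeled_ms_per_trial is not None and \
                np.asarray(labeled_ms_per_trial)[idx].sum() < min_coverage_ms:
            continue
        if cache is not None:
            counts = cache["csum"][:, idx, -1].sum(axis=1)
        else:
            X = _select(raster, idx)
            counts = X.sum(axis=(1, 2))
        ok = (counts[pj] > 0) & (counts[pk] > 0)
        if not ok.any():
            continue
        jj, kk = pj[ok], pk[ok]
        if cache is not None:
            X32 = np.asarray(raster.values[:, idx, :], dtype=np.float32)
            raw = _cached_raw_numerators(cache, idx, jj, kk)
            jit = _jitter_numerators(X32, jj, kk, window_ms,
                                     Fx=cache["Fx"][:, idx, :])
            den = _cached_denominator(cache, idx, jj, kk)
        else:
            raw = _raw_numerators(X, jj, kk)
            jit = _jitter_numerators(X, jj, kk, window_ms)
            den = _denominator(X, jj, kk)
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.where(den > 0, (raw - jit) / den, 0.0)
        s, pl, pz = flag_significant_ccg(corr)
        sig[ok, ci] = s
        evaluated[ok, ci] = True
        peak_lag[ok, ci] = pl
        peak_z[ok, ci] = pz
    return {"significant": sig, "evaluated": evaluated, "peak_lag": peak_lag,
            "peak_z": peak_z, "pairs": pairs, "conditions": np.asarray(conditions)}


def state_restricted_raster(raster: BinaryRaster, segments: StateSegments,
                            which: str) -> BinaryRaster:
    """Zero all bins not labeled ``which`` ("On"/"Off"); 10-ms labels are
    expanded to the 1-ms grid."""
    code = LABEL_ON if which == "On" else LABEL_OFF
    t0 = raster.window[0]
    bin_times = t0 + np.arange(raster.n_bins)  # 1-ms resolution
    lab = segments.timepoint_labels(raster.trial_ids, bin_times)
    mask = (lab == code)
    if not mask.any():
        warnings.warn(f"state mask empty: no {which}-labeled bins",
                      stacklevel=2)
    out = (raster.values * mask[None, :, :].astype(raster.values.dtype))
    return BinaryRaster(out, raster.unit_ids, raster.trial_ids, raster.window)


def state_restricted_ccg(raster: BinaryRaster, segments: StateSegments,
                         which: str, trial_conditions, pairs,
                         window_ms: int = JITTER_WINDOW_MS,
                         min_coverage_ms: float = 50.0, **kwargs):
    """Full significance pipeline on a state-masked raster.

    Masks all bins not labeled ``which``, recomputes denominators, PSTHs and
    jitter expectations on the masked data, and excludes condition subsets
    with under ``min_coverage_ms`` of labeled time.
    """
    masked = state_restricted_raster(raster, segments, which)
    code = LABEL_ON if which == "On" else LABEL_OFF
    bin_times = raster.window[0] + np.arange(raster.n_bins)
    lab = segments.timepoint_labels(raster.trial_ids, bin_times)
    per_trial = (lab == code).sum(axis=1).astype(float)
    return ccg_condition_edges(masked, trial_conditions, pairs,
                               window_ms=window_ms,
                               min_coverage_ms=min_coverage_ms,
                               labeled_ms_per_trial=per_trial, **kwargs)


def delay_raster_from_spikes(spikes, trials, unit_ids=None,
                             window=DELAY_WINDOW) -> BinaryRaster:
    from .preprocess import bin_raster
    return bin_raster(spikes, window, trial_ids=trials["trial_id"].to_numpy(),
                      unit_ids=unit_ids)


def distance_dependence(pairs, significant_any, positions_um,
                        n_bins: int = 8):
    """Connection probability vs inter-unit distance.

    ``significant_any``: bool per pair (significant in any condition).
    Returns (table DataFrame with distance-bin centers and probabilities,
    Pearson r over pairs between distance and significance indicator).
    """
    import pandas as pd
    from scipy import stats as _st
    pairs = np.asarray(pairs)
    pos = np.asarray(positions_um, dtype=float)
    d = np.abs(pos[pairs[:, 0]] - pos[pairs[:, 1]])
    sig = np.asarray(significant_any, dtype=float)
    edges = np.linspace(d.min(), d.max() + 1e-9, n_bins + 1)
    which = np.digitize(d, edges) - 1
    rows = []
    for b in range(n_bins):
        m = which == b
        if m.sum() == 0:
            continue
        rows.append(((edges[b] + edges[b + 1]) / 2, sig[m].mean(), int(m.sum())))
    tab = pd.DataFrame(rows, columns=["distance_um", "p_connect", "n_pairs"])
    r = _st.pearsonr(d, sig)[0] if np.ptp(d) > 0 and np.ptp(sig) > 0 else 0.0
    return tab, float(r)
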