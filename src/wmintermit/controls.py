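"""Control analyses: microsaccade detection and LFP phase vs state onsets.

Microsaccades are velocity peaks: positions are smoothed with a Gaussian
kernel (sigma = 4.75 ms), differentiated by central differences, combined
into speed, and peaks above 10 deg/s with >= 50 ms separation are events.
The phase-state test asks whether the circular mean LFP phase at On-state
onsets differs from that at Off-state onsets more than label permutations
allow, per channel and frequency (4-60 Hz).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage, signal

from .core import EyeTraceSet, PhaseArray, StateSegments

__all__ = ["detect_microsaccades", "phase_state_association",
           "frequency_cluster_test", "circular_mean"]

SPEED_THRESHOLD_DEG_S = 10.0
MIN_INTERPEAK_MS = 50.0
SMOOTH_SIGMA_MS = 4.75


def detect_microsaccades(eyes: EyeTraceSet,
                         threshold_deg_s: float = SPEED_THRESHOLD_DEG_S,
                         min_interpeak_ms: float = MIN_INTERPEAK_MS) -> dict:
    """Velocity-peak microsaccade times (ms) per trial.

    Trials containing NaN samples are skipped (empty result, key retained).
    """
    if eyes.fs_hz != 1000.0:
        raise ValueError("detector expects 1 kHz eye traces")
    out = {}
    for i in range(eyes.position.shape[0]):
        pos = eyes.position[i]
        if not np.all(np.isfinite(pos)):
            out[i] = np.array([])
            continue
        sm = ndimage.gaussian_filter1d(pos, SMOOTH_SIGMA_MS, axis=0,
                                       truncate=4.0)
        vel = np.gradient(sm, axis=0) * 1000.0  # deg/s, central differences
        speed = np.sqrt((vel ** 2).sum(axis=1))
        peaks, _ = signal.find_peaks(speed, height=threshold_deg_s,
                                     distance=int(min_interpeak_ms))
        out[i] = peaks.astype(float)
    return out


def circular_mean(phases: np.ndarray) -> float:
    return float(np.angle(np.mean(np.exp(1j * np.asarray(phases)))))


def _angdiff(a: float, b: float) -> float:
    """Magnitude of the angular difference, wrapped to [0, pi]."""
    return abs(float(np.angle(np.exp(1j * (a - b)))))


def phase_state_association(phases: PhaseArray, segments: StateSegments,
                            n_perm: int = 1000, seed: int = 0,
                            min_onsets: int = 5):
    """Per-frequency z-scores of the On-vs-Off onset phase separation.

    For each channel and frequency, the statistic is the magnitude of the
    angular difference between the circular mean phases at On onsets and at
    Off onsets; the null permutes On/Off labels across onsets. Channel
    z-scores are averaged, yielding one z per frequency.
    """
    on = segments.onset_times("On")
    off = segments.onset_times("Off")
    n_time = phases.phase.shape[3]

    def onset_idx(df):
        tr = df["trial_id"].to_numpy().astype(int)
        ix = (df["t_start_ms"].to_numpy() * phases.fs_hz / 1000.0).astype(int)
        ok = (ix >= 0) & (ix < n_time)
        return tr[ok], ix[ok]
    tr_on, ix_on = onset_idx(on)
    tr_off, ix_off = onset_idx(off)
    if len(tr_on) < min_onsets or len(tr_off) < min_onsets:
        raise ValueError("too few On/Off onsets for the phase-state test")

    n_ch, n_f = phases.phase.shape[:2]
    rng = np.random.default_rng(np.random.SeedSequence([seed, 41]))
    labels = np.concatenate([np.ones(len(tr_on), bool),
                             np.zeros(len(tr_off), bool)])
    z = np.zeros((n_ch, n_f))
    for f in range(n_f):
        ph_on = phases.phase[:, f, tr_on, ix_on]    # (ch, n_on)
        ph_off = phases.phase[:, f, tr_off, ix_off]
        allph = np.concatenate([ph_on, ph_off], axis=1)
        for ch in range(n_ch):
            obs = _angdiff(circular_mean(ph_on[ch]), circular_mean(ph_off[ch]))
            null = np.empty(n_perm)
            for p in range(n_perm):
                lab = rng.permutation(labels)
                null[p] = _angdiff(circular_mean(allph[ch][lab]),
                                   circular_mean(allph[ch][~lab]))
            sd = null.std(ddof=1)
            z[ch, f] = (obs - null.mean()) / sd if sd > 0 else 0.0
    return z.mean(axis=0)  # one z per frequency


def frequency_cluster_test(z_by_session: np.ndarray, n_perm: int = 1000,
                           seed: int = 0, entry_z: float = 1.645):
    """One-sided cluster-corrected test of z > 0 across the frequency axis.

    ``z_by_session``: sessions x frequencies. Adjacent frequencies whose
    across-session t-exceeds the entry threshold form clusters; cluster
    masses are compared against a sign-flip permutation null.

    Returns (significant frequency mask, cluster p-values by cluster id map).
    """
    z = np.asarray(z_by_session, float)
    S, F = z.shape
    rng = np.random.default_rng(np.random.SeedSequence([seed, 43]))

    def tvals(m):
        sd = m.std(axis=0, ddof=1)
        sd = np.where(sd > 0, sd, np.inf)
        return m.mean(axis=0) / (sd / np.sqrt(S))

    def max_mass(t):
        above = t > entry_z
        best, cur = 0.0, 0.0
        for i in range(F):
            cur = cur + t[i] if above[i] else 0.0
            best = max(best, cur)
        return best

    t_obs = tvals(z)
    null = np.empty(n_perm)
    for p in range(n_perm):
        flips = rng.choice([-1.0, 1.0], size=(S, 1))
        null[p] = max_mass(tvals(z * flips))

    sig = np.zeros(F, bool)
    pvals = {}
    above = t_obs > entry_z
    i = 0
    cid = 0
    while i < F:
        if above[i]:
            j = i
            while j < F and above[j]:
                j += 1
            mass = t_obs[i:j].sum()
            pv = float((null >= mass).mean())
            pvals[cid] = {"freq_slice": (i, j), "mass": mass, "p": pv}
            if pv < 0.05:
                sig[i:j] = True
            cid += 1
            i = j
        else:
            i += 1
    return sig, pvals
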