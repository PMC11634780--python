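"""Synthetic session generator with known ground truth.

Emulates a delayed spatial working-memory session: 8 cue locations at 45
degree spacing, a 50-ms cue, a 1,400-1,600-ms delay, Bernoulli (1-ms bin)
spiking around a ~5.8 Hz baseline, a single population-shared alternating
On/Off state sequence (mean durations ~192/146 ms), von-Mises-shaped cue
tuning expressed only inside On states, and cue-specific excess spike
coincidences at short lags injected into ensemble pairs throughout the delay
irrespective of state.

Every generative quantity (state intervals, preferred locations, ensemble
pairs, coincidence times) is returned as :class:`~wmintermit.core.GroundTruth`
so downstream detectors can be scored against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .core import (CUE_MS, EyeTraceSet, GroundTruth, PhaseArray, cue_angle_deg)

__all__ = ["SimConfig", "simulate_session", "simulate_eye_traces",
           "simulate_phases", "truncated_gamma_scale"]


@dataclass
class SimConfig:
    """Parameters of a synthetic session.

    Rates are in Hz, durations in ms. ``tuning_gain`` is the multiplicative
    peak gain at the preferred location during On states (rate multiplier
    ``1 + gain`` at the peak); ``tuning_width_deg`` is the half-width at half
    maximum of the von-Mises-like tuning profile. ``evoked_gain`` scales a
    transient rate increase inside ``evoked_window_ms`` after cue onset.
    State durations are gamma-distributed (shape ``state_shape``) truncated
    at ``state_min_ms``; the scale is solved so the truncated mean equals the
    configured mean.
    """

    n_units: int = 64
    n_trials_per_condition: int = 20
    n_conditions: int = 8
    baseline_rate_hz: float = 5.8
    tuning_gain: float = 4.0
    tuning_width_deg: float = 60.0
    evoked_gain: float = 2.0
    evoked_window_ms: tuple[float, float] = (0.0, 200.0)
    on_mean_ms: float = 192.0
    off_mean_ms: float = 146.0
    state_shape: float = 2.0
    state_min_ms: float = 50.0
    population_states: bool = True   # False desynchronizes states across units
    tuning_in_off: bool = False      # True makes tuning state-blind
    ensemble_pairs_per_condition: int = 4
    sync_rate_hz: float = 1.5
    sync_jitter_ms: int = 1
    condition_specific_ensembles: bool = True
    ensembles_match_tuning: bool = False  # assign pairs among same-preference units
    delay_range_ms: tuple[float, float] = (1400.0, 1600.0)
    fixation_ms: float = 400.0
    time_step_ms: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.baseline_rate_hz < 0 or self.tuning_gain < 0 or self.sync_rate_hz < 0:
            raise ValueError("rates and gains must be non-negative")
        if self.on_mean_ms <= 0 or self.off_mean_ms <= 0:
            raise ValueError("state mean durations must be positive")
        if not (0 <= self.sync_jitter_ms <= 10):
            raise ValueError("sync_jitter_ms must be within [0, 10] so injected "
                             "structure falls inside the short-lag CCG peak window")
        if self.time_step_ms != 1.0:
            raise ValueError("only 1-ms simulation bins are supported")
        p_max = (self.baseline_rate_hz * (1 + self.evoked_gain)
                 * (1 + self.tuning_gain) * self.time_step_ms / 1000.0)
        if p_max >= 1.0:
            raise ValueError("per-bin firing probability reaches 1; the Bernoulli "
                             "approximation is invalid for this configuration")
        for name in ("n_units", "n_trials_per_condition", "n_conditions",
                     "ensemble_pairs_per_condition"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"{name} must be a non-negative integer")


def truncated_gamma_scale(mean_ms: float, shape: float, min_ms: float) -> float:
    """Scale of a gamma(shape) distribution left-truncated at ``min_ms`` whose
    truncated mean equals ``mean_ms`` (solved numerically)."""
    if mean_ms <= min_ms:
        raise ValueError("target mean must exceed the truncation point")

    def trunc_mean(scale):
        g = stats.gamma(shape, scale=scale)
        tail = g.sf(min_ms)
        # E[X 1{X>a}] = shape*scale * SF_{shape+1}(a)
        upper = shape * scale * stats.gamma.sf(min_ms, shape + 1, scale=scale)
        return upper / tail

    lo, hi = mean_ms / (10 * shape), mean_ms / shape * 4
    return optimize.brentq(lambda s: trunc_mean(s) - mean_ms, lo, hi, xtol=1e-6)


def _draw_state_sequence(rng, total_ms, on_scale, off_scale, shape, min_ms,
                         start_on=True):
    """Alternating (label, t0, t1) intervals tiling [0, total_ms)."""
    out, t, on = [], 0.0, start_on
    while t < total_ms:
        scale = on_scale if on else off_scale
        d = 0.0
        while d < min_ms:
            d = rng.gamma(shape, scale)
        t1 = min(t + d, total_ms)
        out.append(("On" if on else "Off", t, t1))
        t, on = t1, not on
    return out


def _tuning_kappa(width_deg: float) -> float:
    # half-width at half-maximum of exp(kappa*(cos(x)-1))
    return np.log(2.0) / (1.0 - np.cos(np.deg2rad(width_deg)))


def simulate_session(config: SimConfig):
    """Generate one synthetic session.

    Returns
    -------
    spikes : DataFrame (unit_id, trial_id, t_ms), cue-aligned, sorted.
    trials : DataFrame (trial_id, cue_location, cue_angle_deg, delay_ms,
        task_type, correct, go_time_ms).
    truth : GroundTruth.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    U, C = config.n_units, config.n_conditions
    n_trials = C * config.n_trials_per_condition

    pref = (np.arange(U) % C) + 1
    rng.shuffle(pref)
    gains = np.full(U, float(config.tuning_gain))
    kappa = _tuning_kappa(config.tuning_width_deg)
    # tuning factor per (unit, condition): 1 + gain * vm(angle diff)
    dtheta = np.deg2rad(cue_angle_deg(np.arange(1, C + 1))[None, :]
                        - cue_angle_deg(pref)[:, None])
    tuning = gains[:, None] * np.exp(kappa * (np.cos(dtheta) - 1.0))

    on_scale = truncated_gamma_scale(config.on_mean_ms, config.state_shape,
                                     config.state_min_ms)
    off_scale = truncated_gamma_scale(config.off_mean_ms, config.state_shape,
                                      config.state_min_ms)

    conditions = np.repeat(np.arange(1, C + 1), config.n_trials_per_condition)
    rng.shuffle(conditions)
    delays = rng.uniform(*config.delay_range_ms, size=n_trials)

    pairs = _assign_ensembles(rng, config, pref)

    fix = int(config.fixation_ms)
    base_p = config.baseline_rate_hz / 1000.0
    ev0, ev1 = config.evoked_window_ms

    rows_u, rows_t, rows_s = [], [], []
    truth = GroundTruth(preferred_location=pref, tuning_gain=gains,
                        ensemble_pairs=pairs)
    trial_meta = []
    for i in range(n_trials):
        c = int(conditions[i])
        go = CUE_MS + delays[i]
        n_bins = fix + int(np.ceil(go))
        t_axis = np.arange(n_bins) - fix  # bin start, ms relative to cue onset

        states = _draw_state_sequence(rng, go, on_scale, off_scale,
                                      config.state_shape, config.state_min_ms)
        truth.states[i] = states
        if config.population_states:
            on_mask = np.zeros(n_bins, bool)
            for lab, t0, t1 in states:
                if lab == "On":
                    on_mask[(t_axis >= t0) & (t_axis < t1)] = True
            on_masks = on_mask[None, :]
        else:
            on_masks = np.zeros((U, n_bins), bool)
            for u in range(U):
                seq = _draw_state_sequence(rng, go, on_scale, off_scale,
                                           config.state_shape, config.state_min_ms)
                for lab, t0, t1 in seq:
                    if lab == "On":
                        on_masks[u, (t_axis >= t0) & (t_axis < t1)] = True

        evoked = np.where((t_axis >= ev0) & (t_axis < ev1),
                          1.0 + config.evoked_gain, 1.0)
        if config.tuning_in_off:  # state-blind tuning
            tune_t = 1.0 + tuning[:, c - 1][:, None] * np.ones((1, n_bins))
        else:
            tune_t = 1.0 + tuning[:, c - 1][:, None] * on_masks
        p = base_p * evoked[None, :] * tune_t
        spk = rng.random((U, n_bins)) < p

        coinc = []
        win0, win1 = CUE_MS, go
        for (j, k) in pairs.get(c, ()):
            n_ev = rng.poisson(config.sync_rate_hz * (win1 - win0) / 1000.0)
            if n_ev == 0:
                continue
            t_ev = rng.uniform(win0, win1 - config.sync_jitter_ms - 1, size=n_ev)
            lags = rng.integers(-config.sync_jitter_ms, config.sync_jitter_ms + 1,
                                size=n_ev)
            bj = (t_ev + fix).astype(int)
            bk = np.clip(bj + lags, 0, n_bins - 1)
            spk[j, bj] = True
            spk[k, bk] = True
            coinc.extend(t_ev.tolist())
        truth.coincidences[i] = np.sort(np.asarray(coinc))

        uu, bb = np.nonzero(spk)
        rows_u.append(uu)
        rows_t.append(np.full(uu.size, i))
        rows_s.append(bb - fix + 0.5)
        trial_meta.append((i, c, float(cue_angle_deg(c)), float(delays[i]),
                           "MTS" if i % 2 == 0 else "MGS", True, float(go)))

    spikes = pd.DataFrame({
        "unit_id": np.concatenate(rows_u),
        "trial_id": np.concatenate(rows_t),
        "t_ms": np.concatenate(rows_s),
    }).sort_values(["unit_id", "trial_id", "t_ms"], kind="stable",
                   ignore_index=True)
    trials = pd.DataFrame(trial_meta, columns=list(
        ("trial_id", "cue_location", "cue_angle_deg", "delay_ms", "task_type",
         "correct", "go_time_ms")))
    return spikes, trials, truth


def _assign_ensembles(rng, config: SimConfig, pref):
    """Ensemble pair assignment; disjoint across conditions when specific."""
    U, C = config.n_units, config.n_conditions
    k = config.ensemble_pairs_per_condition
    if k == 0:
        return {}
    pairs: dict[int, list[tuple[int, int]]] = {}
    used = set()
    if not config.condition_specific_ensembles:
        shared = _sample_pairs(rng, np.arange(U), k, used)
        return {c: shared for c in range(1, C + 1)}
    for c in range(1, C + 1):
        pool = np.flatnonzero(pref == c) if config.ensembles_match_tuning \
            else np.arange(U)
        if config.ensembles_match_tuning and len(pool) < 2:
            pool = np.arange(U)
        pairs[c] = _sample_pairs(rng, pool, k, used)
    return pairs


def _sample_pairs(rng, pool, k, used):
    out = []
    attempts = 0
    while len(out) < k and attempts < 1000:
        j, kk = rng.choice(pool, size=2, replace=False)
        key = (min(int(j), int(kk)), max(int(j), int(kk)))
        attempts += 1
        if key in used:
            continue
        used.add(key)
        out.append(key)
    return out


# ---------------------------------------------------------------------------
# eye traces and LFP phases


def simulate_eye_traces(n_trials: int, msacc_rate_hz: float,
                        amplitude_deg=(0.25, 0.6), seed: int = 0,
                        duration_ms: int = 2000, drift_sd_deg: float = 5e-4,
                        peak_speed_deg_s: float | None = None,
                        min_spacing_ms: float = 200.0):
    """Fixational eye traces: random-walk drift plus injected microsaccades.

    Microsaccades have symmetric Gaussian velocity profiles (sigma = 5 ms)
    whose peak speed follows from the drawn amplitude (>= ~14 deg/s after
    kernel attenuation for the default amplitude range) unless overridden by ``peak_speed_deg_s``.
    Returns (EyeTraceSet, ground-truth event times per trial).
    """
    lo, hi = amplitude_deg
    if lo <= 0 or hi <= 0 or hi < lo:
        raise ValueError("amplitude range must be positive")
    rng = np.random.default_rng(seed)
    tau = 5.0  # ms, velocity-profile width
    pos = np.zeros((n_trials, duration_ms, 2))
    events: dict[int, np.ndarray] = {}
    t_grid = np.arange(duration_ms)
    for i in range(n_trials):
        vel = rng.normal(0.0, drift_sd_deg, size=(duration_ms, 2))
        n_ev = rng.poisson(msacc_rate_hz * duration_ms / 1000.0)
        times = np.sort(rng.uniform(50, duration_ms - 50, size=n_ev))
        keep = []
        for t in times:
            if not keep or t - keep[-1] >= min_spacing_ms:
                keep.append(t)
        for t0 in keep:
            amp = rng.uniform(lo, hi)
            v_peak = amp / (tau * np.sqrt(2 * np.pi))  # deg/ms
            if peak_speed_deg_s is not None:
                v_peak = peak_speed_deg_s / 1000.0
            ang = rng.uniform(0, 2 * np.pi)
            prof = v_peak * np.exp(-0.5 * ((t_grid - t0) / tau) ** 2)
            vel[:, 0] += prof * np.cos(ang)
            vel[:, 1] += prof * np.sin(ang)
        pos[i] = np.cumsum(vel, axis=0)
        events[i] = np.asarray(keep)
    return EyeTraceSet(position=pos), events


def simulate_phases(n_channels: int, freqs_hz, kappa, locked_to: str = "none",
                    seed: int = 0, n_trials: int = 40, duration_ms: int = 2000,
                    fs_hz: float = 100.0, onsets_on=None, onsets_off=None):
    """Phase arrays, uniform by default, optionally locked to state onsets.

    ``kappa`` may be scalar or per-frequency. When ``locked_to`` is ``"On"``
    or ``"Off"``, phases at On/Off state-onset samples are drawn from von
    Mises distributions around channel-specific means separated by pi;
    everywhere else phases are uniform on (-pi, pi].
    ``onsets_on``/``onsets_off`` map trial index -> onset times (ms).
    """
    freqs_hz = np.asarray(freqs_hz, dtype=float)
    if np.any((freqs_hz < 4) | (freqs_hz > 60)):
        raise ValueError("frequencies must lie within the 4-60 Hz analysis range")
    kap = np.broadcast_to(np.asarray(kappa, dtype=float), freqs_hz.shape).copy()
    if np.any(kap < 0):
        raise ValueError("kappa must be non-negative")
    if locked_to not in ("none", "On", "Off"):
        raise ValueError("locked_to must be 'none', 'On' or 'Off'")

    rng = np.random.default_rng(seed)
    n_time = int(duration_ms * fs_hz / 1000.0)
    phase = rng.uniform(-np.pi, np.pi,
                        size=(n_channels, freqs_hz.size, n_trials, n_time))
    if locked_to != "none":
        mu = rng.uniform(-np.pi, np.pi, size=(n_channels, freqs_hz.size))
        mu_on = mu if locked_to == "On" else mu + np.pi
        mu_off = mu_on + np.pi
        for onsets, mu_use in ((onsets_on, mu_on), (onsets_off, mu_off)):
            if onsets is None:
                continue
            for tr, times in onsets.items():
                idx = (np.asarray(times) * fs_hz / 1000.0).astype(int)
                idx = idx[(idx >= 0) & (idx < n_time)]
                for f in range(freqs_hz.size):
                    if kap[f] == 0:
                        continue
                    draws = rng.vonmises(mu_use[:, f][:, None], kap[f],
                                         size=(n_channels, idx.size))
                    phase[:, f, tr, idx] = draws
    phase = np.angle(np.exp(1j * phase))  # wrap to (-pi, pi]
    return PhaseArray(phase=phase, freqs_hz=freqs_hz, fs_hz=fs_hz)
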