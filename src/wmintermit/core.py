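"""Shared containers and time conventions.

All spike times are in milliseconds relative to cue onset (t = 0). Analysis
windows are half-open ``[start, end)``. The memory-delay summary window is
``[500, 1400)`` ms, chosen to avoid visually evoked transients; the state
labeling span covers cue + delay, ``[0, 1400)`` ms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: cue duration (ms)
CUE_MS = 50.0
#: memory-delay summary window, ms relative to cue onset
DELAY_WINDOW = (500.0, 1400.0)
#: span over which On/Off states are labeled (cue + delay epochs)
LABEL_SPAN = (0.0, 1400.0)
#: baseline (pre-cue fixation) window for rate normalization
BASELINE_WINDOW = (-400.0, 0.0)

SPIKE_COLUMNS = ("unit_id", "trial_id", "t_ms")
TRIAL_COLUMNS = ("trial_id", "cue_location", "cue_angle_deg", "delay_ms",
                 "task_type", "correct", "go_time_ms")


def cue_angle_deg(cue_location: np.ndarray | int) -> np.ndarray | float:
    """Angle of a cue location index (1-8, 45 degree spacing; location 1 = 0 deg)."""
    return (np.asarray(cue_location) - 1) * 45.0


def opposite_location(cue_location):
    """Cue location diametrically opposite (180 deg away) on the 8-point ring."""
    return (np.asarray(cue_location) - 1 + 4) % 8 + 1


@dataclass
class RateTensor:
    """Boxcar-smoothed firing rates, units x trials x timepoints.

    ``values`` are spikes/s (or z-units when ``zscored``); ``time_ms`` is the
    sample grid (10-ms steps by default). ``valid`` marks (unit, timepoint)
    cells whose across-trial variance was nonzero before z-scoring;
    zero-variance cells are imputed to 0.
    """

    values: np.ndarray
    unit_ids: np.ndarray
    trial_ids: np.ndarray
    time_ms: np.ndarray
    zscored: bool = False
    valid: np.ndarray | None = None

    @property
    def n_units(self) -> int:
        return self.values.shape[0]

    @property
    def n_trials(self) -> int:
        return self.values.shape[1]

    def time_mask(self, window) -> np.ndarray:
        return (self.time_ms >= window[0]) & (self.time_ms < window[1])

    def subset_units(self, unit_ids) -> "RateTensor":
        idx = np.flatnonzero(np.isin(self.unit_ids, unit_ids))
        return RateTensor(self.values[idx], self.unit_ids[idx], self.trial_ids,
                          self.time_ms, self.zscored,
                          None if self.valid is None else self.valid[idx])


@dataclass
class BinaryRaster:
    """1-ms binarized spike trains over a stated window (units x trials x bins)."""

    values: np.ndarray  # uint8 in {0, 1}
    unit_ids: np.ndarray
    trial_ids: np.ndarray
    window: tuple[float, float]

    @property
    def n_bins(self) -> int:
        return self.values.shape[2]


@dataclass
class ConfidenceSeries:
    """Per-trial decoder confidence (posterior of the correct cue label)."""

    values: np.ndarray    # trials x timepoints, in (0, 1)
    accuracy: np.ndarray  # trials x timepoints, {0, 1}
    trial_ids: np.ndarray
    time_ms: np.ndarray

    def delay_mean_accuracy(self, window=DELAY_WINDOW) -> float:
        m = (self.time_ms >= window[0]) & (self.time_ms < window[1])
        return float(np.nanmean(self.accuracy[:, m]))


@dataclass
class NullConfidenceEnsemble:
    """Shuffled-label confidence replicates (trials x timepoints x n_shuffles)."""

    values: np.ndarray
    trial_ids: np.ndarray
    time_ms: np.ndarray

    @property
    def n_shuffles(self) -> int:
        return self.values.shape[2]

    @property
    def mean(self) -> np.ndarray:
        return self.values.mean(axis=2)

    @property
    def sd(self) -> np.ndarray:
        return self.values.std(axis=2, ddof=1)


@dataclass
class StateZSeries:
    """Confidence z-scored against the shuffled-label null."""

    z: np.ndarray  # trials x timepoints
    trial_ids: np.ndarray
    time_ms: np.ndarray


#: integer codes used in timepoint label maps
LABEL_OFF, LABEL_ON, LABEL_INCORRECT, LABEL_NONE = 0, 1, 2, -1
_LABEL_CODES = {"Off": LABEL_OFF, "On": LABEL_ON, "incorrect": LABEL_INCORRECT}


@dataclass
class StateSegments:
    """Labeled On/Off intervals per trial.

    ``table`` is tidy: trial_id, label in {On, Off, incorrect}, t_start_ms,
    t_end_ms (half-open). Points belonging to no interval are unlabeled.
    """

    table: pd.DataFrame
    span: tuple[float, float] = LABEL_SPAN
    step_ms: float = 10.0

    def timepoint_labels(self, trial_ids, time_ms) -> np.ndarray:
        """Label code per (trial, timepoint); -1 where unlabeled."""
        trial_ids = np.asarray(trial_ids)
        time_ms = np.asarray(time_ms)
        out = np.full((len(trial_ids), len(time_ms)), LABEL_NONE, dtype=np.int8)
        row = {t: i for i, t in enumerate(trial_ids)}
        for rec in self.table.itertuples(index=False):
            i = row.get(rec.trial_id)
            if i is None:
                continue
            m = (time_ms >= rec.t_start_ms) & (time_ms < rec.t_end_ms)
            out[i, m] = _LABEL_CODES[rec.label]
        return out

    def onset_times(self, label: str) -> pd.DataFrame:
        sub = self.table[self.table["label"] == label]
        return sub[["trial_id", "t_start_ms"]].reset_index(drop=True)


@dataclass
class EnsembleGraph:
    """Binary functional-connectivity graph for one cue condition."""

    condition: int
    adjacency: np.ndarray       # bool, n_units x n_units, symmetric
    evaluated: np.ndarray       # bool mask of pairs that could be evaluated
    unit_ids: np.ndarray

    def n_edges(self) -> int:
        return int(np.triu(self.adjacency, 1).sum())


@dataclass
class EyeTraceSet:
    """Horizontal/vertical eye position (deg) at 1 kHz, trials x samples x 2."""

    position: np.ndarray
    fs_hz: float = 1000.0


@dataclass
class PhaseArray:
    """LFP phases (radians, wrapped to (-pi, pi]), channels x freqs x trials x time."""

    phase: np.ndarray
    freqs_hz: np.ndarray
    fs_hz: float = 100.0


@dataclass
class GroundTruth:
    """Generative ground truth attached to a synthetic session."""

    states: dict = field(default_factory=dict)            # trial_id -> [(label, t0, t1)]
    preferred_location: np.ndarray | None = None          # per unit, 1-8
    tuning_gain: np.ndarray | None = None                 # per unit
    ensemble_pairs: dict = field(default_factory=dict)    # condition -> [(j, k)]
    coincidences: dict = field(default_factory=dict)      # trial_id -> array of t_ms
    microsaccade_times: dict = field(default_factory=dict)
    phase_kappa: np.ndarray | None = None

    def state_labels_on_grid(self, trial_ids, time_ms) -> np.ndarray:
        """True On(1)/Off(0) label per (trial, 10-ms timepoint)."""
        time_ms = np.asarray(time_ms)
        out = np.full((len(trial_ids), len(time_ms)), LABEL_NONE, dtype=np.int8)
        for i, t in enumerate(np.asarray(trial_ids)):
            for label, t0, t1 in self.states.get(int(t), ()):
                m = (time_ms >= t0) & (time_ms < t1)
                out[i, m] = _LABEL_CODES[label]
        return out
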