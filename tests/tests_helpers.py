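"""Shared helpers for the test suite."""

import numpy as np
import pandas as pd

import wmintermit as wm


def ground_truth_segments(truth, trial_ids):
    """StateSegments built directly from generator ground truth."""
    rows = []
    for t in trial_ids:
        for lab, a, b in truth.states.get(int(t), ()):
            rows.append((t, lab, a, b))
    return wm.StateSegments(table=pd.DataFrame(
        rows, columns=["trial_id", "label", "t_start_ms", "t_end_ms"]))


def labeled_ms_per_trial(segments, trial_ids, which, window=(500.0, 1400.0)):
    """Total ms labeled ``which`` per trial inside the analysis window."""
    tab = segments.table
    out = np.zeros(len(trial_ids))
    for i, tid in enumerate(trial_ids):
        sub = tab[(tab.trial_id == tid) & (tab.label == which)]
        for _, r in sub.iterrows():
            out[i] += max(0.0, min(r.t_end_ms, window[1])
                          - max(r.t_start_ms, window[0]))
    return out
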