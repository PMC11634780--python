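"""Readers and writers for session tables (CSV/Parquet) and ground truth."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .core import SPIKE_COLUMNS, TRIAL_COLUMNS, GroundTruth

__all__ = ["read_table", "write_table", "write_session", "read_session",
           "ground_truth_to_json", "ground_truth_from_json"]


def read_table(path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix == ".parquet":
        return pd.read_parquet(path)
    return pd.read_csv(path)


def write_table(df: pd.DataFrame, path) -> None:
    path = Path(path)
    if path.suffix == ".parquet":
        df.to_parquet(path, index=False)
    else:
        df.to_csv(path, index=False)


def _validate(df, cols, name):
    missing = set(cols) - set(df.columns)
    if missing:
        raise ValueError(f"{name} table missing columns: {sorted(missing)}")


def write_session(out_dir, spikes, trials, truth: GroundTruth | None = None,
                  fmt: str = "csv") -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ext = ".parquet" if fmt == "parquet" else ".csv"
    write_table(spikes, out / f"spikes{ext}")
    write_table(trials, out / f"trials{ext}")
    if truth is not None:
        (out / "ground_truth.json").write_text(ground_truth_to_json(truth))


def read_session(in_dir):
    in_dir = Path(in_dir)
    for ext in (".csv", ".parquet"):
        if (in_dir / f"spikes{ext}").exists():
            spikes = read_table(in_dir / f"spikes{ext}")
            trials = read_table(in_dir / f"trials{ext}")
            break
    else:
        raise FileNotFoundError(f"no spikes table under {in_dir}")
    _validate(spikes, SPIKE_COLUMNS, "spikes")
    _validate(trials, TRIAL_COLUMNS, "trials")
    truth = None
    gt = in_dir / "ground_truth.json"
    if gt.exists():
        truth = ground_truth_from_json(gt.read_text())
    return spikes, trials, truth


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def ground_truth_to_json(truth: GroundTruth) -> str:
    return json.dumps(_jsonable(asdict(truth)), indent=1)


def ground_truth_from_json(text: str) -> GroundTruth:
    d = json.loads(text)
    return GroundTruth(
        states={int(k): [(lab, float(a), float(b)) for lab, a, b in v]
                for k, v in d.get("states", {}).items()},
        preferred_location=np.asarray(d["preferred_location"])
        if d.get("preferred_location") is not None else None,
        tuning_gain=np.asarray(d["tuning_gain"])
        if d.get("tuning_gain") is not None else None,
        ensemble_pairs={int(k): [tuple(p) for p in v]
                        for k, v in d.get("ensemble_pairs", {}).items()},
        coincidences={int(k): np.asarray(v)
                      for k, v in d.get("coincidences", {}).items()},
        microsaccade_times={int(k): np.asarray(v)
                            for k, v in d.get("microsaccade_times", {}).items()},
    )
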