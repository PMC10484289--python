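"""Cohort container (HDF5) and plain-text table I/O.

Layout of the cohort file::

    /seizures/<id>/features     (n_windows, feature_dim)
    /seizures/<id>  attrs: onset_day
    /spike_rate                 (n_samples, 2) columns time_days, spikes_per_hour
    /truth/W                    ground-truth basis (synthetic cohorts only)
    /truth/sequences/<id>       planted per-window state labels
    /truth/cycles/<i>/phase     wrapped ground-truth phase per hourly sample
    /truth/seizure_phases       (n_seizures, n_cycles) onset phases

Annotation and spike-rate side files are CSV; derived tables are TSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .synthetic_data import Cohort

__all__ = [
    "write_cohort",
    "read_features",
    "read_spike_rate",
    "write_annotations_csv",
    "write_spike_rate_csv",
    "read_spike_rate_csv",
]


def write_cohort(path: str | Path, cohort: Cohort) -> None:
    with h5py.File(path, "w") as f:
        for s in cohort.seizures:
            g = f.create_group(f"seizures/{s.id}")
            g.create_dataset("features", data=s.features.T)  # windows x features
            g.attrs["onset_day"] = s.onset_day
        f.create_dataset(
            "spike_rate", data=np.column_stack([cohort.time_days, cohort.spike_rate])
        )
        tr = f.create_group("truth")
        tr.create_dataset("W", data=cohort.truth.true_W)
        seq = tr.create_group("sequences")
        for s in cohort.seizures:
            seq.create_dataset(str(s.id), data=s.state_sequence)
        for i, c in enumerate(cohort.truth.cycles):
            cg = tr.create_group(f"cycles/{i}")
            cg.create_dataset("phase", data=c.phase)
            cg.attrs["nominal_period"] = c.nominal_period
        tr.create_dataset("seizure_phases", data=cohort.truth.seizure_phases)


def read_features(path: str | Path) -> tuple[list[np.ndarray], np.ndarray, list[str]]:
    """Per-seizure (n_windows, feature_dim) arrays, onset days and ids, in onset order."""
    feats, onsets, ids = [], [], []
    with h5py.File(path, "r") as f:
        for sid in f["seizures"]:
            g = f[f"seizures/{sid}"]
            feats.append(np.asarray(g["features"]))
            onsets.append(float(g.attrs["onset_day"]))
            ids.append(sid)
    order = np.argsort(onsets)
    return (
        [feats[i] for i in order],
        np.array([onsets[i] for i in order]),
        [ids[i] for i in order],
    )


def read_spike_rate(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    with h5py.File(path, "r") as f:
        arr = np.asarray(f["spike_rate"])
    return arr[:, 0], arr[:, 1]


def write_annotations_csv(path: str | Path, cohort: Cohort) -> None:
    pd.DataFrame(
        {
            "seizure_id": [s.id for s in cohort.seizures],
            "onset_day": [s.onset_day for s in cohort.seizures],
            "duration_s": [
                s.duration_s(cohort.config.window_s, cohort.config.step_s)
                for s in cohort.seizures
            ],
        }
    ).to_csv(path, index=False)


def write_spike_rate_csv(path: str | Path, time_days: np.ndarray, rate: np.ndarray) -> None:
    pd.DataFrame({"time_days": time_days, "spikes_per_hour": rate}).to_csv(path, index=False)


def read_spike_rate_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path)
    return df["time_days"].to_numpy(), df["spikes_per_hour"].to_numpy()


def write_json(path: str | Path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonable) + "\n")


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON-serialisable: {type(x)}")
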