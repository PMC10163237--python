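"""File dialects: trial-table CSV, fluorescence/event HDF5, JSON sidecars.

Conventions (also stated in the file headers/attrs): all times are seconds
from trial start, all frame indices are 0-based, fluorescence arrays are
``neurons x frames x trials``.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .preprocess import EventTrace
from .synthgen import GroundTruth, RegistrationMap, SessionRecord
from .task import TRIAL_COLUMNS

EPOCH_KEYS = ("open", "open_complete", "response", "close")


# ---------------------------------------------------------------------------
# trial table CSV
# ---------------------------------------------------------------------------
def write_trials(trials: pd.DataFrame, path: str | Path) -> None:
    out = trials.copy()
    out["lick_times"] = [
        ";".join(f"{t:.6g}" for t in licks) for licks in out["lick_times"]
    ]
    out.to_csv(path, index=False)


def read_trials(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, keep_default_na=False)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial table {path} missing column(s): {missing}")
    df["lick_times"] = [
        [float(t) for t in str(s).split(";") if t not in ("", "nan")]
        for s in df["lick_times"]
    ]
    df["rewarded"] = df["rewarded"].astype(str).str.lower().isin(("true", "1"))
    return df


# ---------------------------------------------------------------------------
# fluorescence HDF5
# ---------------------------------------------------------------------------
def write_fluorescence(session: SessionRecord, path: str | Path) -> None:
    with h5py.File(path, "w") as h:
        d = h.create_dataset("F", data=session.F)
        d.attrs["layout"] = "neurons x frames x trials"
        h.attrs["frame_rate_hz"] = session.frame_rate_hz
        h.attrs["day"] = session.day
        h.attrs["category_map"] = json.dumps(session.category_map)
        for k in EPOCH_KEYS:
            h.attrs[f"epoch_{k}"] = session.epoch_frames[k]


def read_session(trials_path: str | Path, h5_path: str | Path) -> SessionRecord:
    trials = read_trials(trials_path)
    with h5py.File(h5_path, "r") as h:
        if "F" not in h:
            raise ValueError(f"{h5_path} has no dataset 'F'")
        F = h["F"][()]
        if F.ndim != 3:
            raise ValueError(
                f"dataset 'F' in {h5_path} must be 3-D (neurons x frames x trials), "
                f"got shape {F.shape}"
            )
        if F.shape[2] != len(trials):
            raise ValueError(
                f"'F' trial axis ({F.shape[2]}) does not match trial table "
                f"({len(trials)} rows); expected layout neurons x frames x trials"
            )
        epochs = {k: int(h.attrs[f"epoch_{k}"]) for k in EPOCH_KEYS}
        bad = [k for k in EPOCH_KEYS if not 0 <= epochs[k] < F.shape[1]]
        if bad:
            raise ValueError(f"epoch frame indices out of range in {h5_path}: {bad}")
        return SessionRecord(
            trials=trials,
            F=F,
            frame_rate_hz=float(h.attrs["frame_rate_hz"]),
            epoch_frames=epochs,
            day=int(h.attrs.get("day", trials["day"].iloc[0] if len(trials) else 0)),
            category_map=json.loads(h.attrs.get("category_map", "{}")),
        )


def write_session(session: SessionRecord, out_dir: str | Path, stem: str = "session") -> dict:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    trials_path = out_dir / f"{stem}_trials.csv"
    h5_path = out_dir / f"{stem}_fluorescence.h5"
    write_trials(session.trials, trials_path)
    write_fluorescence(session, h5_path)
    return {"trials": str(trials_path), "fluorescence": str(h5_path)}


# ---------------------------------------------------------------------------
# event traces
# ---------------------------------------------------------------------------
def write_events(events: EventTrace, path: str | Path) -> None:
    with h5py.File(path, "w") as h:
        h.create_dataset("dff", data=events.dff)
        h.create_dataset("events", data=events.events)
        h.attrs["layout"] = "neurons x frames x trials"
        h.create_dataset("f0", data=events.f0)
        h.create_dataset("threshold", data=events.threshold)
        h.create_dataset("fp_ratio", data=events.fp_ratio)


def read_events(path: str | Path) -> EventTrace:
    with h5py.File(path, "r") as h:
        for name in ("dff", "events", "f0", "threshold", "fp_ratio"):
            if name not in h:
                raise ValueError(f"{path} has no dataset '{name}'")
        return EventTrace(
            dff=h["dff"][()],
            f0=h["f0"][()],
            threshold=h["threshold"][()],
            events=h["events"][()],
            fp_ratio=h["fp_ratio"][()],
        )


# ---------------------------------------------------------------------------
# JSON sidecars
# ---------------------------------------------------------------------------
def write_registration(regmap: RegistrationMap, path: str | Path) -> None:
    Path(path).write_text(json.dumps(regmap.to_json_dict(), indent=1))


def read_registration(path: str | Path) -> RegistrationMap:
    return RegistrationMap.from_json_dict(json.loads(Path(path).read_text()))


def write_truth(truth: GroundTruth, path: str | Path) -> None:
    Path(path).write_text(json.dumps(truth.to_records(), indent=1))


def read_truth(path: str | Path) -> GroundTruth:
    return GroundTruth.from_records(json.loads(Path(path).read_text()))
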