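"""File round-trips: trial tables (CSV), epochs (HDF5), configs (YAML) and
import of externally recorded epochs (EDF / BrainVision) through MNE.

Conventions recorded in the container attributes: times in ms, amplitudes in
microvolts, evidences in nats.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import h5py
import numpy as np
import pandas as pd
import yaml

from .task_sim import (
    EEGEpochs,
    RaceParams,
    Session,
    TaskConfig,
    TrialRecord,
    TrialType,
)

__all__ = [
    "sessions_to_frame",
    "frame_to_sessions",
    "write_trials_csv",
    "read_trials_csv",
    "write_epochs_h5",
    "read_epochs_h5",
    "task_config_to_dict",
    "task_config_from_dict",
    "race_params_to_dict",
    "race_params_from_dict",
    "read_external_epochs",
]

TRIAL_COLUMNS = [
    "subject", "condition", "block", "index", "type",
    "ssd_ms", "responded", "rt_ms", "stop_success",
]


def sessions_to_frame(sessions: Iterable[Session]) -> pd.DataFrame:
    """One row per trial across sessions, in the canonical column order."""
    rows = []
    for s in sessions:
        for t in s.trials:
            rows.append(
                {
                    "subject": s.subject_id,
                    "condition": s.condition,
                    "block": t.block,
                    "index": t.index,
                    "type": t.trial_type.value,
                    "ssd_ms": t.ssd,
                    "responded": t.responded,
                    "rt_ms": t.rt,
                    "stop_success": t.stop_success,
                }
            )
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def frame_to_sessions(
    df: pd.DataFrame, config: TaskConfig, params: RaceParams | None = None
) -> list[Session]:
    """Rebuild Session objects from a trial table.

    ``config`` must describe the sessions' block structure; ``params`` is
    attached as metadata (defaults used when the generating parameters are
    unknown, e.g. for external data).
    """
    params = params if params is not None else RaceParams()
    sessions = []
    for (subj, cond), grp in df.groupby(["subject", "condition"], sort=True):
        grp = grp.sort_values("index")
        trials = []
        for row in grp.itertuples(index=False):
            is_stop = row.type == "STOP"
            trials.append(
                TrialRecord(
                    index=int(row.index),
                    block=int(row.block),
                    trial_type=TrialType(row.type),
                    ssd=float(row.ssd_ms) if is_stop and pd.notna(row.ssd_ms) else None,
                    responded=bool(row.responded),
                    rt=float(row.rt_ms) if pd.notna(row.rt_ms) else None,
                    stop_success=bool(row.stop_success) if is_stop else None,
                )
            )
        sessions.append(Session(str(subj), str(cond), trials, config, params))
    return sessions


def write_trials_csv(path: str | Path, sessions: Iterable[Session]) -> None:
    sessions_to_frame(sessions).to_csv(path, index=False)


def read_trials_csv(path: str | Path) -> pd.DataFrame:
    # round_trip float parsing so write/read is an identity on RTs and SSDs
    return pd.read_csv(path, float_precision="round_trip")


def write_epochs_h5(path: str | Path, epochs: EEGEpochs) -> None:
    """Epoch container: datasets ``data`` (trials x channels x samples, uV),
    ``labels``, a trial table, and window/srate attributes.  Creation
    timestamps are disabled so identical data yields identical files."""
    rows = []
    for t in epochs.trial_meta:
        rows.append(
            [t.block, t.index, t.trial_type.value,
             np.nan if t.ssd is None else t.ssd,
             t.responded,
             np.nan if t.rt is None else t.rt,
             -1 if t.stop_success is None else int(t.stop_success)]
        )
    trial_arr = np.array(
        [tuple(r) for r in rows],
        dtype=[("block", "i8"), ("index", "i8"), ("type", "S12"), ("ssd_ms", "f8"),
               ("responded", "?"), ("rt_ms", "f8"), ("stop_success", "i8")],
    )
    with h5py.File(path, "w", track_order=False) as f:
        f.attrs["srate_hz"] = float(epochs.srate)
        f.attrs["window_ms"] = np.asarray(epochs.window, dtype=float)
        f.attrs["alignment"] = epochs.alignment
        f.attrs["units"] = "time: ms, amplitude: uV"
        f.create_dataset("data", data=epochs.data, track_times=False)
        f.create_dataset(
            "labels",
            data=np.array([l.encode() for l in epochs.channel_labels]),
            track_times=False,
        )
        f.create_dataset("trials", data=trial_arr, track_times=False)
        if epochs.ground_truth is not None:
            f.create_dataset("ground_truth", data=epochs.ground_truth, track_times=False)


def read_epochs_h5(path: str | Path) -> EEGEpochs:
    with h5py.File(path, "r") as f:
        data = f["data"][()]
        labels = tuple(l.decode() for l in f["labels"][()])
        trials = []
        for r in f["trials"][()]:
            ttype = TrialType(r["type"].decode())
            trials.append(
                TrialRecord(
                    index=int(r["index"]),
                    block=int(r["block"]),
                    trial_type=ttype,
                    ssd=None if np.isnan(r["ssd_ms"]) else float(r["ssd_ms"]),
                    responded=bool(r["responded"]),
                    rt=None if np.isnan(r["rt_ms"]) else float(r["rt_ms"]),
                    stop_success=None if r["stop_success"] < 0 else bool(r["stop_success"]),
                )
            )
        gt = f["ground_truth"][()] if "ground_truth" in f else None
        return EEGEpochs(
            data,
            float(f.attrs["srate_hz"]),
            labels,
            tuple(float(x) for x in f.attrs["window_ms"]),
            str(f.attrs["alignment"]),
            trials,
            ground_truth=gt,
        )


def task_config_to_dict(config: TaskConfig) -> dict:
    d = dataclasses.asdict(config)
    d["proportions"] = {k.value: v for k, v in config.proportions.items()}
    d["ssd_bounds"] = list(config.ssd_bounds)
    return d


def task_config_from_dict(d: dict) -> TaskConfig:
    d = dict(d)
    d["proportions"] = {TrialType(k): float(v) for k, v in d["proportions"].items()}
    d["ssd_bounds"] = tuple(d["ssd_bounds"])
    return TaskConfig(**d)


def race_params_to_dict(params: RaceParams) -> dict:
    return dataclasses.asdict(params)


def race_params_from_dict(d: dict) -> RaceParams:
    return RaceParams(**d)


def write_yaml(path: str | Path, obj: dict) -> None:
    Path(path).write_text(yaml.safe_dump(obj, sort_keys=False))


def read_yaml(path: str | Path) -> dict:
    return yaml.safe_load(Path(path).read_text())


def read_external_epochs(
    path: str | Path,
    window: tuple[float, float],
    events: np.ndarray | None = None,
    event_id: dict | None = None,
) -> EEGEpochs:
    """Import raw EEG from EDF or a BrainVision triplet and epoch it.

    Events default to the annotations embedded in the file.  The returned
    container carries empty trial metadata (external recordings do not ship
    the behavioral table); align it separately via the trial CSV.
    """
    import mne

    path = Path(path)
    if path.suffix.lower() == ".edf":
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    elif path.suffix.lower() == ".vhdr":
        raw = mne.io.read_raw_brainvision(path, preload=True, verbose="error")
    else:
        raise ValueError(f"unsupported raw EEG format: {path.suffix}")
    if events is None:
        events, event_id = mne.events_from_annotations(raw, verbose="error")
    ep = mne.Epochs(
        raw,
        events,
        event_id=event_id,
        tmin=window[0] / 1000.0,
        tmax=window[1] / 1000.0,
        baseline=None,
        preload=True,
        verbose="error",
    )
    data_uv = ep.get_data() * 1e6
    n = data_uv.shape[0]
    meta = [
        TrialRecord(index=i, block=0, trial_type=TrialType.GO, responded=False)
        for i in range(n)
    ]
    tmin_ms = ep.times[0] * 1000.0
    tmax_ms = tmin_ms + (data_uv.shape[2] - 1) * 1000.0 / ep.info["sfreq"]
    return EEGEpochs(
        data_uv,
        float(ep.info["sfreq"]),
        tuple(ep.ch_names),
        (tmin_ms, tmax_ms),
        "GO_CUE",
        meta,
    )
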