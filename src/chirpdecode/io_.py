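"""Reading and writing recordings, event tables, and reports.

Events travel as TSV with columns ``onset_s`` and ``label``.  Recordings
round-trip through NumPy ``.npz`` archives; EDF files can be *read* when
``mne`` is installed (the ``edf`` extra).  Ground truth and ICA
decompositions are stored as compressed archives of named arrays.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synth import Event, EventList, Recording, GroundTruth

__all__ = [
    "read_events_tsv", "write_events_tsv",
    "load_recording", "save_recording", "read_recording_edf",
    "save_ground_truth", "write_report_json",
]


def write_events_tsv(events: EventList, path) -> None:
    df = pd.DataFrame({
        "onset_s": [e.onset_sample / events.fs for e in events],
        "label": [e.label for e in events],
    })
    df.to_csv(path, sep="\t", index=False)


def read_events_tsv(path, fs: float) -> EventList:
    df = pd.read_csv(path, sep="\t")
    if not {"onset_s", "label"} <= set(df.columns):
        raise ValueError("events TSV needs 'onset_s' and 'label' columns")
    evs = tuple(
        Event(int(round(row.onset_s * fs)), str(row.label))
        for row in df.itertuples()
    )
    return EventList(events=evs, fs=fs)


def save_recording(recording: Recording, path) -> None:
    np.savez_compressed(
        path,
        data=recording.data,
        fs=np.array(recording.fs),
        channel_labels=np.array(recording.channel_labels),
        event_onsets=recording.events.onsets(),
        event_labels=recording.events.labels(),
    )


def load_recording(path) -> Recording:
    with np.load(path, allow_pickle=False) as z:
        fs = float(z["fs"])
        events = EventList(
            tuple(Event(int(o), str(l))
                  for o, l in zip(z["event_onsets"], z["event_labels"])),
            fs=fs,
        )
        return Recording(
            data=z["data"], fs=fs,
            channel_labels=tuple(str(l) for l in z["channel_labels"]),
            events=events,
        )


def read_recording_edf(path, events: EventList | None = None,
                       events_tsv=None) -> Recording:
    """Load an EDF recording (requires mne); events from a TSV if given."""
    try:
        import mne
    except ImportError as err:  # pragma: no cover - depends on extras
        raise ImportError(
            "reading EDF requires mne; install the 'edf' extra"
        ) from err
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data_uv = raw.get_data() * 1e6  # mne uses volts
    fs = float(raw.info["sfreq"])
    if events is None:
        if events_tsv is not None:
            from .io_ import read_events_tsv as _r
            events = _r(events_tsv, fs)
        else:
            events = EventList(events=(), fs=fs)
    return Recording(data=data_uv, fs=fs,
                     channel_labels=tuple(raw.ch_names), events=events)


def save_ground_truth(gt: GroundTruth, path) -> None:
    np.savez_compressed(
        path,
        mixing=gt.mixing,
        sources=gt.sources,
        source_names=np.array(gt.source_names),
        erp_waveform_per_trial=gt.erp_waveform_per_trial,
        bad_channel_index=np.array([c for c, _ in gt.bad_channels], dtype=int),
        bad_channel_kind=np.array([k for _, k in gt.bad_channels]),
        jitter_latency_samples=gt.jitters["latency_samples"],
        jitter_amplitude=gt.jitters["amplitude"],
    )


def write_report_json(report, path) -> None:
    obj = report.to_dict() if hasattr(report, "to_dict") else report
    Path(path).write_text(json.dumps(_jsonable(obj), indent=2))


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
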