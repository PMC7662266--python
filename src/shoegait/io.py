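"""Plain-text persistence: recording CSV + JSON sidecar, segments CSV."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .layout import SensorLayout
from .segmentation import Segment
from .simulate import GroundTruthEvent, Recording


def save_recording(recording: Recording, directory: str | Path) -> Path:
    """Write ``<recording_id>.csv`` (time_s + 20 channels) and a JSON
    sidecar with metadata and ground-truth events."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    t = np.arange(recording.n_samples) / recording.sampling_rate
    frame = pd.DataFrame({"time_s": t})
    for i, name in enumerate(recording.layout.channel_names):
        frame[name] = recording.samples[i]
    csv_path = directory / f"{recording.recording_id}.csv"
    frame.to_csv(csv_path, index=False)
    sidecar = {
        "participant_id": recording.participant_id,
        "gait_class": recording.gait_class,
        "sampling_rate": recording.sampling_rate,
        "channel_names": list(recording.layout.channel_names),
        "ground_truth": [
            {"event_type": e.event_type, "foot": e.foot, "time": e.time}
            for e in (recording.ground_truth or [])
        ],
    }
    with open(csv_path.with_suffix(".json"), "w") as fh:
        json.dump(sidecar, fh, indent=1)
    return csv_path


def load_recording(csv_path: str | Path) -> Recording:
    csv_path = Path(csv_path)
    frame = pd.read_csv(csv_path)
    with open(csv_path.with_suffix(".json")) as fh:
        meta = json.load(fh)
    layout = SensorLayout(tuple(meta["channel_names"]))
    samples = frame[list(layout.channel_names)].to_numpy().T
    truth = [
        GroundTruthEvent(e["event_type"], e["foot"], e["time"])
        for e in meta.get("ground_truth", [])
    ] or None
    return Recording(
        participant_id=meta["participant_id"],
        gait_class=meta["gait_class"],
        sampling_rate=meta["sampling_rate"],
        samples=samples,
        layout=layout,
        ground_truth=truth,
        recording_id=csv_path.stem,
    )


def load_cohort(directory: str | Path) -> list[Recording]:
    return [load_recording(p) for p in sorted(Path(directory).glob("*.csv"))]


def save_segments(segments: list[Segment], path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame([
        {"recording_id": s.recording_id, "scheme": s.scheme,
         "reference_foot": s.reference_foot, "start_index": s.start_index,
         "end_index": s.end_index, "gait_class": s.gait_class,
         "participant_id": s.participant_id}
        for s in segments
    ]).to_csv(path, index=False)
    return path


def load_segments(path: str | Path) -> list[Segment]:
    frame = pd.read_csv(path)
    return [
        Segment(r.scheme, r.reference_foot, int(r.start_index),
                int(r.end_index), r.recording_id, r.gait_class,
                int(r.participant_id))
        for r in frame.itertuples()
    ]
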