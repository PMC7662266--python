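"""Pressure-threshold gait-event detection and gait-cycle segmentation.

A foot is "in contact" whenever any of its four plantar pressure channels
reads at or above a threshold (default 40 ADC units).  Heel-strike /
toe-off events are the rising / falling edges of that contact indicator
after debouncing, and seven segmentation schemes cut a recording into
labelled windows:

========================  ====================================================
stride                    reference-foot heel-strike to the next one
step                      heel-strike of one foot to the next of the other
stance                    reference-foot heel-strike to its next toe-off
swing                     reference-foot toe-off to its next heel-strike
left_single_limb_support  left foot only in contact
right_single_limb_support right foot only in contact
double_limb_support       both feet in contact
========================  ====================================================

All intervals are half-open ``[start, end)`` in 0-based sample indices;
incomplete leading/trailing cycles are dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .simulate import Recording

DEFAULT_THRESHOLD = 40.0
DEFAULT_MIN_PHASE_S = 0.05
MIN_SEGMENT_SAMPLES = 4

SCHEMES = (
    "stride", "step", "stance", "swing",
    "left_single_limb_support", "right_single_limb_support",
    "double_limb_support",
)


@dataclass(frozen=True)
class GaitEvent:
    event_type: str  # heel_strike | toe_off
    foot: str
    sample_index: int
    time: float


@dataclass(frozen=True)
class Segment:
    scheme: str
    reference_foot: str  # left | right | both
    start_index: int
    end_index: int  # half-open
    recording_id: str
    gait_class: str
    participant_id: int

    def __post_init__(self) -> None:
        if self.end_index <= self.start_index:
            raise ValueError("segment must have end_index > start_index")

    @property
    def n_samples(self) -> int:
        return self.end_index - self.start_index


def detect_contact(
    recording: Recording, threshold: float = DEFAULT_THRESHOLD
) -> dict[str, np.ndarray]:
    """Per-foot boolean contact series (any pressure channel >= threshold)."""
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    out = {}
    for foot in ("left", "right"):
        block = recording.pressure(foot)
        if block.shape[0] == 0:
            raise ValueError(f"recording has no pressure channels for {foot} foot")
        out[foot] = np.any(block >= threshold, axis=0)
    return out


def _debounce(contact: np.ndarray, min_samples: int) -> np.ndarray:
    """Merge runs shorter than min_samples into their neighbours.

    Boundary runs are left alone (they are incomplete phases, not noise).
    Iterates until stable; each pass flips the interior runs that are too
    short, which merges them with the surrounding phase.
    """
    x = contact.copy()
    if min_samples <= 1 or x.size == 0:
        return x
    while True:
        edges = np.flatnonzero(np.diff(x.astype(np.int8)))
        starts = np.concatenate(([0], edges + 1))
        ends = np.concatenate((edges + 1, [x.size]))
        changed = False
        for s, e in zip(starts, ends):
            if s == 0 or e == x.size:
                continue
            if e - s < min_samples:
                x[s:e] = ~x[s]
                changed = True
                break  # run boundaries changed; recompute
        if not changed:
            return x


def detect_events(
    contact: dict[str, np.ndarray],
    sampling_rate: float,
    min_phase_duration: float = DEFAULT_MIN_PHASE_S,
) -> list[GaitEvent]:
    """Time-sorted heel-strike/toe-off events from contact edges."""
    min_samples = int(round(min_phase_duration * sampling_rate))
    events: list[GaitEvent] = []
    for foot, series in contact.items():
        x = _debounce(np.asarray(series, dtype=bool), min_samples)
        diff = np.diff(x.astype(np.int8))
        for i in np.flatnonzero(diff == 1):
            events.append(GaitEvent("heel_strike", foot, int(i + 1), (i + 1) / sampling_rate))
        for i in np.flatnonzero(diff == -1):
            events.append(GaitEvent("toe_off", foot, int(i + 1), (i + 1) / sampling_rate))
    events.sort(key=lambda e: (e.sample_index, e.foot, e.event_type))
    return events


def _foot_events(events: list[GaitEvent], foot: str, event_type: str) -> list[GaitEvent]:
    return [e for e in events if e.foot == foot and e.event_type == event_type]


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, end) runs of True, excluding boundary-touching runs."""
    if mask.size == 0:
        return []
    edges = np.flatnonzero(np.diff(mask.astype(np.int8)))
    starts = np.concatenate(([0], edges + 1))
    ends = np.concatenate((edges + 1, [mask.size]))
    out = []
    for s, e in zip(starts, ends):
        if not mask[s]:
            continue
        if s == 0 or e == mask.size:  # incomplete leading/trailing phase
            continue
        out.append((int(s), int(e)))
    return out


def segment(
    recording: Recording,
    scheme: str,
    threshold: float = DEFAULT_THRESHOLD,
    min_phase_duration: float = DEFAULT_MIN_PHASE_S,
    anchor: str = "right",
    min_segment_samples: int = MIN_SEGMENT_SAMPLES,
) -> list[Segment]:
    """Cut a recording into segments under one gait-cycle scheme."""
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; valid: {SCHEMES}")
    contact = detect_contact(recording, threshold)
    fs = recording.sampling_rate
    min_samples = int(round(min_phase_duration * fs))
    deb = {f: _debounce(c, min_samples) for f, c in contact.items()}
    events = detect_events(contact, fs, min_phase_duration)

    def make(start: int, end: int, foot: str) -> Segment | None:
        if end - start < min_segment_samples:
            return None
        return Segment(scheme, foot, start, end, recording.recording_id,
                       recording.gait_class, recording.participant_id)

    intervals: list[Segment] = []
    if scheme == "stride":
        hs = _foot_events(events, anchor, "heel_strike")
        for a, b in zip(hs, hs[1:]):
            if (s := make(a.sample_index, b.sample_index, anchor)) is not None:
                intervals.append(s)
    elif scheme == "step":
        hs_all = sorted(
            (e for e in events if e.event_type == "heel_strike"),
            key=lambda e: e.sample_index,
        )
        for a, b in zip(hs_all, hs_all[1:]):
            if a.foot == b.foot:
                continue  # missed opposite-foot strike; skip this gap
            if (s := make(a.sample_index, b.sample_index, a.foot)) is not None:
                intervals.append(s)
    elif scheme in ("stance", "swing"):
        hs = _foot_events(events, anchor, "heel_strike")
        to = _foot_events(events, anchor, "toe_off")
        first, second = (hs, to) if scheme == "stance" else (to, hs)
        j = 0
        for a in first:
            while j < len(second) and second[j].sample_index <= a.sample_index:
                j += 1
            if j == len(second):
                break
            if (s := make(a.sample_index, second[j].sample_index, anchor)) is not None:
                intervals.append(s)
    elif scheme in ("left_single_limb_support", "right_single_limb_support"):
        foot = scheme.split("_")[0]
        other = "right" if foot == "left" else "left"
        mask = deb[foot] & ~deb[other]
        for a, b in _runs(mask):
            if (s := make(a, b, foot)) is not None:
                intervals.append(s)
    elif scheme == "double_limb_support":
        mask = deb["left"] & deb["right"]
        for a, b in _runs(mask):
            if (s := make(a, b, "both")) is not None:
                intervals.append(s)

    if len(events) < 2 and not intervals:
        warnings.warn(
            f"recording {recording.recording_id}: fewer than 2 gait events; "
            f"no {scheme} segments", stacklevel=2,
        )
    return intervals


def segment_cohort(
    recordings: list[Recording],
    scheme: str,
    threshold: float = DEFAULT_THRESHOLD,
    min_phase_duration: float = DEFAULT_MIN_PHASE_S,
    anchor: str = "right",
) -> list[Segment]:
    """Segment every recording; concatenated, recording order preserved."""
    out: list[Segment] = []
    for rec in recordings:
        out.extend(segment(rec, scheme, threshold, min_phase_duration, anchor))
    return out
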