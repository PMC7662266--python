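"""Per-segment statistical feature battery and canonical feature table.

Eleven feature kinds are computed per segment: ten single-channel
statistics (mean, standard deviation, kurtosis, crest factor, skewness,
entropy, spectral flux, power, zero-crossing count, maximum value) and one
two-channel statistic (Pearson correlation between same-shoe, same-sensor
channel pairs).  Over the full 20-channel layout this yields exactly
224 feature columns: 24 correlations (C(4,2)=6 pressure pairs per shoe,
C(3,2)=3 per IMU per shoe) plus 10 statistics x 20 channels.

Definitions (x a segment of one channel, length N):

* mean        x̄ = (1/N) Σ x(i)
* std         sqrt( Σ (x − x̄)² / (N−1) )
* kurtosis    E[(x − x̄)⁴] / Std⁴ − 3   (excess; see ``table1_literal``)
* crest       max(x) / sqrt( Σ x² / (N−1) )
* skewness    E[((x − x̄)/Std)³]        (see ``table1_literal``)
* entropy     −Σ p ln p over a 10-bin equal-width histogram of the segment
* spectral flux  Σ_{i=2..N} (x(i) − x(i−1))²   (time-domain successive
  differences, one scalar per channel, despite the name)
* power       (1/N) Σ x(i)²
* zerocrossing   number of strict sign changes
* maxvalue    max(x)

``table1_literal=True`` switches kurtosis to a Std² denominator and
skewness to a squared (rather than cubed) standardized deviation —
dimensionally odd printed variants kept available for comparison.

Degenerate segments (zero variance) return 0 for correlation, skewness,
kurtosis and entropy rather than NaN so downstream standardization and
PCA stay finite.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd

from .layout import DEFAULT_LAYOUT, SENSOR_TYPES, SensorLayout
from .segmentation import Segment
from .simulate import Recording

#: single-channel feature names, canonical order
CHANNEL_FEATURES = (
    "mean", "std", "kurtosis", "crest_factor", "skewness", "entropy",
    "spectral_flux", "power", "zerocrossing", "maxvalue",
)
ALL_FEATURES = ("correlation",) + CHANNEL_FEATURES

#: metadata columns appended to every feature table
META_COLUMNS = ("gait_class", "participant_id")

ENTROPY_BINS = 10

#: features dropped by the family discard rule, per sensor type
DISCARDED: dict[str, tuple[str, ...]] = {
    "pressure": ("zerocrossing", "maxvalue"),
    "accelerometer": ("power", "zerocrossing", "maxvalue"),
    "gyroscope": ("power", "zerocrossing", "maxvalue"),
}


def _entropy(x: np.ndarray) -> float:
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi == lo:
        return 0.0
    counts, _ = np.histogram(x, bins=ENTROPY_BINS, range=(lo, hi))
    p = counts[counts > 0] / x.size
    return float(-np.sum(p * np.log(p)))


def feature_value(
    name: str,
    samples: np.ndarray,
    samples_b: np.ndarray | None = None,
    table1_literal: bool = False,
) -> float:
    """One scalar feature of a segment (two segments for correlation)."""
    x = np.asarray(samples, dtype=float)
    n = x.size
    if name == "mean":
        return float(np.mean(x))
    if name == "maxvalue":
        return float(np.max(x))
    if name == "power":
        return float(np.mean(x**2))
    if name == "spectral_flux":
        return float(np.sum(np.diff(x) ** 2))
    if name == "zerocrossing":
        return float(np.count_nonzero(x[1:] * x[:-1] < 0))
    if n < 2:
        raise ValueError(f"feature {name!r} needs at least 2 samples")
    if name == "std":
        return float(np.std(x, ddof=1))
    if name == "crest_factor":
        rms = np.sqrt(np.sum(x**2) / (n - 1))
        return float(np.max(x) / rms) if rms > 0 else 0.0
    xm = x - np.mean(x)
    sd = np.std(x, ddof=1)
    if name == "kurtosis":
        if sd == 0:
            return 0.0
        denom = sd**2 if table1_literal else sd**4
        return float(np.mean(xm**4) / denom - 3.0)
    if name == "skewness":
        if sd == 0:
            return 0.0
        expo = 2 if table1_literal else 3
        return float(np.mean((xm / sd) ** expo))
    if name == "entropy":
        return _entropy(x)
    if name == "correlation":
        if samples_b is None:
            raise ValueError("correlation needs a second channel")
        y = np.asarray(samples_b, dtype=float)
        ym = y - np.mean(y)
        sy = np.std(y, ddof=1)
        if sd == 0 or sy == 0:
            return 0.0
        return float(np.sum(xm * ym) / ((n - 1) * sd * sy))
    raise ValueError(f"unknown feature {name!r}; valid: {ALL_FEATURES}")


def correlation_pairs(
    layout: SensorLayout = DEFAULT_LAYOUT, sensor_type: str | None = None
) -> list[tuple[str, str]]:
    """Unordered within-shoe, within-sensor-type channel pairs.

    Pressure yields C(4,2)=6 pairs per shoe (12 total); each IMU yields
    C(3,2)=3 per shoe (6 total).
    """
    types = SENSOR_TYPES if sensor_type is None else (sensor_type,)
    for t in types:
        if t not in SENSOR_TYPES:
            raise ValueError(f"unknown sensor type {t!r}")
    pairs = []
    for t in types:
        for foot in ("left", "right"):
            chans = layout.channels((t,), foot)
            pairs.extend(combinations(chans, 2))
    return pairs


def correlation_feature_name(chan_a: str, chan_b: str,
                             layout: SensorLayout = DEFAULT_LAYOUT) -> str:
    foot = layout.foot_of_channel(chan_a)
    return (f"{foot}_{layout.base_of_channel(chan_a)}"
            f"x{layout.base_of_channel(chan_b)}_correlation")


def feature_columns(
    layout: SensorLayout = DEFAULT_LAYOUT,
    include_discarded: bool = True,
    sensor_types: tuple[str, ...] | None = None,
) -> list[str]:
    """Canonical feature-column order for a layout (and sensor subset).

    Per sensor type: correlation pairs first (left shoe then right), then
    per-channel statistics in layout order.  Full battery over 20 channels
    gives 224 columns; with the discard rule applied, 172.
    """
    types = tuple(sensor_types) if sensor_types else SENSOR_TYPES
    cols: list[str] = []
    for t in types:
        for a, b in correlation_pairs(layout, t):
            cols.append(correlation_feature_name(a, b, layout))
        dropped = DISCARDED[t] if not include_discarded else ()
        for chan in layout.channels((t,)):
            for feat in CHANNEL_FEATURES:
                if feat in dropped:
                    continue
                cols.append(f"{chan}_{feat}")
    return cols


def sensor_of_feature(name: str, layout: SensorLayout = DEFAULT_LAYOUT) -> str:
    """Sensor type that produced a feature column."""
    base = name.split("_", 1)[1]  # strip foot prefix
    if base.startswith("pressure"):
        return "pressure"
    if base.startswith("acc"):
        return "accelerometer"
    if base.startswith("gyro"):
        return "gyroscope"
    raise ValueError(f"cannot infer sensor type of feature {name!r}")


def _column_plan(
    layout: SensorLayout, include_discarded: bool
) -> list[tuple[str, int, int | str]]:
    """Computation plan aligned 1:1 with :func:`feature_columns` order.

    Entries are ("pair", i_a, i_b) for correlations and
    ("chan", i_chan, feature_name) for single-channel statistics.
    """
    plan: list[tuple[str, int, int | str]] = []
    for t in SENSOR_TYPES:
        for a, b in correlation_pairs(layout, t):
            plan.append(("pair", layout.index_of(a), layout.index_of(b)))
        dropped = DISCARDED[t] if not include_discarded else ()
        for chan in layout.channels((t,)):
            for feat in CHANNEL_FEATURES:
                if feat in dropped:
                    continue
                plan.append(("chan", layout.index_of(chan), feat))
    return plan


def _segment_features(
    window: np.ndarray,
    plan: list[tuple[str, int, int | str]],
    table1_literal: bool,
) -> np.ndarray:
    """All features of one channels x time window, vectorized per kind."""
    w = window.astype(float)
    n = w.shape[1]
    mean = w.mean(axis=1)
    xm = w - mean[:, None]
    sd = np.sqrt((xm**2).sum(axis=1) / (n - 1))
    safe_sd = np.where(sd > 0, sd, 1.0)

    vals: dict[str, np.ndarray] = {}
    vals["mean"] = mean
    vals["std"] = sd
    if table1_literal:
        vals["kurtosis"] = np.where(sd > 0, (xm**4).mean(axis=1) / safe_sd**2 - 3.0, 0.0)
        vals["skewness"] = np.where(sd > 0, ((xm / safe_sd[:, None]) ** 2).mean(axis=1), 0.0)
    else:
        vals["kurtosis"] = np.where(sd > 0, (xm**4).mean(axis=1) / safe_sd**4 - 3.0, 0.0)
        vals["skewness"] = np.where(sd > 0, ((xm / safe_sd[:, None]) ** 3).mean(axis=1), 0.0)
    rms = np.sqrt((w**2).sum(axis=1) / (n - 1))
    vals["crest_factor"] = np.where(rms > 0, w.max(axis=1) / np.where(rms > 0, rms, 1.0), 0.0)
    vals["entropy"] = np.array([_entropy(row) for row in w])
    vals["spectral_flux"] = (np.diff(w, axis=1) ** 2).sum(axis=1)
    vals["power"] = (w**2).mean(axis=1)
    vals["zerocrossing"] = np.count_nonzero(w[:, 1:] * w[:, :-1] < 0, axis=1).astype(float)
    vals["maxvalue"] = w.max(axis=1)

    out = np.empty(len(plan))
    for k, (kind, i, j) in enumerate(plan):
        if kind == "pair":
            if sd[i] == 0 or sd[j] == 0:
                out[k] = 0.0
            else:
                out[k] = (xm[i] * xm[j]).sum() / ((n - 1) * sd[i] * sd[j])
        else:
            out[k] = vals[j][i]
    return out


def build_feature_table(
    segments: list[Segment],
    recordings: list[Recording],
    layout: SensorLayout = DEFAULT_LAYOUT,
    include_discarded: bool = True,
    table1_literal: bool = False,
    min_segment_samples: int = 4,
) -> pd.DataFrame:
    """Segments x features table with ``gait_class``/``participant_id``.

    Column order is the canonical :func:`feature_columns` order, so tables
    are byte-comparable across runs.  Segments shorter than
    ``min_segment_samples`` are skipped (count reported via a warning-free
    attrs entry ``n_skipped``).
    """
    by_id = {rec.recording_id: rec for rec in recordings}
    cols = feature_columns(layout, include_discarded)
    plan = _column_plan(layout, include_discarded)

    rows, meta_cls, meta_pid = [], [], []
    n_skipped = 0
    for seg in segments:
        if seg.recording_id not in by_id:
            raise KeyError(f"segment references unknown recording {seg.recording_id!r}")
        if seg.n_samples < min_segment_samples:
            n_skipped += 1
            continue
        rec = by_id[seg.recording_id]
        window = rec.samples[:, seg.start_index:seg.end_index]
        rows.append(_segment_features(window, plan, table1_literal))
        meta_cls.append(seg.gait_class)
        meta_pid.append(seg.participant_id)

    table = pd.DataFrame(np.array(rows).reshape(len(rows), len(cols)), columns=cols)
    table["gait_class"] = meta_cls
    table["participant_id"] = meta_pid
    table.attrs["n_skipped"] = n_skipped
    return table


def select_sensor_columns(
    table: pd.DataFrame, sensor_types: tuple[str, ...] | set[str],
    layout: SensorLayout = DEFAULT_LAYOUT,
) -> pd.DataFrame:
    """Restrict a feature table to features of the given sensor types."""
    keep = [
        c for c in table.columns
        if c in META_COLUMNS or sensor_of_feature(c, layout) in sensor_types
    ]
    return table[keep].copy()
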