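"""Information-gain feature ranking and the family discard rule.

Information gain of a feature against the gait-class label is
``IG = H(label) − H(label | binned feature)`` in bits, with the feature
discretized into equal-width bins (default 10, base-2 logarithm).  A
perfect predictor attains the label entropy; a constant or independent
feature scores (near) zero, up to finite-sample bias.

The production pipeline discards a fixed family of low-information
features rather than re-ranking each run: power on the accelerometer and
gyroscope channels (12 columns), all zero-crossing counts (20) and all
maximum values (20) — 52 of the 224 full-battery columns, leaving 172.
A ranking-based ``discard_bottom_k`` is provided for experiments.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .features import (DISCARDED, META_COLUMNS, feature_columns,
                       sensor_of_feature)
from .layout import DEFAULT_LAYOUT, SensorLayout


def _label_entropy_bits(labels: np.ndarray) -> float:
    _, counts = np.unique(labels, return_counts=True)
    p = counts / counts.sum()
    return float(-np.sum(p * np.log2(p)))


def information_gain(
    values: np.ndarray, labels: np.ndarray, n_bins: int = 10
) -> float:
    """IG in bits of a (discretized) feature about the class label."""
    x = np.asarray(values, dtype=float)
    y = np.asarray(labels)
    if x.shape[0] != y.shape[0]:
        raise ValueError("values and labels must have equal length")
    if x.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    h_label = _label_entropy_bits(y)
    if h_label == 0.0:
        return 0.0
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi == lo:
        return 0.0
    edges = np.linspace(lo, hi, n_bins + 1)
    bins = np.clip(np.digitize(x, edges[1:-1]), 0, n_bins - 1)
    n = x.shape[0]
    h_cond = 0.0
    for b in np.unique(bins):
        sub = y[bins == b]
        h_cond += (sub.shape[0] / n) * _label_entropy_bits(sub)
    return max(float(h_label - h_cond), 0.0)


def rank_features(
    table: pd.DataFrame, label_column: str = "gait_class", n_bins: int = 10
) -> pd.DataFrame:
    """IG of every feature column, sorted descending (ties by name)."""
    if label_column not in table.columns:
        raise ValueError(f"table lacks label column {label_column!r}")
    labels = table[label_column].to_numpy()
    feats = [c for c in table.columns if c not in META_COLUMNS]
    ig = [information_gain(table[c].to_numpy(), labels, n_bins) for c in feats]
    ranking = pd.DataFrame({"feature": feats, "ig_bits": ig})
    return (ranking.sort_values(["ig_bits", "feature"],
                                ascending=[False, True])
            .reset_index(drop=True))


def discarded_columns(layout: SensorLayout = DEFAULT_LAYOUT) -> list[str]:
    """The 52 full-battery columns removed by the family rule."""
    out = []
    for col in feature_columns(layout, include_discarded=True):
        if col.endswith("_correlation"):
            continue
        feat = col.rsplit("_", 1)[1]
        if feat in DISCARDED[sensor_of_feature(col, layout)]:
            out.append(col)
    return out


def apply_discard_rule(
    table: pd.DataFrame,
    layout: SensorLayout = DEFAULT_LAYOUT,
    strict: bool = False,
) -> pd.DataFrame:
    """Drop the fixed 52-column family from a full-battery table.

    Idempotent by default; with ``strict=True`` the table must contain
    the complete 224-column battery and a ``ValueError`` lists anything
    missing.
    """
    to_drop = discarded_columns(layout)
    if strict:
        expected = feature_columns(layout, include_discarded=True)
        missing = [c for c in expected if c not in table.columns]
        if missing:
            raise ValueError(f"table missing expected columns: {missing}")
    present = [c for c in to_drop if c in table.columns]
    return table.drop(columns=present)


def discard_bottom_k(
    table: pd.DataFrame, k: int, label_column: str = "gait_class",
    n_bins: int = 10,
) -> pd.DataFrame:
    """Data-driven alternative: drop the k lowest-IG feature columns."""
    ranking = rank_features(table, label_column, n_bins)
    if k < 0 or k > len(ranking):
        raise ValueError(f"k must be in [0, {len(ranking)}]")
    drop = ranking["feature"].tail(k).tolist()
    return table.drop(columns=drop)
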