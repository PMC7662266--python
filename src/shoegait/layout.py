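"""Canonical 20-channel smart-shoe sensor layout.

Each shoe carries four plantar pressure sensors (heel, lateral midfoot,
medial forefoot, toe), a three-axis accelerometer and a three-axis
gyroscope, giving 10 channels per foot and 20 in total.  Channel names are
``<foot>_<base>``, e.g. ``left_pressure_heel`` or ``right_gyro_z``; the
ordering below is the canonical column order used everywhere in the
package (recordings, CSV export, feature naming).
"""

from __future__ import annotations

from dataclasses import dataclass, field

FEET = ("left", "right")
SENSOR_TYPES = ("pressure", "accelerometer", "gyroscope")

PRESSURE_SITES = ("heel", "lateral_midfoot", "medial_forefoot", "toe")
ACC_AXES = ("acc_x", "acc_y", "acc_z")
GYRO_AXES = ("gyro_x", "gyro_y", "gyro_z")

#: base (foot-less) channel names for one shoe, in canonical order
BASE_CHANNELS = tuple(
    [f"pressure_{s}" for s in PRESSURE_SITES] + list(ACC_AXES) + list(GYRO_AXES)
)


def _sensor_of_base(base: str) -> str:
    if base.startswith("pressure"):
        return "pressure"
    if base.startswith("acc"):
        return "accelerometer"
    if base.startswith("gyro"):
        return "gyroscope"
    raise ValueError(f"unknown channel base name: {base!r}")


@dataclass(frozen=True)
class SensorLayout:
    """Ordered 20-channel layout with per-channel sensor-type and foot maps."""

    channel_names: tuple[str, ...] = field(
        default_factory=lambda: tuple(
            f"{foot}_{base}" for foot in FEET for base in BASE_CHANNELS
        )
    )

    def __post_init__(self) -> None:
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")
        counts = {t: 0 for t in SENSOR_TYPES}
        per_foot = {f: 0 for f in FEET}
        for name in self.channel_names:
            counts[self.sensor_of_channel(name)] += 1
            per_foot[self.foot_of_channel(name)] += 1
        if counts != {"pressure": 8, "accelerometer": 6, "gyroscope": 6}:
            raise ValueError(f"bad sensor-type counts: {counts}")
        if any(n != 10 for n in per_foot.values()):
            raise ValueError(f"each foot needs 10 channels, got {per_foot}")

    def foot_of_channel(self, name: str) -> str:
        foot = name.split("_", 1)[0]
        if foot not in FEET:
            raise ValueError(f"channel {name!r} has no valid foot prefix")
        return foot

    def base_of_channel(self, name: str) -> str:
        return name.split("_", 1)[1]

    def sensor_of_channel(self, name: str) -> str:
        return _sensor_of_base(self.base_of_channel(name))

    def index_of(self, name: str) -> int:
        return self.channel_names.index(name)

    def channels(
        self, sensor_types: tuple[str, ...] | set[str] | None = None,
        foot: str | None = None,
    ) -> list[str]:
        """Channel names filtered by sensor type and/or foot, layout order."""
        out = []
        for name in self.channel_names:
            if sensor_types is not None and self.sensor_of_channel(name) not in sensor_types:
                continue
            if foot is not None and self.foot_of_channel(name) != foot:
                continue
            out.append(name)
        return out

    def pressure_indices(self, foot: str) -> list[int]:
        return [self.index_of(c) for c in self.channels(("pressure",), foot)]


#: module-level default layout
DEFAULT_LAYOUT = SensorLayout()
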