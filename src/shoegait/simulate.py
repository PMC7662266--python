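"""Synthetic smart-shoe cohort generator with ground-truth gait events.

Emulates treadmill recordings of five gait classes — normal, unstable
left, unstable right, supination (toe-out) and pronation (toe-in) — on a
20-channel shoe layout.  Plantar pressure is modelled as stance-locked
bursts (fast cosine attack/release, gentle mid-stance hump) in ADC-like
units on [0, 1023]; the accelerometer carries a heel-strike impact
transient plus cycle-locked oscillation; the gyroscope carries a
swing-phase angular-velocity peak.  Every recording exports the exact
modelled heel-strike and toe-off times so downstream event detection and
parameter recovery can be validated against ground truth.

Class signatures encode the qualitative abnormality directions: unstable
gait shortens the target foot's step and shifts its stance/swing ratio;
toe-out gait reduces the heel-to-metatarsal contact gap and loads the
lateral border; toe-in gait here also shifts load laterally (the
convention this package follows by default; the direction is a plain
parameter, override ``lateral_weight_share`` to flip it).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .layout import DEFAULT_LAYOUT, SensorLayout

GAIT_CLASSES = ("normal", "unstable_left", "unstable_right", "supination", "pronation")

PRESSURE_MAX = 1023.0
#: resting sensor output (ADC units); well below the contact threshold 40
PRESSURE_BASELINE = 8.0
#: pressure noise SD at noise_scale = 1
PRESSURE_NOISE_SD = 3.0
#: IMU noise SD at noise_scale = 1 (sensor units)
IMU_NOISE_SD = 0.05
#: attack/release ramp of a pressure burst, seconds
BURST_RAMP_S = 0.02


@dataclass(frozen=True)
class ClassSignature:
    """Per-class gait parameters driving the signal model."""

    gait_class: str
    stance_fraction_left: float
    stance_fraction_right: float
    heel_metatarsal_gap: float  # seconds between heel and forefoot contact
    lateral_weight_share: float  # forefoot load split, lateral vs medial
    step_length_scale_left: float
    step_length_scale_right: float

    def __post_init__(self) -> None:
        if self.gait_class not in GAIT_CLASSES:
            raise ValueError(
                f"unknown gait class {self.gait_class!r}; valid: {GAIT_CLASSES}"
            )
        for name in ("stance_fraction_left", "stance_fraction_right",
                     "lateral_weight_share"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if self.heel_metatarsal_gap < 0:
            raise ValueError("heel_metatarsal_gap must be >= 0")
        for name in ("step_length_scale_left", "step_length_scale_right"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


_SIGNATURE_DEFAULTS: dict[str, dict[str, float]] = {
    # symmetric reference gait
    "normal": dict(
        stance_fraction_left=0.60, stance_fraction_right=0.60,
        heel_metatarsal_gap=0.12, lateral_weight_share=0.50,
        step_length_scale_left=1.0, step_length_scale_right=1.0,
    ),
    # target foot: shortened step, altered stance/swing ratio
    "unstable_left": dict(
        stance_fraction_left=0.54, stance_fraction_right=0.60,
        heel_metatarsal_gap=0.12, lateral_weight_share=0.50,
        step_length_scale_left=0.75, step_length_scale_right=1.0,
    ),
    "unstable_right": dict(
        stance_fraction_left=0.60, stance_fraction_right=0.54,
        heel_metatarsal_gap=0.12, lateral_weight_share=0.50,
        step_length_scale_left=1.0, step_length_scale_right=0.75,
    ),
    # toe-out: heel→metatarsal gap shrinks, lateral border loads up
    "supination": dict(
        stance_fraction_left=0.60, stance_fraction_right=0.60,
        heel_metatarsal_gap=0.05, lateral_weight_share=0.72,
        step_length_scale_left=1.0, step_length_scale_right=1.0,
    ),
    # toe-in: lateral load shift (default convention here), slightly
    # widened heel→metatarsal gap
    "pronation": dict(
        stance_fraction_left=0.60, stance_fraction_right=0.60,
        heel_metatarsal_gap=0.16, lateral_weight_share=0.62,
        step_length_scale_left=1.0, step_length_scale_right=1.0,
    ),
}


def class_signature(gait_class: str, **overrides: float) -> ClassSignature:
    """Default :class:`ClassSignature` for a gait class, with overrides.

    Raises ``ValueError`` for an unknown class, an unknown override key,
    or an override that violates the signature invariants.
    """
    if gait_class not in _SIGNATURE_DEFAULTS:
        raise ValueError(
            f"unknown gait class {gait_class!r}; valid: {GAIT_CLASSES}"
        )
    params = dict(_SIGNATURE_DEFAULTS[gait_class])
    for key, value in overrides.items():
        if key not in params:
            raise ValueError(f"unknown signature parameter {key!r}")
        params[key] = float(value)
    sig = ClassSignature(gait_class=gait_class, **params)
    if gait_class == "normal" and not overrides:
        assert sig.stance_fraction_left == sig.stance_fraction_right
    return sig


@dataclass(frozen=True)
class ParticipantProfile:
    """Participant-level random effects, a pure function of (seed, id)."""

    participant_id: int
    cadence: float  # strides per minute
    amplitude_scale: float
    noise_scale: float
    stance_factor: float  # multiplicative perturbation of stance fractions
    rng_seed: int

    def __post_init__(self) -> None:
        if self.cadence <= 0:
            raise ValueError("cadence must be > 0")
        if self.amplitude_scale <= 0 or self.noise_scale < 0:
            raise ValueError("scales must be positive (noise may be 0)")


@dataclass(frozen=True)
class GroundTruthEvent:
    event_type: str  # heel_strike | toe_off
    foot: str
    time: float  # seconds


@dataclass
class Recording:
    """One participant x gait-class multichannel time series."""

    participant_id: int
    gait_class: str
    sampling_rate: float
    samples: np.ndarray  # channels x time, layout order
    layout: SensorLayout = field(default_factory=lambda: DEFAULT_LAYOUT)
    ground_truth: list[GroundTruthEvent] | None = None
    recording_id: str = ""

    def __post_init__(self) -> None:
        if self.samples.shape[0] != len(self.layout.channel_names):
            raise ValueError(
                f"samples has {self.samples.shape[0]} channels, layout has "
                f"{len(self.layout.channel_names)}"
            )
        if not self.recording_id:
            self.recording_id = f"p{self.participant_id:02d}_{self.gait_class}"

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    def channel(self, name: str) -> np.ndarray:
        return self.samples[self.layout.index_of(name)]

    def pressure(self, foot: str) -> np.ndarray:
        """4 x time pressure block for one foot."""
        return self.samples[self.layout.pressure_indices(foot)]

    def truth_times(self, event_type: str, foot: str) -> np.ndarray:
        if self.ground_truth is None:
            return np.empty(0)
        return np.array(
            [e.time for e in self.ground_truth
             if e.event_type == event_type and e.foot == foot]
        )


def _burst(t: np.ndarray, on: float, off: float, ramp: float) -> np.ndarray:
    """Unit-amplitude stance burst: cosine ramps at both ends, slight
    mid-stance hump, exactly zero outside [on, off]."""
    dur = off - on
    ramp = min(ramp, dur / 2.0)
    env = np.zeros_like(t)
    inside = (t >= on) & (t <= off)
    ti = t[inside]
    e = np.ones_like(ti)
    rise = ti < on + ramp
    e[rise] = 0.5 * (1.0 - np.cos(np.pi * (ti[rise] - on) / ramp))
    fall = ti > off - ramp
    e[fall] = 0.5 * (1.0 - np.cos(np.pi * (off - ti[fall]) / ramp))
    # gentle loading/unloading hump so mid-stance is not flat
    hump = 0.85 + 0.15 * np.sin(np.pi * np.clip((ti - on) / dur, 0, 1))
    env[inside] = e * hump
    return env


def _impact(t: np.ndarray, t0: float, amp: float, f: float = 25.0,
            tau: float = 0.05) -> np.ndarray:
    """Decaying sinusoid starting at t0 (heel-strike shock)."""
    dt = t - t0
    mask = (dt >= 0) & (dt < 6 * tau)
    out = np.zeros_like(t)
    d = dt[mask]
    out[mask] = amp * np.exp(-d / tau) * np.sin(2 * np.pi * f * d)
    return out


def _foot_schedule(
    signature: ClassSignature, foot: str, cadence: float, stance_factor: float,
    duration: float,
) -> tuple[float, float, np.ndarray]:
    """(stride period T, stance duration S, heel-strike times) for a foot."""
    T = 60.0 / cadence
    sf = getattr(signature, f"stance_fraction_{foot}") * stance_factor
    sf = float(np.clip(sf, 0.40, 0.75))
    S = sf * T
    t0 = 0.2 + (0.5 * T if foot == "left" else 0.0)
    # include one lead-in stride so the recording starts mid-gait
    ks = np.arange(-1, int(math.ceil(duration / T)) + 1)
    hs = t0 + ks * T
    return T, S, hs


def simulate_recording(
    profile: ParticipantProfile,
    signature: ClassSignature,
    duration: float,
    sampling_rate: float = 100.0,
    layout: SensorLayout = DEFAULT_LAYOUT,
) -> Recording:
    """Simulate one labelled recording with exported ground-truth events.

    Deterministic given ``(profile.rng_seed, signature, duration,
    sampling_rate)``.  Raises ``ValueError`` if the duration is shorter
    than one stride.
    """
    if duration <= 0 or sampling_rate <= 0:
        raise ValueError("duration and sampling_rate must be > 0")
    T = 60.0 / profile.cadence
    if duration < T:
        raise ValueError(
            f"duration {duration:.2f}s is shorter than one stride ({T:.2f}s)"
        )
    rng = np.random.default_rng(profile.rng_seed)
    n = int(round(duration * sampling_rate))
    t = np.arange(n) / sampling_rate
    samples = np.zeros((len(layout.channel_names), n))
    truth: list[GroundTruthEvent] = []

    amp = profile.amplitude_scale
    share = signature.lateral_weight_share
    gap = signature.heel_metatarsal_gap

    for foot in ("left", "right"):
        T, S, hs_times = _foot_schedule(
            signature, foot, profile.cadence, profile.stance_factor, duration
        )
        step_scale = getattr(signature, f"step_length_scale_{foot}")
        gap_eff = min(gap, 0.5 * S)

        # --- pressure: per-sensor onset/offset within the stance window
        windows = {
            "pressure_heel": (0.0, 0.70 * S, 650.0),
            "pressure_lateral_midfoot": (gap_eff, 0.85 * S, 2 * share * 500.0),
            "pressure_medial_forefoot": (gap_eff, 0.90 * S, 2 * (1 - share) * 500.0),
            "pressure_toe": (gap_eff + 0.10 * S, S, 450.0),
        }
        for base, (d_on, d_off, peak) in windows.items():
            idx = layout.index_of(f"{foot}_{base}")
            sig = np.zeros(n)
            for hs in hs_times:
                if hs + d_off < 0 or hs + d_on > duration:
                    continue
                sig += peak * amp * _burst(t, hs + d_on, hs + d_off, BURST_RAMP_S)
            sig += PRESSURE_BASELINE
            sig += rng.normal(0.0, PRESSURE_NOISE_SD * profile.noise_scale, n)
            samples[idx] = np.clip(sig, 0.0, PRESSURE_MAX)

        # --- IMU amplitude modulation encoding the class signature
        phase = 0.0 if foot == "right" else np.pi
        w = 2 * np.pi / T
        # transverse/frontal-plane rotation grows with lateral loading and
        # with early forefoot contact (toe-out/in signatures)
        yaw_amp = 0.4 + 2.0 * (share - 0.5) + 2.0 * (0.12 - gap)
        roll_amp = 0.8 * (1.0 + 4.0 * (0.12 - gap))
        sway_amp = 0.3 * (1.0 + 1.5 * (share - 0.5))

        acc_x = 0.5 * amp * step_scale * np.sin(w * t + phase)
        acc_x += 0.15 * amp * np.sin(2 * w * t + phase)
        acc_y = sway_amp * amp * np.sin(0.5 * w * t + phase / 2)
        acc_z = 0.3 * amp * np.sin(w * t + phase + np.pi / 3)
        gyro_x = 0.3 * amp * np.sin(w * t + phase)
        gyro_y = roll_amp * amp * step_scale * np.sin(w * t + phase + np.pi / 4)
        gyro_z = yaw_amp * amp * np.sin(w * t + phase + np.pi / 2)

        for hs in hs_times:
            if hs < -1.0 or hs > duration:
                continue
            acc_z = acc_z + _impact(t, hs, 1.2 * amp * step_scale)
            # swing-phase sagittal angular-velocity peak
            gyro_x = gyro_x + 3.0 * amp * step_scale * _burst(
                t, hs + S, hs + T, 0.15 * (T - S)
            )

        for base, sig in (("acc_x", acc_x), ("acc_y", acc_y), ("acc_z", acc_z),
                          ("gyro_x", gyro_x), ("gyro_y", gyro_y),
                          ("gyro_z", gyro_z)):
            idx = layout.index_of(f"{foot}_{base}")
            samples[idx] = sig + rng.normal(
                0.0, IMU_NOISE_SD * profile.noise_scale, n
            )

        # --- ground truth: whole-foot contact is [hs, hs + S)
        for hs in hs_times:
            if 0.0 <= hs < duration:
                truth.append(GroundTruthEvent("heel_strike", foot, float(hs)))
            to = hs + S
            if 0.0 <= to < duration:
                truth.append(GroundTruthEvent("toe_off", foot, float(to)))

    truth.sort(key=lambda e: (e.time, e.foot, e.event_type))
    return Recording(
        participant_id=profile.participant_id,
        gait_class=signature.gait_class,
        sampling_rate=sampling_rate,
        samples=samples,
        layout=layout,
        ground_truth=truth,
    )


def participant_profiles(
    n_participants: int,
    seed: int,
    noise_scale: float = 1.0,
    cadence_range: tuple[float, float] = (55.0, 65.0),
    amplitude_sigma: float = 0.10,
    stance_sigma: float = 0.03,
) -> list[ParticipantProfile]:
    """Derive per-participant profiles from a cohort seed.

    Cadence is uniform on ``cadence_range``; amplitude and stance-fraction
    perturbations are log-normal (sigma in log space) so they are positive
    multiplicative effects shared by all of a participant's recordings.
    """
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_participants)
    profiles = []
    for pid, child in enumerate(children, start=1):
        rng = np.random.default_rng(child)
        profiles.append(ParticipantProfile(
            participant_id=pid,
            cadence=float(rng.uniform(*cadence_range)),
            amplitude_scale=float(rng.lognormal(0.0, amplitude_sigma)),
            noise_scale=float(noise_scale * rng.lognormal(0.0, 0.10)),
            stance_factor=float(rng.lognormal(0.0, stance_sigma)),
            rng_seed=int(child.generate_state(1)[0] % (2**31)),
        ))
    return profiles


DEFAULT_DURATIONS: dict[str, float] = {
    "normal": 180.0, "unstable_left": 60.0, "unstable_right": 60.0,
    "supination": 60.0, "pronation": 60.0,
}


def simulate_cohort(
    n_participants: int = 18,
    seed: int = 0,
    sampling_rate: float = 100.0,
    layout: SensorLayout = DEFAULT_LAYOUT,
    durations_per_class: dict[str, float] | None = None,
    noise_scale: float = 1.0,
    signature_overrides: dict[str, dict[str, float]] | None = None,
) -> list[Recording]:
    """Simulate a labelled cohort: one recording per participant per class.

    Default durations follow the acquisition protocol this package
    emulates: 180 s of normal gait and 60 s of each abnormal gait.
    """
    if n_participants < 2:
        raise ValueError("need at least 2 participants (LOOCV requires >= 2)")
    durations = dict(DEFAULT_DURATIONS)
    if durations_per_class:
        durations.update(durations_per_class)
    overrides = signature_overrides or {}
    signatures = {
        cls: class_signature(cls, **overrides.get(cls, {})) for cls in GAIT_CLASSES
    }
    profiles = participant_profiles(n_participants, seed, noise_scale=noise_scale)
    recordings = []
    for profile in profiles:
        for i, cls in enumerate(GAIT_CLASSES):
            rec_profile = replace(
                profile, rng_seed=(profile.rng_seed * 5 + i) % (2**31)
            )
            recordings.append(simulate_recording(
                rec_profile, signatures[cls], durations[cls], sampling_rate,
                layout,
            ))
    return recordings
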