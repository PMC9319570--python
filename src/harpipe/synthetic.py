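"""Synthetic accelerometer cohorts with the statistical structure the analysis assumes.

The generator does not attempt biomechanically realistic gait. It emulates the
properties the pipeline relies on: gait classes are harmonic signals whose
fundamental lies in the 1.5-2.5 Hz band (with class-specific amplitude and
harmonic ratios across axes), sedentary driving is low-amplitude band-limited
noise with its power below 0.5 Hz, classes are severely imbalanced (driving
majority, stair classes a few percent each), subjects differ by a relative
jitter on profile parameters, and every activity boundary carries an explicit
transition segment so the transition-exclusion rule is exercised. Units are g,
with a constant gravity-like offset on the y axis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .ingest import (
    ACTIVITY_CLASSES,
    SENSOR_LOCATIONS,
    TRANSITION_LABEL,
    RawRecording,
)

WALKING_CLASSES = ("level_walking", "ascending_stairs", "descending_stairs")
GAIT_BAND_HZ = (1.5, 2.5)


class ConfigurationError(ValueError):
    """Raised for invalid generator configuration (unknown activity, bad shares...)."""


@dataclass
class ActivityProfile:
    """Signal recipe for one activity class.

    ``harmonic_amps`` holds the amplitudes (g) of the fundamental and its two
    harmonics, per axis (shape 3 axes x 3 harmonics). For driving the
    fundamental frequency is 0 and the first column is reused as the amplitude
    of a slow drift component at ``lowfreq_drift_hz``.
    """

    activity_name: str
    fundamental_freq_hz: float
    harmonic_amps: np.ndarray
    baseline_offset: np.ndarray
    noise_sd: float
    lowfreq_drift_hz: float = 0.3

    def __post_init__(self) -> None:
        self.harmonic_amps = np.asarray(self.harmonic_amps, dtype=float)
        self.baseline_offset = np.asarray(self.baseline_offset, dtype=float)
        if self.harmonic_amps.shape != (3, 3):
            raise ConfigurationError(
                f"harmonic_amps must be (3 axes, 3 harmonics), got {self.harmonic_amps.shape}"
            )
        if self.baseline_offset.shape != (3,):
            raise ConfigurationError("baseline_offset must have one entry per axis")
        if (self.harmonic_amps < 0).any():
            raise ConfigurationError("amplitudes must be >= 0")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be > 0")
        if self.activity_name in WALKING_CLASSES:
            lo, hi = GAIT_BAND_HZ
            if not (lo <= self.fundamental_freq_hz <= hi):
                raise ConfigurationError(
                    f"{self.activity_name}: fundamental {self.fundamental_freq_hz} Hz "
                    f"outside the gait band [{lo}, {hi}] Hz"
                )
        elif self.activity_name == "driving":
            if self.fundamental_freq_hz != 0:
                raise ConfigurationError("driving must have fundamental_freq_hz = 0")
            if not (0 < self.lowfreq_drift_hz < 0.5):
                raise ConfigurationError("driving drift must lie below 0.5 Hz")
        else:
            raise ConfigurationError(f"unknown activity {self.activity_name!r}")


def default_profiles() -> dict[str, ActivityProfile]:
    """Default activity profiles.

    The study's source data carry no per-activity amplitude statistics, so the
    amplitudes here are free parameters chosen to look like adult gait in g
    units: sub-g oscillation dominated by the y (vertical) axis, stair classes
    separated from level walking by cadence within the gait band and by
    harmonic-ratio differences rather than by leaving the band, driving an
    order of magnitude weaker with only sub-0.5 Hz structure.
    """
    return {
        "level_walking": ActivityProfile(
            "level_walking",
            fundamental_freq_hz=1.9,
            harmonic_amps=np.array(
                [[0.22, 0.07, 0.025], [0.50, 0.15, 0.05], [0.30, 0.09, 0.03]]
            ),
            baseline_offset=np.array([0.0, 1.0, 0.0]),
            noise_sd=0.10,
        ),
        "ascending_stairs": ActivityProfile(
            "ascending_stairs",
            fundamental_freq_hz=1.7,
            harmonic_amps=np.array(
                [[0.20, 0.12, 0.05], [0.42, 0.25, 0.09], [0.26, 0.15, 0.06]]
            ),
            baseline_offset=np.array([0.0, 1.0, 0.0]),
            noise_sd=0.10,
        ),
        "descending_stairs": ActivityProfile(
            "descending_stairs",
            fundamental_freq_hz=2.15,
            harmonic_amps=np.array(
                [[0.28, 0.06, 0.02], [0.58, 0.10, 0.08], [0.36, 0.07, 0.025]]
            ),
            baseline_offset=np.array([0.0, 1.0, 0.0]),
            noise_sd=0.10,
        ),
        "driving": ActivityProfile(
            "driving",
            fundamental_freq_hz=0.0,
            harmonic_amps=np.array(
                [[0.030, 0.0, 0.0], [0.040, 0.0, 0.0], [0.030, 0.0, 0.0]]
            ),
            baseline_offset=np.array([0.0, 1.0, 0.0]),
            noise_sd=0.02,
            lowfreq_drift_hz=0.3,
        ),
    }


#: Per-location gain: a wrist moves less coherently with gait than an ankle.
_LOCATION_GAIN = {
    "left_wrist": 0.7,
    "left_hip": 0.85,
    "left_ankle": 1.0,
    "right_ankle": 1.0,
}


@dataclass
class CohortSpec:
    """Study-condition description for a synthetic cohort.

    The default class shares mirror the severe imbalance of the study data
    (driving majority, stair classes under 5% each); the per-subject recording
    length defaults to 360 s, a desk-scale stand-in for the study's multi-hour
    streams that still yields tens of stair epochs per subject.
    """

    n_subjects: int = 8
    class_share: dict = field(
        default_factory=lambda: {
            "driving": 0.64,
            "level_walking": 0.27,
            "ascending_stairs": 0.045,
            "descending_stairs": 0.045,
        }
    )
    sensor_locations: tuple = ("left_ankle",)
    sample_rate_hz: float = 100.0
    subject_variability: float = 0.08
    duration_s: float = 360.0
    transition_s: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.class_share.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(f"class_share sums to {total}, expected 1")
        unknown = set(self.class_share) - set(ACTIVITY_CLASSES)
        if unknown:
            raise ConfigurationError(f"unknown activities in class_share: {unknown}")
        bad = set(self.sensor_locations) - set(SENSOR_LOCATIONS)
        if bad:
            raise ConfigurationError(f"unknown sensor locations: {bad}")


def _activity_block(
    profile: ActivityProfile,
    n: int,
    fs: float,
    rng: np.random.Generator,
    gain: float = 1.0,
) -> np.ndarray:
    """One continuous block of samples (n, 3) for an activity."""
    t = np.arange(n) / fs
    out = np.empty((n, 3))
    f0 = profile.fundamental_freq_hz if profile.fundamental_freq_hz > 0 else profile.lowfreq_drift_hz
    harmonics = (1.0, 2.0, 3.0) if profile.fundamental_freq_hz > 0 else (1.0,)
    for ax in range(3):
        sig = np.full(n, profile.baseline_offset[ax])
        for h_idx, h in enumerate(harmonics):
            amp = gain * profile.harmonic_amps[ax, h_idx]
            if amp <= 0:
                continue
            phase = rng.uniform(0, 2 * math.pi)
            sig = sig + amp * np.sin(2 * math.pi * h * f0 * t + phase)
        sig = sig + rng.normal(0.0, profile.noise_sd, size=n)
        out[:, ax] = sig
    return out


def simulate_recording(
    subject_id: str,
    sensor_location: str,
    schedule: list[tuple[str, float]],
    profiles: dict[str, ActivityProfile] | None = None,
    seed: int | np.random.SeedSequence = 0,
    sample_rate_hz: float = 100.0,
    transition_s: float = 2.0,
) -> RawRecording:
    """Simulate one subject/sensor stream following an (activity, duration_s) schedule.

    A ``transition_s``-long segment labeled ``transition`` is inserted at every
    activity boundary; it carries low-amplitude noise only. Deterministic for a
    fixed seed.
    """
    if profiles is None:
        profiles = default_profiles()
    for activity, dur in schedule:
        if activity not in profiles:
            raise ConfigurationError(f"no profile for scheduled activity {activity!r}")
        if dur <= 0:
            raise ConfigurationError(f"non-positive duration for {activity!r}")

    rng = np.random.default_rng(seed)
    gain = _LOCATION_GAIN.get(sensor_location, 1.0)
    fs = sample_rate_hz
    chunks: list[np.ndarray] = []
    labels: list[np.ndarray] = []
    n_trans = int(round(transition_s * fs))
    for idx, (activity, dur) in enumerate(schedule):
        if idx > 0 and n_trans > 0:
            trans = rng.normal(0.0, 0.05, size=(n_trans, 3))
            trans[:, 1] += 1.0  # keep gravity on y through the boundary
            chunks.append(trans)
            labels.append(np.full(n_trans, TRANSITION_LABEL, dtype=object))
        n = int(round(dur * fs))
        chunks.append(_activity_block(profiles[activity], n, fs, rng, gain=gain))
        labels.append(np.full(n, activity, dtype=object))

    acc = np.concatenate(chunks, axis=0)
    lab = np.concatenate(labels)
    t = np.arange(len(lab)) / fs
    return RawRecording(
        subject_id=subject_id,
        sensor_location=sensor_location,
        sample_rate_hz=fs,
        t=t,
        acc=acc,
        labels=lab.astype(str),
    )


def _jitter_profile(
    profile: ActivityProfile, rel_sd: float, rng: np.random.Generator
) -> ActivityProfile:
    """Per-subject multiplicative jitter; gait fundamentals stay in band."""
    if rel_sd <= 0:
        return profile
    amp = profile.harmonic_amps * np.clip(
        1.0 + rng.normal(0, rel_sd, size=profile.harmonic_amps.shape), 0.05, None
    )
    f0 = profile.fundamental_freq_hz
    if f0 > 0:
        f0 = float(np.clip(f0 * (1.0 + rng.normal(0, rel_sd)), *GAIT_BAND_HZ))
    noise = float(profile.noise_sd * np.clip(1.0 + rng.normal(0, rel_sd), 0.2, None))
    return replace(profile, harmonic_amps=amp, fundamental_freq_hz=f0, noise_sd=noise)


def _subject_schedule(spec: CohortSpec) -> list[tuple[str, float]]:
    """Interleaved block schedule realizing the class shares exactly.

    Walking is split into three bouts and each stair class into two, mirroring
    the repeated short trials of a stair/walk circuit, with driving last.
    """
    n_blocks = {"level_walking": 3, "ascending_stairs": 2, "descending_stairs": 2, "driving": 1}
    per_class = {a: spec.duration_s * s for a, s in spec.class_share.items() if s > 0}
    pattern = [
        "level_walking", "ascending_stairs", "descending_stairs",
        "level_walking", "ascending_stairs", "descending_stairs",
        "level_walking", "driving",
    ]
    schedule = []
    for activity in pattern:
        if activity not in per_class:
            continue
        schedule.append((activity, per_class[activity] / n_blocks[activity]))
    return schedule


def make_cohort(spec: CohortSpec, profiles: dict[str, ActivityProfile] | None = None) -> list[RawRecording]:
    """Generate one RawRecording per subject x sensor location.

    Realized per-class shares (over activity-labeled samples) match
    ``spec.class_share`` up to sample rounding; subjects differ by profile
    jitter but the whole cohort is reproducible from ``spec.seed``.
    """
    if spec.n_subjects < 2:
        raise ConfigurationError("n_subjects must be >= 2")
    if profiles is None:
        profiles = default_profiles()
    root = np.random.SeedSequence(spec.seed)
    subject_seeds = root.spawn(spec.n_subjects)
    recordings: list[RawRecording] = []
    for s_idx, s_seed in enumerate(subject_seeds):
        subject_id = f"S{s_idx + 1:02d}"
        jitter_rng = np.random.default_rng(s_seed.spawn(1)[0])
        subj_profiles = {
            name: _jitter_profile(p, spec.subject_variability, jitter_rng)
            for name, p in profiles.items()
        }
        schedule = _subject_schedule(spec)
        sensor_seeds = s_seed.spawn(len(spec.sensor_locations))
        for loc, loc_seed in zip(spec.sensor_locations, sensor_seeds):
            recordings.append(
                simulate_recording(
                    subject_id,
                    loc,
                    schedule,
                    profiles=subj_profiles,
                    seed=loc_seed,
                    sample_rate_hz=spec.sample_rate_hz,
                    transition_s=spec.transition_s,
                )
            )
    return recordings


def write_subject_csv(recordings: list[RawRecording], path) -> None:
    """Write one subject's recordings (one per sensor) in the ingest CSV layout.

    All recordings must share the same subject, time base and labels; columns
    are ``time_s``, ``activity`` (integer code) and ``<loc>_x/y/z`` per sensor.
    """
    import pandas as pd

    from .ingest import DEFAULT_CODE_MAP

    if not recordings:
        raise ConfigurationError("no recordings to write")
    first = recordings[0]
    for rec in recordings[1:]:
        if rec.subject_id != first.subject_id or len(rec) != len(first):
            raise ConfigurationError("recordings must share subject and length")
    label_to_code = {v: k for k, v in DEFAULT_CODE_MAP.items()}
    codes = np.array([label_to_code.get(lab, -1) for lab in first.labels])
    data = {"time_s": first.t, "activity": codes}
    for rec in recordings:
        for j, ax in enumerate("xyz"):
            data[f"{rec.sensor_location}_{ax}"] = rec.acc[:, j]
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.6f")


def write_cohort_csv(recordings: list[RawRecording], directory) -> list:
    """Write a cohort as one CSV per subject; returns the written paths."""
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    by_subject: dict[str, list[RawRecording]] = {}
    for rec in recordings:
        by_subject.setdefault(rec.subject_id, []).append(rec)
    paths = []
    for subject_id, recs in sorted(by_subject.items()):
        path = directory / f"{subject_id}.csv"
        write_subject_csv(recs, path)
        paths.append(path)
    return paths


def make_toy_signal(kind: str, n: int, params: dict | None = None, seed: int = 0) -> np.ndarray:
    """Closed-form 1-D test signals used as feature oracles.

    kinds: ``constant`` (value), ``white_noise`` (sd), ``sine`` (freq, fs,
    amplitude, phase), ``logistic_map`` (r, x0).
    """
    if n < 8:
        raise ConfigurationError("n must be >= 8")
    params = dict(params or {})
    rng = np.random.default_rng(seed)
    if kind == "constant":
        return np.full(n, float(params.get("value", 1.0)))
    if kind == "white_noise":
        return rng.normal(0.0, float(params.get("sd", 1.0)), size=n)
    if kind == "sine":
        fs = float(params.get("fs", 100.0))
        freq = float(params.get("freq", 2.0))
        amp = float(params.get("amplitude", 1.0))
        phase = float(params.get("phase", 0.0))
        t = np.arange(n) / fs
        return amp * np.sin(2 * math.pi * freq * t + phase)
    if kind == "logistic_map":
        r = float(params.get("r", 4.0))
        x = float(params.get("x0", rng.uniform(0.1, 0.9)))
        out = np.empty(n)
        for i in range(n):
            out[i] = x
            x = r * x * (1.0 - x)
        return out
    raise ConfigurationError(f"unknown toy-signal kind {kind!r}")
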