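"""Reading labeled raw accelerometry and segmenting it into single-activity epochs.

A recording is a uniformly sampled tri-axial acceleration stream (units of g)
with a per-sample activity label. Feature extraction operates on fixed-length
windows ("epochs", default 5 s) slid with a configurable hop (default 1 s,
i.e. 4 s overlap). Windows containing more than one label — any transition or
non-study sample, or two different activity labels — are excluded, so every
emitted epoch carries a single unanimous activity label.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: The four physical-activity classes under study, in canonical order.
ACTIVITY_CLASSES = (
    "level_walking",
    "ascending_stairs",
    "descending_stairs",
    "driving",
)

#: Label used for inter-activity boundary segments; never emitted in epochs.
TRANSITION_LABEL = "transition"
#: Label for samples whose activity code is unknown / outside the study.
NON_STUDY_LABEL = "non_study"

SENSOR_LOCATIONS = ("left_wrist", "left_hip", "left_ankle", "right_ankle")

#: Default integer coding used by the CSV writer/reader. Dataset-specific
#: codings (e.g. the PhysioNet layout) can be supplied via ``code_map``.
DEFAULT_CODE_MAP = {
    1: "level_walking",
    2: "descending_stairs",
    3: "ascending_stairs",
    4: "driving",
    0: "transition",
}

_TIME_TOL_S = 1e-6


class FormatError(ValueError):
    """Raised when an input file violates the documented CSV layout."""


@dataclass
class RawRecording:
    """One subject/sensor stream of tri-axial samples with per-sample labels.

    Attributes
    ----------
    subject_id : str
    sensor_location : str
        One of ``SENSOR_LOCATIONS``.
    sample_rate_hz : float
    t : ndarray, shape (n,)
        Seconds since start, uniformly spaced at ``1/sample_rate_hz``.
    acc : ndarray, shape (n, 3)
        Acceleration in g for axes (x, y, z).
    labels : ndarray of str, shape (n,)
    """

    subject_id: str
    sensor_location: str
    sample_rate_hz: float
    t: np.ndarray
    acc: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.acc = np.asarray(self.acc, dtype=float)
        self.labels = np.asarray(self.labels)
        if not (len(self.t) == len(self.acc) == len(self.labels)):
            raise ValueError(
                f"length mismatch: t={len(self.t)} acc={len(self.acc)} "
                f"labels={len(self.labels)}"
            )
        if self.acc.ndim != 2 or self.acc.shape[1] != 3:
            raise ValueError(f"acc must be (n, 3), got {self.acc.shape}")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        if len(self.t) > 1:
            dt = np.diff(self.t)
            expected = 1.0 / self.sample_rate_hz
            bad = np.flatnonzero(np.abs(dt - expected) > _TIME_TOL_S)
            if bad.size:
                raise FormatError(
                    f"non-uniform time base at sample {bad[0] + 1}: "
                    f"dt={dt[bad[0]]:.6g}s, expected {expected:.6g}s"
                )

    @property
    def duration_s(self) -> float:
        return len(self.t) / self.sample_rate_hz

    def __len__(self) -> int:
        return len(self.t)


@dataclass
class Epoch:
    """A fixed-length, single-label window of tri-axial samples."""

    subject_id: str
    sensor_location: str
    label: str
    start_s: float
    samples: np.ndarray  # (window_samples, 3)
    sample_rate_hz: float = 100.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise ValueError(f"samples must be (n, 3), got {self.samples.shape}")


def _sensor_columns(location: str) -> list[str]:
    return [f"{location}_{ax}" for ax in "xyz"]


def read_labeled_accelerometry(
    path,
    sensor_location: str,
    code_map: dict | None = None,
    subject_id: str | None = None,
) -> RawRecording:
    """Read one sensor's stream from a labeled-accelerometry CSV.

    The layout is a header row with columns ``time_s``, ``activity`` (integer
    code) and one ``<loc>_x/<loc>_y/<loc>_z`` triplet per sensor location.
    Activity codes not present in ``code_map`` are mapped to the non-study
    label (and hence excluded from epochs).
    """
    if sensor_location not in SENSOR_LOCATIONS:
        raise ValueError(
            f"unknown sensor_location {sensor_location!r}; "
            f"expected one of {SENSOR_LOCATIONS}"
        )
    code_map = dict(DEFAULT_CODE_MAP if code_map is None else code_map)
    df = pd.read_csv(path, comment="#")
    needed = ["time_s", "activity"] + _sensor_columns(sensor_location)
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")

    t = df["time_s"].to_numpy(dtype=float)
    codes = df["activity"].to_numpy()
    labels = np.array([code_map.get(int(c), NON_STUDY_LABEL) for c in codes])
    acc = df[_sensor_columns(sensor_location)].to_numpy(dtype=float)
    if len(t) > 1:
        dt = np.diff(t)
        med = np.median(dt)
        if med <= 0:
            bad = int(np.flatnonzero(dt <= 0)[0]) + 1
            raise FormatError(
                f"{path}: non-uniform time base (non-increasing at line {bad + 1})"
            )
        rate = 1.0 / med
    else:
        rate = 100.0
    if subject_id is None:
        subject_id = str(path)
    return RawRecording(
        subject_id=subject_id,
        sensor_location=sensor_location,
        sample_rate_hz=float(round(rate, 6)),
        t=t,
        acc=acc,
        labels=labels,
    )


def epoch_stream(
    recording: RawRecording,
    window_s: float = 5.0,
    hop_s: float = 1.0,
) -> list[Epoch]:
    """Slide a window over a recording and keep single-label epochs.

    Epochs whose samples carry more than one label — any transition or
    non-study sample, or two different activity labels — are dropped; a
    partial tail window is dropped as well. A recording shorter than one
    window yields an empty list.
    """
    fs = recording.sample_rate_hz
    win = window_s * fs
    if abs(win - round(win)) > 1e-9:
        raise ValueError(
            f"window_s × sample_rate_hz must be an integer sample count, "
            f"got {win}"
        )
    win = int(round(win))
    if hop_s > window_s:
        raise ValueError("hop_s must not exceed window_s")
    hop = int(round(hop_s * fs))
    if hop < 1:
        raise ValueError("hop_s must be at least one sample")

    n = len(recording)
    epochs: list[Epoch] = []
    valid = set(ACTIVITY_CLASSES)
    labels = recording.labels
    for start in range(0, n - win + 1, hop):
        window_labels = labels[start : start + win]
        first = window_labels[0]
        if first not in valid or not (window_labels == first).all():
            continue
        epochs.append(
            Epoch(
                subject_id=recording.subject_id,
                sensor_location=recording.sensor_location,
                label=str(first),
                start_s=recording.t[start],
                samples=recording.acc[start : start + win],
                sample_rate_hz=fs,
            )
        )
    return epochs
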