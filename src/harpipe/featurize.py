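"""Assembly of the 75-column labeled feature matrix.

Per axis, 25 features in a fixed documented order (temporal 1-8, spectral
9-20, nonlinear 21-25); the three axis blocks (x, y, z) are concatenated to a
75-feature vector per epoch. Matrices carry per-row metadata (subject, label,
sensor location, epoch start) and serialize to CSV with a small commented
metadata header.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .ingest import Epoch
from .nonlinear import nonlinear_features
from .spectral import compute_psd, spectral_features
from .temporal import temporal_features

logger = logging.getLogger(__name__)

#: The 25 per-axis feature names, in the fixed export order.
FEATURE_NAMES_PER_AXIS = (
    "rms",
    "sd",
    "skewness",
    "kurtosis",
    "zc",
    "ptp",
    "hjorth_mobility",
    "hjorth_complexity",
    "pp1",
    "pp2",
    "pp3",
    "df1",
    "df2",
    "df3",
    "te",
    "spec_en",
    "pp_band",
    "df_band",
    "te_band",
    "spec_en_band",
    "hurst",
    "ami",
    "fnn",
    "lyapunov",
    "sampen",
)

AXES = ("x", "y", "z")

#: The 75 feature column names: 25 per axis, axis blocks in x, y, z order.
FEATURE_COLUMNS = tuple(
    f"{name}_{axis}" for axis in AXES for name in FEATURE_NAMES_PER_AXIS
)

META_COLUMNS = ("subject_id", "sensor_location", "label", "start_s")


def axis_features(
    x: np.ndarray,
    sample_rate_hz: float,
    window_s: float = 5.0,
) -> dict[str, float]:
    """The 25 features for one axis of one epoch, keyed by per-axis name."""
    t = temporal_features(x)
    psd = compute_psd(x, sample_rate_hz, window_s=window_s)
    s = spectral_features(psd)
    nl = nonlinear_features(x)
    return {
        "rms": t.rms,
        "sd": t.sd,
        "skewness": t.skewness,
        "kurtosis": t.kurtosis,
        "zc": t.zero_crossings,
        "ptp": t.ptp,
        "hjorth_mobility": t.hjorth_mobility,
        "hjorth_complexity": t.hjorth_complexity,
        "pp1": s.pp1,
        "pp2": s.pp2,
        "pp3": s.pp3,
        "df1": s.df1,
        "df2": s.df2,
        "df3": s.df3,
        "te": s.total_energy,
        "spec_en": s.spectral_entropy,
        "pp_band": s.pp_band,
        "df_band": s.df_band,
        "te_band": s.total_energy_band,
        "spec_en_band": s.spectral_entropy_band,
        "hurst": nl.hurst,
        "ami": nl.ami,
        "fnn": nl.fnn,
        "lyapunov": nl.lyapunov,
        "sampen": nl.sampen,
    }


def feature_vector(epoch: Epoch, window_s: float = 5.0) -> np.ndarray:
    """The ordered 75-value feature vector for one epoch."""
    values = []
    for j, _axis in enumerate(AXES):
        feats = axis_features(epoch.samples[:, j], epoch.sample_rate_hz, window_s)
        values.extend(feats[name] for name in FEATURE_NAMES_PER_AXIS)
    return np.asarray(values, dtype=float)


@dataclass
class LabeledFeatureMatrix:
    """Epochs x 75 features with subject/label/sensor metadata.

    Backed by a DataFrame whose columns are ``META_COLUMNS`` followed by
    ``FEATURE_COLUMNS``.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in (*META_COLUMNS, *FEATURE_COLUMNS) if c not in self.df.columns]
        if missing:
            raise ValueError(f"feature matrix missing columns: {missing[:5]}...")
        self.df = self.df[[*META_COLUMNS, *FEATURE_COLUMNS]].reset_index(drop=True)
        all_nan = self.df[list(FEATURE_COLUMNS)].isna().all(axis=1)
        if all_nan.any():
            raise ValueError(f"{int(all_nan.sum())} rows have all-missing features")

    @property
    def X(self) -> np.ndarray:
        return self.df[list(FEATURE_COLUMNS)].to_numpy(dtype=float)

    @property
    def labels(self) -> np.ndarray:
        return self.df["label"].to_numpy()

    @property
    def subjects(self) -> np.ndarray:
        return self.df["subject_id"].to_numpy()

    @property
    def feature_names(self) -> tuple:
        return FEATURE_COLUMNS

    def __len__(self) -> int:
        return len(self.df)

    def class_counts(self) -> dict[str, int]:
        return self.df["label"].value_counts().to_dict()

    def select_rows(self, mask) -> "LabeledFeatureMatrix":
        return LabeledFeatureMatrix(self.df.loc[mask].reset_index(drop=True))

    def subset_subjects(self, subject_ids) -> "LabeledFeatureMatrix":
        wanted = set(subject_ids)
        return self.select_rows(self.df["subject_id"].isin(wanted).to_numpy())

    def to_csv(self, path) -> None:
        path = Path(path)
        with open(path, "w") as fh:
            fh.write("# harpipe labeled feature matrix\n")
            fh.write(f"# rows: {len(self.df)}\n")
            fh.write(f"# features: {len(FEATURE_COLUMNS)}\n")
            self.df.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path) -> "LabeledFeatureMatrix":
        return cls(pd.read_csv(path, comment="#"))


def extract_features(
    epochs: list[Epoch], window_s: float = 5.0
) -> LabeledFeatureMatrix:
    """Compute the 75-feature vector for every epoch and assemble the matrix."""
    if not epochs:
        raise ValueError("no epochs to featurize")
    rows = []
    for ep in epochs:
        row = {
            "subject_id": ep.subject_id,
            "sensor_location": ep.sensor_location,
            "label": ep.label,
            "start_s": ep.start_s,
        }
        row.update(zip(FEATURE_COLUMNS, feature_vector(ep, window_s=window_s)))
        rows.append(row)
    return LabeledFeatureMatrix(pd.DataFrame(rows))
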