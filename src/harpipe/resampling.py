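"""Class balancing by random undersampling or SMOTE oversampling.

Both operate on a labeled feature matrix and are meant to be applied to the
training fold only, strictly after the subject-wise split — the evaluation
harness enforces that. Undersampling deletes uniformly chosen majority-class
rows until every class matches the smallest class, leaving minority rows
untouched; because the deletion is random it is repeated (default 10 times)
and downstream metrics averaged. SMOTE raises every non-majority class to the
majority count by interpolating each synthetic row between a minority row and
one of its k nearest same-class neighbors, with the neighbor search run in
z-scored feature space so Euclidean distance is meaningful across feature
scales.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from .featurize import FEATURE_COLUMNS, LabeledFeatureMatrix

logger = logging.getLogger(__name__)


class ResamplingError(ValueError):
    """Raised when a class cannot be resampled (empty or singleton class)."""


def undersampled_size(counts) -> int:
    """Total rows after undersampling: n_classes x min class count."""
    counts = list(counts)
    return len(counts) * min(counts)


def oversampled_size(counts) -> int:
    """Total rows after oversampling: n_classes x max class count."""
    counts = list(counts)
    return len(counts) * max(counts)


def random_undersample(
    matrix: LabeledFeatureMatrix, seed: int | np.random.SeedSequence = 0
) -> LabeledFeatureMatrix:
    """Delete random majority-class rows until all classes match the minimum.

    Deleted rows are chosen uniformly without replacement; rows of the
    smallest class are untouched. Deterministic per seed.
    """
    counts = matrix.class_counts()
    if len(counts) < 2:
        raise ResamplingError("need at least 2 classes to balance")
    for cls, cnt in counts.items():
        if cnt == 0:
            raise ResamplingError(f"class {cls!r} has zero rows")
    n_min = min(counts.values())
    rng = np.random.default_rng(seed)
    labels = matrix.labels
    keep = np.zeros(len(matrix), dtype=bool)
    for cls in sorted(counts):
        idx = np.flatnonzero(labels == cls)
        if len(idx) > n_min:
            idx = rng.choice(idx, size=n_min, replace=False)
        keep[idx] = True
    before = {k: counts[k] for k in sorted(counts)}
    logger.debug("undersample: %s -> %d per class", before, n_min)
    return matrix.select_rows(keep)


def repeat_undersample(
    matrix: LabeledFeatureMatrix,
    n_repeats: int = 10,
    seed: int | np.random.SeedSequence = 0,
) -> list[LabeledFeatureMatrix]:
    """``n_repeats`` independent undersampling draws with derived seeds."""
    root = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    return [random_undersample(matrix, s) for s in root.spawn(n_repeats)]


def smote_oversample(
    matrix: LabeledFeatureMatrix,
    k: int = 5,
    seed: int | np.random.SeedSequence = 0,
    scaler: tuple[np.ndarray, np.ndarray] | None = None,
) -> LabeledFeatureMatrix:
    """Raise every class to the majority count with SMOTE interpolation.

    Each synthetic row is ``x + u * (x_nn - x)`` with ``u ~ Uniform(0, 1)``
    and ``x_nn`` one of the ``k`` nearest same-class neighbors of ``x``
    (Euclidean in z-scored feature space). All original rows are retained.
    ``scaler`` is an optional (means, sds) pair — in the pipeline, the
    training-fold scaler; by default it is fit on the given matrix. ``k`` is
    clipped to class size - 1 when a class is smaller than k+1 (logged).
    """
    counts = matrix.class_counts()
    if len(counts) < 2:
        raise ResamplingError("need at least 2 classes to balance")
    n_max = max(counts.values())
    labels = matrix.labels
    X = matrix.X
    if scaler is None:
        means = np.nanmean(X, axis=0)
        sds = np.nanstd(X, axis=0)
    else:
        means, sds = scaler
    sds = np.where(sds > 0, sds, 1.0)
    # median-impute NaNs (flagged nonlinear values) for the neighbor search
    med = np.nanmedian(X, axis=0)
    X_imp = np.where(np.isnan(X), med, X)
    Z = (X_imp - means) / sds

    rng = np.random.default_rng(seed)
    synth_frames = [matrix.df]
    for cls in sorted(counts):
        n_need = n_max - counts[cls]
        if n_need == 0:
            continue
        if counts[cls] < 2:
            raise ResamplingError(
                f"class {cls!r} has a single row; SMOTE cannot interpolate"
            )
        idx = np.flatnonzero(labels == cls)
        k_cls = min(k, len(idx) - 1)
        if k_cls < k:
            logger.debug("smote: class %s has %d rows, clipping k to %d",
                         cls, len(idx), k_cls)
        nn = NearestNeighbors(n_neighbors=k_cls + 1).fit(Z[idx])
        neighbor_of = nn.kneighbors(Z[idx], return_distance=False)[:, 1:]
        base = rng.integers(0, len(idx), size=n_need)
        pick = rng.integers(0, k_cls, size=n_need)
        u = rng.uniform(0.0, 1.0, size=n_need)
        xi = X_imp[idx[base]]
        xn = X_imp[idx[neighbor_of[base, pick]]]
        new_X = xi + u[:, None] * (xn - xi)
        frame = pd.DataFrame(new_X, columns=list(FEATURE_COLUMNS))
        parent = matrix.df.iloc[idx[base]].reset_index(drop=True)
        frame.insert(0, "subject_id", parent["subject_id"].to_numpy())
        frame.insert(1, "sensor_location", parent["sensor_location"].to_numpy())
        frame.insert(2, "label", cls)
        frame.insert(3, "start_s", np.nan)
        synth_frames.append(frame)
    out = pd.concat(synth_frames, ignore_index=True)
    logger.debug("smote: %s -> %d per class", counts, n_max)
    return LabeledFeatureMatrix(out)
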