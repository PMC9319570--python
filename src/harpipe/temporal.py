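"""Temporal features of a single-axis epoch.

Eight per-axis descriptors of amplitude and distribution shape: peak-to-peak,
RMS, standard deviation, skewness, kurtosis (non-excess; Gaussian -> 3), the
two Hjorth parameters (mobility = sd of the first difference over sd of the
signal, a mean-frequency proxy; complexity = mobility of the first difference
over mobility of the signal), and the zero-crossing count (a fundamental-
frequency proxy). Moments use population (1/n) normalization throughout.

Zero crossings are counted on the mean-removed signal by default: with a
constant gravity offset on an axis the raw signal may never cross zero, which
would make the count uninformative as a frequency estimate. ``detrend=False``
restores the literal raw-signal count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields

import numpy as np

logger = logging.getLogger(__name__)

TEMPORAL_FEATURE_NAMES = (
    "rms",
    "sd",
    "skewness",
    "kurtosis",
    "zero_crossings",
    "ptp",
    "hjorth_mobility",
    "hjorth_complexity",
)


@dataclass
class TemporalFeatures:
    ptp: float
    rms: float
    sd: float
    skewness: float
    kurtosis: float
    hjorth_mobility: float
    hjorth_complexity: float
    zero_crossings: float

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def zero_crossings(x: np.ndarray, detrend: bool = True) -> float:
    """(1/2) * sum |sgn(x_i) - sgn(x_{i-1})|, with sgn(0) = 0.

    A sample sitting exactly on zero contributes two half-steps, so the count
    stays consistent with one crossing.
    """
    x = np.asarray(x, dtype=float)
    if detrend:
        x = x - x.mean()
    s = np.sign(x)
    return 0.5 * float(np.abs(np.diff(s)).sum())


def _mobility(x: np.ndarray) -> float:
    sd = x.std()
    if sd == 0:
        return 0.0
    dx = np.diff(x)
    return float(dx.std() / sd)


def temporal_features(x: np.ndarray, zc_detrend: bool = True) -> TemporalFeatures:
    """Compute the eight temporal features for one axis of an epoch.

    A constant input (sd = 0) returns 0 for the shape and Hjorth features
    rather than raising; the degenerate case is logged.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError(f"need at least 3 samples, got {n}")
    mu = x.mean()
    sd = x.std()  # population (1/n)
    ptp = float(x.max() - x.min())
    rms = float(np.sqrt(np.mean(x**2)))
    if sd == 0:
        logger.debug("temporal_features: constant input, shape features set to 0")
        skew = kurt = mob = comp = 0.0
    else:
        c = x - mu
        skew = float(np.mean(c**3) / sd**3)
        kurt = float(np.mean(c**4) / sd**4)
        mob = _mobility(x)
        dx = np.diff(x)
        mob_dx = _mobility(dx)
        comp = float(mob_dx / mob) if mob > 0 else 0.0
    return TemporalFeatures(
        ptp=ptp,
        rms=rms,
        sd=float(sd),
        skewness=skew,
        kurtosis=kurt,
        hjorth_mobility=mob,
        hjorth_complexity=comp,
        zero_crossings=zero_crossings(x, detrend=zc_detrend),
    )
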