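"""Spectral features of a single-axis epoch from a Hamming-windowed periodogram.

Each 5-s epoch is one analysis frame: the signal is mean-removed, multiplied by
a Hamming window and Fourier transformed, giving a power spectral density with
bin spacing 1/window_s (0.2 Hz at the 5-s default). The DC bin is excluded and
bins up to 15 Hz retained, which leaves 75 candidate bins at the defaults.
The 1-s hop between successive epochs realizes the sliding of a short-time
Fourier transform, so no within-epoch averaging is performed.

Twelve features per axis: total energy, spectral entropy, the three largest
bin powers (descending) and their frequencies (re-sorted ascending) over the
full 0-15 Hz band, and peak power / dominant frequency / total energy /
spectral entropy restricted to the sub-2.5 Hz band, where resting behavior
(< 0.5 Hz) and gait (1.5-2.5 Hz) live.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields

import numpy as np
from scipy.signal import get_window

logger = logging.getLogger(__name__)

SPECTRAL_FEATURE_NAMES = (
    "pp1",
    "pp2",
    "pp3",
    "df1",
    "df2",
    "df3",
    "total_energy",
    "spectral_entropy",
    "pp_band",
    "df_band",
    "total_energy_band",
    "spectral_entropy_band",
)


@dataclass
class EpochPSD:
    """Single-frame PSD restricted to (0, band_max_hz]; DC excluded."""

    freqs_hz: np.ndarray
    psd: np.ndarray

    def __post_init__(self) -> None:
        self.freqs_hz = np.asarray(self.freqs_hz, dtype=float)
        self.psd = np.asarray(self.psd, dtype=float)
        if self.freqs_hz.shape != self.psd.shape:
            raise ValueError("freqs_hz and psd must align")
        if (self.psd < 0).any():
            raise ValueError("psd must be non-negative")


@dataclass
class SpectralFeatures:
    pp1: float
    pp2: float
    pp3: float
    df1: float
    df2: float
    df3: float
    total_energy: float
    spectral_entropy: float
    pp_band: float
    df_band: float
    total_energy_band: float
    spectral_entropy_band: float

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def compute_psd(
    x: np.ndarray,
    sample_rate_hz: float,
    window_s: float = 5.0,
    band_max_hz: float = 15.0,
    window: str = "hamming",
) -> EpochPSD:
    """Hamming-windowed periodogram of a mean-removed epoch.

    The signal must be exactly one analysis window long so the bin spacing is
    1/window_s (0.2 Hz for the 5-s default).
    """
    x = np.asarray(x, dtype=float)
    expected = int(round(window_s * sample_rate_hz))
    if len(x) != expected:
        raise ValueError(
            f"epoch length {len(x)} does not match the {window_s}-s analysis "
            f"window ({expected} samples at {sample_rate_hz} Hz)"
        )
    w = get_window(window, len(x))
    spec = np.fft.rfft((x - x.mean()) * w)
    psd = (np.abs(spec) ** 2) / len(x)
    freqs = np.fft.rfftfreq(len(x), d=1.0 / sample_rate_hz)
    keep = (freqs > 0) & (freqs <= band_max_hz + 1e-9)
    return EpochPSD(freqs_hz=freqs[keep], psd=psd[keep])


def _entropy(psd: np.ndarray, normalized: bool) -> float:
    """Shannon entropy (bits) of the PSD; normalized = treat it as a pmf."""
    total = psd.sum()
    if total <= 0:
        return 0.0
    p = psd / total if normalized else psd
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def spectral_features(
    epoch_psd: EpochPSD,
    band_hz: float = 2.5,
    normalized_entropy: bool = True,
) -> SpectralFeatures:
    """Twelve spectral features from an epoch PSD.

    The three peak powers are the three largest bin values (descending, ties
    broken toward lower frequency); their frequencies are reported re-sorted
    ascending, so PP_i and DF_i are deliberately decoupled. Band features use
    bins strictly below ``band_hz``. ``normalized_entropy=False`` evaluates
    the raw -sum(P log2 P) form on unnormalized powers instead of the
    probability-normalized (scale-invariant) default.
    """
    f, p = epoch_psd.freqs_hz, epoch_psd.psd
    if p.sum() == 0:
        logger.debug("spectral_features: all-zero psd, degenerate output")
        return SpectralFeatures(*([0.0] * 12))

    order = np.lexsort((f, -p))  # by descending power, then ascending frequency
    top = order[:3]
    pps = p[top]
    dfs = np.sort(f[top])

    in_band = f < band_hz
    fb, pb = f[in_band], p[in_band]
    if pb.sum() > 0:
        b_idx = np.lexsort((fb, -pb))[0]
        pp_band, df_band = float(pb[b_idx]), float(fb[b_idx])
    else:
        pp_band = df_band = 0.0

    return SpectralFeatures(
        pp1=float(pps[0]),
        pp2=float(pps[1]) if len(pps) > 1 else 0.0,
        pp3=float(pps[2]) if len(pps) > 2 else 0.0,
        df1=float(dfs[0]),
        df2=float(dfs[1]) if len(dfs) > 1 else 0.0,
        df3=float(dfs[2]) if len(dfs) > 2 else 0.0,
        total_energy=float(p.sum()),
        spectral_entropy=_entropy(p, normalized_entropy),
        pp_band=pp_band,
        df_band=df_band,
        total_energy_band=float(pb.sum()),
        spectral_entropy_band=_entropy(pb, normalized_entropy),
    )
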