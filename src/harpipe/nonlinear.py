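"""Nonlinear time-series features: embedding parameters, Lyapunov exponent,
sample entropy and Hurst exponent.

The five per-axis features quantify the inherent nonlinearity of an epoch:

* the phase-space delay tau, the first local minimum of the auto mutual
  information (AMI) curve;
* the embedding dimension d, the first dimension at which the false-nearest-
  neighbor (FNN) fraction drops to (approximately) zero and stays there;
* the largest Lyapunov exponent, a nearest-neighbor divergence-rate estimate
  (positive for chaotic, about zero for periodic, negative for contracting
  signals);
* sample entropy, the negative log conditional probability that templates
  matching at length m (Chebyshev distance, self-matches excluded) also match
  at m+1;
* the Hurst exponent from rescaled-range analysis (about 0.5 for uncorrelated
  series, 0.5-1 for persistent ones).

Degenerate inputs (constant signals, no valid neighbor pairs, zero match
counts) yield NaN or zero with a logged note rather than an exception; the
feature-matrix assembly imputes such values with the training-fold median.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

NONLINEAR_FEATURE_NAMES = ("hurst", "ami", "fnn", "lyapunov", "sampen")

#: Kennel-style false-neighbor distance-ratio tolerance.
DEFAULT_RTOL = 15.0
#: "dropped to 0" read as an FNN fraction of at most 1%.
DEFAULT_FNN_ZERO_TOL = 0.01
#: Equal-width histogram bins per axis for the AMI estimate.
DEFAULT_AMI_BINS = 16
#: Candidate-lag range for the AMI curve (1 s at 100 Hz).
DEFAULT_MAX_LAG = 100


@dataclass
class EmbeddingParams:
    """Delay-embedding parameters plus the curves they were read off."""

    tau: int
    dim: int
    ami_curve: np.ndarray
    fnn_fractions: np.ndarray
    tau_fallback: bool = False
    dim_fallback: bool = False

    @property
    def ami_at_tau(self) -> float:
        return float(self.ami_curve[self.tau])


@dataclass
class NonlinearFeatures:
    tau: int
    dim: int
    ami: float  # AMI curve value at tau
    fnn: float  # embedding dimension, exported as the FNN score
    lyapunov: float
    sampen: float
    hurst: float

    def as_dict(self) -> dict[str, float]:
        return {
            "hurst": self.hurst,
            "ami": self.ami,
            "fnn": self.fnn,
            "lyapunov": self.lyapunov,
            "sampen": self.sampen,
        }


# ---------------------------------------------------------------------------
# delay via auto mutual information


def auto_mutual_information(
    x: np.ndarray, max_lag: int = DEFAULT_MAX_LAG, n_bins: int = DEFAULT_AMI_BINS
) -> np.ndarray:
    """AMI(tau) for tau = 0..max_lag from an equal-width 2-D histogram (bits).

    AMI(0) is the marginal (self-information) entropy estimate. A constant
    signal returns an all-zero curve.
    """
    x = np.asarray(x, dtype=float)
    if len(x) <= max_lag + 1:
        raise ValueError(f"need more than max_lag+1={max_lag + 1} samples, got {len(x)}")
    lo, hi = x.min(), x.max()
    if hi == lo:
        logger.debug("auto_mutual_information: constant signal, zero curve")
        return np.zeros(max_lag + 1)
    idx = np.clip(((x - lo) / (hi - lo) * n_bins).astype(int), 0, n_bins - 1)
    out = np.empty(max_lag + 1)
    for lag in range(max_lag + 1):
        a = idx[: len(idx) - lag]
        b = idx[lag:]
        joint = np.bincount(a * n_bins + b, minlength=n_bins * n_bins).astype(float)
        joint = joint.reshape(n_bins, n_bins)
        n = joint.sum()
        pxy = joint / n
        px = pxy.sum(axis=1, keepdims=True)
        py = pxy.sum(axis=0, keepdims=True)
        mask = pxy > 0
        out[lag] = float(
            (pxy[mask] * np.log2(pxy[mask] / (px @ py)[mask])).sum()
        )
    return out


def optimal_delay(ami_curve: np.ndarray) -> tuple[int, bool]:
    """First local minimum of the AMI curve: smallest tau >= 1 with
    AMI(tau) < AMI(tau-1) and AMI(tau) <= AMI(tau+1).

    Returns ``(tau, fallback)``; when no local minimum exists within range the
    curve argmin (over tau >= 1) is returned with ``fallback=True``.
    """
    c = np.asarray(ami_curve, dtype=float)
    if len(c) < 3:
        raise ValueError("ami curve must have at least 3 points")
    for tau in range(1, len(c) - 1):
        if c[tau] < c[tau - 1] and c[tau] <= c[tau + 1]:
            return tau, False
    tau = int(np.argmin(c[1:])) + 1
    logger.debug("optimal_delay: no local minimum, falling back to argmin=%d", tau)
    return tau, True


# ---------------------------------------------------------------------------
# embedding dimension via false nearest neighbors


def _embed(x: np.ndarray, tau: int, dim: int, n_vectors: int | None = None) -> np.ndarray:
    """Delay-embedding matrix with rows (x_i, x_{i+tau}, ..., x_{i+(dim-1)tau})."""
    if n_vectors is None:
        n_vectors = len(x) - (dim - 1) * tau
    if n_vectors <= 0:
        raise ValueError("signal too short to embed")
    return np.stack([x[k * tau : k * tau + n_vectors] for k in range(dim)], axis=1)


def false_nearest_neighbors(
    x: np.ndarray, tau: int, dim: int, rtol: float = DEFAULT_RTOL
) -> float:
    """Fraction of nearest neighbors in ``dim`` dimensions that are false.

    Each point's nearest (Euclidean) neighbor is found among the delay
    vectors; the neighbor is false when the extra coordinate gained at
    dimension dim+1 moves the pair apart by more than ``rtol`` times their
    dim-dimensional distance.
    """
    x = np.asarray(x, dtype=float)
    if tau < 1 or dim < 1:
        raise ValueError("tau and dim must be >= 1")
    n_vec = len(x) - dim * tau  # extension x[i + dim*tau] must exist
    if n_vec < 10:
        raise ValueError(
            f"too few points to embed: need len(x) - dim*tau >= 10, have {n_vec}"
        )
    scale = float(x.std())
    if scale == 0:
        logger.debug("false_nearest_neighbors: degenerate embedding, fraction 0")
        return 0.0
    emb = _embed(x, tau, dim, n_vectors=n_vec)
    tree = cKDTree(emb)
    dist, nn = tree.query(emb, k=2)
    dist, nn = dist[:, 1], nn[:, 1]
    ext = np.abs(x[np.arange(n_vec) + dim * tau] - x[nn + dim * tau])
    # the absolute floor keeps exactly-recurrent points (distance at rounding
    # level, as on a noise-free periodic signal) from being flagged false
    false = (ext > rtol * dist) & (ext > 1e-8 * scale)
    return float(false.mean())


def dimension_from_fractions(
    fractions: np.ndarray, zero_tol: float = DEFAULT_FNN_ZERO_TOL
) -> tuple[int, bool]:
    """Smallest dimension whose FNN fraction is <= zero_tol and does not
    drop by more than zero_tol at the next dimension.

    ``fractions[k]`` is the FNN fraction at dimension k+1. Returns
    ``(dim, fallback)``; fallback means no dimension qualified and the last
    one was returned.
    """
    f = np.asarray(fractions, dtype=float)
    if len(f) < 2:
        raise ValueError("need fractions for at least two dimensions")
    for k in range(len(f) - 1):
        if f[k] <= zero_tol and f[k + 1] >= f[k] - zero_tol:
            return k + 1, False
    return len(f), True


def embedding_dimension(
    x: np.ndarray,
    tau: int,
    max_dim: int = 10,
    zero_tol: float = DEFAULT_FNN_ZERO_TOL,
    rtol: float = DEFAULT_RTOL,
) -> tuple[int, np.ndarray, bool]:
    """Embedding dimension from the FNN criterion.

    Returns ``(dim, fractions, fallback)`` where ``fractions[k]`` is the FNN
    fraction at dimension k+1 (NaN where the signal is too short to embed).
    """
    fractions = np.full(max_dim, np.nan)
    for d in range(1, max_dim + 1):
        try:
            fractions[d - 1] = false_nearest_neighbors(x, tau, d, rtol=rtol)
        except ValueError:
            break
        # stop scanning once the vanish-and-stay criterion is decidable
        if (
            d >= 2
            and fractions[d - 2] <= zero_tol
            and fractions[d - 1] >= fractions[d - 2] - zero_tol
        ):
            return d - 1, fractions, False
    valid = fractions[~np.isnan(fractions)]
    if len(valid) < 2:
        logger.debug("embedding_dimension: too short to scan dimensions, dim=1")
        return 1, fractions, True
    dim, fallback = dimension_from_fractions(valid, zero_tol=zero_tol)
    if fallback:
        logger.debug("embedding_dimension: FNN never vanished, dim=%d (fallback)", dim)
    return dim, fractions, fallback


def estimate_embedding(
    x: np.ndarray,
    max_lag: int = DEFAULT_MAX_LAG,
    max_dim: int = 10,
    n_bins: int = DEFAULT_AMI_BINS,
) -> EmbeddingParams:
    """AMI delay and FNN dimension in one call."""
    x = np.asarray(x, dtype=float)
    max_lag = min(max_lag, len(x) - 2)
    ami = auto_mutual_information(x, max_lag=max_lag, n_bins=n_bins)
    tau, tau_fb = optimal_delay(ami)
    dim, fractions, dim_fb = embedding_dimension(x, tau, max_dim=max_dim)
    return EmbeddingParams(
        tau=tau,
        dim=dim,
        ami_curve=ami,
        fnn_fractions=fractions,
        tau_fallback=tau_fb,
        dim_fallback=dim_fb,
    )


# ---------------------------------------------------------------------------
# largest Lyapunov exponent


def _mean_period_samples(x: np.ndarray) -> int:
    """Mean period via the dominant frequency of the mean-removed signal."""
    x = x - x.mean()
    spec = np.abs(np.fft.rfft(x)) ** 2
    spec[0] = 0.0
    k = int(np.argmax(spec))
    if k == 0 or spec[k] == 0:
        return 1
    return max(1, int(round(len(x) / k)))


def largest_lyapunov(
    x: np.ndarray,
    tau: int,
    dim: int,
    horizon: int | None = None,
    min_separation: int | None = None,
    sample_rate_hz: float | None = None,
) -> float:
    """Largest Lyapunov exponent via nearest-neighbor divergence tracking.

    Each embedded point is paired with its nearest neighbor at least one mean
    period away in time; the mean log separation of the pairs is tracked over
    ``horizon`` steps and the exponent is the least-squares slope of that
    curve. Returned per sample, or per second when ``sample_rate_hz`` is
    given. NaN (logged) when no valid pairs exist.
    """
    x = np.asarray(x, dtype=float)
    m = len(x) - (dim - 1) * tau
    if m < 20:
        raise ValueError("signal too short for Lyapunov estimation")
    emb = _embed(x, tau, dim)
    period = _mean_period_samples(x)
    if min_separation is None:
        min_separation = period
    if horizon is None:
        # long enough to see divergence, short of trajectory saturation
        horizon = int(np.clip(period, 5, 30))
    horizon = min(horizon, m - 2)

    from scipy.spatial.distance import cdist

    d2 = cdist(emb, emb, metric="sqeuclidean")
    i_idx = np.arange(m)
    too_close = np.abs(i_idx[:, None] - i_idx[None, :]) <= min_separation
    d2[too_close] = np.inf
    # both trajectories must be trackable over the full horizon
    usable = m - horizon
    if usable < 2:
        logger.debug("largest_lyapunov: horizon exhausts the trajectory")
        return float("nan")
    d2 = d2[:usable, :usable]
    nn = np.argmin(d2, axis=1)
    base = np.sqrt(d2[np.arange(usable), nn])
    ok = np.isfinite(base) & (base > 0)
    if not ok.any():
        logger.debug("largest_lyapunov: no valid neighbor pairs")
        return float("nan")
    pairs_i = np.flatnonzero(ok)
    pairs_j = nn[ok]

    steps = np.arange(horizon + 1)
    diff = emb[pairs_i[:, None] + steps] - emb[pairs_j[:, None] + steps]
    sep = np.linalg.norm(diff, axis=2)  # (n_pairs, horizon+1)
    with np.errstate(divide="ignore"):
        log_sep = np.where(sep > 0, np.log(np.maximum(sep, 1e-300)), np.nan)
    with np.errstate(invalid="ignore"):
        mean_log = np.nanmean(log_sep, axis=0)
    t = np.arange(horizon + 1, dtype=float)
    valid = np.isfinite(mean_log)
    if valid.sum() < 2:
        return float("nan")
    slope = np.polyfit(t[valid], mean_log[valid], 1)[0]
    if sample_rate_hz is not None:
        slope *= sample_rate_hz
    return float(slope)


# ---------------------------------------------------------------------------
# sample entropy


def sample_entropy(
    x: np.ndarray, m: int = 2, r: float | None = None, tau: int = 1
) -> float:
    """SampEn = -log(A/B): B counts template pairs (i < j) within Chebyshev
    distance ``r`` at length m, A the same at length m+1; self-matches are
    excluded. ``r`` defaults to 0.2 x the signal SD.

    Returns NaN (logged) when A or B is zero.
    """
    x = np.asarray(x, dtype=float)
    if r is None:
        r = 0.2 * float(x.std())
    if r <= 0:
        raise ValueError("tolerance r must be > 0 (constant signals have sd 0)")
    n_templates = len(x) - m * tau  # room for the (m+1)-length extension
    if n_templates < 10:
        raise ValueError(f"need len(x) >= m*tau + 10, got len(x)={len(x)}")

    diff = np.abs(x[:, None] - x[None, :])
    cheb_m = np.zeros((n_templates, n_templates))
    for k in range(m):
        cheb_m = np.maximum(cheb_m, diff[k * tau : k * tau + n_templates,
                                         k * tau : k * tau + n_templates])
    cheb_m1 = np.maximum(cheb_m, diff[m * tau : m * tau + n_templates,
                                      m * tau : m * tau + n_templates])
    iu = np.triu_indices(n_templates, k=1)
    b = int((cheb_m[iu] < r).sum())
    a = int((cheb_m1[iu] < r).sum())
    if a == 0 or b == 0:
        logger.debug("sample_entropy: zero match count (A=%d, B=%d)", a, b)
        return float("nan")
    return float(-math.log(a / b))


# ---------------------------------------------------------------------------
# Hurst exponent


def rescaled_range_table(
    x: np.ndarray, min_window: int = 16
) -> tuple[np.ndarray, np.ndarray]:
    """(window sizes, mean R/S) over a dyadic window grid.

    For each window size the signal is cut into non-overlapping segments; per
    segment R is the peak-to-peak range of the cumulative mean-removed sums
    and S the segment SD; segments with S = 0 are skipped.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 4 * min_window:
        raise ValueError(f"need at least {4 * min_window} samples, got {n}")
    sizes = []
    rs_values = []
    w = min_window
    while w <= n // 2:
        rs_list = []
        for start in range(0, n - w + 1, w):
            seg = x[start : start + w]
            s = seg.std()
            if s == 0:
                continue
            z = np.cumsum(seg - seg.mean())
            rs_list.append((z.max() - z.min()) / s)
        if rs_list:
            sizes.append(w)
            rs_values.append(float(np.mean(rs_list)))
        w *= 2
    return np.asarray(sizes, dtype=float), np.asarray(rs_values, dtype=float)


def hurst_exponent(x: np.ndarray, min_window: int = 16) -> float:
    """Rescaled-range Hurst exponent: slope of log(R/S) against log(window).

    About 0.5 for uncorrelated series, toward 1 for persistent (trending)
    ones. NaN (logged) when every segment is constant.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 64:
        raise ValueError(f"need at least 64 samples, got {len(x)}")
    sizes, rs = rescaled_range_table(x, min_window=min_window)
    if len(sizes) < 2:
        logger.debug("hurst_exponent: degenerate R/S table")
        return float("nan")
    slope = np.polyfit(np.log(sizes), np.log(rs), 1)[0]
    return float(slope)


# ---------------------------------------------------------------------------
# assembly


def nonlinear_features(
    x: np.ndarray,
    max_lag: int = DEFAULT_MAX_LAG,
    max_dim: int = 10,
    sampen_r_factor: float = 0.2,
) -> NonlinearFeatures:
    """The five nonlinear features for one axis of an epoch.

    The embedding delay and dimension feed the Lyapunov and sample-entropy
    estimates (SampEn template length m = min(d, 3), tolerance 0.2 sd, template
    delay tau). The exported AMI score is the AMI curve value at tau and the
    exported FNN score is the embedding dimension itself.
    """
    x = np.asarray(x, dtype=float)
    emb = estimate_embedding(x, max_lag=max_lag, max_dim=max_dim)
    sd = x.std()
    if sd == 0:
        return NonlinearFeatures(
            tau=emb.tau, dim=emb.dim, ami=emb.ami_at_tau, fnn=float(emb.dim),
            lyapunov=0.0, sampen=0.0, hurst=float("nan"),
        )
    try:
        lyap = largest_lyapunov(x, emb.tau, emb.dim)
    except ValueError:
        lyap = float("nan")
    m = min(emb.dim, 3)
    try:
        sampen = sample_entropy(x, m=m, r=sampen_r_factor * sd, tau=emb.tau)
    except ValueError:
        sampen = float("nan")
    try:
        hurst = hurst_exponent(x)
    except ValueError:
        hurst = float("nan")
    return NonlinearFeatures(
        tau=emb.tau,
        dim=emb.dim,
        ami=emb.ami_at_tau,
        fnn=float(emb.dim),
        lyapunov=lyap,
        sampen=sampen,
        hurst=hurst,
    )
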