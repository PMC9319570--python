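"""Nonlinear features against analytic values and brute-force oracles."""

import math

import numpy as np
import pytest

from harpipe import make_toy_signal
from harpipe.nonlinear import (
    auto_mutual_information,
    dimension_from_fractions,
    embedding_dimension,
    estimate_embedding,
    false_nearest_neighbors,
    hurst_exponent,
    largest_lyapunov,
    nonlinear_features,
    optimal_delay,
    rescaled_range_table,
    sample_entropy,
)


def brute_force_mi(a, b, n_bins=16):
    """Plug-in MI (bits) from an explicit double loop over histogram cells."""
    lo, hi = min(a.min(), b.min()), max(a.max(), b.max())
    ia = np.clip(((a - lo) / (hi - lo) * n_bins).astype(int), 0, n_bins - 1)
    ib = np.clip(((b - lo) / (hi - lo) * n_bins).astype(int), 0, n_bins - 1)
    n = len(a)
    mi = 0.0
    for u in range(n_bins):
        for v in range(n_bins):
            pxy = np.mean((ia == u) & (ib == v))
            if pxy == 0:
                continue
            px, py = np.mean(ia == u), np.mean(ib == v)
            mi += pxy * math.log2(pxy / (px * py))
    return mi


def naive_divergence_slope(x, horizon, min_sep):
    """Literal log-divergence tracking for a 1-D series with explicit loops."""
    n = len(x)
    usable = n - horizon
    logs = np.zeros(horizon + 1)
    counts = np.zeros(horizon + 1)
    for i in range(usable):
        best, best_j = np.inf, None
        for j in range(usable):
            if abs(i - j) <= min_sep:
                continue
            d = abs(x[i] - x[j])
            if 0 < d < best:
                best, best_j = d, j
        if best_j is None:
            continue
        for k in range(horizon + 1):
            d = abs(x[i + k] - x[best_j + k])
            if d > 0:
                logs[k] += math.log(d)
                counts[k] += 1
    mean_log = logs / counts
    t = np.arange(horizon + 1)
    return np.polyfit(t, mean_log, 1)[0]


class TestAutoMutualInformation:
    def test_matches_brute_force_histogram_mi(self):
        x = make_toy_signal("sine", 300, {"freq": 2.0, "fs": 100.0})
        ami = auto_mutual_information(x, max_lag=30)
        for lag in (0, 7, 25):
            want = brute_force_mi(x[: len(x) - lag], x[lag:])
            assert ami[lag] == pytest.approx(want, abs=1e-9)

    def test_self_information_is_maximal(self):
        for seed in range(5):
            x = np.random.default_rng(seed).normal(size=400)
            ami = auto_mutual_information(x, max_lag=50)
            assert (ami[0] >= ami[1:] - 1e-12).all()

    def test_independent_samples_have_near_zero_ami(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=2000)
        ami = auto_mutual_information(x, max_lag=20)
        # small positive plug-in bias only: ~bins^2/(2 n ln 2) ~= 0.09 bits
        assert ami[1:].max() < 0.15

    def test_sine_ami_periodic_with_signal_period(self):
        x = make_toy_signal("sine", 1000, {"freq": 2.0, "fs": 100.0})
        ami = auto_mutual_information(x, max_lag=100)
        assert np.argmax(ami[30:70]) + 30 == pytest.approx(50, abs=2)

    def test_constant_signal_flagged_zero(self):
        assert (auto_mutual_information(np.ones(200), 20) == 0).all()


class TestOptimalDelay:
    def test_first_local_minimum_by_definition(self):
        tau, fb = optimal_delay([5.0, 3.0, 1.0, 2.0, 1.5])
        assert (tau, fb) == (2, False)

    def test_monotone_curve_falls_back_to_argmin(self):
        tau, fb = optimal_delay(np.linspace(5, 1, 10))
        assert tau == 9 and fb

    def test_white_noise_delay_is_immediate(self):
        """With a flat AMI tail the first local minimum lands within the
        first few lags (tau=1 whenever AMI(1) <= AMI(2), ~half the time)."""
        taus = []
        for seed in range(20):
            x = np.random.default_rng(seed).normal(size=500)
            tau, _ = optimal_delay(auto_mutual_information(x, 50))
            taus.append(tau)
        assert np.median(taus) <= 3
        assert min(taus) == 1


class TestFalseNearestNeighbors:
    def test_sine_circle_embeds_in_the_plane(self):
        x = make_toy_signal("sine", 500, {"freq": 2.0, "fs": 100.0})
        assert false_nearest_neighbors(x, tau=12, dim=2) <= 0.01

    def test_noise_stays_high_at_low_dimensions(self):
        x = np.random.default_rng(0).normal(size=500)
        assert false_nearest_neighbors(x, tau=1, dim=1) > 0.5
        assert false_nearest_neighbors(x, tau=1, dim=2) > 0.1

    def test_fraction_non_increasing_in_dim_for_sine(self):
        x = make_toy_signal("sine", 500, {"freq": 2.0, "fs": 100.0})
        fr = [false_nearest_neighbors(x, 12, d) for d in (1, 2, 3)]
        assert fr[0] >= fr[1] - 0.02 >= fr[2] - 0.04

    def test_too_short_input_rejected(self):
        with pytest.raises(ValueError, match="too few points"):
            false_nearest_neighbors(np.arange(12.0), tau=2, dim=5)


class TestEmbeddingDimension:
    def test_given_fraction_curve(self):
        assert dimension_from_fractions([0.8, 0.3, 0.0, 0.0], 0.01) == (3, False)

    def test_never_vanishing_curve_falls_back(self):
        dim, fb = dimension_from_fractions([0.9, 0.5, 0.3, 0.2], 0.01)
        assert dim == 4 and fb

    def test_sine_embeds_at_two(self):
        x = make_toy_signal("sine", 500, {"freq": 2.0, "fs": 100.0})
        dim, _, fb = embedding_dimension(x, tau=12)
        assert dim == 2 and not fb


class TestLargestLyapunov:
    def test_sine_is_neutral(self):
        x = make_toy_signal("sine", 500, {"freq": 2.0, "fs": 100.0})
        assert abs(largest_lyapunov(x, tau=12, dim=2)) < 0.02

    def test_logistic_map_matches_ln2(self):
        x = make_toy_signal("logistic_map", 2000, {"r": 4.0, "x0": 0.4}, seed=1)
        lam = largest_lyapunov(x, tau=1, dim=2)
        assert lam == pytest.approx(math.log(2), abs=0.1)

    def test_matches_naive_divergence_tracker_on_logistic_map(self):
        x = make_toy_signal("logistic_map", 400, {"r": 4.0, "x0": 0.37}, seed=0)
        fast = largest_lyapunov(x, tau=1, dim=1, horizon=5, min_separation=1)
        naive = naive_divergence_slope(x, horizon=5, min_sep=1)
        assert fast == pytest.approx(naive, abs=1e-9)

    def test_white_noise_diverges(self):
        positives = sum(
            largest_lyapunov(np.random.default_rng(s).normal(size=500), 1, 3) > 0
            for s in range(5)
        )
        assert positives == 5


class TestSampleEntropy:
    def test_constant_signal_is_zero(self):
        assert sample_entropy(np.ones(100), m=2, r=0.5) == 0.0

    def test_exact_period_three_pattern_is_zero(self):
        x = np.tile([1.0, 2.0, 3.0], 40)
        assert sample_entropy(x, m=2, r=0.5, tau=1) == 0.0

    def test_noise_exceeds_sine(self):
        n = 500
        noise = np.random.default_rng(0).normal(size=n)
        sine = make_toy_signal("sine", n, {"freq": 2.0, "fs": 100.0})
        assert sample_entropy(noise, m=2) > sample_entropy(sine, m=2)

    def test_monotone_non_increasing_in_tolerance(self):
        x = np.random.default_rng(2).normal(size=300)
        values = [sample_entropy(x, m=2, r=r) for r in (0.1, 0.2, 0.4, 0.8)]
        assert all(a >= b - 1e-12 for a, b in zip(values, values[1:]))

    def test_exhaustive_pair_count_oracle(self):
        """-log(A/B) with A and B counted by explicit loops."""
        x = np.random.default_rng(5).normal(size=60)
        m, r = 2, 0.4
        nt = len(x) - m
        b = a = 0
        for i in range(nt):
            for j in range(i + 1, nt):
                dm = max(abs(x[i + k] - x[j + k]) for k in range(m))
                dm1 = max(dm, abs(x[i + m] - x[j + m]))
                b += dm < r
                a += dm1 < r
        assert sample_entropy(x, m=m, r=r) == pytest.approx(-math.log(a / b), abs=1e-12)

    def test_non_positive_tolerance_rejected(self):
        with pytest.raises(ValueError):
            sample_entropy(np.random.default_rng(0).normal(size=100), m=2, r=0.0)


class TestHurstExponent:
    def test_iid_noise_near_half(self):
        hs = [hurst_exponent(np.random.default_rng(s).normal(size=500))
              for s in range(200)]
        assert np.mean(hs) == pytest.approx(0.5, abs=0.1)

    def test_trending_series_is_persistent(self):
        rng = np.random.default_rng(0)
        x = np.linspace(0, 10, 500) + rng.normal(0, 0.05, 500)
        assert hurst_exponent(x) > 0.8

    def test_shuffling_destroys_persistence(self):
        rng = np.random.default_rng(1)
        x = np.cumsum(rng.normal(size=500))  # strongly persistent walk
        assert hurst_exponent(x) > 0.8
        hs = []
        for s in range(50):
            sh = x.copy()
            np.random.default_rng(s).shuffle(sh)
            hs.append(hurst_exponent(sh))
        assert np.mean(hs) == pytest.approx(0.5, abs=0.1)

    def test_slope_equals_manual_regression_on_rs_table(self):
        x = np.random.default_rng(4).normal(size=512)
        w, rs = rescaled_range_table(x)
        lw, lr = np.log(w), np.log(rs)
        slope = ((lw - lw.mean()) * (lr - lr.mean())).sum() / ((lw - lw.mean()) ** 2).sum()
        assert hurst_exponent(x) == pytest.approx(slope, abs=1e-12)


@pytest.mark.parametrize("seed", range(3))
def test_affine_invariance_of_all_five_features(seed):
    """x -> a x + b leaves tau, d, lambda, SampEn (relative R) and H unchanged."""
    x = np.random.default_rng(seed).normal(size=500)
    y = 3.7 * x + 11.0
    fx = nonlinear_features(x)
    fy = nonlinear_features(y)
    assert fx.tau == fy.tau and fx.dim == fy.dim
    assert fy.ami == pytest.approx(fx.ami, abs=1e-9)
    assert fy.lyapunov == pytest.approx(fx.lyapunov, abs=1e-6)
    assert fy.sampen == pytest.approx(fx.sampen, abs=1e-9)
    assert fy.hurst == pytest.approx(fx.hurst, abs=1e-9)
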