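"""Delay-embedding estimators against analytic and brute-force oracles."""

import numpy as np
import pytest

from trisyn.benchmarks import logistic_map, noisy_sine
from trisyn.nonlinear import (
    EmbeddingParams,
    ami_delay,
    correlation_dimension,
    correlation_sum,
    divergence_curve,
    embed,
    fnn_dimension,
    line_length_entropy,
    max_lyapunov,
    rqa_entropy,
)


def incommensurate_sine(n=6000, period=97.31):
    return np.sin(2 * np.pi * np.arange(n) / period)


# --- embedding parameters -------------------------------------------------

def test_ami_delay_of_sine_is_quarter_period(noisy_sine_series):
    d = ami_delay(noisy_sine_series.values, max_lag=60, n_bins=16)
    assert abs(d - 25) <= 2


def test_ami_delay_of_noise_is_small():
    x = np.random.default_rng(0).uniform(size=100_000)
    assert ami_delay(x, max_lag=20) <= 5


def test_ami_delay_rejects_constant():
    with pytest.raises(ValueError):
        ami_delay(np.ones(1000), max_lag=10)


def test_fnn_dimension_sine_is_two():
    assert fnn_dimension(incommensurate_sine(), 24, theiler_window=25) == 2


def test_fnn_dimension_henon_is_two(henon_series):
    assert fnn_dimension(henon_series.values, 1, theiler_window=2) == 2


def test_fnn_dimension_lorenz_is_three(lorenz_x):
    x = lorenz_x.values
    d = ami_delay(x, max_lag=100, n_bins=16)
    assert fnn_dimension(x, d, theiler_window=10) == 3


# --- correlation dimension ------------------------------------------------

def test_correlation_dimension_of_plane_filling_noise():
    x = np.random.default_rng(1).uniform(size=4000)
    d2 = correlation_dimension(x, EmbeddingParams(1, 2, 0))
    assert abs(d2 - 2.0) < 0.15


def test_correlation_dimension_of_henon(henon_series):
    d2 = correlation_dimension(henon_series.values[:4000], EmbeddingParams(1, 2, 2))
    assert 1.1 <= d2 <= 1.3


def test_correlation_dimension_of_sine_is_one():
    d2 = correlation_dimension(incommensurate_sine(4000), EmbeddingParams(24, 2, 30))
    assert abs(d2 - 1.0) < 0.1


def test_correlation_sum_matches_brute_force(henon_series):
    """KD-tree pair counting equals the all-pairs oracle exactly."""
    pts = embed(henon_series.values[:800], 1, 2)
    w = 3
    radii = np.array([0.05, 0.2, 0.5, 1.0])
    fast = correlation_sum(pts, radii, theiler_window=w)
    n = pts.shape[0]
    oracle = []
    for r in radii:
        count = 0
        pairs = 0
        for i in range(n):
            for j in range(i + 1, n):
                if j - i <= w:
                    continue
                pairs += 1
                if np.linalg.norm(pts[i] - pts[j]) <= r:
                    count += 1
        oracle.append(count / pairs)
    np.testing.assert_allclose(fast, oracle, rtol=0, atol=1e-12)


def test_no_scaling_region_returns_nan():
    x = np.zeros(2000)
    x[::2] = 1.0  # two-point alternation: no power-law regime
    val = correlation_dimension(x, EmbeddingParams(1, 2, 1))
    assert np.isnan(val)


# --- recurrence entropy ---------------------------------------------------

def test_rqa_entropy_zero_for_periodic():
    x = np.tile(np.sin(2 * np.pi * np.arange(8) / 8), 500)
    assert rqa_entropy(x, EmbeddingParams(2, 2, 4)) == 0.0


def test_line_length_entropy_two_equal_classes():
    lengths = [2] * 8 + [3] * 8
    assert line_length_entropy(lengths) == 1.0


def test_line_length_entropy_single_class_and_empty():
    assert line_length_entropy([4] * 10) == 0.0
    assert line_length_entropy([]) == 0.0


def test_rqa_entropy_noise_exceeds_periodic():
    rng = np.random.default_rng(0)
    noise = rng.standard_normal(4000)
    periodic = np.tile(np.sin(2 * np.pi * np.arange(8) / 8), 500)
    h_noise = rqa_entropy(noise, EmbeddingParams(1, 2, 2))
    h_sine = rqa_entropy(periodic, EmbeddingParams(2, 2, 4))
    assert h_noise > h_sine


def test_rqa_entropy_hits_target_recurrence_rate():
    rng = np.random.default_rng(2)
    _, diag = rqa_entropy(rng.standard_normal(3000), EmbeddingParams(1, 3, 2),
                          target_recurrence_rate=0.1, return_diagnostics=True)
    assert abs(diag["recurrence_rate"] - 0.1) < 0.01


def test_rqa_entropy_rejects_degenerate_rate():
    with pytest.raises(ValueError):
        rqa_entropy(np.sin(np.arange(500.0)), EmbeddingParams(1, 2, 0),
                    target_recurrence_rate=1.5)


# --- maximal Lyapunov exponent --------------------------------------------

def test_lyapunov_logistic_fully_chaotic():
    x = logistic_map(4.0, 0.3, 5000).values
    lam = max_lyapunov(x, EmbeddingParams(1, 1, 1), fit_window=(0, 5))
    assert abs(lam - np.log(2)) / np.log(2) < 0.1


def test_lyapunov_logistic_periodic_is_negative():
    x = logistic_map(3.2, 0.31, 5000).values  # transient retained
    lam = max_lyapunov(x, EmbeddingParams(1, 1, 1), fit_window=(0, 10))
    assert lam < 0


def test_lyapunov_of_limit_cycle_is_tiny():
    x = incommensurate_sine()
    lam = max_lyapunov(x, EmbeddingParams(24, 2, 30), fit_window=(1, 60))
    assert lam <= 0.01


def test_lyapunov_auto_window_matches_explicit_for_chaos():
    x = logistic_map(4.0, 0.3, 5000).values
    lam = max_lyapunov(x, EmbeddingParams(1, 1, 1))
    assert abs(lam - np.log(2)) / np.log(2) < 0.1


# --- invariance properties ------------------------------------------------

@pytest.mark.parametrize("scale", [0.3, 4.2])
def test_scale_invariance(henon_series, scale):
    x = henon_series.values[:4000]
    emb = EmbeddingParams(1, 2, 2)
    d2a = correlation_dimension(x, emb)
    d2b = correlation_dimension(scale * x, emb)
    assert abs(d2a - d2b) < 1e-9
    la = max_lyapunov(x, emb, fit_window=(0, 8))
    lb = max_lyapunov(scale * x, emb, fit_window=(0, 8))
    assert abs(la - lb) < 0.02
    assert ami_delay(x, max_lag=20) == ami_delay(scale * x, max_lag=20)


def test_shuffled_surrogate_fills_embedding_space(henon_series):
    """Destroying temporal order pushes D2 toward the embedding dimension."""
    x = henon_series.values[:4000]
    rng = np.random.default_rng(0)
    surrogate = rng.permutation(x)
    emb = EmbeddingParams(1, 2, 2)
    assert correlation_dimension(surrogate, emb) > correlation_dimension(x, emb) + 0.4


def test_divergence_curve_starts_at_neighbour_distance(henon_series):
    y = divergence_curve(embed_series := henon_series.values[:3000],
                         EmbeddingParams(1, 2, 2), 10)
    assert np.isfinite(y[0]) and y[0] < y[5]
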