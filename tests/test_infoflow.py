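"""Histogram information estimators against closed forms and enumeration."""

import numpy as np
import pytest

import trisyn
from trisyn.benchmarks import coupled_binary_processes, exact_te_coupled_binary
from trisyn.infoflow import (
    bin_activity,
    control_normalize,
    mutual_information,
    region_infoflow,
    shannon_entropy,
    transfer_entropy,
)


# --- binning ---------------------------------------------------------------

def test_bin_activity_hand_example():
    act = bin_activity([np.array([1.0, 2.0, 15.0])], 10.0, 30.0)
    np.testing.assert_array_equal(act.counts, [2, 1, 0])


def test_bin_activity_empty_and_conserving():
    assert bin_activity([], 10.0, 50.0).counts.sum() == 0
    rng = np.random.default_rng(0)
    trains = [np.sort(rng.uniform(0, 1000, 40)) for _ in range(3)]
    act = bin_activity(trains, 10.0, 1000.0)
    assert act.counts.sum() == 120


# --- entropy ---------------------------------------------------------------

def test_entropy_equiprobable_four_symbols():
    assert shannon_entropy([0, 1, 2, 3] * 100) == 2.0


def test_entropy_constant_is_zero():
    assert shannon_entropy([5] * 50) == 0.0


def test_entropy_half_quarter_quarter():
    seq = [0, 0, 1, 2] * 100
    assert abs(shannon_entropy(seq) - 1.5) < 1e-12


def test_entropy_empty_raises():
    with pytest.raises(ValueError):
        shannon_entropy([])


# --- mutual information ----------------------------------------------------

def test_mi_identity_channel_equals_entropy():
    x = np.random.default_rng(0).integers(0, 4, 5000)
    assert abs(mutual_information(x, x) - shannon_entropy(x)) < 1e-12


def test_mi_independent_binary_small():
    rng = np.random.default_rng(1)
    x = rng.integers(0, 2, 100_000)
    y = rng.integers(0, 2, 100_000)
    assert mutual_information(x, y) < 0.01


def test_mi_from_joint_tables():
    # uniform joint over four cells: independent, 0 bits
    x = [0] * 25 + [0] * 25 + [1] * 25 + [1] * 25
    y = [0] * 25 + [1] * 25 + [0] * 25 + [1] * 25
    assert abs(mutual_information(x, y)) < 1e-12
    # perfectly correlated diagonal: 1 bit
    x2 = [0] * 50 + [1] * 50
    assert abs(mutual_information(x2, x2) - 1.0) < 1e-12


def test_mi_symmetry_and_length_check():
    rng = np.random.default_rng(2)
    x = rng.integers(0, 3, 2000)
    y = np.roll(x, 1)
    assert abs(mutual_information(x, y) - mutual_information(y, x)) < 1e-12
    with pytest.raises(ValueError):
        mutual_information(x, y[:-1])


def test_data_processing_bound():
    x = np.random.default_rng(3).integers(0, 4, 20_000)
    f_of_x = x % 2
    assert mutual_information(x, f_of_x) <= shannon_entropy(x) + 1e-12


# --- transfer entropy -------------------------------------------------------

def test_te_copy_channel():
    bx, by = coupled_binary_processes(1.0, 100_000, seed=0)
    x, y = bx.values.astype(int), by.values.astype(int)
    assert abs(transfer_entropy(x, y) - 1.0) < 0.01
    assert transfer_entropy(y, x) < 0.01


def test_te_independent_streams():
    rng = np.random.default_rng(4)
    x = rng.integers(0, 2, 100_000)
    y = rng.integers(0, 2, 100_000)
    assert transfer_entropy(x, y) < 0.01
    assert transfer_entropy(y, x) < 0.01


@pytest.mark.parametrize("coupling", [0.2, 0.5])
def test_te_direction_of_coupled_processes(coupling):
    bx, by = coupled_binary_processes(coupling, 200_000, seed=1)
    x, y = bx.values.astype(int), by.values.astype(int)
    assert transfer_entropy(x, y) > transfer_entropy(y, x)


@pytest.mark.parametrize("coupling", [0.0, 0.5, 1.0])
def test_te_plugin_matches_enumeration(coupling):
    """Plug-in estimate within 0.01 bits of the exact value at n = 10^6."""
    bx, by = coupled_binary_processes(coupling, 1_000_000, seed=2)
    exact = exact_te_coupled_binary(coupling)
    est = transfer_entropy(bx.values.astype(int), by.values.astype(int))
    assert abs(est - exact) < 0.01


def test_te_exact_closed_form_agreement():
    """Enumeration agrees with 1 - H_b((1+c)/2)."""
    for c in (0.1, 0.3, 0.5, 0.9):
        p = (1 + c) / 2
        hb = -p * np.log2(p) - (1 - p) * np.log2(1 - p)
        assert abs(exact_te_coupled_binary(c) - (1 - hb)) < 1e-12


def test_te_short_series_raises():
    with pytest.raises(ValueError):
        transfer_entropy([1], [1], k_history=2, l_history=2)


# --- control normalization --------------------------------------------------

def test_control_normalize_arithmetic():
    assert control_normalize(1.0, 1.0) == 100.0
    assert control_normalize(0.0, 1.0) == 0.0
    assert abs(control_normalize(0.35, 1.0) - 35.0) < 1e-12
    with pytest.raises(ValueError):
        control_normalize(0.5, 0.0)


# --- simulator-level flow ---------------------------------------------------

def test_feedforward_te_direction_on_control(control_result):
    """Information flows DG -> CA3 -> CA1, not backwards, in the control."""
    cfg, res = control_result
    m = region_infoflow(res, cfg, settle_ms=2000.0)
    te = m.transfer_entropy
    assert te[("DG", "CA3")] > te[("CA3", "DG")]
    assert te[("CA3", "CA1")] > te[("CA1", "CA3")]
    for v in m.entropy.values():
        assert v >= 0.0
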