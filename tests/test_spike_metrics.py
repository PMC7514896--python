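"""Spike detection, burst segmentation and the four burst statistics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from trisyn.spike_metrics import (
    BurstStats,
    SpikeTrain,
    burst_statistics,
    detect_spikes,
    region_aggregate,
    segment_bursts,
)


def test_detect_spikes_flat_trace():
    v = np.full(1000, -65.0)
    assert detect_spikes(v, 0.1).times.size == 0


def test_detect_spikes_three_pulses():
    v = np.full(3000, -65.0)
    for onset in (500, 1500, 2500):  # 50, 150, 250 ms at dt=0.1
        v[onset:onset + 5] = 10.0
    train = detect_spikes(v, 0.1, threshold=-20.0)
    np.testing.assert_allclose(train.times, [50.0, 150.0, 250.0])


def test_detect_spikes_refractory_merge():
    v = np.full(200, -65.0)
    for onset in (10, 15, 20, 25):  # pulses every 0.5 ms
        v[onset:onset + 2] = 10.0
    train = detect_spikes(v, 0.1, threshold=-20.0, refractory=2.0)
    assert train.times.size == 1


def test_detect_spikes_rejects_nan():
    with pytest.raises(ValueError):
        detect_spikes(np.array([0.0, np.nan]), 0.1)


def test_segment_bursts_hand_example():
    train = SpikeTrain("c", np.array([0.0, 5.0, 8.0, 100.0, 104.0]), 200.0)
    bursts = segment_bursts(train, isi_threshold=20.0)
    assert bursts == [(0.0, 8.0, 3), (100.0, 104.0, 2)]


def test_segment_bursts_empty_and_isolated():
    assert segment_bursts(SpikeTrain("c", np.array([]), 100.0), 20.0) == []
    isolated = SpikeTrain("c", np.array([0.0, 50.0, 100.0]), 200.0)
    assert segment_bursts(isolated, 20.0) == []


def test_burst_statistics_hand_example():
    train = SpikeTrain("c", np.array([0.0, 5.0, 8.0, 100.0, 104.0]), 200.0)
    s = burst_statistics(train, isi_threshold=20.0)
    assert s.n_spikes == 5
    assert s.n_bursts == 2
    assert s.spikes_per_burst == 2.5
    assert s.burst_duration == 6.0
    assert s.inter_burst_interval == 92.0


def test_burst_statistics_empty_train():
    s = burst_statistics(SpikeTrain("c", np.array([]), 100.0))
    assert s.n_spikes == 0 and s.n_bursts == 0
    assert math.isnan(s.spikes_per_burst)
    assert math.isnan(s.burst_duration)
    assert math.isnan(s.inter_burst_interval)


def test_single_burst_has_no_ibi():
    s = burst_statistics(SpikeTrain("c", np.array([1.0, 5.0, 9.0]), 100.0), 20.0)
    assert s.n_bursts == 1
    assert not math.isnan(s.burst_duration)
    assert math.isnan(s.inter_burst_interval)


def test_spikes_in_bursts_never_exceed_total():
    train = SpikeTrain("c", np.sort(np.random.default_rng(0).uniform(0, 1000, 80)), 1000.0)
    bursts = segment_bursts(train, 15.0)
    assert sum(b[2] for b in bursts) <= train.times.size
    for b in bursts:
        assert b[2] >= 2


@given(st.floats(0.0, 500.0))
@settings(deadline=None, max_examples=25)
def test_time_shift_invariance(shift):
    base = np.array([3.0, 9.0, 14.0, 80.0, 86.0, 200.0])
    a = burst_statistics(SpikeTrain("c", base, 1000.0), 20.0)
    b = burst_statistics(SpikeTrain("c", base + shift, 1000.0 + shift), 20.0)
    assert a.n_spikes == b.n_spikes and a.n_bursts == b.n_bursts
    np.testing.assert_allclose(
        [a.spikes_per_burst, a.burst_duration, a.inter_burst_interval],
        [b.spikes_per_burst, b.burst_duration, b.inter_burst_interval],
    )


def test_strictly_increasing_enforced():
    with pytest.raises(ValueError):
        SpikeTrain("c", np.array([1.0, 1.0, 2.0]), 10.0)


def _stats(n, spb=float("nan"), dur=float("nan"), ibi=float("nan"), nb=0):
    return BurstStats(n, spb, dur, ibi, nb)


def test_region_aggregate_means():
    stats = {"a": _stats(10, 2.0, 5.0, 50.0, 3), "b": _stats(20, 4.0, 7.0, 70.0, 5)}
    rmap = {"a": "DG", "b": "DG"}
    agg = region_aggregate(stats, rmap, ["DG"])
    assert agg["DG"].n_spikes == 15
    assert agg["DG"].spikes_per_burst == 3.0


def test_region_aggregate_excludes_missing():
    stats = {"a": _stats(10, 2.0, 5.0, 50.0, 3), "b": _stats(20, 4.0, 7.0, float("nan"), 5)}
    rmap = {"a": "CA3", "b": "CA3"}
    agg = region_aggregate(stats, rmap, ["CA3"])
    assert agg["CA3"].inter_burst_interval == 50.0


def test_region_aggregate_union_is_mean_of_members():
    stats = {f"c{i}": _stats(10 * (i + 1), 2.0, 5.0, 50.0, 2) for i in range(6)}
    rmap = {f"c{i}": ("DG" if i < 2 else "CA3" if i < 4 else "CA1") for i in range(6)}
    agg = region_aggregate(stats, rmap, ["DG-CA3-CA1"])
    assert agg["DG-CA3-CA1"].n_spikes == np.mean([10, 20, 30, 40, 50, 60])


def test_region_aggregate_empty_region_raises():
    with pytest.raises(ValueError):
        region_aggregate({"a": _stats(1)}, {"a": "DG"}, ["CA1"])
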