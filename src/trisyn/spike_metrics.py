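"""Burst statistics of spike trains.

Four statistics per cell: number of spikes, spikes per burst, burst
duration and inter-burst interval.  Bursts are maximal runs of at least
two spikes whose consecutive inter-spike intervals stay below a
threshold (default: a quarter theta period).  The inter-burst interval
is measured from burst offset to the next burst onset, so that
``burst_duration + IBI`` approximates one theta cycle for theta-locked
trains.  Undefined statistics are reported as NaN, never as 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

DEFAULT_ISI_THRESHOLD = 1000.0 / 8.0 / 4.0  # quarter of an 8 Hz theta period, ms


@dataclass
class SpikeTrain:
    cell_id: str
    times: np.ndarray  # sorted, ms
    duration: float  # ms

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError("spike times must be strictly increasing")
        if t.size and (t[0] < 0 or t[-1] >= self.duration):
            raise ValueError("spike times must lie in [0, duration)")
        self.times = t


@dataclass
class BurstStats:
    n_spikes: int
    spikes_per_burst: float  # NaN if no bursts
    burst_duration: float  # mean ms, NaN if no bursts
    inter_burst_interval: float  # mean ms, NaN if < 2 bursts
    n_bursts: int


def detect_spikes(voltage_trace, dt: float, threshold: float = -20.0,
                  refractory: float = 2.0, cell_id: str = "") -> SpikeTrain:
    """Extract spike times from a voltage trace by upward threshold crossing.

    Crossings closer than ``refractory`` (ms) are merged into one spike.
    """
    v = np.asarray(voltage_trace, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("voltage trace contains non-finite samples")
    above = v >= threshold
    onsets = np.flatnonzero(above & ~np.roll(above, 1))
    if above.size and above[0]:
        onsets = np.union1d(onsets, [0])
    times = onsets * dt
    if times.size:
        kept = [times[0]]
        for t in times[1:]:
            if t - kept[-1] >= refractory:
                kept.append(t)
        times = np.array(kept)
    return SpikeTrain(cell_id=cell_id, times=times, duration=v.size * dt)


def segment_bursts(train: SpikeTrain, isi_threshold: float = DEFAULT_ISI_THRESHOLD):
    """Maximal runs of >= 2 spikes with consecutive ISIs <= threshold.

    Returns a list of ``(t_first, t_last, n_spikes)`` tuples, disjoint
    and in temporal order.  Isolated spikes do not form bursts.
    """
    if isi_threshold <= 0:
        raise ValueError("isi_threshold must be > 0")
    t = train.times
    if t.size < 2:
        return []
    bursts = []
    start = 0
    for i in range(1, t.size + 1):
        if i == t.size or t[i] - t[i - 1] > isi_threshold:
            if i - start >= 2:
                bursts.append((t[start], t[i - 1], i - start))
            start = i
    return bursts


def burst_statistics(train: SpikeTrain, isi_threshold: float = DEFAULT_ISI_THRESHOLD) -> BurstStats:
    bursts = segment_bursts(train, isi_threshold)
    n_bursts = len(bursts)
    if n_bursts == 0:
        spb = dur = ibi = float("nan")
    else:
        spb = float(np.mean([b[2] for b in bursts]))
        dur = float(np.mean([b[1] - b[0] for b in bursts]))
        if n_bursts >= 2:
            ibi = float(np.mean([bursts[i + 1][0] - bursts[i][1] for i in range(n_bursts - 1)]))
        else:
            ibi = float("nan")
    return BurstStats(
        n_spikes=int(train.times.size),
        spikes_per_burst=spb,
        burst_duration=dur,
        inter_burst_interval=ibi,
        n_bursts=n_bursts,
    )


def _nanmean(values: Iterable[float]) -> float:
    arr = np.asarray(list(values), dtype=float)
    arr = arr[np.isfinite(arr)]
    return float(arr.mean()) if arr.size else float("nan")


def region_aggregate(stats_by_cell: dict[str, BurstStats], region_map: dict[str, str],
                     regions: Iterable[str] = ("DG", "CA3", "CA1", "DG-CA3-CA1", "CA3-CA1")
                     ) -> dict[str, BurstStats]:
    """Unweighted mean of per-cell statistics over each region or union.

    ``region_map`` maps cell_id -> region; union labels join member
    regions with '-'.  Missing (NaN) per-cell values are excluded from
    the means; a region with no cells raises ``ValueError``.
    """
    out = {}
    for label in regions:
        members = set(label.split("-"))
        cells = [cid for cid, r in region_map.items() if r in members and cid in stats_by_cell]
        if not cells:
            raise ValueError(f"no cells in region {label!r}")
        st = [stats_by_cell[c] for c in cells]
        out[label] = BurstStats(
            n_spikes=_nanmean(s.n_spikes for s in st),
            spikes_per_burst=_nanmean(s.spikes_per_burst for s in st),
            burst_duration=_nanmean(s.burst_duration for s in st),
            inter_burst_interval=_nanmean(s.inter_burst_interval for s in st),
            n_bursts=_nanmean(s.n_bursts for s in st),
        )
    return out
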