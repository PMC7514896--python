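"""Directed information flow between regions from binned spike activity.

Plug-in (maximum-likelihood histogram) estimators of Shannon entropy,
mutual information and Schreiber transfer entropy on discretized spike
counts.  Counts are clipped to a small alphabet (0, 1, 2, >=3 by
default) so the joint histograms stay well-populated at the series
lengths a desk-scale simulation produces.  All quantities are in bits.

Region-level defaults use 20 ms bins with three bins of history: with
theta-locked activity, a state covering roughly half a theta cycle is
needed before transfer entropy separates genuine feedforward prediction
from within-cycle phase-lag artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

DEFAULT_BIN_MS = 20.0
DEFAULT_MAX_COUNT = 3  # counts clipped to {0, 1, 2, >=3}


@dataclass
class BinnedActivity:
    region: str
    bin_width: float  # ms
    counts: np.ndarray  # non-negative ints

    def __post_init__(self):
        if self.bin_width <= 0:
            raise ValueError("bin_width must be > 0")
        c = np.asarray(self.counts, dtype=np.int64)
        if c.size and c.min() < 0:
            raise ValueError("counts must be non-negative")
        self.counts = c


@dataclass
class InfoFlowMetrics:
    """Entropies, MI and TE for a set of regions, in bits."""

    entropy: dict[str, float] = field(default_factory=dict)  # per region
    mutual_information: dict[tuple[str, str], float] = field(default_factory=dict)
    transfer_entropy: dict[tuple[str, str], float] = field(default_factory=dict)
    control_ratio: dict[tuple[str, str], float] = field(default_factory=dict)  # percent
    bin_width: float = DEFAULT_BIN_MS


def bin_activity(trains: Iterable[np.ndarray], bin_width: float, duration: float,
                 region: str = "") -> BinnedActivity:
    """Per-bin summed spike counts over a region's cells."""
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    n_bins = int(duration // bin_width)
    counts = np.zeros(n_bins, dtype=np.int64)
    for t in trains:
        t = np.asarray(t, dtype=float)
        idx = (t / bin_width).astype(np.int64)
        idx = idx[(idx >= 0) & (idx < n_bins)]
        np.add.at(counts, idx, 1)
    return BinnedActivity(region=region, bin_width=bin_width, counts=counts)


def clip_counts(counts, max_count: int = DEFAULT_MAX_COUNT) -> np.ndarray:
    return np.minimum(np.asarray(counts, dtype=np.int64), max_count)


def _entropy_from_codes(codes: np.ndarray) -> float:
    _, freq = np.unique(codes, return_counts=True)
    p = freq / freq.sum()
    return float(-(p * np.log2(p)).sum())


def shannon_entropy(counts) -> float:
    """Plug-in Shannon entropy (bits) of the empirical symbol distribution."""
    c = np.asarray(counts)
    if c.size == 0:
        raise ValueError("empty sequence has no entropy")
    return _entropy_from_codes(c)


def _joint_codes(*seqs):
    seqs = [np.asarray(s, dtype=np.int64) for s in seqs]
    n = seqs[0].size
    if any(s.size != n for s in seqs):
        raise ValueError("sequences must have equal length")
    code = np.zeros(n, dtype=np.int64)
    for s in seqs:
        code = code * (int(s.max()) + 1 if s.size else 1) + s
    return code


def mutual_information(x_counts, y_counts) -> float:
    """Plug-in mutual information (bits); symmetric and non-negative.

    Computed as H(X) + H(Y) - H(X, Y) on the joint histogram, so
    MI(X, X) equals H(X) exactly.
    """
    x = np.asarray(x_counts, dtype=np.int64)
    y = np.asarray(y_counts, dtype=np.int64)
    if x.size != y.size:
        raise ValueError("length mismatch")
    hx = _entropy_from_codes(x)
    hy = _entropy_from_codes(y)
    hxy = _entropy_from_codes(_joint_codes(x, y))
    return max(0.0, hx + hy - hxy)


def _history_stack(seq: np.ndarray, k: int, offset: int, n_rows: int) -> list[np.ndarray]:
    """Columns seq[offset - 1 - j : ...] for j in 0..k-1, each n_rows long."""
    return [seq[offset - 1 - j : offset - 1 - j + n_rows] for j in range(k)]


def transfer_entropy(source_counts, target_counts, k_history: int = 1,
                     l_history: int = 1) -> float:
    """Schreiber transfer entropy source -> target, in bits.

    ``TE = I(target_next ; source_past | target_past)`` with ``k_history``
    bins of target history and ``l_history`` bins of source history,
    estimated by plug-in joint histograms.  Non-negative and directional.
    """
    if k_history < 1 or l_history < 1:
        raise ValueError("histories must be >= 1")
    x = np.asarray(source_counts, dtype=np.int64)
    y = np.asarray(target_counts, dtype=np.int64)
    if x.size != y.size:
        raise ValueError("length mismatch")
    h = max(k_history, l_history)
    n_rows = y.size - h
    if n_rows < 1:
        raise ValueError("series shorter than history + 1")
    y_next = y[h:]
    y_past = _history_stack(y, k_history, h, n_rows)
    x_past = _history_stack(x, l_history, h, n_rows)
    # TE = H(y+, y-) - H(y-) - H(y+, y-, x-) + H(y-, x-)
    h_yp_y = _entropy_from_codes(_joint_codes(y_next, *y_past))
    h_y = _entropy_from_codes(_joint_codes(*y_past))
    h_all = _entropy_from_codes(_joint_codes(y_next, *y_past, *x_past))
    h_yx = _entropy_from_codes(_joint_codes(*y_past, *x_past))
    return max(0.0, h_yp_y - h_y - h_all + h_yx)


def control_normalize(te_pathology: float, te_control: float) -> float:
    """Pathology TE as a percentage of the control TE."""
    if not te_control > 0:
        raise ValueError("control transfer entropy must be positive")
    return 100.0 * te_pathology / te_control


REGION_PAIRS = (("DG", "CA3"), ("CA3", "CA1"))


def region_infoflow(result, config, bin_width: float = DEFAULT_BIN_MS,
                    max_count: int = DEFAULT_MAX_COUNT,
                    settle_ms: float = 0.0,
                    k_history: int = 3, l_history: int = 3) -> InfoFlowMetrics:
    """Entropy per region plus MI / TE along and against DG->CA3->CA1.

    Activity is the summed principal-cell spike count per ``bin_width``
    bin, clipped to the small estimator alphabet.
    """
    from .network import region_cells

    duration = config.duration
    binned = {}
    for region in ("DG", "CA3", "CA1"):
        trains = [result.spike_times[cid] for cid in region_cells(config, region)]
        act = bin_activity(trains, bin_width, duration, region)
        counts = act.counts
        if settle_ms > 0:
            counts = counts[int(settle_ms // bin_width):]
        binned[region] = clip_counts(counts, max_count)
    out = InfoFlowMetrics(bin_width=bin_width)
    for region, c in binned.items():
        out.entropy[region] = shannon_entropy(c)
    for a, b in REGION_PAIRS:
        out.mutual_information[(a, b)] = mutual_information(binned[a], binned[b])
        out.transfer_entropy[(a, b)] = transfer_entropy(binned[a], binned[b],
                                                        k_history, l_history)
        out.transfer_entropy[(b, a)] = transfer_entropy(binned[b], binned[a],
                                                        k_history, l_history)
    return out
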