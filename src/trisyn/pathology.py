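"""Staged entorhinal-synapse deletion modelling AD-like degeneration.

Degeneration is modelled as cumulative inactivation of perforant-path
(EC2) synapses: at each stage a fixed fraction of the EC2 synapses onto
DG granule cells, CA3 pyramids and the basket cells of both regions is
switched off, in a deterministic order, so that milder stages are always
subsets of more severe ones.  Synapses are never removed from the config
— only their ``active`` flag changes — and nothing outside the target
pathways is ever touched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .config import NetworkConfig, PATHWAY_TAGS

DEFAULT_FRACTIONS = (0.09, 0.18, 0.26, 0.35)
DEFAULT_TARGETS = tuple(t for t in PATHWAY_TAGS if t.startswith("EC2_"))


@dataclass
class DeletionSchedule:
    """Which synapses degenerate, how fast, and in what order."""

    fractions: tuple[float, ...] = DEFAULT_FRACTIONS
    target_pathways: tuple[str, ...] = DEFAULT_TARGETS
    order_policy: str = "indexed"  # indexed | seeded_random
    seed: int = 0

    def __post_init__(self):
        fr = tuple(self.fractions)
        if any(not (0.0 <= f <= 1.0) for f in fr):
            raise ValueError("fractions must lie in [0, 1]")
        if any(b <= a for a, b in zip(fr, fr[1:])):
            raise ValueError("fractions must be strictly increasing")
        if not self.target_pathways:
            raise ValueError("target_pathways must be non-empty")
        unknown = set(self.target_pathways) - set(PATHWAY_TAGS)
        if unknown:
            raise ValueError(f"unknown pathway tags: {sorted(unknown)}")
        if self.order_policy not in ("indexed", "seeded_random"):
            raise ValueError("order_policy must be 'indexed' or 'seeded_random'")
        self.fractions = fr
        self.target_pathways = tuple(self.target_pathways)


def _target_order(config: NetworkConfig, schedule: DeletionSchedule) -> list[int]:
    targets = [
        i for i, s in enumerate(config.synapses) if s.pathway_tag in schedule.target_pathways
    ]
    if not targets:
        raise ValueError("no synapses match the target pathways")
    if schedule.order_policy == "seeded_random":
        rng = np.random.default_rng(schedule.seed)
        targets = [targets[i] for i in rng.permutation(len(targets))]
    return targets


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def apply_deletion(
    config: NetworkConfig, fraction: float, schedule: DeletionSchedule | None = None
) -> NetworkConfig:
    """Return a copy of ``config`` with ``round(fraction * N_target)``
    target-pathway synapses inactivated (round half up).

    Deletions are cumulative across fractions: the synapses removed at a
    lower fraction are a subset of those removed at any higher one.
    """
    if not (0.0 <= fraction <= 1.0):
        raise ValueError("fraction must lie in [0, 1]")
    schedule = schedule or DeletionSchedule()
    order = _target_order(config, schedule)
    n_del = _round_half_up(fraction * len(order))
    out = config.copy()
    for i in order[:n_del]:
        out.synapses[i].active = False
    return out


def deletion_series(
    config: NetworkConfig, schedule: DeletionSchedule | None = None
) -> list[tuple[float, NetworkConfig]]:
    """Control (fraction 0) plus one config per scheduled fraction."""
    schedule = schedule or DeletionSchedule()
    series = [(0.0, apply_deletion(config, 0.0, schedule))]
    for f in schedule.fractions:
        series.append((f, apply_deletion(config, f, schedule)))
    return series


def deletion_manifest(config: NetworkConfig, schedule: DeletionSchedule | None = None):
    """Rows (pathway_tag, pre, post, fraction_at_which_deleted) for export."""
    import pandas as pd

    schedule = schedule or DeletionSchedule()
    order = _target_order(config, schedule)
    rows = []
    for f in schedule.fractions:
        n_del = _round_half_up(f * len(order))
        for i in order[:n_del]:
            s = config.synapses[i]
            key = (s.pathway_tag, s.pre_cell_id, s.post_cell_id, i)
            if not any(r[:4] == key for r in rows):
                rows.append((*key, f))
    return pd.DataFrame(
        rows,
        columns=["pathway_tag", "pre", "post", "synapse_index", "fraction_at_which_deleted"],
    )
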