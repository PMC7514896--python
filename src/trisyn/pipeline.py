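"""Full study orchestration: control plus staged deletion, seeded replicates,
burst statistics, complexity measures and directed information flow,
collected into one tidy result table.

The replication unit is the seed (different initial membrane states on
the same deterministic drive clock).  Runs are resumable: each
(level, seed) cell is written to disk as its own CSV chunk keyed by the
configuration hash, and completed cells are skipped on re-run.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .config import NetworkConfig
from .dynamics import integrate_network
from .infoflow import region_infoflow, control_normalize
from .network import build_default_network, region_cells
from .nonlinear import region_complexity
from .pathology import DeletionSchedule, apply_deletion
from .spike_metrics import SpikeTrain, burst_statistics, region_aggregate

log = logging.getLogger("trisyn.pipeline")

REGION_GROUPS = ("DG", "CA3", "CA1", "DG-CA3-CA1", "CA3-CA1")
COMPLEXITY_REGIONS = ("DG", "CA3", "CA1", "DG-CA3-CA1", "CA3-CA1")
TABLE_COLUMNS = ["region", "deletion_fraction", "seed", "metric", "value", "units"]

#: expected trend direction of each burst statistic under progressing
#: synapse loss (sign of the Spearman correlation with deletion fraction)
TREND_SIGNS = {
    "n_spikes": -1,
    "spikes_per_burst": -1,
    "burst_duration": -1,
    "inter_burst_interval": +1,
}


@dataclass
class ExperimentSpec:
    """Everything needed to reproduce one full study."""

    base_config: Optional[NetworkConfig] = None  # default network if None
    schedule: DeletionSchedule = field(default_factory=DeletionSchedule)
    n_seeds: int = 10
    duration: float = 12000.0  # ms
    settle_ms: float = 4000.0  # discarded before analysis
    isi_threshold: Optional[float] = None  # burst criterion; default theta/4
    out_dir: Optional[str] = None
    complexity: bool = True
    infoflow: bool = True

    def __post_init__(self):
        if self.n_seeds < 1:
            raise ValueError("n_seeds must be >= 1")

    def config_for(self, seed: int) -> NetworkConfig:
        if self.base_config is None:
            return build_default_network(seed=seed, duration=self.duration)
        cfg = self.base_config.copy()
        cfg.seed = seed
        cfg.duration = self.duration
        return cfg


def _analysis_rows(result, config, frac, seed, spec: ExperimentSpec) -> list[tuple]:
    """All metric rows for one simulated (level, seed)."""
    from .spike_metrics import DEFAULT_ISI_THRESHOLD

    duration = config.duration
    isi_thr = spec.isi_threshold or DEFAULT_ISI_THRESHOLD
    rmap = {c.cell_id: c.region for c in config.cells}
    rows = []

    settle = spec.settle_ms
    stats = {}
    for cid in region_cells(config, "DG-CA3-CA1"):
        t = result.spike_times[cid]
        t = t[t >= settle] - settle
        stats[cid] = burst_statistics(
            SpikeTrain(cid, t, duration - settle), isi_thr
        )
    agg = region_aggregate(stats, rmap, REGION_GROUPS)
    for region, a in agg.items():
        rows += [
            (region, frac, seed, "n_spikes", a.n_spikes, "count"),
            (region, frac, seed, "spikes_per_burst", a.spikes_per_burst, "count"),
            (region, frac, seed, "burst_duration", a.burst_duration, "ms"),
            (region, frac, seed, "inter_burst_interval", a.inter_burst_interval, "ms"),
            (region, frac, seed, "n_bursts", a.n_bursts, "count"),
        ]

    if spec.complexity:
        for region in COMPLEXITY_REGIONS:
            cm = region_complexity(result, config, region, settle_ms=settle)
            rows += [
                (region, frac, seed, "max_lyapunov", cm.max_lyapunov, "1/ms"),
                (region, frac, seed, "correlation_dimension",
                 cm.correlation_dimension, "dimensionless"),
                (region, frac, seed, "rqa_entropy", cm.rqa_entropy, "bits"),
            ]

    if spec.infoflow:
        fl = region_infoflow(result, config, settle_ms=settle)
        for region, h in fl.entropy.items():
            rows.append((region, frac, seed, "shannon_entropy", h, "bits"))
        for (a, b), v in fl.mutual_information.items():
            rows.append((f"{a}->{b}", frac, seed, "mutual_information", v, "bits"))
        for (a, b), v in fl.transfer_entropy.items():
            rows.append((f"{a}->{b}", frac, seed, "transfer_entropy", v, "bits"))
    return rows


def _add_control_ratios(table: pd.DataFrame) -> pd.DataFrame:
    """Per seed and directed pair: TE as percent of that seed's control TE."""
    te = table[table.metric == "transfer_entropy"]
    extra = []
    for (region, seed), grp in te.groupby(["region", "seed"]):
        ctrl = grp[grp.deletion_fraction == 0.0]
        if ctrl.empty or not ctrl.value.iloc[0] > 0:
            continue
        c = ctrl.value.iloc[0]
        for _, r in grp.iterrows():
            extra.append((region, r.deletion_fraction, seed,
                          "te_control_ratio", control_normalize(r.value, c), "percent"))
    if extra:
        table = pd.concat([table, pd.DataFrame(extra, columns=TABLE_COLUMNS)],
                          ignore_index=True)
    return table


def run_experiment(spec: ExperimentSpec) -> pd.DataFrame:
    """Simulate all deletion levels x seeds and collect the result table.

    With ``spec.out_dir`` set, each completed (level, seed) is persisted
    as a chunk CSV stamped with the configuration hash; an interrupted
    run resumes from the chunks on disk and a hash mismatch aborts.
    A failure in one (level, seed) is logged and the run continues.
    """
    out_dir = Path(spec.out_dir) if spec.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    frames = []
    for seed in range(spec.n_seeds):
        base = spec.config_for(seed)
        chash = base.config_hash()
        for frac in (0.0,) + tuple(spec.schedule.fractions):
            tag = f"level{frac:.2f}_seed{seed}"
            chunk = out_dir / f"chunk_{tag}.csv" if out_dir else None
            meta = out_dir / f"chunk_{tag}.json" if out_dir else None
            if chunk and chunk.exists():
                stored = json.loads(meta.read_text())["config_hash"]
                if stored != chash:
                    raise RuntimeError(
                        f"resume hash mismatch for {tag}: {stored} != {chash}"
                    )
                log.info("skipping %s (already on disk)", tag)
                frames.append(pd.read_csv(chunk, float_precision="round_trip"))
                continue
            try:
                config = apply_deletion(base, frac, spec.schedule)
                result = integrate_network(config)
                rows = _analysis_rows(result, config, frac, seed, spec)
            except Exception:
                log.exception("level %.2f seed %d failed; continuing", frac, seed)
                continue
            df = pd.DataFrame(rows, columns=TABLE_COLUMNS)
            if chunk:
                df.to_csv(chunk, index=False, float_format="%.17g")
                meta.write_text(json.dumps({"config_hash": chash, "seed": seed,
                                            "deletion_fraction": frac}))
            frames.append(df)
    table = pd.concat(frames, ignore_index=True)
    table = _add_control_ratios(table)
    dupes = table.duplicated(["region", "deletion_fraction", "seed", "metric"])
    if dupes.any():
        raise RuntimeError("duplicate (region, level, seed, metric) rows")
    if out_dir:
        table.to_csv(out_dir / "results.csv", index=False)
    return table


def summarize_trends(table: pd.DataFrame) -> pd.DataFrame:
    """Spearman rank correlation of each metric with deletion fraction.

    Pooled over seeds, per metric x region.  Constant metrics yield a
    missing correlation.  The ``direction`` flag is the sign of rho.
    """
    if table.deletion_fraction.nunique() < 2:
        raise ValueError("need at least two deletion levels")
    rows = []
    for (region, metric), grp in table.groupby(["region", "metric"]):
        g = grp.dropna(subset=["value"])
        if g.empty or g.value.nunique() < 2:
            rho, p = float("nan"), float("nan")
        else:
            rho, p = sstats.spearmanr(g.deletion_fraction, g.value)
        direction = 0 if not np.isfinite(rho) else int(np.sign(rho))
        rows.append((region, metric, rho, p, direction))
    return pd.DataFrame(rows, columns=["region", "metric", "spearman_rho",
                                       "p_value", "direction"])


def median_by_level(table: pd.DataFrame, region: str, metric: str) -> pd.Series:
    """Median metric value per deletion level for one region."""
    sub = table[(table.region == region) & (table.metric == metric)]
    return sub.groupby("deletion_fraction").value.median()
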