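"""Plain-text import/export: spike CSVs, voltage CSVs, scalar series."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .config import SimulationResult


def export_spikes(result: SimulationResult, path) -> None:
    """Two-column CSV (cell_id, time_ms), sorted by time within cell."""
    rows = []
    for cid, times in result.spike_times.items():
        for t in times:
            rows.append((cid, t))
    pd.DataFrame(rows, columns=["cell_id", "time_ms"]).to_csv(path, index=False)


def import_spikes(path) -> dict[str, np.ndarray]:
    df = pd.read_csv(path)
    return {
        cid: np.sort(g["time_ms"].to_numpy(dtype=float))
        for cid, g in df.groupby("cell_id")
    }


def export_traces(result: SimulationResult, path, sidecar_path=None) -> None:
    """Wide CSV (time_ms + one column per cell) with a JSON metadata sidecar."""
    cfg = result.config_echo
    data = {"time_ms": result.time}
    data.update(result.voltage_traces)
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.4f")
    if sidecar_path is None:
        sidecar_path = str(path) + ".json"
    meta = {
        "dt_ms": cfg.dt,
        "duration_ms": cfg.duration,
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "schema_version": cfg.schema_version,
        "units": "mV",
    }
    Path(sidecar_path).write_text(json.dumps(meta, indent=2))


def read_series(path) -> np.ndarray:
    """Single-column numeric series; '#' comment lines and blanks tolerated."""
    values = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            values.append(float(line.split(",")[0]))
    return np.array(values)


def export_series(values, path, properties: dict | None = None) -> None:
    """Single-column CSV plus optional JSON sidecar of known properties."""
    with open(path, "w") as fh:
        for v in np.asarray(values, dtype=float):
            fh.write(f"{v:.10g}\n")
    if properties is not None:
        Path(str(path) + ".json").write_text(json.dumps(properties, indent=2, default=float))
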