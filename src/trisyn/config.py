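"""Network description types and config (de)serialization.

Everything needed to reproduce a simulation — cells, compartments,
synapses, external drives, plasticity parameters and seeds — lives in a
:class:`NetworkConfig`.  Configs round-trip through YAML with an explicit
schema version, and a SHA-256 hash of the canonical serialization is used
for resumability checks.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from typing import Optional

import yaml

SCHEMA_VERSION = 1

CELL_CLASSES = ("pyramidal", "granule", "basket", "olm", "mossy")
REGIONS = ("DG", "CA3", "CA1", "septum", "EC2", "EC3")
RECEPTORS = ("AMPA", "NMDA", "GABA_A")
COMPARTMENT_ROLES = ("soma", "axon", "proximal_dendrite", "distal_dendrite")

#: closed vocabulary of pathway tags
PATHWAY_TAGS = (
    "EC2_to_DG_granule",
    "EC2_to_CA3_pyramidal",
    "EC2_to_basket",
    "EC3_to_CA1",
    "mossy_fiber",
    "mossy_cell_feedback",
    "schaffer",
    "local_excitation",
    "local_inhibition",
    "septal",
)

N_COMPARTMENTS = 16  # per hippocampal cell


@dataclass
class CompartmentParams:
    """Passive electrical parameters of one cable compartment.

    Units: capacitance µF/cm², conductances mS/cm², reversal mV.
    ``axial_coupling_to_parent`` is 0 for the soma (tree root).
    """

    membrane_capacitance: float = 1.0
    leak_conductance: float = 0.1
    leak_reversal: float = -65.0
    axial_coupling_to_parent: float = 10.0
    compartment_role: str = "proximal_dendrite"
    parent: int = -1  # index within the cell; -1 for the soma

    def validate(self) -> None:
        if not self.membrane_capacitance > 0:
            raise ValueError("membrane_capacitance must be > 0")
        if self.leak_conductance < 0:
            raise ValueError("leak_conductance must be >= 0")
        if self.compartment_role not in COMPARTMENT_ROLES:
            raise ValueError(f"unknown compartment_role {self.compartment_role!r}")


@dataclass
class CellModel:
    """A neuron: soma-rooted tree of compartments plus spiking parameters."""

    cell_id: str
    cell_class: str
    region: str
    compartments: list[CompartmentParams] = field(default_factory=list)
    spike_threshold: float = -50.0
    reset_potential: float = -72.0
    refractory_period: float = 2.0  # ms

    def validate(self) -> None:
        if self.cell_class not in CELL_CLASSES:
            raise ValueError(f"unknown cell_class {self.cell_class!r}")
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}")
        if self.region in ("DG", "CA3", "CA1") and len(self.compartments) != N_COMPARTMENTS:
            raise ValueError(
                f"hippocampal cell {self.cell_id} must have {N_COMPARTMENTS} compartments"
            )
        roots = [i for i, c in enumerate(self.compartments) if c.parent < 0]
        if len(roots) != 1 or self.compartments[roots[0]].compartment_role != "soma":
            raise ValueError(f"cell {self.cell_id}: exactly one soma-rooted tree required")
        for i, c in enumerate(self.compartments):
            c.validate()
            if c.parent >= i:
                raise ValueError(f"cell {self.cell_id}: compartments must be parent-ordered")
        soma = self.compartments[roots[0]]
        if not self.spike_threshold > soma.leak_reversal:
            raise ValueError(f"cell {self.cell_id}: spike_threshold must exceed leak reversal")


@dataclass
class SynapseSpec:
    """One synaptic contact with difference-of-exponentials kinetics."""

    pre_cell_id: str
    post_cell_id: str
    post_compartment_index: int
    receptor: str
    pathway_tag: str
    weight: float = 1.0
    max_conductance: float = 0.1  # mS/cm²
    rise_time: float = 0.5  # ms
    decay_time: float = 3.0  # ms
    reversal: float = 0.0  # mV
    delay: float = 1.0  # ms
    active: bool = True
    plastic: bool = False

    def validate(self) -> None:
        if self.receptor not in RECEPTORS:
            raise ValueError(f"unknown receptor {self.receptor!r}")
        if self.pathway_tag not in PATHWAY_TAGS:
            raise ValueError(f"unknown pathway_tag {self.pathway_tag!r}")
        if not (self.decay_time > self.rise_time > 0):
            raise ValueError("need decay_time > rise_time > 0")
        if self.delay < 0:
            raise ValueError("delay must be >= 0")
        if self.weight < 0:
            raise ValueError("weight must be >= 0")


@dataclass
class DriveSpec:
    """Theta-nested gamma drive from one extrahippocampal source.

    ``n_fibers`` independent spike trains are generated; synapses reference
    them by pre_cell_id ``"<source>:<fiber>"``.
    """

    source: str  # EC2 | EC3 | septum
    theta_frequency: float = 8.0  # Hz, within [4, 12]
    gamma_frequency: float = 40.0  # Hz
    theta_phase_offset: float = 0.0  # radians
    mean_rate: float = 40.0  # spikes/s per fiber
    n_fibers: int = 8
    theta_sharpness: float = 6.0  # exponent of the theta envelope
    deterministic: bool = False  # septal pacemaker trains are clock-locked
    seed: int = 0

    def validate(self) -> None:
        if self.source not in ("EC2", "EC3", "septum"):
            raise ValueError(f"unknown drive source {self.source!r}")
        if not (4.0 <= self.theta_frequency <= 12.0):
            raise ValueError("theta_frequency must lie in [4, 12] Hz")
        if not self.gamma_frequency > self.theta_frequency:
            raise ValueError("gamma_frequency must exceed theta_frequency")
        if not self.mean_rate >= 0:
            raise ValueError("mean_rate must be >= 0")


@dataclass
class LTPParams:
    """Potentiation-only Hebbian plasticity (no depression)."""

    learning_rate: float = 0.1
    weight_ceiling: float = 2.0
    coincidence_window: float = 20.0  # ms

    def validate(self) -> None:
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if self.weight_ceiling <= 0:
            raise ValueError("weight_ceiling must be > 0")


@dataclass
class NetworkConfig:
    """Complete, hashable description of one simulation."""

    cells: list[CellModel] = field(default_factory=list)
    synapses: list[SynapseSpec] = field(default_factory=list)
    drives: list[DriveSpec] = field(default_factory=list)
    ltp_params: LTPParams = field(default_factory=LTPParams)
    dt: float = 0.1  # ms
    duration: float = 10000.0  # ms
    seed: int = 0
    #: seed-dependent initial hyperpolarizing offset range (mV); replicate
    #: runs differ only through these initial conditions
    init_perturbation_mv: float = 2.0
    schema_version: int = SCHEMA_VERSION

    def validate(self) -> None:
        if not self.dt > 0:
            raise ValueError("dt must be > 0")
        ids = [c.cell_id for c in self.cells]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate cell_id")
        id_set = set(ids)
        fiber_ids = {
            f"{d.source}:{k}" for d in self.drives for k in range(d.n_fibers)
        }
        for c in self.cells:
            c.validate()
        by_id = {c.cell_id: c for c in self.cells}
        for s in self.synapses:
            s.validate()
            if s.post_cell_id not in id_set:
                raise ValueError(f"synapse onto unknown cell {s.post_cell_id!r}")
            post = by_id[s.post_cell_id]
            if not (0 <= s.post_compartment_index < len(post.compartments)):
                raise ValueError(f"synapse onto invalid compartment of {s.post_cell_id}")
            if s.pre_cell_id not in id_set and s.pre_cell_id not in fiber_ids:
                raise ValueError(f"synapse from unknown source {s.pre_cell_id!r}")
        for d in self.drives:
            d.validate()
            if self.duration < 1000.0 / d.theta_frequency:
                raise ValueError("duration must cover at least one theta period")
        self.ltp_params.validate()

    # -- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        d = dict(d)
        cells = [
            CellModel(
                **{**c, "compartments": [CompartmentParams(**p) for p in c["compartments"]]}
            )
            for c in d.pop("cells")
        ]
        synapses = [SynapseSpec(**s) for s in d.pop("synapses")]
        drives = [DriveSpec(**dr) for dr in d.pop("drives")]
        ltp = LTPParams(**d.pop("ltp_params"))
        return cls(cells=cells, synapses=synapses, drives=drives, ltp_params=ltp, **d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "NetworkConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if d.get("schema_version", 1) != SCHEMA_VERSION:
            raise ValueError(f"unsupported schema_version {d.get('schema_version')}")
        return cls.from_dict(d)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def copy(self) -> "NetworkConfig":
        return NetworkConfig.from_dict(self.to_dict())


@dataclass
class SimulationResult:
    """Output of one network integration.

    ``voltage_traces`` holds the somatic potential of every cell sampled
    every ``dt`` (spike peaks are stamped at +30 mV so threshold crossings
    survive in the trace).  ``spike_times`` are in ms from stimulus onset.
    """

    voltage_traces: dict[str, "np.ndarray"]  # cell_id -> mV array
    spike_times: dict[str, "np.ndarray"]  # cell_id -> sorted ms
    final_weights: list[float]
    config_echo: NetworkConfig
    time: Optional["np.ndarray"] = None  # ms axis, shared by all traces
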