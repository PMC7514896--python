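"""Default 21-cell DG-CA3-CA1 microcircuit.

Cell complement: DG = 4 granule + 2 basket + 1 mossy cell; CA3 and CA1 =
4 pyramidal + 2 basket + 1 O-LM each.  External sources are entorhinal
layer II (EC2, projecting to DG and CA3), layer III (EC3, projecting to
CA1 distal dendrites) and the medial septum (theta-locked GABAergic
pacemaker trains onto interneurons only).

Compartment layout per hippocampal cell (16 compartments): 0 = soma,
1 = axon, 2-8 = proximal dendrite chain, 9-15 = distal dendrite chain.
Perisomatic basket inhibition lands on the soma; O-LM and EC3 inputs on
the distal dendrites; mossy fibers on proximal CA3 dendrites — the
dendritic segregation the circuit's computations rely on.

Quantitative defaults (conductances, rates, weights) were calibrated so
that the control circuit shows theta-locked bursting of principal cells;
all of them live in the pathway tables below.
"""

from __future__ import annotations

import math

from .config import (
    CellModel,
    CompartmentParams,
    DriveSpec,
    LTPParams,
    NetworkConfig,
    SynapseSpec,
)

THETA_HZ = 8.0
GAMMA_HZ = 40.0

# receptor kinetics: (rise ms, decay ms, reversal mV)
RECEPTOR_KINETICS = {
    "AMPA": (0.5, 3.0, 0.0),
    "NMDA": (3.0, 80.0, 0.0),
    "GABA_A": (0.5, 7.0, -75.0),
}

# pathway -> (max_conductance mS/cm², delay ms, plastic)
# NMDA conductance is a fixed fraction of the AMPA one on the same contact.
PATHWAY_GMAX = {
    "EC2_to_DG_granule": (1.1, 2.0, True),
    "EC2_to_CA3_pyramidal": (0.83, 2.0, True),
    "EC2_to_basket": (0.15, 2.0, False),
    "EC3_to_CA1": (0.45, 2.0, True),
    "mossy_fiber": (0.305, 1.5, True),
    "mossy_cell_feedback": (0.12, 1.5, False),
    "schaffer": (0.44, 1.5, True),
    "local_excitation": (0.6, 1.0, False),
    "local_inhibition": (1.3, 1.0, False),
    "septal": (0.9, 1.0, False),
}
NMDA_FRACTION = 0.25
DG_NMDA_FRACTION = 0.05  # granule dendrites: no O-LM opposition in DG

# drive statistics per fiber
EC_MEAN_RATE = 62.0  # spikes/s
EC2_FIBERS_PER_CELL = 4
SEPTAL_CELLS = 9

# compartment targets per pathway (index into the 16-compartment cell)
SOMA, AXON = 0, 1
PROXIMAL = 3
MID = 8
DISTAL = 12
TIP = 14


def _hippocampal_compartments() -> list[CompartmentParams]:
    comps = [
        CompartmentParams(compartment_role="soma", parent=-1, axial_coupling_to_parent=0.0),
        CompartmentParams(compartment_role="axon", parent=0),
    ]
    # proximal chain 2..8 hangs off the soma, distal chain 9..15 continues it
    for i in range(2, 16):
        role = "proximal_dendrite" if i <= 8 else "distal_dendrite"
        parent = 0 if i == 2 else i - 1
        comps.append(CompartmentParams(compartment_role=role, parent=parent))
    return comps


def _cell(cell_id: str, cell_class: str, region: str, thresh_offset: float = 0.0) -> CellModel:
    refrac = 2.0 if cell_class in ("pyramidal", "granule", "mossy") else 1.5
    return CellModel(
        cell_id=cell_id,
        cell_class=cell_class,
        region=region,
        compartments=_hippocampal_compartments(),
        spike_threshold=-50.0 + thresh_offset,
        reset_potential=-72.0,
        refractory_period=refrac,
    )


# fixed per-cell spike-threshold offsets (mV): principal cells are not
# electrically identical, and the spread staggers each cell's response to
# graded denervation instead of moving all cells through it in lockstep
THRESHOLD_SPREAD = (-0.6, -0.2, 0.2, 0.6)


def default_cells() -> list[CellModel]:
    cells = []
    for i in range(1, 5):
        cells.append(_cell(f"G{i}", "granule", "DG", THRESHOLD_SPREAD[i - 1]))
    cells.append(_cell("B1", "basket", "DG"))
    cells.append(_cell("B2", "basket", "DG"))
    cells.append(_cell("MC", "mossy", "DG"))
    for i in range(1, 5):
        cells.append(_cell(f"P{i}", "pyramidal", "CA3", THRESHOLD_SPREAD[i - 1]))
    cells.append(_cell("B3", "basket", "CA3"))
    cells.append(_cell("B4", "basket", "CA3"))
    cells.append(_cell("OLM1", "olm", "CA3"))
    for i in range(5, 9):
        cells.append(_cell(f"P{i}", "pyramidal", "CA1", THRESHOLD_SPREAD[i - 5]))
    cells.append(_cell("B5", "basket", "CA1"))
    cells.append(_cell("B6", "basket", "CA1"))
    cells.append(_cell("OLM2", "olm", "CA1"))
    return cells


def _excitatory(pre, post, comp, tag, gmax_scale=1.0, nmda_fraction=None) -> list[SynapseSpec]:
    """AMPA + NMDA contact pair for one glutamatergic connection."""
    gmax, delay, plastic = PATHWAY_GMAX[tag]
    if nmda_fraction is None:
        nmda_fraction = NMDA_FRACTION
    out = []
    for receptor, g in (("AMPA", gmax), ("NMDA", gmax * nmda_fraction)):
        rise, decay, rev = RECEPTOR_KINETICS[receptor]
        out.append(
            SynapseSpec(
                pre_cell_id=pre,
                post_cell_id=post,
                post_compartment_index=comp,
                receptor=receptor,
                pathway_tag=tag,
                max_conductance=g * gmax_scale,
                rise_time=rise,
                decay_time=decay,
                reversal=rev,
                delay=delay,
                plastic=plastic and receptor == "AMPA",
            )
        )
    return out


def _inhibitory(pre, post, comp, tag, gmax_scale=1.0) -> list[SynapseSpec]:
    gmax, delay, _ = PATHWAY_GMAX[tag]
    gmax = gmax * gmax_scale
    rise, decay, rev = RECEPTOR_KINETICS["GABA_A"]
    return [
        SynapseSpec(
            pre_cell_id=pre,
            post_cell_id=post,
            post_compartment_index=comp,
            receptor="GABA_A",
            pathway_tag=tag,
            max_conductance=gmax,
            rise_time=rise,
            decay_time=decay,
            reversal=rev,
            delay=delay,
        )
    ]


def default_synapses() -> list[SynapseSpec]:
    syns: list[SynapseSpec] = []
    granules = [f"G{i}" for i in range(1, 5)]
    ca3_pyr = [f"P{i}" for i in range(1, 5)]
    ca1_pyr = [f"P{i}" for i in range(5, 9)]
    dg_baskets = ["B1", "B2"]
    ca3_baskets = ["B3", "B4"]
    ca1_baskets = ["B5", "B6"]

    # --- entorhinal layer II (perforant path): DG + CA3, with feedforward
    # inhibition through the basket cells of both regions
    # one contact per target cell per pass, cells interleaved across the
    # three EC2-recipient populations, so that ordered deletion thins the
    # perforant path evenly over cells and pathways
    baskets = dg_baskets + ca3_baskets
    ec2_targets = []
    for i in range(4):
        ec2_targets.append((granules[i], DISTAL, "EC2_to_DG_granule"))
        ec2_targets.append((ca3_pyr[i], DISTAL, "EC2_to_CA3_pyramidal"))
        ec2_targets.append((baskets[i], MID, "EC2_to_basket"))
    fiber = 0
    for _ in range(EC2_FIBERS_PER_CELL):
        for post, comp, tag in ec2_targets:
            nf = DG_NMDA_FRACTION if tag == "EC2_to_DG_granule" else None
            syns += _excitatory(f"EC2:{fiber}", post, comp, tag, nmda_fraction=nf)
            fiber += 1
    n_ec2_fibers = fiber

    # --- entorhinal layer III onto CA1 distal dendrites
    fiber = 0
    for post in ca1_pyr:
        for _ in range(2):
            syns += _excitatory(f"EC3:{fiber}", post, TIP, "EC3_to_CA1")
            fiber += 1
    n_ec3_fibers = fiber

    # --- mossy fibers: granule -> CA3 pyramids (detonator, proximal),
    # CA3 baskets (feedforward inhibition) and the hilar mossy cell
    for g in granules:
        for p in ca3_pyr:
            syns += _excitatory(g, p, PROXIMAL, "mossy_fiber")
        for b in ca3_baskets:
            syns += _excitatory(g, b, PROXIMAL, "mossy_fiber", gmax_scale=0.8)
        syns += _excitatory(g, "MC", PROXIMAL, "mossy_fiber", gmax_scale=0.5)

    # --- mossy cell feedback onto DG
    for g in granules:
        syns += _excitatory("MC", g, PROXIMAL, "mossy_cell_feedback",
                            nmda_fraction=DG_NMDA_FRACTION)
    for b in dg_baskets:
        syns += _excitatory("MC", b, PROXIMAL, "mossy_cell_feedback")

    # --- Schaffer collaterals: CA3 pyramids -> CA1 pyramids + CA1 baskets
    for p in ca3_pyr:
        for q in ca1_pyr:
            syns += _excitatory(p, q, MID, "schaffer")
        for b in ca1_baskets:
            syns += _excitatory(p, b, MID, "schaffer", gmax_scale=0.8)

    # --- local excitation of O-LM cells by the region's pyramids
    for p in ca3_pyr:
        syns += _excitatory(p, "OLM1", MID, "local_excitation")
    for p in ca1_pyr:
        syns += _excitatory(p, "OLM2", MID, "local_excitation", gmax_scale=0.7)

    # --- local inhibition: baskets -> principal somata, O-LM -> distal dendrites
    for b in dg_baskets:
        for g in granules:
            syns += _inhibitory(b, g, SOMA, "local_inhibition")
    for b in ca3_baskets:
        for p in ca3_pyr:
            syns += _inhibitory(b, p, SOMA, "local_inhibition", gmax_scale=0.6)
    for b in ca1_baskets:
        for p in ca1_pyr:
            syns += _inhibitory(b, p, SOMA, "local_inhibition", gmax_scale=0.8)
    for p in ca3_pyr:
        syns += _inhibitory("OLM1", p, TIP - 1, "local_inhibition")
    for p in ca1_pyr:
        syns += _inhibitory("OLM2", p, TIP - 1, "local_inhibition", gmax_scale=0.7)

    # --- septal pacemaker: rhythmic inhibition of interneurons only
    interneurons = dg_baskets + ca3_baskets + ca1_baskets + ["OLM1", "OLM2"]
    for t, post in enumerate(interneurons):
        syns += _inhibitory(f"septum:{t % SEPTAL_CELLS}", post, SOMA, "septal")
    syns += _inhibitory(f"septum:{SEPTAL_CELLS - 1}", "OLM1", SOMA, "septal")

    assert n_ec2_fibers <= 48 and n_ec3_fibers <= 8
    return syns


def default_drives(seed: int = 0) -> list[DriveSpec]:
    """EC2 and EC3 drives in theta antiphase, plus the septal pacemaker."""
    return [
        DriveSpec(
            source="EC2",
            theta_frequency=THETA_HZ,
            gamma_frequency=GAMMA_HZ,
            theta_phase_offset=0.0,
            mean_rate=EC_MEAN_RATE,
            n_fibers=48,
            deterministic=True,
            seed=seed,
        ),
        DriveSpec(
            source="EC3",
            theta_frequency=THETA_HZ,
            gamma_frequency=GAMMA_HZ,
            theta_phase_offset=math.pi,
            mean_rate=EC_MEAN_RATE,
            n_fibers=8,
            deterministic=True,
            seed=seed + 1,
        ),
        DriveSpec(
            source="septum",
            theta_frequency=THETA_HZ,
            gamma_frequency=GAMMA_HZ,
            theta_phase_offset=0.0,
            mean_rate=40.0,
            n_fibers=SEPTAL_CELLS,
            deterministic=True,
            seed=seed + 2,
        ),
    ]


def build_default_network(seed: int = 0, duration: float = 10000.0, dt: float = 0.1) -> NetworkConfig:
    """Assemble the default control-model configuration.

    Parameters
    ----------
    seed
        Master seed; drive trains derive their seeds from it, so the same
        seed reproduces the identical simulation bit-for-bit.
    duration, dt
        Simulated time and integration step, both in ms.
    """
    cfg = NetworkConfig(
        cells=default_cells(),
        synapses=default_synapses(),
        drives=default_drives(seed),
        ltp_params=LTPParams(),
        dt=dt,
        duration=duration,
        seed=seed,
    )
    cfg.validate()
    return cfg


def region_cells(config: NetworkConfig, region: str, principal_only: bool = True) -> list[str]:
    """Cell ids of a region ('DG', 'CA3', 'CA1') or union ('DG-CA3-CA1')."""
    regions = region.split("-")
    out = []
    for c in config.cells:
        if c.region not in regions:
            continue
        if principal_only and c.cell_class not in ("pyramidal", "granule"):
            continue
        out.append(c.cell_id)
    return out
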