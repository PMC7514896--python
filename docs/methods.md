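# Methods

## The model

`trisyn` simulates a 21-cell microcircuit of the hippocampal trisynaptic
pathway.  The dentate gyrus (DG) holds four granule cells, two basket
cells and one hilar mossy cell; CA3 and CA1 each hold four pyramidal
cells, two basket cells and one O-LM interneuron.  Entorhinal cortex
layer II (EC2) drives DG granule cells, CA3 pyramids and the basket
cells of both regions (the perforant path); layer III (EC3) contacts the
distal dendrites of CA1 pyramids; granule-cell mossy fibers contact
proximal CA3 dendrites, CA3 baskets and the mossy cell; Schaffer
collaterals carry CA3 output to CA1 pyramids and baskets; the medial
septum delivers rhythmic GABAergic input to interneurons only,
disinhibiting the principal cells at theta rhythm.

Each cell is a tree of 16 passive compartments (soma, axon stub, a
proximal and a distal dendritic chain) with conductance-based leaky
dynamics, threshold-reset spiking at the soma and an absolute refractory
period.  Membrane parameters: C = 1 µF/cm², g_leak = 0.1 mS/cm²
(τ = 10 ms), E_leak = −65 mV, threshold ≈ −50 mV (±0.6 mV fixed spread
across principal cells — real cells are not electrically identical, and
the spread staggers their response to graded denervation), reset −72 mV.
Axial coupling is 10 mS/cm², making the cells electrotonically compact
enough for distal synapses to drive somatic spiking while preserving the
proximal/distal targeting logic (perisomatic baskets vs. distal
O-LM/EC3).

Synapses are difference-of-exponentials conductances (AMPA 0.5/3 ms,
NMDA 3/80 ms, GABA_A 0.5/7 ms) with the NMDA conductance gated by the
standard magnesium-block sigmoid 1/(1 + [Mg]/3.57·e^(−0.062V)) at
1 mM.  The NMDA share of each glutamatergic contact is 25% of the AMPA
peak, except onto DG granule dendrites (5%): DG has no O-LM cell to
oppose a distal NMDA plateau, and larger shares put the granule cells
into continuous regenerative firing.

Long-term potentiation is potentiation-only and coincidence-gated: when
a cell fires within 20 ms of a presynaptic arrival, that synapse's
weight moves by lr·(1 − w/w_max) toward the ceiling (w_max = 2, lr =
0.1) and never decreases.  The rate is deliberately fast so that the
weights saturate during the settling window (below); weights within
1e−6 of the ceiling snap to it exactly, because an asymptotically
creeping weight adds a spurious slow-divergence signature to the
Lyapunov analysis of an otherwise stationary run.

## Drives

The entorhinal and septal inputs are theta-nested gamma spike trains
(8 Hz theta carrier, 40 Hz gamma, EC3 shifted by π relative to EC2 so
strong input from one coincides with weak input from the other; the
septal pacemaker is in phase with EC2, silencing interneurons during the
excitatory volley and releasing them to terminate the burst).

Two generators implement the same rate contract.  The stochastic one is
an inhomogeneous Poisson process (thinning) under a sharpened theta
envelope times a gamma carrier.  The default is the deterministic
pacemaker: each fiber emits round(rate/θ) spikes per cycle at the gamma
interval, compressed into the theta-on window, with a fixed per-fiber
stagger.  The default study uses the pacemaker because the scientific
target of the study is a *deterministic* chaos transition: with Poisson
drive the divergence statistics of every regime are dominated by the
stochastic noise floor and the measured maximal Lyapunov exponent is
positive even for a perfectly entrained control.  Replicates (seeds)
differ through the initial membrane state (uniform 0–2 mV
hyperpolarizing offsets per compartment), i.e. different trajectories of
the same deterministic system.

## Pathology

Alzheimer's-like degeneration inactivates perforant-path synapses
cumulatively at 9, 18, 26 and 35% (round-half-up of fraction × 96 EC2
synapses), in a deterministic order that interleaves granule, pyramidal
and basket targets so every stage thins the pathway evenly; lower stages
are strict subsets of higher ones, no non-EC2 synapse is ever touched,
and synapse objects are only flagged inactive, never removed.  A seeded
random order is available for sensitivity runs.

## Analysis

* **Burst statistics** — bursts are maximal runs of ≥2 spikes with
  inter-spike intervals below a quarter theta period (31.25 ms);
  reported per cell and averaged (unweighted, NaN-excluded) over the
  principal cells of DG, CA3, CA1 and the cumulative areas DG-CA3-CA1
  and CA3-CA1.  The inter-burst interval runs from burst offset to next
  onset, so duration + IBI ≈ one theta cycle for entrained cells.
* **Analysis signal** — per-cell z-scored somatic voltage averaged over
  a region's principal cells, decimated to 1 ms.  The first 4 s of each
  12 s run (initial transient + LTP saturation) are discarded.
* **Complexity** — delay embedding with delay 20 samples (first minimum
  of the auto mutual information of control region voltage), dimension
  5 (false-nearest-neighbour estimate) and a Theiler window of 150
  samples (more than one theta cycle, so neighbours come from distinct
  cycles).  Correlation dimension by Grassberger–Procaccia with an
  automatically selected scaling region (longest window of <10% local
  slope variation, saturation regime C(r) > 0.25 excluded); recurrence
  entropy as the Shannon entropy (bits) of the diagonal line-length
  histogram at a fixed 10% recurrence rate, ℓ_min = 2, with
  border-truncated lines excluded so a strictly periodic signal scores
  0; maximal Lyapunov exponent by the Rosenstein method.  For the
  Lyapunov fit the informative branch is chosen automatically: if the
  mean log-divergence curve rises by more than 1.5 natural-log units the
  exponent is the growth rate of the rising branch (strong chaos
  saturates within a few samples and a fixed late window would misread
  it as flat); otherwise the signal is non-divergent and the exponent is
  the least-squares slope of the whole curve (≈0 for a torus, negative
  for a contracting limit cycle).
* **Information flow** — spike counts of a region's principal cells in
  20 ms bins, clipped to the alphabet {0, 1, 2, ≥3}; plug-in Shannon
  entropy, mutual information, and Schreiber transfer entropy with three
  bins of history per side.  The 20 ms/third-order state (about half a
  theta cycle) is the smallest at which transfer entropy separates
  genuine feedforward prediction from within-cycle phase-lag artifacts;
  with 10 ms first-order states the direction of the estimate inverts on
  theta-locked data.  Pathology TE is also reported as a percentage of
  the same seed's control TE.  No bias correction is applied by default
  (alphabet and history sizes keep the plug-in bias below 0.01 bits at
  the series lengths used, verified against enumeration-exact values).

## Calibration and what the defaults show

All quantitative parameters live in `network.py` and were calibrated so
the control circuit reproduces the qualitative physiology the study
design assumes: every principal cell bursts once per theta cycle
(median burst duration + IBI within a few percent of the 125 ms theta
period in DG, CA3 and the cumulative areas), and the control dynamics
converge to a stable limit cycle whose measured maximal Lyapunov
exponent is negative, while every deletion stage (9–35%) destabilizes
the cumulative CA3-CA1 and DG-CA3-CA1 voltages into deterministic chaos
with a positive exponent.  Burst trends under progressive deletion are
monotone in DG (fewer spikes, fewer spikes per burst, shorter bursts,
longer intervals); in CA1 the chaotic regime adds irregular off-phase
firing that partially offsets the loss of drive, so the cumulative-area
inter-burst-interval trend is weaker than in DG and can invert — a known
limitation of this implementation, in which burst-trend monotonicity and
the chaos transition trade off against each other through CA1.

## Synthetic benchmarks

The estimator suite is validated without any external data: logistic map
(λ = ln 2 at r = 4, stable period-2 at r = 3.2), Hénon map (D2 ≈ 1.2,
planar), Lorenz system (3-dimensional embedding; decay below ρ = 1),
noisy and incommensurate sines (delay = quarter period, D2 = 1, λ ≈ 0),
and coupled binary processes whose transfer entropy is known exactly by
enumeration (1 − H_b((1+c)/2) forward, 0 backward).  Brute-force
all-pairs correlation sums and exact joint-distribution enumeration act
as independent oracles in the tests.  These fixtures exercise the
estimators, not the biology: passing them shows the estimators are
correct, not that the microcircuit reproduces any particular biological
magnitude.

## Problem sizes

Default study: 12 s simulated time per run at dt = 0.1 ms, five levels
(control + 4) × 10 seeds; analyses use the final 8 s.  These sizes give
estimator standard errors well below the effect sizes of interest while
keeping a full study under a few CPU-minutes; they are the package's
default study conditions, configurable through `ExperimentSpec`.

## Known limitations

Passive compartments only (no active dendritic channels); spiking is
threshold-reset, so spike shape is stereotyped; potentiation-only
plasticity (no depression, by design); 21 cells cannot show population
statistics (cell-to-cell variability enters only through fixed threshold
spread and seeds); the deterministic-drive default means drive
variability is not modelled — the stochastic generator is available but
changes the Lyapunov phenomenology (see above); absolute magnitudes of
the complexity measures depend on embedding and binning choices and only
signs and directions should be compared across studies.
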