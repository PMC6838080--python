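# Methods

## Circuit model

All neurons are conductance-based leaky integrate-and-fire units integrated
by forward Euler at dt = 0.1 ms:

    C_m dv_i/dt = -g_l (v_i - V_l) - g_E_i (v_i - V_E) - g_I_i (v_i - V_I)
                  + I_gap,i + noise

with C_m = 200 pF, g_l = 10 nS (membrane time constant 20 ms), V_l = −60 mV,
V_E = 0 mV, V_I = −80 mV. A spike is emitted when v ≥ −50 mV (inclusive)
and v is reset to V_l; there is no refractory period and no synaptic or
gap-junction transmission delay — spikes of step t raise target
conductances from step t+1. Conductances decay with τ_E = 5 ms and
τ_I = 10 ms; the per-step decay is applied as the exact factor
exp(−dt/τ), which is error-free for pure decay, rather than an Euler
approximation.

Populations (base model): 400 PCs in four orientation subpopulations of
100; 120 PVs (untuned); 120 SSTs in four tuned subpopulations of 30; 50
VIPs (untuned); and a 100-neuron top-down relay population with PC
parameters. Class-level connection probabilities and initial weights follow
measured mouse V1 L2/3 connectivity (`connectivity._P_DEFAULT`,
`_W_DEFAULT`); connections are sampled independently per ordered pair,
autapses excluded. Two entries are drawn per connection from
zero-truncated Gaussians via rejection sampling (PC→PC: N(0.01, 0.01) nS;
SST→PV: N(0.2, 0.1) nS); truncation by redraw, not clipping, so no atom at
zero arises. The V→V entry of the weight matrix is zero, so VIP→VIP
connections are sampled but carry no weight.

### Gap junctions

PVs are coupled all-to-all (topology not otherwise constrained by data):
each PV spike increments every other PV's spikelet current by
c_gap = 13 pA; spikelet currents decay with τ_spikelet = 9 ms, so one spike
delivers a total charge c_gap·τ_spikelet = 117 pA·ms. A subthreshold
coupling term w_gap Σ_j (v_j − v_i) with w_gap = 0.4 nS is implemented but
disabled by default (`w_gap=0`); when enabled it is evaluated inside the
membrane integration on the pre-update potentials, since it is part of the
membrane equation.

### Membrane noise

The stochastic term is discretised as an additive white voltage increment
per step with amplitude sqrt(σ²(1 − α²)), α = 1 − dt·g_l/C_m, so that the
stationary voltage s.d. of the leak-only membrane is exactly σ = 2 mV and
the fluctuations inherit the 20 ms membrane correlation time. Rationale:
the noise term of the membrane equation is dimensionally ambiguous as
printed; read literally as a voltage-rate with amplitude sqrt(2σ²/τ_noise),
τ_noise = 5 ms, it yields a stationary s.d. of ≈ 4 mV — twice the printed
σ. We take σ to be the intended stationary membrane fluctuation amplitude;
with this reading the developmental clustering, reward-phase inhibitory
structure, and refinement-phase retuning all reproduce at both full and
scaled-down protocol durations, while the doubled-noise reading obscures
the refinement-phase effects behind elevated spontaneous firing. τ_noise is
retained in `NoiseParams` as metadata only. The noise test asserts the
empirical stationary s.d. of this documented discretisation (= σ) within
5%.

## Inputs (synthetic-data generator)

Stimuli are four discrete orientations on a fixed 70 ms cycle: 50 ms
stimulus, 20 ms gap. Each orientation has one layer-4 channel: a single
Poisson process at 4 kHz while its stimulus is shown, 0 Hz during other
stimuli, and 1.6 kHz during every gap. The channel's spikes fan out
identically to its 100 tuned PCs (0.28 nS) and 30 tuned SSTs (0.15 nS
during the stimulus, 0.165 nS during the gap — the efficacy switches with
the stimulus clock). Because each channel is one shared process, same-tuned
neurons receive strongly correlated drive; this synchrony is part of the
model, not an artifact. PCs and PVs additionally receive independent
per-neuron 4 kHz baseline Poisson drive (0.13 nS and 0.01 nS). VIPs receive
no external drive outside the reward pathway.

The reward pathway: the relay population receives the rewarded
(vertical-bar) channel at 0.3 nS only while that stimulus is on screen
during the rewarded phase, and projects to every VIP at 0.2 nS (connection
probability 1). The top-down signal is untuned; its stimulus specificity
arises purely from temporal coincidence.

What the generator emulates: orientation-tuned feedforward drive with
stimulus-locked timing, stimulus gaps, and a reward-gated neuromodulatory
pathway. What it does not: continuous orientation space, contrast, drifting
gratings, adaptation, trial-to-trial gain fluctuations, or realistic
afferent-count variability (each channel is one process, not ~100
afferents). Passing tests therefore demonstrate the circuit mechanism under
idealised, strongly stimulus-locked input statistics, not performance on
physiological spike trains.

## Plasticity

Classical pair-based STDP with all-to-all spike pairing via per-neuron
exponential traces (τ+ = τ− = 20 ms): on a presynaptic spike
w → clip(w − η·a_post); on a postsynaptic spike w → clip(w + η·a_pre);
afterwards the spiking neuron's own trace increments by A+ (pre) or A−
(post). A− = 1.05·A+, so uncorrelated activity drifts toward depression.
Excitatory pathway (PC→PC): A+ = 0.005 nS, bounds [0, 0.25] nS. Inhibitory
pathway (SST→PV): A+ = 0.015 nS, bounds [0, 1] nS. η = 1 in the
full-duration protocol.

Numerical conventions: hard bounds are applied per update (clipping).
When a connection's pre and post neurons spike in the same 0.1 ms step,
the pairing is treated as Δt = 0, which belongs to the potentiation branch:
the two trace updates use the partner traces *excluding* the same-step
increments, plus an explicit +η·A+ for the simultaneous pair. With bounds
disabled this makes the online rule equal the brute-force all-pairs kernel
sum to machine precision (the oracle-equivalence test pins this down).
Traces are per-neuron, shared by all of a neuron's plastic synapses, and
restart at zero at phase boundaries (the 20 ms trace memory is negligible
against phase durations).

## Protocol

Phases (base model): pre-probe (1.4 s, balanced stimuli, plasticity off) →
developmental (42 s, random stimuli; PC→PC and SST→PV plastic; no reward) →
post-development probe → rewarded (24.5 s, top-down pathway active) →
mid-probe → refinement (66 s, no reward) → post-probe. All probes replay
one identical balanced 20-cycle schedule with identical input and noise
streams, so probe-to-probe response differences reflect circuit changes
only. The post-development probe is the baseline for all "before vs after
learning" comparisons, since the developmental phase merely brings the
random initial circuit to its adult operating point. Probes never change
weights (verified bit-exactly).

Randomness is organised as named streams (connectivity, schedules, inputs,
noise, probe-inputs, probe-noise) spawned from one master seed;
(seed, config) fully determines every spike and weight. The numba-compiled
inner loop and the vectorised numpy reference backend consume identical
pre-drawn random blocks and agree to floating-point summation order.

### Scaled-down preset

`ProtocolConfig.desk`: learning-phase durations divided by 4 (floored to
whole 70 ms cycles: 10.5 s / 6.09 s / 16.45 s) with learning rate η = 2;
probes stay at 1.4 s since 5 cycles cannot balance 4 stimuli. The
directional outcomes (which weight groups separate, which responses grow)
are preserved at this scale and it is the default for tests and the
acceptance script. STDP drift scales roughly linearly in rate × time, but
structure formation is self-reinforcing, so scaled runs reach weaker
absolute weights; conclusions drawn at desk scale are directional, never
about magnitudes.

## Translation-invariance variant

A second set of 4 × 100 PCs represents a second visual-field location; the
single PV/SST/VIP network serves both PC sets (interneurons are spatially
broad), SSTs receive the L4 channels of both locations, and PC→interneuron
strengths are scaled by 0.6 to compensate for the doubled PC count per
interneuron. There are no PC→PC connections across locations; any transfer
of the learned preference must flow through the shared interneurons.
Reward is paired only with the vertical bar at location 0.

Presentation is interleaved: each 70 ms cycle shows one stimulus at one
location (drawn uniformly), with the other location's channels fully
silent. Simultaneous independent presentation at both locations was tried
first and rejected: it doubles every SST's feedforward drive, collapses PC
stimulus responses, and destroys the transfer. Interleaving keeps every
interneuron's drive at base-model statistics. Probes are lengthened in
proportion to the location count (2.8 s) so each (location, stimulus) pair
keeps five measurement windows.

The unshared-interneuron control duplicates the full PV/SST/VIP set per
location at original (unscaled) PC→interneuron strengths, each pool seeing
and serving only its own location; the relay still projects to all VIPs.
In this control each SST pool is silent during the other location's cycles
while its PV pool keeps firing, which drives the SST→PV weights toward the
lower bound and globally disinhibits both PC sets — response magnitudes
therefore grow generically. The reward-specific transfer measure is
consequently the *vertical tuning index* (response to vertical minus mean
response to the other stimuli) of the non-vertically-tuned subpopulations
at the non-rewarded location: with shared interneurons its
post-refinement-minus-post-development gain is strongly positive; in the
control it falls below half the shared value.

## Analysis definitions

- **Tuning curve**: mean spike count per neuron in the 50 ms window after
  each stimulus onset, averaged over all occurrences of that stimulus in
  the probe. Zero-occurrence stimuli are flagged NaN, never reported as 0.
- **Tuning index toward stimulus s**: response to s minus the mean response
  to the other stimuli.
- **Grouped weight trajectories**: mean and population s.d. (divisor n)
  over the fixed member-connection set of each group at every snapshot
  (500 ms cadence). PC→PC groups: vert→vert / vert→other / other→vert /
  other→other relative to the rewarded orientation; SST→PV groups: by the
  presynaptic SST's tuning.
- **Synaptic currents** of sampled PCs (5 per subpopulation): positive
  magnitudes E = g_E(V_E − v), I = g_I(v − V_I) in pA, recorded per step
  during probes and averaged over stimulus windows; E/I is NaN where I = 0.
- **Predictions suite** (evaluated post-development vs after-reward vs
  after-refinement): (1) pooled PC vertical tuning index up; (2) PV index
  down after reward AND up after refinement; (3) SST vertical response up
  (sign only — no magnitude is specified); (4) VIP tuning unchanged,
  operationalised as |index change| < max(25% of the mean VIP response,
  0.05 spikes/window) since VIPs are nearly silent outside reward;
  (5)/(6) mean PC/PV rate gain for the vertical bar exceeds the mean gain
  for other stimuli; (7) mean E and I currents during the vertical bar both
  up; (8) at least one sampled PC increases its E/I ratio. Directional
  predictions are reported per seed; a claim "holds" only if consistent
  across all seeds.

## Known limitations and deviations

- Some directional PC→PC asymmetry (vert→other over other→vert) already
  forms during the rewarded phase (about 60% of its final value in pooled
  desk runs): the onset volley of vertically tuned PCs precedes the
  VIP-mediated interneuron rebalancing within each rewarded stimulus, so
  stray spikes of other PCs late in the window potentiate vert→other.
  This co-development regime is a known possibility of the model family;
  in this implementation it is not fully suppressed.
- The vertically tuned PC subpopulation's own vertical response declines
  from its post-development value: once PVs become vertical-tuned their
  added inhibition outweighs that subpopulation's recurrent gain. The other
  three subpopulations' vertical responses rise strongly, which is the core
  representational change.
- SST→PV weights of the rewarded group partially decay during refinement
  rather than strengthening further: SSTs causally inhibit PVs, so their
  within-window pairing is depression-leaning once the reward-driven PV
  elevation is gone. The stored structure nonetheless remains several-fold
  above the other groups throughout.
- Point neurons only: SST and PV inputs are not segregated onto dendritic
  versus somatic compartments.
- The discrete 4-orientation stimulus space cannot express tuning-curve
  broadening, only response re-weighting among the four stimuli.
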