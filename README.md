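# v1plasticity

A spiking-network model of how reward reshapes stimulus representations in
layer 2/3 of mouse primary visual cortex, in two stages: the reward first
writes a memory into the *inhibitory* circuitry (SST→PV connections), and
that inhibitory structure later instructs *excitatory* plasticity after the
reward is gone.

The package is for computational neuroscientists who want to simulate,
probe, or extend the microcircuit mechanism: it provides the full circuit
(pyramidal cells plus PV, SST and VIP interneurons), the plasticity rule,
the stimulation protocol, the analysis metrics, and a CLI.

## Model

Neurons are conductance-based leaky integrate-and-fire units,

```
C_m dv/dt = -g_l (v - V_l) - g_E (v - V_E) - g_I (v - V_I) + I_gap + noise
```

with C_m = 200 pF, g_l = 10 nS, V_l = −60 mV, V_E = 0 mV, V_I = −80 mV,
threshold −50 mV (reset to V_l). Synaptic conductances jump by the synaptic
weight W_ij on presynaptic spikes and decay with τ_E = 5 ms, τ_I = 10 ms.
PV cells are electrically coupled: each PV spike adds a 13 pA spikelet
current to its partners, decaying with τ = 9 ms.

The circuit contains 400 pyramidal cells (PCs, four orientation
subpopulations of 100), 120 PVs, 120 SSTs (4 × 30, orientation tuned), and
50 VIPs, wired with measured mouse-V1 connection probabilities and
strengths. Four layer-4 Poisson channels (4 kHz during their preferred
50 ms stimulus, 1.6 kHz during 20 ms stimulus gaps) drive the tuned PCs and
SSTs; PCs and PVs get 4 kHz baseline Poisson input.

Two pathways are plastic under classical pair-based STDP with
pre/postsynaptic traces (τ± = 20 ms, A− = 1.05 A+): the recurrent PC→PC
synapses (A+ = 0.005 nS, bound 0.25 nS) and the SST→PV synapses
(A+ = 0.015 nS, bound 1 nS). Pre-before-post (or simultaneous) pairings
potentiate; post-before-pre pairings depress.

The protocol: a tuning probe, a 42 s developmental phase (orientation
clusters form among PCs), a 24.5 s rewarded phase in which a top-down relay
pathway excites VIPs whenever the vertical bar is shown, a 66 s reward-free
refinement phase, and a final probe. During reward, VIPs silence the SSTs
and thereby disinhibit the PVs; the vertical-tuned SSTs' onset volleys pair
with the elevated PV firing and potentiate selectively. Afterwards, that
SST→PV structure silences PVs whenever the vertical bar appears, opening a
disinhibition window in which PC→PC plasticity grows connections from
vertically tuned PCs onto the rest of the network.

## Worked example

The `desk` preset runs the protocol at a quarter of the published phase
durations with a doubled learning rate (~30 s of wall time):

```python
from v1plasticity import ProtocolConfig, run_full_protocol

result = run_full_protocol(ProtocolConfig.desk(seed=1))
s = result.summary
print("SST->PV group means (nS) at end of rewarded phase:")
for grp, m in s["S->P_group_means_end_rewarded"].items():
    print(f"  {grp}: {m:.3f}")
```

```
SST->PV group means (nS) at end of rewarded phase:
  SST0->PV: 0.607
  SST1->PV: 0.168
  SST2->PV: 0.131
  SST3->PV: 0.054
```

Group 0 is the vertically tuned (rewarded) SST subpopulation: its
connections onto PVs have grown three- to tenfold above the other groups —
the inhibitory memory of the reward. The PV tuning curves show its effect:

```python
print(s["pv_curve_mid_probe"])   # after the rewarded phase
print(s["pv_curve_post_probe"])  # after refinement
```

```
0.000  0.002  0.008  0.008     # PVs are silenced by the vertical bar
0.470  0.303  0.328  0.242     # after refinement they fire most for it
```

(spikes per 50 ms stimulus window, stimuli 0–3; stimulus 0 is the vertical
bar). After the rewarded phase PVs respond *least* to the vertical bar —
they are being suppressed through the new SST→PV connections. After
refinement the excitatory structure (mean PC-vertical→PC-other weight
0.119 nS versus 0.016 nS in the reverse direction) drives them hardest for
the vertical bar. The eight testable predictions are evaluated in
`s["predictions"]`; all eight hold in this run.

## Command line

```bash
v1plasticity simulate --preset desk --seed 1 --outdir out/
v1plasticity simulate --preset desk --seed 1 --no-reward --outdir out_ctrl/
v1plasticity simulate-translation --preset desk --seed 1 --outdir out_tr/
v1plasticity simulate-translation --unshared-interneurons ...
```

Outputs: spike rasters, stimulus schedules, grouped weight trajectories
(CSV) and a JSON summary per run. `--preset paper` runs the full-duration
protocol; `--config file.json` overrides any `ProtocolConfig` field.

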