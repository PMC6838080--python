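"""Assembled microcircuit and the clock-driven simulation loop.

The base circuit holds 400 PCs (four orientation subpopulations of 100),
120 PVs, 120 SSTs (four subpopulations of 30), 50 VIPs and a 100-neuron
top-down relay population, laid out contiguously in one index space.  All
chemical synapses live in a dense weight matrix ``W[post, pre]``; spike
delivery sums the columns of this step's spiking neurons into g_E or g_I.
The PC->PC and SST->PV blocks are plastic (online trace STDP with hard
bounds); PVs are electrically coupled all-to-all by spikelet currents.

The two-location (translation-invariance) variant adds a second set of
4 x 100 PCs with its own stimulus location.  With shared interneurons the
single PV/SST/VIP set serves both PC sets, SSTs receive L4 input from both
locations, and PC->interneuron strengths are scaled by 0.6; the unshared
control duplicates the interneuron set per location at original strengths.

Each step (dt = 0.1 ms): integrate membranes (noise included) -> threshold &
reset -> gap-junction spikelets -> synaptic delivery -> STDP updates on
gated pathways -> external L4/baseline/top-down input -> recorders.  Spikes
of step t therefore affect conductances from step t+1 (no transmission
delays).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import connectivity as conn
from . import core, plasticity, stimulation

__all__ = ["Circuit", "PlasticPathway", "PhaseRecording", "build_circuit", "run_phase"]

_BLOCK_STEPS = 2000  # RNG draws are batched in blocks of this many steps


@dataclass
class PlasticPathway:
    """A plastic dense block of W with its own STDP parameters."""

    name: str
    post_slice: slice
    pre_slice: slice
    mask: np.ndarray  # bool (n_post, n_pre)
    params: plasticity.STDPParams


@dataclass
class ChannelWiring:
    """One L4 channel: which subpopulations its spikes fan out to."""

    location: int
    channel_id: int
    pc_idx: slice | None
    sst_idx: list
    feeds_relay: bool = False


@dataclass
class Circuit:
    populations: list[core.PopulationSpec]
    slices: dict[str, slice]
    n: int
    state: core.NetworkState
    W: np.ndarray
    groups: list[conn.SynapseGroup]
    pathways: list[PlasticPathway]
    neuron_params: core.NeuronParams
    noise_params: core.NoiseParams
    gap_params: core.GapJunctionParams
    input_spec: stimulation.InputChannelSpec
    topdown: stimulation.TopDownSpec
    is_exc: np.ndarray
    pv_slices: list
    channels: list
    baseline_targets: list  # (slice, weight) pairs
    relay_slice: slice | None
    n_locations: int = 1
    # STDP traces (shared per neuron across pathways) and their increments
    a_pre: np.ndarray = field(default=None)
    a_post: np.ndarray = field(default=None)
    inc_pre: np.ndarray = field(default=None)
    inc_post: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        if self.a_pre is None:
            self.a_pre = np.zeros(self.n)
            self.a_post = np.zeros(self.n)
        if self.inc_pre is None:
            self.inc_pre = np.zeros(self.n)
            self.inc_post = np.zeros(self.n)
            for pw in self.pathways:
                self.inc_pre[pw.pre_slice] = pw.params.A_plus
                self.inc_post[pw.post_slice] = pw.params.A_minus

    def population_table(self) -> pd.DataFrame:
        """Per-neuron (id, population, cell_class, tuning, location) table."""
        rows = []
        for p in self.populations:
            sl = self.slices[p.name]
            labels = (p.tuning_labels if p.tuning_labels is not None
                      else np.full(p.size, -1))
            for k, i in enumerate(range(sl.start, sl.stop)):
                rows.append((i, p.name, p.cell_class, int(labels[k]),
                             p.location_id))
        return pd.DataFrame(rows, columns=["neuron_id", "population",
                                           "cell_class", "tuning", "location"])

    def connection_counts(self) -> pd.DataFrame:
        """Realised connection counts per pathway (for the run log)."""
        rows = [(g.pre_pop.name, g.post_pop.name, g.n_connections,
                 g.plastic) for g in self.groups]
        return pd.DataFrame(rows, columns=["pre", "post", "n_connections",
                                           "plastic"])

    def pathway_weights(self, name: str) -> np.ndarray:
        for pw in self.pathways:
            if pw.name == name:
                return self.W[pw.post_slice, pw.pre_slice]
        raise KeyError(name)

    def pathway(self, name: str) -> PlasticPathway:
        for pw in self.pathways:
            if pw.name == name:
                return pw
        raise KeyError(name)


def _tuned_labels(n: int, per_group: int) -> np.ndarray:
    return np.repeat(np.arange(4), per_group)[:n]


def build_circuit(
    rng: np.random.Generator,
    *,
    n_locations: int = 1,
    shared_interneurons: bool = True,
    eta: float = 1.0,
    reward_enabled: bool = True,
    w_gap: float = 0.0,
    spec: conn.ConnectivitySpec | None = None,
    input_spec: stimulation.InputChannelSpec | None = None,
    topdown: stimulation.TopDownSpec | None = None,
) -> Circuit:
    """Sample and wire a circuit instance.

    ``n_locations=1`` is the base model; ``n_locations=2`` the
    translation-invariance variant (shared interneurons scale PC->interneuron
    weights by 0.6; the unshared control keeps original strengths with one
    interneuron set per location).
    """
    if spec is None:
        spec = conn.default_connectivity()
    input_spec = input_spec or stimulation.InputChannelSpec()
    topdown = topdown or stimulation.TopDownSpec(enabled=reward_enabled)
    if not reward_enabled:
        topdown = stimulation.TopDownSpec(
            relay_size=topdown.relay_size,
            w_l4_to_relay=topdown.w_l4_to_relay,
            w_relay_to_vip=topdown.w_relay_to_vip,
            rewarded_stimulus_id=topdown.rewarded_stimulus_id,
            enabled=False,
        )

    pops: list[core.PopulationSpec] = []
    if n_locations == 1:
        pops.append(core.PopulationSpec("E", "E", 400, _tuned_labels(400, 100), 0))
        int_sets = [(None, 0)]  # (suffix, location) with None = shared
    else:
        pops.append(core.PopulationSpec("E0", "E", 400, _tuned_labels(400, 100), 0))
        pops.append(core.PopulationSpec("E1", "E", 400, _tuned_labels(400, 100), 1))
        int_sets = [(None, -1)] if shared_interneurons else [("0", 0), ("1", 1)]
        if shared_interneurons:
            spec = spec.scale_pc_to_interneurons(0.6)
    for suffix, loc in int_sets:
        tag = suffix or ""
        pops.append(core.PopulationSpec(f"P{tag}", "P", 120, None, loc))
        pops.append(core.PopulationSpec(f"S{tag}", "S", 120, _tuned_labels(120, 30), loc))
        pops.append(core.PopulationSpec(f"V{tag}", "V", 50, None, loc))
    relay = core.PopulationSpec("relay", "relay", topdown.relay_size, None, -1)
    pops.append(relay)

    slices: dict[str, slice] = {}
    start = 0
    for p in pops:
        slices[p.name] = slice(start, start + p.size)
        start += p.size
    n = start

    def exclude(post: core.PopulationSpec, pre: core.PopulationSpec) -> bool:
        # cross-location pairs never connect; shared interneurons carry
        # location -1 and connect to everything
        if post.location_id < 0 or pre.location_id < 0:
            return False
        return post.location_id != pre.location_id

    groups = conn.sample_connectivity(
        spec, pops, rng,
        offsets={p.name: slices[p.name].start for p in pops},
        exclude=exclude,
    )
    groups = conn.initialize_weights(groups, spec, rng)

    # reward relay -> all VIPs, connection probability 1, fixed weight
    relay_sl = slices["relay"]
    for p in pops:
        if p.cell_class != "V":
            continue
        vsl = slices[p.name]
        post_loc, pre_loc = np.mgrid[0:p.size, 0:relay.size]
        groups.append(conn.SynapseGroup(
            pre_pop=relay, post_pop=p,
            pre_idx=pre_loc.ravel() + relay_sl.start,
            post_idx=post_loc.ravel() + vsl.start,
            w=np.full(p.size * relay.size, topdown.w_relay_to_vip),
            sign="exc", plastic=False,
        ))

    W, _ = conn.assemble_dense(groups, n)

    # plastic pathway blocks (contiguous slices of W)
    pathways: list[PlasticPathway] = []
    exc_params = plasticity.excitatory_stdp(eta)
    inh_params = plasticity.inhibitory_stdp(eta)
    for g in groups:
        if not g.plastic:
            continue
        post_sl = slices[g.post_pop.name]
        pre_sl = slices[g.pre_pop.name]
        mask = np.zeros((post_sl.stop - post_sl.start,
                         pre_sl.stop - pre_sl.start), dtype=bool)
        mask[g.post_idx - post_sl.start, g.pre_idx - pre_sl.start] = True
        key = (g.post_pop.cell_class, g.pre_pop.cell_class)
        params = exc_params if key == ("E", "E") else inh_params
        pathways.append(PlasticPathway(
            name=f"{g.pre_pop.name}->{g.post_pop.name}",
            post_slice=post_sl, pre_slice=pre_sl, mask=mask, params=params,
        ))

    is_exc = np.zeros(n, dtype=bool)
    pv_slices = []
    for p in pops:
        if p.cell_class in ("E", "relay"):
            is_exc[slices[p.name]] = True
        if p.cell_class == "P":
            pv_slices.append(slices[p.name])

    # L4 channel fan-out
    channels: list[ChannelWiring] = []
    for loc in range(n_locations):
        e_name = "E" if n_locations == 1 else f"E{loc}"
        esl = slices[e_name]
        for c in range(4):
            pc_idx = slice(esl.start + 100 * c, esl.start + 100 * (c + 1))
            sst_idx = []
            for p in pops:
                if p.cell_class != "S":
                    continue
                if p.location_id >= 0 and p.location_id != loc:
                    continue  # unshared SST set of the other location
                ssl = slices[p.name]
                sst_idx.append(slice(ssl.start + 30 * c, ssl.start + 30 * (c + 1)))
            channels.append(ChannelWiring(
                location=loc, channel_id=c, pc_idx=pc_idx, sst_idx=sst_idx,
                feeds_relay=(loc == 0 and c == topdown.rewarded_stimulus_id),
            ))

    baseline_targets = []
    for p in pops:
        if p.cell_class == "E":
            baseline_targets.append((slices[p.name], input_spec.baseline_w_pc))
        elif p.cell_class == "P":
            baseline_targets.append((slices[p.name], input_spec.baseline_w_pv))

    gap = core.GapJunctionParams(
        w_gap=w_gap,
        pv_indices=np.arange(pv_slices[0].start, pv_slices[0].stop)
        if len(pv_slices) == 1 else None,
    )
    if w_gap > 0 and len(pv_slices) != 1:
        raise ValueError("subthreshold gap coupling supports one PV pool only")

    return Circuit(
        populations=pops, slices=slices, n=n,
        state=core.NetworkState.zeros(n),
        W=W, groups=groups, pathways=pathways,
        neuron_params=core.NeuronParams(),
        noise_params=core.NoiseParams(),
        gap_params=gap,
        input_spec=input_spec, topdown=topdown,
        is_exc=is_exc, pv_slices=pv_slices,
        channels=channels, baseline_targets=baseline_targets,
        relay_slice=relay_sl, n_locations=n_locations,
    )


@dataclass
class PhaseRecording:
    """Everything recorded during one protocol phase."""

    name: str
    t0: float
    duration: float
    dt: float
    schedules: list
    spike_times: np.ndarray  # ms, phase-relative
    spike_ids: np.ndarray
    weight_snapshot_times: np.ndarray
    weight_snapshots: dict  # pathway name -> (k, n_post, n_pre) float32
    current_sample: np.ndarray | None = None
    current_E: np.ndarray | None = None  # (n_steps, k) pA, float32
    current_I: np.ndarray | None = None
    saturation: dict | None = None  # pathway -> fraction at bounds at end

    @property
    def schedule(self) -> stimulation.StimulusSchedule:
        return self.schedules[0]

    def raster_frame(self, pop_table: pd.DataFrame) -> pd.DataFrame:
        df = pd.DataFrame({"neuron_id": self.spike_ids,
                           "time_ms": self.spike_times})
        return df.merge(pop_table[["neuron_id", "population"]], on="neuron_id")




def _plastic_arrays(circuit: Circuit) -> tuple[np.ndarray, np.ndarray]:
    """Global plastic-connection mask and per-postsynaptic-neuron bound.

    The two plastic pathways have disjoint postsynaptic classes (PCs for
    PC->PC, PVs for SST->PV), so the upper weight bound can be stored per
    postsynaptic neuron.  Cached on the circuit.
    """
    if not hasattr(circuit, "_M"):
        M = np.zeros((circuit.n, circuit.n), dtype=np.uint8)
        wmax_post = np.zeros(circuit.n)
        for pw in circuit.pathways:
            sub = M[pw.post_slice, pw.pre_slice]
            sub[pw.mask] = 1
            wmax_post[pw.post_slice] = pw.params.w_max
        circuit._M = M
        circuit._wmax_post = wmax_post
    return circuit._M, circuit._wmax_post


def run_phase(
    circuit: Circuit,
    schedules,
    *,
    plastic: bool,
    rewarded: bool = False,
    rng_inputs: np.random.Generator,
    rng_noise: np.random.Generator,
    dt: float = 0.1,
    snapshot_cadence_ms: float = 500.0,
    current_sample: np.ndarray | None = None,
    name: str = "phase",
    backend: str = "auto",
) -> PhaseRecording:
    """Simulate one protocol phase; mutates the circuit state and weights.

    ``schedules`` is one StimulusSchedule per stimulus location (cycles are
    time-aligned across locations).  ``plastic`` gates the STDP updates;
    ``rewarded`` gates the top-down relay drive.  Spikes, periodic plastic
    weight snapshots and (optionally) per-step E/I synaptic currents of
    ``current_sample`` neurons are recorded.

    ``backend`` is 'numba' (compiled inner loop), 'numpy' (vectorised
    reference loop) or 'auto'.  Both consume identical random streams; they
    agree to floating-point summation order.
    """
    from . import _kernel

    if backend == "auto":
        use_numba = _kernel.HAVE_NUMBA
    elif backend == "numba":
        if not _kernel.HAVE_NUMBA:
            raise RuntimeError("numba backend requested but numba is missing")
        use_numba = True
    elif backend == "numpy":
        use_numba = False
    else:
        raise ValueError(f"unknown backend {backend!r}")

    if isinstance(schedules, stimulation.StimulusSchedule):
        schedules = [schedules]
    if len(schedules) != circuit.n_locations:
        raise ValueError("need one schedule per stimulus location")
    durations = {s.duration for s in schedules}
    if len(durations) != 1:
        raise ValueError("schedules must have equal duration")
    duration = durations.pop()
    n_steps = int(round(duration / dt))

    prm = circuit.neuron_params
    gap = circuit.gap_params
    ins = circuit.input_spec
    st = circuit.state
    t0 = st.t

    # ---- per-step stimulus context and pre-drawn channel counts
    stim_ids = np.stack([s.step_arrays(dt)[0] for s in schedules])  # (L, n)
    in_stim = schedules[0].step_arrays(dt)[1]
    ch_loc = np.array([c.location for c in circuit.channels])
    ch_id = np.array([c.channel_id for c in circuit.channels])
    active = stim_ids[ch_loc, :] == ch_id[:, None]
    loc_on = stim_ids[ch_loc, :] >= 0  # -1 marks an inactive location's cycle
    lam = np.where(in_stim[None, :],
                   np.where(active, ins.rate_preferred, ins.rate_nonpreferred),
                   np.where(loc_on, ins.rate_gap, 0.0)) * dt
    ch_counts = rng_inputs.poisson(lam)
    w_sst_arr = np.where(in_stim, ins.w_to_sst_stim, ins.w_to_sst_gap)
    reward_gate = np.zeros(n_steps, dtype=bool)
    if rewarded and circuit.topdown.enabled:
        reward_gate = in_stim & (stim_ids[0] == circuit.topdown.rewarded_stimulus_id)

    # ---- static wiring arrays
    ch_pc_start = np.array([c.pc_idx.start for c in circuit.channels])
    ch_pc_stop = np.array([c.pc_idx.stop for c in circuit.channels])
    for c in circuit.channels:
        if len(c.sst_idx) != 1:
            raise AssertionError("each channel feeds exactly one SST slice")
    ch_sst_start = np.array([c.sst_idx[0].start for c in circuit.channels])
    ch_sst_stop = np.array([c.sst_idx[0].stop for c in circuit.channels])
    ch_feeds_relay = np.array([c.feeds_relay for c in circuit.channels])
    base_idx = np.concatenate([np.arange(sl.start, sl.stop)
                               for sl, _ in circuit.baseline_targets])
    base_w = np.concatenate([np.full(sl.stop - sl.start, w)
                             for sl, w in circuit.baseline_targets])
    n_base = base_idx.size
    base_lam = ins.baseline_rate * dt
    pv_bounds = np.array([[sl.start, sl.stop] for sl in circuit.pv_slices],
                         dtype=np.int64)

    noise_amp = circuit.noise_params.step_amplitude(dt, prm.tau_m)
    decay_E = np.exp(-dt / prm.tau_E)
    decay_I = np.exp(-dt / prm.tau_I)
    decay_spk = np.exp(-dt / gap.tau_spikelet)
    c_over = dt / prm.C_m
    if circuit.pathways:
        etas = {pw.params.eta for pw in circuit.pathways}
        taus = {(pw.params.tau_plus, pw.params.tau_minus)
                for pw in circuit.pathways}
        if len(etas) != 1 or len(taus) != 1:
            raise AssertionError("pathways must share eta and trace taus")
        eta = etas.pop()
        tau_p, tau_m = taus.pop()
        if tau_p != tau_m:
            raise AssertionError("shared-trace decay assumes tau_plus == tau_minus")
        decay_trace = np.exp(-dt / tau_p)
    else:
        eta, decay_trace = 1.0, 1.0
    M, wmax_post = _plastic_arrays(circuit)

    # traces restart at each phase boundary
    circuit.a_pre[:] = 0.0
    circuit.a_post[:] = 0.0

    v, gE, gI, Isp = st.v, st.g_E, st.g_I, st.I_spikelet
    a_pre, a_post = circuit.a_pre, circuit.a_post
    W = circuit.W
    is_exc = circuit.is_exc
    relay_sl = circuit.relay_slice

    # ---- recording buffers
    snap_every = max(1, int(round(snapshot_cadence_ms / dt)))
    snap_times: list[float] = []
    snaps: dict[str, list[np.ndarray]] = {pw.name: [] for pw in circuit.pathways}

    def _snapshot(k: int) -> None:
        snap_times.append(k * dt)
        for pw in circuit.pathways:
            snaps[pw.name].append(
                W[pw.post_slice, pw.pre_slice].astype(np.float32))

    rec_cur = current_sample is not None
    if rec_cur:
        current_sample = np.asarray(current_sample, dtype=np.int64)
        cE = np.empty((n_steps, current_sample.size), dtype=np.float32)
        cI = np.empty((n_steps, current_sample.size), dtype=np.float32)
        cur_idx = current_sample
    else:
        cE = cI = np.zeros((1, 1), dtype=np.float32)
        cur_idx = np.zeros(1, dtype=np.int64)

    cap = max(1_000_000, 4 * n_steps)
    spk_steps = np.empty(cap, dtype=np.int64)
    spk_ids = np.empty(cap, dtype=np.int64)
    n_spk = 0

    edges = sorted({0, n_steps}
                   | set(range(0, n_steps, _BLOCK_STEPS))
                   | set(range(0, n_steps, snap_every)))

    _snapshot(0)
    for k0, k1 in zip(edges[:-1], edges[1:]):
        m = k1 - k0
        noise_block = rng_noise.standard_normal((m, circuit.n))
        base_block = rng_inputs.poisson(base_lam, (m, n_base))
        if n_spk + m * 64 > spk_steps.size:  # grow spike buffers
            spk_steps = np.resize(spk_steps, 2 * spk_steps.size)
            spk_ids = np.resize(spk_ids, 2 * spk_ids.size)
        if use_numba:
            n_spk = _kernel.run_block(
                v, gE, gI, Isp, W, a_pre, a_post,
                is_exc, wmax_post, circuit.inc_pre, circuit.inc_post, M,
                plastic, eta,
                prm.g_l, prm.V_l, prm.V_E, prm.V_I, prm.v_theta,
                c_over, noise_amp,
                decay_E, decay_I, decay_spk, decay_trace,
                gap.c_gap, gap.w_gap,
                pv_bounds,
                ch_counts, ch_pc_start, ch_pc_stop, ch_sst_start, ch_sst_stop,
                ins.w_to_pc, w_sst_arr, ch_feeds_relay, reward_gate,
                relay_sl.start, relay_sl.stop, circuit.topdown.w_l4_to_relay,
                base_idx, base_w, base_block,
                noise_block,
                rec_cur, cur_idx, cE, cI,
                spk_steps, spk_ids, n_spk,
                k0,
            )
            if n_spk < 0:
                raise core.NumericalError(
                    "spike buffer overflow: network activity is pathological")
        else:
            n_spk = _run_block_numpy(
                circuit, plastic, eta, decay_trace, k0, m,
                noise_block, base_block, noise_amp,
                decay_E, decay_I, decay_spk, c_over,
                ch_counts, ch_pc_start, ch_pc_stop, ch_sst_start, ch_sst_stop,
                w_sst_arr, ch_feeds_relay, reward_gate,
                base_idx, base_w,
                rec_cur, cur_idx, cE, cI,
                spk_steps, spk_ids, n_spk,
            )
        if k1 % snap_every == 0 or k1 == n_steps:
            _snapshot(k1)

    if not np.isfinite(v).all():
        bad = int(np.flatnonzero(~np.isfinite(v))[0])
        raise core.NumericalError(
            f"non-finite membrane potential in neuron {bad} "
            f"at t={t0 + n_steps * dt:.1f} ms")

    spike_times = spk_steps[:n_spk].astype(np.float64) * dt
    spike_ids_arr = spk_ids[:n_spk].copy()

    saturation = {}
    for pw in circuit.pathways:
        wblk = W[pw.post_slice, pw.pre_slice][pw.mask]
        if wblk.size:
            saturation[pw.name] = {
                "at_lower": float((wblk <= pw.params.w_min).mean()),
                "at_upper": float((wblk >= pw.params.w_max).mean()),
            }

    st.t = t0 + duration
    return PhaseRecording(
        name=name, t0=t0, duration=duration, dt=dt, schedules=list(schedules),
        spike_times=spike_times, spike_ids=spike_ids_arr,
        weight_snapshot_times=np.asarray(snap_times),
        weight_snapshots={k2: np.stack(vl) for k2, vl in snaps.items()},
        current_sample=current_sample if rec_cur else None,
        current_E=cE if rec_cur else None,
        current_I=cI if rec_cur else None,
        saturation=saturation,
    )


def _run_block_numpy(
    circuit, plastic, eta, decay_trace, k0, m,
    noise_block, base_block, noise_amp,
    decay_E, decay_I, decay_spk, c_over,
    ch_counts, ch_pc_start, ch_pc_stop, ch_sst_start, ch_sst_stop,
    w_sst_arr, ch_feeds_relay, reward_gate,
    base_idx, base_w,
    rec_cur, cur_idx, cE, cI,
    spk_steps, spk_ids, n_spk,
):
    """Vectorised reference implementation of one simulation block.

    Mirrors `_kernel.run_block` operation for operation; used as the
    cross-check backend and as the fallback when numba is unavailable.
    """
    prm = circuit.neuron_params
    gap = circuit.gap_params
    st = circuit.state
    v, gE, gI, Isp = st.v, st.g_E, st.g_I, st.I_spikelet
    a_pre, a_post = circuit.a_pre, circuit.a_post
    W = circuit.W
    is_exc = circuit.is_exc
    C = ch_counts.shape[0]

    for k in range(m):
        kk = k0 + k
        if rec_cur:
            vs = v[cur_idx]
            cE[kk] = gE[cur_idx] * (prm.V_E - vs)
            cI[kk] = gI[cur_idx] * (vs - prm.V_I)

        I = -prm.g_l * (v - prm.V_l)
        I -= gE * (v - prm.V_E)
        I -= gI * (v - prm.V_I)
        I += Isp
        if gap.w_gap > 0:
            for sl in circuit.pv_slices:
                v_pv = v[sl]
                I[sl] += gap.w_gap * (v_pv.sum() - v_pv.shape[0] * v_pv)
        v += c_over * I
        v += noise_amp * noise_block[k]
        gE *= decay_E
        gI *= decay_I
        Isp *= decay_spk

        spk = np.flatnonzero(v >= prm.v_theta)
        if spk.size:
            v[spk] = prm.V_l
            spk_steps[n_spk:n_spk + spk.size] = kk
            spk_ids[n_spk:n_spk + spk.size] = spk
            n_spk += spk.size

            for sl in circuit.pv_slices:
                pv_spk = spk[(spk >= sl.start) & (spk < sl.stop)]
                if pv_spk.size:
                    Isp[sl] += gap.c_gap * pv_spk.size
                    Isp[pv_spk] -= gap.c_gap

            exc_spk = spk[is_exc[spk]]
            inh_spk = spk[~is_exc[spk]]
            if exc_spk.size:
                gE += W[:, exc_spk].sum(axis=1)
            if inh_spk.size:
                gI += W[:, inh_spk].sum(axis=1)

        if plastic:
            a_pre *= decay_trace
            a_post *= decay_trace
            if spk.size:
                for pw in circuit.pathways:
                    psl, qsl = pw.pre_slice, pw.post_slice
                    pre_spk = spk[(spk >= psl.start) & (spk < psl.stop)] - psl.start
                    post_spk = spk[(spk >= qsl.start) & (spk < qsl.stop)] - qsl.start
                    if pre_spk.size or post_spk.size:
                        plasticity.stdp_matrix_update(
                            W[qsl, psl], pw.mask,
                            a_pre[psl], a_post[qsl],
                            pre_spk, post_spk, pw.params.with_eta(eta),
                        )
                a_pre[spk] += circuit.inc_pre[spk]
                a_post[spk] += circuit.inc_post[spk]

        counts = ch_counts[:, kk]
        ws = w_sst_arr[kk]
        for ci in range(C):
            kc = counts[ci]
            if kc:
                gE[ch_pc_start[ci]:ch_pc_stop[ci]] += circuit.input_spec.w_to_pc * kc
                gE[ch_sst_start[ci]:ch_sst_stop[ci]] += ws * kc
                if ch_feeds_relay[ci] and reward_gate[kk]:
                    gE[circuit.relay_slice] += circuit.topdown.w_l4_to_relay * kc
        row = base_block[k]
        np.add.at(gE, base_idx, base_w * row)

    return n_spk
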