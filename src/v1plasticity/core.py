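"""Conductance-based leaky integrate-and-fire dynamics.

Membrane equation (per neuron, forward Euler at ``dt``)::

    C_m dv/dt = -g_l (v - V_l) - g_E (v - V_E) - g_I (v - V_I) + I_gap + noise

Synaptic conductances jump by the synaptic weight on presynaptic spikes and
decay exponentially (the decay is applied as an exact per-step factor
``exp(-dt/tau)`` rather than an Euler step, which is error-free for pure
decay). PV interneurons additionally carry a gap-junction current: a spikelet
current incremented by ``c_gap`` on a coupled partner's spike and decaying
with ``tau_spikelet``, plus an optional subthreshold coupling term
``w_gap * (v_j - v_i)``.

The stochastic membrane term is discretised as an additive white voltage
increment per step whose amplitude is chosen so that the leak-only membrane
has a stationary voltage s.d. of exactly ``sigma`` (2 mV): increment s.d.
``sqrt(sigma^2 (1 - alpha^2))`` with ``alpha = 1 - dt g_l / C_m``.  See
docs/methods.md for the reasoning behind this reading of the noise term.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "NeuronParams",
    "NoiseParams",
    "GapJunctionParams",
    "PopulationSpec",
    "NetworkState",
    "SpikeEvent",
    "integrate_membrane_step",
    "apply_threshold_and_reset",
    "gap_junction_event",
]


@dataclass(frozen=True)
class NeuronParams:
    """LIF parameters. Units: pF, mV, nS, ms."""

    C_m: float = 200.0
    V_l: float = -60.0
    V_E: float = 0.0
    V_I: float = -80.0
    g_l: float = 10.0
    v_theta: float = -50.0
    tau_E: float = 5.0
    tau_I: float = 10.0

    def __post_init__(self) -> None:
        if min(self.C_m, self.g_l, self.tau_E, self.tau_I) <= 0:
            raise ValueError("C_m, g_l, tau_E, tau_I must be positive")
        if not (self.V_I < self.V_l < self.v_theta < self.V_E):
            raise ValueError("require V_I < V_l < v_theta < V_E")

    @property
    def tau_m(self) -> float:
        """Membrane time constant C_m / g_l (ms)."""
        return self.C_m / self.g_l


@dataclass(frozen=True)
class NoiseParams:
    """Stochastic membrane fluctuations.

    ``sigma`` (mV) is the stationary standard deviation of the membrane
    potential under leak-only dynamics: the discretisation adds a white
    voltage increment of s.d. ``sqrt(sigma^2 (1 - alpha^2))`` per step,
    with ``alpha = 1 - dt g_l / C_m``, so that the leak integrates the
    increments to a stationary voltage s.d. of exactly ``sigma``.  The
    membrane time constant (20 ms) then sets the fluctuations' correlation
    time.  ``tau_noise`` (ms) is the nominal correlation time of the
    underlying noise process; it is retained for reference but is not a
    free parameter of this white-increment discretisation.
    """

    sigma: float = 2.0
    tau_noise: float = 5.0
    enabled: bool = True

    def __post_init__(self) -> None:
        if self.sigma < 0 or self.tau_noise <= 0:
            raise ValueError("sigma >= 0 and tau_noise > 0 required")

    def step_amplitude(self, dt: float, tau_m: float = 20.0) -> float:
        """Per-step voltage increment s.d. (mV) for membrane constant tau_m."""
        if not self.enabled:
            return 0.0
        alpha = 1.0 - dt / tau_m
        return math.sqrt(self.sigma**2 * (1.0 - alpha**2))


@dataclass
class GapJunctionParams:
    """Electrical coupling among PV interneurons.

    ``pairs`` is an (M, 2) array of directed (pre, post) PV index pairs, or
    None for all-to-all coupling among ``pv_indices`` (excluding self-pairs).
    ``w_gap`` (nS) is the subthreshold coupling constant, 0 by default (the
    spikelet-only model); ``c_gap`` (pA) the spikelet jump, ``tau_spikelet``
    (ms) its decay constant.
    """

    c_gap: float = 13.0
    tau_spikelet: float = 9.0
    w_gap: float = 0.0
    pv_indices: np.ndarray | None = None
    pairs: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.c_gap < 0 or self.tau_spikelet <= 0 or self.w_gap < 0:
            raise ValueError("c_gap >= 0, tau_spikelet > 0, w_gap >= 0 required")
        if self.pv_indices is not None:
            self.pv_indices = np.asarray(self.pv_indices, dtype=np.intp)
        if self.pairs is not None:
            self.pairs = np.asarray(self.pairs, dtype=np.intp)
            if self.pairs.ndim != 2 or self.pairs.shape[1] != 2:
                raise ValueError("pairs must be (M, 2)")
            if np.any(self.pairs[:, 0] == self.pairs[:, 1]):
                raise ValueError("self gap junctions are not allowed")
            if self.pv_indices is not None:
                pv = set(self.pv_indices.tolist())
                if not set(self.pairs.ravel().tolist()) <= pv:
                    raise ValueError("gap-junction pairs must lie in the PV population")


@dataclass(frozen=True)
class PopulationSpec:
    """One cell population.

    cell_class: 'E' (pyramidal), 'P' (PV), 'S' (SST), 'V' (VIP) or 'relay'.
    tuning_labels: per-neuron preferred stimulus id (0-3), or None if untuned.
    """

    name: str
    cell_class: str
    size: int
    tuning_labels: np.ndarray | None = None
    location_id: int = 0

    def __post_init__(self) -> None:
        if self.size <= 0:
            raise ValueError("population size must be positive")
        if self.cell_class not in ("E", "P", "S", "V", "relay"):
            raise ValueError(f"unknown cell class {self.cell_class!r}")
        if self.cell_class in ("E", "S"):
            if self.tuning_labels is None or len(self.tuning_labels) != self.size:
                raise ValueError(f"{self.cell_class} populations must be fully tuned")


@dataclass
class NetworkState:
    """Per-neuron dynamical variables at time ``t`` (ms).

    All arrays have length n_neurons; ``I_spikelet`` is nonzero only at PV
    indices.
    """

    t: float
    v: np.ndarray
    g_E: np.ndarray
    g_I: np.ndarray
    I_spikelet: np.ndarray

    @classmethod
    def zeros(cls, n: int, v_rest: float = -60.0) -> "NetworkState":
        return cls(
            t=0.0,
            v=np.full(n, v_rest, dtype=np.float64),
            g_E=np.zeros(n, dtype=np.float64),
            g_I=np.zeros(n, dtype=np.float64),
            I_spikelet=np.zeros(n, dtype=np.float64),
        )

    @property
    def n(self) -> int:
        return self.v.shape[0]


@dataclass(frozen=True)
class SpikeEvent:
    neuron_id: int
    t: float


class NumericalError(RuntimeError):
    """Raised when the membrane integration produces non-finite values."""


def integrate_membrane_step(
    state: NetworkState,
    params: NeuronParams,
    noise: NoiseParams,
    gap: GapJunctionParams | None,
    dt: float,
    rng: np.random.Generator | None = None,
    I_ext: np.ndarray | None = None,
) -> NetworkState:
    """Advance membrane potentials by one forward-Euler step of ``dt`` ms.

    Conductances and spikelet currents decay by their exact per-step factor.
    ``I_ext`` (pA, optional) is an additional current, used by the engine for
    nothing in the default model but available for probing.  The state is
    modified in place and returned.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    v, gE, gI = state.v, state.g_E, state.g_I

    # total current in pA (nS * mV); gap current only where I_spikelet lives
    I = -params.g_l * (v - params.V_l)
    I -= gE * (v - params.V_E)
    I -= gI * (v - params.V_I)
    I += state.I_spikelet
    if gap is not None and gap.w_gap > 0 and gap.pv_indices is not None:
        pv = gap.pv_indices
        v_pv = v[pv]
        # all-to-all subthreshold coupling: sum_j w(v_j - v_i)
        I[pv] += gap.w_gap * (v_pv.sum() - v_pv.shape[0] * v_pv)
    if I_ext is not None:
        I += I_ext

    v += (dt / params.C_m) * I
    if noise.enabled:
        if rng is None:
            raise ValueError("rng required when noise is enabled")
        v += noise.step_amplitude(dt, params.tau_m) * rng.standard_normal(v.shape[0])

    gE *= math.exp(-dt / params.tau_E)
    gI *= math.exp(-dt / params.tau_I)
    if gap is not None:
        state.I_spikelet *= math.exp(-dt / gap.tau_spikelet)
    state.t += dt

    if not np.isfinite(v).all():
        bad = int(np.flatnonzero(~np.isfinite(v))[0])
        raise NumericalError(
            f"non-finite membrane potential in neuron {bad} at t={state.t:.1f} ms"
        )
    return state


def apply_threshold_and_reset(
    state: NetworkState, params: NeuronParams
) -> tuple[NetworkState, np.ndarray]:
    """Emit spikes for neurons at or above threshold and reset them to V_l.

    Returns (state, array of spiking neuron indices). Threshold is inclusive:
    v >= v_theta fires.
    """
    spikes = np.flatnonzero(state.v >= params.v_theta)
    if spikes.size:
        state.v[spikes] = params.V_l
    return state, spikes


def gap_junction_event(
    state: NetworkState, gap: GapJunctionParams, pv_spikes: np.ndarray
) -> NetworkState:
    """Deliver spikelet increments for this step's PV spikes.

    Each coupled postsynaptic partner of a spiking PV gets
    ``I_spikelet += c_gap``. Raises if a spike index is not a PV neuron.
    """
    pv_spikes = np.asarray(pv_spikes, dtype=np.intp)
    if pv_spikes.size == 0:
        return state
    if gap.pv_indices is None:
        raise ValueError("gap.pv_indices must be set to deliver gap events")
    if not np.isin(pv_spikes, gap.pv_indices).all():
        raise ValueError("gap_junction_event received spikes from non-PV neurons")
    if gap.pairs is None:
        # all-to-all among PVs excluding self: every PV gains c_gap per spike,
        # then remove each spiker's own (self) contribution
        k = pv_spikes.size
        state.I_spikelet[gap.pv_indices] += gap.c_gap * k
        state.I_spikelet[pv_spikes] -= gap.c_gap
    else:
        sel = np.isin(gap.pairs[:, 0], pv_spikes)
        np.add.at(state.I_spikelet, gap.pairs[sel, 1], gap.c_gap)
    return state
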