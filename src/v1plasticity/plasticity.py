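"""Classical spike-timing-dependent plasticity with per-neuron traces.

The pair-based kernel is::

    dw = +A_plus  * exp(-dt_pair / tau_plus)   if dt_pair = t_post - t_pre >= 0
    dw = -A_minus * exp(+dt_pair / tau_minus)  if dt_pair < 0

i.e. causal (pre-before-post or simultaneous) pairings potentiate and
anti-causal pairings depress.  The online form keeps one presynaptic trace
``a_pre`` and one postsynaptic trace ``a_post`` per neuron; each decays
exponentially, is incremented by A_plus (A_minus) on a pre (post) spike, and
the weight is updated by the partner's trace at each spike:

    pre spike at t:   w -= eta * a_post(t);  a_pre += A_plus
    post spike at t:  w += eta * a_pre(t);   a_post += A_minus

On the simulation grid a pre and post spike can land in the same step; that
pairing is treated as dt_pair = 0, i.e. potentiation by A_plus only.  The
weight update at a spike therefore uses the partner trace *excluding* any
same-step partner increment, plus an explicit +A_plus for the simultaneous
pair (`stdp_matrix_update`).  With clipping disabled this reproduces the
all-pairs kernel sum (`pairwise_stdp_oracle`) exactly.

Default pathway parameters: tau_plus = tau_minus = 20 ms, eta = 1,
A_minus = 1.05 A_plus; excitatory (PC->PC) A_plus = 0.005 nS with
w in [0, 0.25] nS; inhibitory (SST->PV) A_plus = 0.015 nS with w in [0, 1] nS.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "STDPParams",
    "TraceState",
    "excitatory_stdp",
    "inhibitory_stdp",
    "decay_traces",
    "on_pre_spike",
    "on_post_spike",
    "pairwise_stdp_oracle",
    "simulate_online_stdp",
    "stdp_matrix_update",
]


@dataclass(frozen=True)
class STDPParams:
    """Kernel constants (nS, ms) and hard weight bounds of one pathway."""

    A_plus: float
    A_minus: float | None = None
    tau_plus: float = 20.0
    tau_minus: float = 20.0
    eta: float = 1.0
    w_min: float = 0.0
    w_max: float = 1.0

    def __post_init__(self) -> None:
        if self.A_minus is None:
            object.__setattr__(self, "A_minus", 1.05 * self.A_plus)
        if self.tau_plus <= 0 or self.tau_minus <= 0:
            raise ValueError("trace time constants must be positive")
        if not self.w_min < self.w_max:
            raise ValueError("w_min must be below w_max")

    def with_eta(self, eta: float) -> "STDPParams":
        return STDPParams(
            self.A_plus, self.A_minus, self.tau_plus, self.tau_minus,
            eta, self.w_min, self.w_max,
        )


def excitatory_stdp(eta: float = 1.0) -> STDPParams:
    """PC->PC pathway: A_plus = 0.005 nS, upper bound 0.25 nS."""
    return STDPParams(A_plus=0.005, eta=eta, w_max=0.25)


def inhibitory_stdp(eta: float = 1.0) -> STDPParams:
    """SST->PV pathway: A_plus = 0.015 nS, upper bound 1 nS."""
    return STDPParams(A_plus=0.015, eta=eta, w_max=1.0)


@dataclass
class TraceState:
    """Per-neuron exponential traces (nS)."""

    a_pre: np.ndarray
    a_post: np.ndarray

    @classmethod
    def zeros(cls, n_pre: int, n_post: int) -> "TraceState":
        return cls(np.zeros(n_pre), np.zeros(n_post))


def decay_traces(traces: TraceState, params: STDPParams, dt: float) -> TraceState:
    """Exponential trace decay over ``dt`` ms (in place)."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    traces.a_pre *= math.exp(-dt / params.tau_plus)
    traces.a_post *= math.exp(-dt / params.tau_minus)
    return traces


def on_pre_spike(w, a_post, params: STDPParams, clip: bool = True):
    """Weight after a presynaptic spike: w - eta * a_post, clipped to bounds.

    The caller increments the spiking neuron's a_pre by A_plus afterwards.
    Accepts scalars or arrays.
    """
    w = w - params.eta * a_post
    return np.clip(w, params.w_min, params.w_max) if clip else w


def on_post_spike(w, a_pre, params: STDPParams, clip: bool = True):
    """Weight after a postsynaptic spike: w + eta * a_pre, clipped to bounds."""
    w = w + params.eta * a_pre
    return np.clip(w, params.w_min, params.w_max) if clip else w


def pairwise_stdp_oracle(pre_times, post_times, params: STDPParams) -> float:
    """Brute-force all-pairs kernel sum (no bounds): the testing oracle.

    Sums the STDP kernel over every (pre, post) spike-time pair; simultaneous
    pairs take the potentiation branch.
    """
    pre = np.asarray(pre_times, dtype=float)
    post = np.asarray(post_times, dtype=float)
    if pre.size == 0 or post.size == 0:
        return 0.0
    dt_pair = post[None, :] - pre[:, None]
    pot = params.A_plus * np.exp(-dt_pair / params.tau_plus)
    dep = -params.A_minus * np.exp(dt_pair / params.tau_minus)
    return float(params.eta * np.where(dt_pair >= 0, pot, dep).sum())


def simulate_online_stdp(
    pre_times,
    post_times,
    params: STDPParams,
    dt: float = 0.1,
    w0: float = 0.0,
    clip: bool = False,
) -> float:
    """Run the online trace rule for one synapse on a time grid of step ``dt``.

    Spike times must lie on the grid (multiples of dt).  Returns the final
    weight; with ``clip=False`` the result equals ``w0 +
    pairwise_stdp_oracle(...)`` to machine precision.
    """
    pre = np.round(np.asarray(pre_times, dtype=float) / dt).astype(np.int64)
    post = np.round(np.asarray(post_times, dtype=float) / dt).astype(np.int64)
    if pre.size == 0 and post.size == 0:
        return w0
    n_steps = int(max(pre.max(initial=0), post.max(initial=0))) + 1
    pre_mask = np.zeros(n_steps, dtype=bool)
    post_mask = np.zeros(n_steps, dtype=bool)
    pre_mask[pre] = True
    post_mask[post] = True

    lam_p = math.exp(-dt / params.tau_plus)
    lam_m = math.exp(-dt / params.tau_minus)
    a_pre = 0.0
    a_post = 0.0
    w = w0
    for k in range(n_steps):
        a_pre *= lam_p
        a_post *= lam_m
        p, q = pre_mask[k], post_mask[k]
        if p:
            w = on_pre_spike(w, a_post, params, clip=clip)
        if q:
            w = on_post_spike(w, a_pre, params, clip=clip)
        if p and q:
            # the simultaneous pair is dt_pair = 0 -> potentiation only; the
            # two updates above used pre-increment traces, so add A_plus once
            w = w + params.eta * params.A_plus
            if clip:
                w = float(np.clip(w, params.w_min, params.w_max))
        if p:
            a_pre += params.A_plus
        if q:
            a_post += params.A_minus
    return w


def stdp_matrix_update(
    W: np.ndarray,
    mask: np.ndarray,
    a_pre: np.ndarray,
    a_post: np.ndarray,
    pre_spikes: np.ndarray,
    post_spikes: np.ndarray,
    params: STDPParams,
    clip: bool = True,
) -> None:
    """One step of the online rule on a dense pathway matrix, in place.

    ``W[i, j]`` is the weight from presynaptic j to postsynaptic i; ``mask``
    marks existing connections.  ``a_pre``/``a_post`` are the traces *before*
    this step's increments; the caller decays them beforehand and increments
    them afterwards.  ``pre_spikes``/``post_spikes`` index this step's spikes
    within the pathway's pre/post populations.
    """
    eta = params.eta
    if pre_spikes.size:
        sub = W[:, pre_spikes]
        sub -= eta * np.where(mask[:, pre_spikes], a_post[:, None], 0.0)
        if clip:
            np.clip(sub, params.w_min, params.w_max, out=sub)
        W[:, pre_spikes] = sub
    if post_spikes.size:
        sub = W[post_spikes, :]
        sub += eta * np.where(mask[post_spikes, :], a_pre[None, :], 0.0)
        if clip:
            np.clip(sub, params.w_min, params.w_max, out=sub)
        W[post_spikes, :] = sub
    if pre_spikes.size and post_spikes.size:
        ix = np.ix_(post_spikes, pre_spikes)
        sub = W[ix] + eta * params.A_plus * mask[ix]
        if clip:
            np.clip(sub, params.w_min, params.w_max, out=sub)
        W[ix] = sub
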