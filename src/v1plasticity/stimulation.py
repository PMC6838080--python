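"""Synthetic feedforward and top-down inputs.

Four oriented stimuli are cycled: each cycle shows one stimulus for 50 ms
followed by a 20 ms gap (70 ms period).  Each stimulus drives one layer-4
(L4) channel, a single Poisson process at 4 kHz during its preferred
stimulus, silent during the other stimuli, and at 1.6 kHz during every gap;
the channel's spikes fan out to the matching PC and SST subpopulations
(0.28 nS to PCs; 0.15 nS to SSTs during the stimulus, 0.165 nS during gaps).
PCs and PVs additionally receive an independent 4 kHz baseline Poisson
process per neuron (0.13 nS to PCs, 0.01 nS to PVs).

The reward pathway is a relay population of 100 neurons (PC parameters) that
receives the rewarded stimulus' L4 channel at 0.3 nS only while the rewarded
stimulus is on screen during the rewarded phase, and projects to every VIP
at 0.2 nS.  The top-down signal is untuned; its stimulus specificity comes
purely from temporal coincidence with the rewarded stimulus.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "StimulusSchedule",
    "InputChannelSpec",
    "TopDownSpec",
    "make_schedule",
    "make_interleaved_schedules",
    "l4_channel_spikes",
    "topdown_relay_drive",
]

N_STIMULI = 4
STIM_MS = 50.0
GAP_MS = 20.0
CYCLE_MS = STIM_MS + GAP_MS


@dataclass
class StimulusSchedule:
    """Ordered stimulus cycles tiling a phase.

    ``stimulus_ids[k]`` is the stimulus (0-3) of cycle k with onset
    ``onsets[k]`` (ms, phase-relative); each cycle is 50 ms stimulus then a
    20 ms gap.
    """

    stimulus_ids: np.ndarray
    stim_duration: float = STIM_MS
    gap_duration: float = GAP_MS
    balanced: bool = False

    def __post_init__(self) -> None:
        self.stimulus_ids = np.asarray(self.stimulus_ids, dtype=np.int8)

    @property
    def n_cycles(self) -> int:
        return self.stimulus_ids.shape[0]

    @property
    def cycle_duration(self) -> float:
        return self.stim_duration + self.gap_duration

    @property
    def onsets(self) -> np.ndarray:
        return np.arange(self.n_cycles) * self.cycle_duration

    @property
    def duration(self) -> float:
        return self.n_cycles * self.cycle_duration

    def step_arrays(self, dt: float) -> tuple[np.ndarray, np.ndarray]:
        """Per-step (stimulus_id, in_stimulus) arrays over the whole schedule.

        Step n covers [n*dt, (n+1)*dt); a step belongs to the stimulus window
        if its start time is within [onset, onset + 50 ms).
        """
        n_steps = int(round(self.duration / dt))
        t = np.arange(n_steps) * dt
        cyc = np.minimum((t / self.cycle_duration).astype(np.int64),
                         self.n_cycles - 1)
        within = t - cyc * self.cycle_duration
        return self.stimulus_ids[cyc], within < self.stim_duration

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cycle": np.arange(self.n_cycles),
                "stimulus_id": self.stimulus_ids,
                "onset_ms": self.onsets,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "StimulusSchedule":
        df = pd.read_csv(path)
        return cls(stimulus_ids=df["stimulus_id"].to_numpy())


@dataclass(frozen=True)
class InputChannelSpec:
    """L4 channel and baseline drive parameters (rates in kHz, weights nS)."""

    rate_preferred: float = 4.0
    rate_nonpreferred: float = 0.0
    rate_gap: float = 1.6
    w_to_pc: float = 0.28
    w_to_sst_stim: float = 0.15
    w_to_sst_gap: float = 0.165
    baseline_rate: float = 4.0
    baseline_w_pc: float = 0.13
    baseline_w_pv: float = 0.01

    def __post_init__(self) -> None:
        vals = (self.rate_preferred, self.rate_nonpreferred, self.rate_gap,
                self.w_to_pc, self.w_to_sst_stim, self.w_to_sst_gap,
                self.baseline_rate, self.baseline_w_pc, self.baseline_w_pv)
        if any(v < 0 for v in vals):
            raise ValueError("rates and weights must be nonnegative")

    def channel_rate(self, channel_id: int, stimulus_id: int, in_stim: bool) -> float:
        """Instantaneous rate (kHz) of one L4 channel."""
        if not in_stim:
            return self.rate_gap
        return self.rate_preferred if channel_id == stimulus_id \
            else self.rate_nonpreferred


@dataclass(frozen=True)
class TopDownSpec:
    """Reward-gated top-down pathway to VIPs via a relay population."""

    relay_size: int = 100
    w_l4_to_relay: float = 0.3
    w_relay_to_vip: float = 0.2
    rewarded_stimulus_id: int = 0  # the vertical bar
    enabled: bool = True

    def relay_active(self, phase_rewarded: bool, stimulus_id: int,
                     in_stim: bool) -> bool:
        return (self.enabled and phase_rewarded and in_stim
                and stimulus_id == self.rewarded_stimulus_id)


def make_schedule(
    duration: float,
    balanced: bool,
    rng: np.random.Generator,
    n_stimuli: int = N_STIMULI,
) -> StimulusSchedule:
    """Build a stimulus schedule covering ``duration`` ms.

    Random mode draws each cycle's stimulus uniformly; balanced mode gives
    each stimulus floor(n/4) or +1 occurrences in shuffled order.  A trailing
    partial cycle is dropped (the schedule covers whole cycles only).
    """
    if duration < CYCLE_MS:
        raise ValueError("duration must cover at least one 70 ms cycle")
    n_cycles = int(duration // CYCLE_MS)
    if balanced:
        ids = np.tile(np.arange(n_stimuli, dtype=np.int8),
                      n_cycles // n_stimuli + 1)[:n_cycles]
        rng.shuffle(ids)
    else:
        ids = rng.integers(0, n_stimuli, size=n_cycles).astype(np.int8)
    return StimulusSchedule(stimulus_ids=ids, balanced=balanced)


def make_interleaved_schedules(
    duration: float,
    n_locations: int,
    balanced: bool,
    rng: np.random.Generator,
    n_stimuli: int = N_STIMULI,
) -> list[StimulusSchedule]:
    """Schedules for multiple retinotopic locations, one active per cycle.

    Each 70 ms cycle presents one stimulus at one location; the other
    location's L4 channels are silent for the whole cycle (stimulus id -1).
    Random mode draws (location, stimulus) uniformly per cycle; balanced mode
    gives every (location, stimulus) combination floor(n / (L*4)) or +1
    occurrences in shuffled order.  Returns one schedule per location.
    """
    if duration < CYCLE_MS:
        raise ValueError("duration must cover at least one 70 ms cycle")
    n_cycles = int(duration // CYCLE_MS)
    combos = n_locations * n_stimuli
    if balanced:
        flat = np.tile(np.arange(combos), n_cycles // combos + 1)[:n_cycles]
        rng.shuffle(flat)
    else:
        flat = rng.integers(0, combos, size=n_cycles)
    loc = flat // n_stimuli
    stim = flat % n_stimuli
    out = []
    for l in range(n_locations):
        ids = np.where(loc == l, stim, -1).astype(np.int8)
        out.append(StimulusSchedule(stimulus_ids=ids, balanced=balanced))
    return out


def l4_channel_spikes(
    schedule: StimulusSchedule,
    channel_id: int,
    window: tuple[float, float],
    rng: np.random.Generator,
    spec: InputChannelSpec | None = None,
    dt: float = 0.1,
) -> np.ndarray:
    """Poisson spike times (ms) of one L4 channel within ``window``.

    The rate is piecewise constant on the simulation grid (4 kHz in the
    channel's preferred-stimulus windows, 1.6 kHz in gaps, 0 otherwise);
    events are drawn per step as Poisson counts, matching the engine's
    inhomogeneous-Poisson discretisation.
    """
    if not 0 <= channel_id < N_STIMULI:
        raise ValueError("channel_id must be in 0..3")
    spec = spec or InputChannelSpec()
    stim_ids, in_stim = schedule.step_arrays(dt)
    n0 = int(round(window[0] / dt))
    n1 = min(int(round(window[1] / dt)), stim_ids.shape[0])
    sid = stim_ids[n0:n1]
    rates = np.where(
        in_stim[n0:n1],
        np.where(sid == channel_id, spec.rate_preferred,
                 spec.rate_nonpreferred),
        np.where(sid >= 0, spec.rate_gap, 0.0),  # -1 = location inactive
    )
    counts = rng.poisson(rates * dt)
    times = np.repeat(np.arange(n0, n1) * dt, counts)
    return times


def topdown_relay_drive(
    schedule: StimulusSchedule,
    phase_rewarded: bool,
    window: tuple[float, float],
    spec: TopDownSpec | None = None,
    dt: float = 0.1,
) -> np.ndarray:
    """Per-step boolean gate of the relay population's L4 drive in ``window``.

    True exactly when the rewarded stimulus is on screen during the rewarded
    phase; the engine multiplies this gate into the rewarded channel's spike
    counts at 0.3 nS.
    """
    spec = spec or TopDownSpec()
    stim_ids, in_stim = schedule.step_arrays(dt)
    n0 = int(round(window[0] / dt))
    n1 = min(int(round(window[1] / dt)), stim_ids.shape[0])
    if not (spec.enabled and phase_rewarded):
        return np.zeros(n1 - n0, dtype=bool)
    return in_stim[n0:n1] & (stim_ids[n0:n1] == spec.rewarded_stimulus_id)
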