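"""Analysis of recordings: tuning curves, weight structure, E/I currents,
and the model's eight testable predictions.

Tuning is measured from non-plastic probe phases with a balanced stimulus
schedule: the response of a population to stimulus s is the mean spike count
per neuron in the 50 ms window after each onset of s, averaged over all
occurrences.  "Tuning toward stimulus s" is operationalised as the response
to s minus the mean response to the other stimuli.

Synaptic currents of sampled neurons are reported as positive magnitudes:
E = g_E (V_E - v), I = g_I (v - V_I) (pA), averaged over stimulus windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .engine import PhaseRecording
from .stimulation import StimulusSchedule

__all__ = [
    "TuningCurve",
    "WeightGroupSeries",
    "PredictionReport",
    "tuning_curve",
    "per_neuron_tuning",
    "group_weight_timeseries",
    "ee_connection_groups",
    "sst_pv_connection_groups",
    "ei_current_report",
    "predictions_report",
]

N_STIMULI = 4


@dataclass
class TuningCurve:
    """Per-(population, stimulus) mean response table.

    ``table`` columns: population, tuning, stimulus, mean_count (spikes per
    neuron per 50 ms window), n_occurrences, n_neurons.  Stimuli with zero
    occurrences get mean_count = NaN (flagged, never silently 0).
    """

    table: pd.DataFrame

    def response(self, population: str, stimulus: int,
                 tuning: int | None = None) -> float:
        t = self.table[(self.table.population == population)
                       & (self.table.stimulus == stimulus)]
        if tuning is not None:
            t = t[t.tuning == tuning]
        if t.empty:
            raise KeyError((population, tuning, stimulus))
        # NaN flags (zero-occurrence stimuli) must propagate, not vanish
        num = (t.mean_count.to_numpy() * t.n_neurons.to_numpy()).sum()
        return float(num / t.n_neurons.sum())

    def population_curve(self, population: str,
                         tuning: int | None = None) -> np.ndarray:
        return np.array([self.response(population, s, tuning)
                         for s in range(N_STIMULI)])

    def tuning_index(self, population: str, stimulus: int,
                     tuning: int | None = None) -> float:
        """Response to ``stimulus`` minus mean response to the others."""
        curve = self.population_curve(population, tuning)
        others = np.delete(curve, stimulus)
        return float(curve[stimulus] - others.mean())


def _window_counts(
    spike_times: np.ndarray,
    spike_ids: np.ndarray,
    schedule: StimulusSchedule,
    neuron_ids: np.ndarray,
) -> np.ndarray:
    """Spike counts of ``neuron_ids`` in each cycle's 50 ms stimulus window.

    Returns (n_cycles, n_neurons). Spike times are phase-relative ms.
    """
    order = np.argsort(spike_times, kind="stable")
    st = spike_times[order]
    sid = spike_ids[order]
    pos = {int(n): j for j, n in enumerate(neuron_ids)}
    counts = np.zeros((schedule.n_cycles, neuron_ids.size))
    for c, onset in enumerate(schedule.onsets):
        lo, hi = np.searchsorted(st, [onset, onset + schedule.stim_duration])
        for n in sid[lo:hi]:
            j = pos.get(int(n))
            if j is not None:
                counts[c, j] += 1
    return counts


def tuning_curve(
    recording: PhaseRecording,
    pop_table: pd.DataFrame,
    schedule: StimulusSchedule | None = None,
) -> TuningCurve:
    """Stimulus-resolved mean response of every (population, tuning) group."""
    schedule = schedule or recording.schedule
    rows = []
    for (pop, tun), grp in pop_table.groupby(["population", "tuning"]):
        ids = grp.neuron_id.to_numpy()
        counts = _window_counts(recording.spike_times, recording.spike_ids,
                                schedule, ids)
        per_cycle = counts.sum(axis=1) / ids.size  # spikes per neuron
        for s in range(N_STIMULI):
            occ = schedule.stimulus_ids == s
            rows.append((pop, tun, s,
                         float(per_cycle[occ].mean()) if occ.any() else np.nan,
                         int(occ.sum()), ids.size))
    return TuningCurve(pd.DataFrame(
        rows, columns=["population", "tuning", "stimulus", "mean_count",
                       "n_occurrences", "n_neurons"]))


def per_neuron_tuning(
    recording: PhaseRecording,
    neuron_ids: np.ndarray,
    schedule: StimulusSchedule | None = None,
) -> np.ndarray:
    """(n_neurons, 4) mean spike count per stimulus window for each neuron."""
    schedule = schedule or recording.schedule
    neuron_ids = np.asarray(neuron_ids)
    counts = _window_counts(recording.spike_times, recording.spike_ids,
                            schedule, neuron_ids)
    out = np.full((neuron_ids.size, N_STIMULI), np.nan)
    for s in range(N_STIMULI):
        occ = schedule.stimulus_ids == s
        if occ.any():
            out[:, s] = counts[occ].mean(axis=0)
    return out


@dataclass
class WeightGroupSeries:
    """Grouped weight trajectories: (group, t_ms, mean_nS, sd_nS) table.

    s.d. is the population standard deviation (divisor n) over the fixed set
    of member connections.
    """

    table: pd.DataFrame

    def group(self, label: str) -> pd.DataFrame:
        return self.table[self.table.group == label].reset_index(drop=True)

    def final_mean(self, label: str) -> float:
        g = self.group(label)
        return float(g.mean_nS.iloc[-1])


def group_weight_timeseries(
    snapshots: np.ndarray,
    times: np.ndarray,
    groups: dict[str, np.ndarray],
) -> WeightGroupSeries:
    """Mean and s.d. per connection group at each snapshot time.

    ``snapshots`` is (k, n_post, n_pre); each group value is a boolean mask
    over (n_post, n_pre) selecting member connections.  Empty groups are
    flagged with NaN.
    """
    rows = []
    for label, mask in groups.items():
        if not mask.any():
            for t in times:
                rows.append((label, float(t), np.nan, np.nan))
            continue
        vals = snapshots[:, mask]  # (k, n_members)
        for t, m, s in zip(times, vals.mean(axis=1), vals.std(axis=1)):
            rows.append((label, float(t), float(m), float(s)))
    return WeightGroupSeries(pd.DataFrame(
        rows, columns=["group", "t_ms", "mean_nS", "sd_nS"]))


def ee_connection_groups(
    labels: np.ndarray, mask: np.ndarray, rewarded: int = 0
) -> dict[str, np.ndarray]:
    """Partition PC->PC connections by tuning relative to the rewarded
    stimulus: vert->vert, vert->other, other->vert, other->other."""
    pre_vert = labels[None, :] == rewarded
    post_vert = labels[:, None] == rewarded
    return {
        "vert->vert": mask & post_vert & pre_vert,
        "vert->other": mask & ~post_vert & pre_vert,
        "other->vert": mask & post_vert & ~pre_vert,
        "other->other": mask & ~post_vert & ~pre_vert,
    }


def sst_pv_connection_groups(
    sst_labels: np.ndarray, mask: np.ndarray
) -> dict[str, np.ndarray]:
    """Partition SST->PV connections by the presynaptic SST's tuning."""
    return {f"SST{c}->PV": mask & (sst_labels[None, :] == c)
            for c in range(N_STIMULI)}


def ei_current_report(
    recording: PhaseRecording,
    schedule: StimulusSchedule | None = None,
) -> pd.DataFrame:
    """Per sampled neuron and stimulus: mean E and I current (pA) and E/I.

    Currents were recorded per step during the probe; each stimulus' value is
    the mean over that stimulus' 50 ms windows.  Ratio is NaN where I = 0.
    """
    if recording.current_E is None:
        raise ValueError("recording has no current traces")
    schedule = schedule or recording.schedule
    stim_ids, in_stim = schedule.step_arrays(recording.dt)
    n = recording.current_E.shape[0]
    stim_ids, in_stim = stim_ids[:n], in_stim[:n]
    rows = []
    for j, nid in enumerate(recording.current_sample):
        for s in range(N_STIMULI):
            sel = in_stim & (stim_ids == s)
            E = float(recording.current_E[sel, j].mean())
            I = float(recording.current_I[sel, j].mean())
            rows.append((int(nid), s, E, I, E / I if I != 0 else np.nan))
    return pd.DataFrame(rows, columns=["neuron_id", "stimulus", "E_pA",
                                       "I_pA", "EI_ratio"])


@dataclass
class PredictionReport:
    """Eight boolean outcomes with the quantities they were derived from."""

    outcomes: dict[str, bool]
    stats: dict[str, dict]

    def as_dict(self) -> dict:
        return {"outcomes": dict(self.outcomes), "stats": self.stats}


def _pooled_class_index(curve: TuningCurve, pop_table: pd.DataFrame,
                        cell_class: str, stimulus: int) -> float:
    pops = pop_table[pop_table.cell_class == cell_class].population.unique()
    t = curve.table[curve.table.population.isin(pops)]
    resp = np.zeros(N_STIMULI)
    for s in range(N_STIMULI):
        ts = t[t.stimulus == s]
        resp[s] = (ts.mean_count.to_numpy()
                   * ts.n_neurons.to_numpy()).sum() / ts.n_neurons.sum()
    others = np.delete(resp, stimulus)
    return float(resp[stimulus] - others.mean())


def _pooled_class_response(curve: TuningCurve, pop_table: pd.DataFrame,
                           cell_class: str, stimulus: int) -> float:
    pops = pop_table[pop_table.cell_class == cell_class].population.unique()
    ts = curve.table[(curve.table.population.isin(pops))
                     & (curve.table.stimulus == stimulus)]
    return float((ts.mean_count.to_numpy()
                  * ts.n_neurons.to_numpy()).sum() / ts.n_neurons.sum())


def predictions_report(
    pre_probe: PhaseRecording,
    post_reward_probe: PhaseRecording,
    post_refinement_probe: PhaseRecording,
    pop_table: pd.DataFrame,
    rewarded: int = 0,
) -> PredictionReport:
    """Evaluate the eight testable predictions from three probe recordings.

    The probes must use identical balanced schedules.  Predictions:

    1. PCs become more tuned to the rewarded stimulus (after refinement).
    2. PVs first become less tuned to it (after the rewarded phase), then
       more tuned (after refinement).
    3. SSTs slightly increase their response to it (sign only).
    4. VIPs do not change their tuning.
    5./6. PC and PV firing-rate responses to it increase relative to other
       stimuli.
    7. E and I currents of sampled PCs increase during the rewarded stimulus.
    8. The E/I ratio increases in at least one sampled PC.
    """
    curves = {name: tuning_curve(rec, pop_table) for name, rec in
              [("pre", pre_probe), ("mid", post_reward_probe),
               ("post", post_refinement_probe)]}
    out: dict[str, bool] = {}
    stats: dict[str, dict] = {}

    # 1: pooled PC tuning index toward the rewarded stimulus increases
    idx = {k: _pooled_class_index(c, pop_table, "E", rewarded)
           for k, c in curves.items()}
    out["pc_tuning_up"] = idx["post"] > idx["pre"]
    stats["pc_tuning_up"] = {"pre": idx["pre"], "post": idx["post"]}

    # 2: PV tuning index down after reward, up after refinement
    pv = {k: _pooled_class_index(c, pop_table, "P", rewarded)
          for k, c in curves.items()}
    out["pv_tuning_down_then_up"] = (pv["mid"] < pv["pre"]
                                     and pv["post"] > pv["pre"])
    stats["pv_tuning_down_then_up"] = dict(pv)

    # 3: SST response to the rewarded stimulus slightly up (sign only)
    sst = {k: _pooled_class_response(c, pop_table, "S", rewarded)
           for k, c in curves.items()}
    out["sst_response_up"] = sst["post"] > sst["pre"]
    stats["sst_response_up"] = dict(sst)

    # 4: VIP tuning unchanged (index change small vs mean VIP response)
    vip = {k: _pooled_class_index(c, pop_table, "V", rewarded)
           for k, c in curves.items()}
    vip_mean = np.mean([_pooled_class_response(curves["pre"], pop_table, "V", s)
                        for s in range(N_STIMULI)])
    # tolerance: a quarter of the mean VIP response, floored at 0.05
    # spikes/window so that near-silent VIPs count as unchanged
    tol = max(0.25 * vip_mean, 0.05)
    out["vip_tuning_unchanged"] = bool(abs(vip["post"] - vip["pre"]) < tol)
    stats["vip_tuning_unchanged"] = {**vip, "mean_response_pre": float(vip_mean)}

    # 5/6: rate responses to the rewarded stimulus up relative to others
    for label, cls in (("pc_rates_up", "E"), ("pv_rates_up", "P")):
        ids = pop_table[pop_table.cell_class == cls].neuron_id.to_numpy()
        r_pre = per_neuron_tuning(pre_probe, ids)
        r_post = per_neuron_tuning(post_refinement_probe, ids)
        d = (r_post - r_pre).mean(axis=0)
        d_vert = d[rewarded]
        d_other = float(np.delete(d, rewarded).mean())
        out[label] = d_vert > d_other
        stats[label] = {"delta_rewarded": float(d_vert),
                        "delta_others": d_other}

    # 7/8: synaptic currents of sampled PCs during the rewarded stimulus
    ei_pre = ei_current_report(pre_probe)
    ei_post = ei_current_report(post_refinement_probe)
    pre_v = ei_pre[ei_pre.stimulus == rewarded].set_index("neuron_id")
    post_v = ei_post[ei_post.stimulus == rewarded].set_index("neuron_id")
    dE = post_v.E_pA.mean() - pre_v.E_pA.mean()
    dI = post_v.I_pA.mean() - pre_v.I_pA.mean()
    out["currents_up"] = bool(dE > 0 and dI > 0)
    stats["currents_up"] = {"delta_E_pA": float(dE), "delta_I_pA": float(dI)}
    ratio_up = (post_v.EI_ratio - pre_v.EI_ratio) > 0
    out["ei_ratio_up_some_cells"] = bool(ratio_up.any())
    stats["ei_ratio_up_some_cells"] = {"n_cells_up": int(ratio_up.sum()),
                                       "n_cells": int(ratio_up.size)}
    return PredictionReport(out, stats)
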