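"""Analysis metrics on hand-built fixtures."""

import numpy as np
import pandas as pd
import pytest

from v1plasticity.analysis import (
    ee_connection_groups,
    ei_current_report,
    group_weight_timeseries,
    per_neuron_tuning,
    predictions_report,
    sst_pv_connection_groups,
    tuning_curve,
)
from v1plasticity.engine import PhaseRecording
from v1plasticity.stimulation import StimulusSchedule


def _recording(spike_times, spike_ids, schedule, **kw):
    return PhaseRecording(
        name="probe", t0=0.0, duration=schedule.duration, dt=0.1,
        schedules=[schedule],
        spike_times=np.asarray(spike_times, dtype=float),
        spike_ids=np.asarray(spike_ids),
        weight_snapshot_times=np.array([0.0]),
        weight_snapshots={}, **kw,
    )


def _pop_table():
    return pd.DataFrame({
        "neuron_id": [0, 1],
        "population": ["E", "E"],
        "cell_class": ["E", "E"],
        "tuning": [0, 0],
        "location": [0, 0],
    })


def test_tuning_curve_hand_counted():
    """2 neurons, stimulus 0 shown twice with 4 and 2 spikes in-window
    -> mean 3 spikes per occurrence = 1.5 per neuron."""
    sched = StimulusSchedule(stimulus_ids=np.array([0, 1, 0, 1], dtype=np.int8))
    # cycle onsets at 0, 70, 140, 210; windows are [onset, onset+50)
    times = [1.0, 2.0, 10.0, 20.0,      # 4 spikes in first stim-0 window
             141.0, 142.0,              # 2 spikes in second stim-0 window
             60.0,                      # gap spike: not counted
             75.0]                      # stim-1 window
    ids = [0, 0, 1, 1, 0, 1, 0, 1]
    curve = tuning_curve(_recording(times, ids, sched), _pop_table())
    assert curve.response("E", 0) == pytest.approx(1.5)
    # one spike over two occurrences of stimulus 1, two neurons -> 0.25
    assert curve.response("E", 1) == pytest.approx(0.25)
    row = curve.table[(curve.table.stimulus == 0)].iloc[0]
    assert row.n_occurrences == 2 and row.n_neurons == 2


def test_tuning_curve_no_spikes_and_missing_stimulus():
    sched = StimulusSchedule(stimulus_ids=np.array([0, 1], dtype=np.int8))
    curve = tuning_curve(_recording([], [], sched), _pop_table())
    assert curve.response("E", 0) == 0.0
    # stimuli 2 and 3 never occur: flagged as NaN, not reported as zero
    assert np.isnan(curve.response("E", 2))
    assert curve.table.loc[curve.table.stimulus == 2, "n_occurrences"].item() == 0


def test_per_neuron_tuning_matches_population_mean():
    sched = StimulusSchedule(stimulus_ids=np.array([2, 2], dtype=np.int8))
    times = [0.5, 71.0, 72.0]
    ids = [0, 0, 1]
    r = per_neuron_tuning(_recording(times, ids, sched), np.array([0, 1]))
    assert r[0, 2] == pytest.approx(1.0)   # neuron 0: 1 spike per window
    assert r[1, 2] == pytest.approx(0.5)
    assert np.isnan(r[0, 0])               # stimulus 0 never shown


def test_group_weight_series_hand_arithmetic():
    snaps = np.array([[[0.1, 0.2, 0.3]]])  # one snapshot, 1 x 3 block
    groups = {"all": np.array([[True, True, True]]),
              "empty": np.zeros((1, 3), dtype=bool)}
    series = group_weight_timeseries(snaps, np.array([0.0]), groups)
    g = series.group("all")
    assert g.mean_nS.item() == pytest.approx(0.2)
    assert g.sd_nS.item() == pytest.approx(np.sqrt(2 / 3) * 0.1, rel=1e-9)
    assert np.isnan(series.group("empty").mean_nS.item())


def test_group_series_matches_naive_recomputation():
    rng = np.random.default_rng(0)
    snaps = rng.random((5, 8, 8))
    mask = rng.random((8, 8)) < 0.5
    labels = np.repeat(np.arange(4), 2)
    groups = ee_connection_groups(labels, mask, rewarded=0)
    series = group_weight_timeseries(snaps, np.arange(5.0), groups)
    for label, gmask in groups.items():
        got = series.group(label)
        for k in range(5):
            vals = snaps[k][gmask]
            assert got.mean_nS[k] == pytest.approx(vals.mean())
            assert got.sd_nS[k] == pytest.approx(vals.std())


def test_ee_groups_partition_connections():
    labels = np.repeat(np.arange(4), 3)
    mask = np.ones((12, 12), dtype=bool)
    np.fill_diagonal(mask, False)
    groups = ee_connection_groups(labels, mask)
    total = np.zeros_like(mask, dtype=int)
    for m in groups.values():
        total += m
    assert np.array_equal(total, mask.astype(int))  # exactly-once cover


def test_sst_pv_groups_partition_by_pre_tuning():
    labels = np.repeat(np.arange(4), 2)
    mask = np.ones((3, 8), dtype=bool)
    groups = sst_pv_connection_groups(labels, mask)
    assert len(groups) == 4
    assert sum(m.sum() for m in groups.values()) == mask.sum()


def test_ei_current_report_sign_conventions():
    """g_E = 1 nS at v = -60 -> E = 60 pA; g_I = 1 nS -> I = 20 pA; E/I = 3."""
    sched = StimulusSchedule(stimulus_ids=np.array([0], dtype=np.int8))
    n_steps = 700
    cE = np.full((n_steps, 2), 60.0, dtype=np.float32)
    cI = np.full((n_steps, 2), 20.0, dtype=np.float32)
    cI[:, 1] = 0.0  # second neuron: no inhibition -> undefined ratio
    rec = _recording([], [], sched, current_sample=np.array([0, 1]),
                     current_E=cE, current_I=cI)
    rep = ei_current_report(rec)
    r0 = rep[(rep.neuron_id == 0) & (rep.stimulus == 0)].iloc[0]
    assert (r0.E_pA, r0.I_pA, r0.EI_ratio) == (60.0, 20.0, 3.0)
    r1 = rep[(rep.neuron_id == 1) & (rep.stimulus == 0)].iloc[0]
    assert np.isnan(r1.EI_ratio)


def test_predictions_null_protocol_all_change_predictions_false():
    """Identical pre/mid/post probes -> no learning is reported."""
    rng = np.random.default_rng(1)
    sched = StimulusSchedule(
        stimulus_ids=np.tile(np.arange(4, dtype=np.int8), 5))
    pops = []
    for i in range(8):
        cls = "E" if i < 4 else ("P" if i < 6 else ("S" if i < 7 else "V"))
        pops.append((i, cls, cls, i % 4 if cls in "ES" else -1, 0))
    pop_table = pd.DataFrame(
        pops, columns=["neuron_id", "population", "cell_class", "tuning",
                       "location"])
    times = np.sort(rng.uniform(0, sched.duration, 200))
    ids = rng.integers(0, 8, 200)
    n_steps = int(sched.duration / 0.1)
    cE = np.full((n_steps, 2), 50.0, dtype=np.float32)
    cI = np.full((n_steps, 2), 25.0, dtype=np.float32)
    rec = _recording(times, ids, sched, current_sample=np.array([0, 1]),
                     current_E=cE, current_I=cI)
    rep = predictions_report(rec, rec, rec, pop_table)
    assert not rep.outcomes["pc_tuning_up"]
    assert not rep.outcomes["pv_tuning_down_then_up"]
    assert not rep.outcomes["sst_response_up"]
    assert not rep.outcomes["pc_rates_up"]
    assert not rep.outcomes["currents_up"]
    assert not rep.outcomes["ei_ratio_up_some_cells"]
    assert rep.outcomes["vip_tuning_unchanged"]  # no change = unchanged
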