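"""Protocol orchestration: probes, developmental, rewarded and refinement
phases, plus the two-location translation-invariance variant.

The full protocol is: tuning probe (1.4 s, balanced stimuli, plasticity off)
-> developmental phase (42 s, random stimuli, PC->PC and SST->PV plastic)
-> rewarded phase (24.5 s, top-down relay active during the vertical bar)
-> tuning probe -> refinement phase (66 s, no reward) -> tuning probe.
All probes replay the identical balanced schedule with identical input and
noise streams, so probe responses are comparable across learning stages.

The ``desk`` preset divides the learning-phase durations by 4 (floored to
whole 70 ms cycles) and doubles the STDP learning rate; directional
outcomes (which weight groups separate, which tuning responses grow) are
preserved at this scale.  Probes stay at the full 1.4 s (20 balanced
cycles).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import analysis
from .engine import Circuit, PhaseRecording, build_circuit, run_phase
from .stimulation import (
    CYCLE_MS,
    StimulusSchedule,
    make_interleaved_schedules,
    make_schedule,
)

__all__ = ["ProtocolConfig", "ProtocolResult", "run_full_protocol",
           "run_translation_protocol", "pathway_group_series", "save_outputs"]


def _cycles_floor(ms: float) -> float:
    return max(CYCLE_MS, (ms // CYCLE_MS) * CYCLE_MS)


@dataclass
class ProtocolConfig:
    """All knobs of one protocol run.  Durations in ms, dt in ms."""

    seed: int = 0
    dt: float = 0.1
    probe_duration: float = 1400.0
    developmental_duration: float = 42_000.0
    rewarded_duration: float = 24_500.0
    refinement_duration: float = 66_000.0
    mid_probe: bool = True
    eta: float = 1.0
    reward_enabled: bool = True
    n_locations: int = 1
    shared_interneurons: bool = True
    w_gap: float = 0.0
    snapshot_cadence_ms: float = 500.0
    current_sample_per_subpop: int = 5

    def __post_init__(self) -> None:
        for d in (self.probe_duration, self.developmental_duration,
                  self.rewarded_duration, self.refinement_duration):
            if d <= 0:
                raise ValueError("phase durations must be positive")

    @classmethod
    def paper(cls, seed: int = 0, **kw) -> "ProtocolConfig":
        """Full-duration protocol."""
        return cls(seed=seed, **kw)

    @classmethod
    def desk(cls, seed: int = 0, **kw) -> "ProtocolConfig":
        """Scaled-down preset: learning phases / 4, learning rate x 2."""
        defaults = dict(
            developmental_duration=_cycles_floor(42_000.0 / 4),
            rewarded_duration=_cycles_floor(24_500.0 / 4),
            refinement_duration=_cycles_floor(66_000.0 / 4),
            eta=2.0,
        )
        defaults.update(kw)
        return cls(seed=seed, **defaults)


@dataclass
class ProtocolResult:
    config: ProtocolConfig
    circuit: Circuit
    recordings: dict[str, PhaseRecording]
    summary: dict

    @property
    def pop_table(self) -> pd.DataFrame:
        return self.circuit.population_table()


def _probe_sample(circuit: Circuit, per_subpop: int) -> np.ndarray:
    """First ``per_subpop`` PCs of each orientation subpopulation."""
    ids = []
    for p in circuit.populations:
        if p.cell_class != "E":
            continue
        sl = circuit.slices[p.name]
        for c in range(4):
            ids.extend(range(sl.start + 100 * c, sl.start + 100 * c + per_subpop))
    return np.array(ids, dtype=np.intp)


def run_full_protocol(config: ProtocolConfig) -> ProtocolResult:
    """Execute the complete protocol and return recordings plus summary."""
    ss = np.random.SeedSequence(config.seed)
    ss_conn, ss_sched, ss_inputs, ss_noise, ss_probe_in, ss_probe_noise = \
        ss.spawn(6)
    rng_conn = np.random.default_rng(ss_conn)
    rng_sched = np.random.default_rng(ss_sched)
    rng_inputs = np.random.default_rng(ss_inputs)
    rng_noise = np.random.default_rng(ss_noise)

    circuit = build_circuit(
        rng_conn,
        n_locations=config.n_locations,
        shared_interneurons=config.shared_interneurons,
        eta=config.eta,
        reward_enabled=config.reward_enabled,
        w_gap=config.w_gap,
    )
    sample = _probe_sample(circuit, config.current_sample_per_subpop)

    # one stimulus at one location per 70 ms cycle; the probe is lengthened
    # in proportion to the number of locations so every (location, stimulus)
    # combination keeps the same number of measurement windows
    def scheds(duration: float, balanced: bool) -> list[StimulusSchedule]:
        if config.n_locations == 1:
            return [make_schedule(duration, balanced, rng_sched)]
        return make_interleaved_schedules(duration, config.n_locations,
                                          balanced, rng_sched)

    probe_scheds = scheds(config.probe_duration * config.n_locations, True)

    def learning_scheds(duration: float) -> list[StimulusSchedule]:
        return scheds(duration, False)

    def probe(name: str) -> PhaseRecording:
        # identical input/noise streams for every probe
        return run_phase(
            circuit, probe_scheds, plastic=False, rewarded=False,
            rng_inputs=np.random.default_rng(ss_probe_in),
            rng_noise=np.random.default_rng(ss_probe_noise),
            dt=config.dt, snapshot_cadence_ms=config.snapshot_cadence_ms,
            current_sample=sample, name=name,
        )

    recordings: dict[str, PhaseRecording] = {}
    recordings["pre_probe"] = probe("pre_probe")
    recordings["developmental"] = run_phase(
        circuit, learning_scheds(config.developmental_duration),
        plastic=True, rewarded=False, rng_inputs=rng_inputs,
        rng_noise=rng_noise, dt=config.dt,
        snapshot_cadence_ms=config.snapshot_cadence_ms, name="developmental")
    # tuning "before the rewarded phase": the adult-circuit baseline that
    # the learned changes are measured against
    recordings["post_dev_probe"] = probe("post_dev_probe")
    recordings["rewarded"] = run_phase(
        circuit, learning_scheds(config.rewarded_duration),
        plastic=True, rewarded=True, rng_inputs=rng_inputs,
        rng_noise=rng_noise, dt=config.dt,
        snapshot_cadence_ms=config.snapshot_cadence_ms, name="rewarded")
    if config.mid_probe:
        recordings["mid_probe"] = probe("mid_probe")
    recordings["refinement"] = run_phase(
        circuit, learning_scheds(config.refinement_duration),
        plastic=True, rewarded=False, rng_inputs=rng_inputs,
        rng_noise=rng_noise, dt=config.dt,
        snapshot_cadence_ms=config.snapshot_cadence_ms, name="refinement")
    recordings["post_probe"] = probe("post_probe")

    summary = summarize(config, circuit, recordings)
    return ProtocolResult(config, circuit, recordings, summary)


def run_translation_protocol(config: ProtocolConfig) -> ProtocolResult:
    """Two-location variant: a second PC set at its own stimulus location.

    Reward is paired with the vertical bar at location 0 only.  With shared
    interneurons (the default) the learned preference generalises to
    location 1; the unshared-interneuron control
    (``shared_interneurons=False``) is the ablation that abolishes it.
    """
    return run_full_protocol(replace(config, n_locations=2))


# ---------------------------------------------------------------- summaries

def _pathway_labels(circuit: Circuit, name: str) -> np.ndarray:
    pre_name = name.split("->")[0]
    for p in circuit.populations:
        if p.name == pre_name:
            return p.tuning_labels
    raise KeyError(name)


def pathway_group_series(
    circuit: Circuit,
    recordings: dict[str, PhaseRecording],
    pathway_name: str,
    rewarded: int = 0,
) -> analysis.WeightGroupSeries:
    """Grouped weight trajectory of one plastic pathway across all phases.

    PC->PC pathways are grouped vert/other x vert/other; SST->PV by SST
    tuning.  Times are global (protocol-relative) ms.
    """
    pw = circuit.pathway(pathway_name)
    labels = _pathway_labels(circuit, pathway_name)
    if pathway_name.startswith("S"):
        groups = analysis.sst_pv_connection_groups(labels, pw.mask)
    else:
        groups = analysis.ee_connection_groups(labels, pw.mask, rewarded)
    frames = []
    for rec in recordings.values():
        snaps = rec.weight_snapshots[pathway_name]
        series = analysis.group_weight_timeseries(
            snaps, rec.weight_snapshot_times + rec.t0, groups)
        tbl = series.table.copy()
        tbl["phase"] = rec.name
        frames.append(tbl)
    return analysis.WeightGroupSeries(pd.concat(frames, ignore_index=True))


def _end_means(rec: PhaseRecording, pathway: str,
               groups: dict[str, np.ndarray]) -> dict[str, float]:
    last = rec.weight_snapshots[pathway][-1]
    return {k: float(last[m].mean()) if m.any() else float("nan")
            for k, m in groups.items()}


def _end_stats(rec: PhaseRecording, pathway: str,
               groups: dict[str, np.ndarray]) -> dict[str, dict]:
    """Mean, population s.d. and member count per group at the phase end."""
    last = rec.weight_snapshots[pathway][-1]
    out = {}
    for k, m in groups.items():
        vals = last[m]
        out[k] = {"mean": float(vals.mean()) if vals.size else float("nan"),
                  "sd": float(vals.std()) if vals.size else float("nan"),
                  "n": int(vals.size)}
    return out


def summarize(config: ProtocolConfig, circuit: Circuit,
              recordings: dict[str, PhaseRecording]) -> dict:
    """Headline quantities of a finished run (JSON-serialisable)."""
    pop_table = circuit.population_table()
    rewarded_id = circuit.topdown.rewarded_stimulus_id
    out: dict = {"n_locations": config.n_locations,
                 "reward_enabled": config.reward_enabled,
                 "shared_interneurons": config.shared_interneurons}

    # per-location curves: a population at location l is probed against
    # location l's stimulus schedule
    probe_names = [n for n in ("pre_probe", "post_dev_probe", "mid_probe",
                               "post_probe") if n in recordings]
    curves_by_loc = {
        name: [analysis.tuning_curve(recordings[name], pop_table,
                                     recordings[name].schedules[l])
               for l in range(config.n_locations)]
        for name in probe_names
    }
    curves = {name: by_loc[0] for name, by_loc in curves_by_loc.items()}

    # SST->PV structure at the end of the rewarded and refinement phases
    sp_names = [pw.name for pw in circuit.pathways if pw.name.startswith("S")]
    for sp in sp_names:
        pw = circuit.pathway(sp)
        groups = analysis.sst_pv_connection_groups(
            _pathway_labels(circuit, sp), pw.mask)
        out[f"{sp}_group_means_end_rewarded"] = _end_means(
            recordings["rewarded"], sp, groups)
        out[f"{sp}_group_means_end_refinement"] = _end_means(
            recordings["refinement"], sp, groups)
        out[f"{sp}_group_stats_end_rewarded"] = _end_stats(
            recordings["rewarded"], sp, groups)

    # PC->PC directional structure
    ee_names = [pw.name for pw in circuit.pathways if pw.name.startswith("E")]
    for ee in ee_names:
        pw = circuit.pathway(ee)
        groups = analysis.ee_connection_groups(
            _pathway_labels(circuit, ee), pw.mask, rewarded_id)
        for phase in ("rewarded", "refinement"):
            means = _end_means(recordings[phase], ee, groups)
            out[f"{ee}_group_means_end_{phase}"] = means
            out[f"{ee}_asymmetry_end_{phase}"] = (
                means["vert->other"] - means["other->vert"])

    # tuning-curve headline numbers
    pv_pop = next(p.name for p in circuit.populations if p.cell_class == "P")
    for name, curve in curves.items():
        out[f"pv_curve_{name}"] = curve.population_curve(pv_pop).tolist()
    e_pops = [p for p in circuit.populations if p.cell_class == "E"]
    vert_resp: dict[str, dict] = {}
    for p in e_pops:
        loc = max(p.location_id, 0)
        vert_resp[p.name] = {
            name: [curves_by_loc[name][loc].response(p.name, rewarded_id,
                                                     tuning=c)
                   for c in range(4)]
            for name in probe_names
        }
    out["pc_vertical_response_per_subpop"] = vert_resp

    # full per-subpopulation tuning curves: response of tuning group c to
    # stimulus s, per probe (rows c, columns s)
    pc_curves: dict[str, dict] = {}
    for p in e_pops:
        loc = max(p.location_id, 0)
        pc_curves[p.name] = {
            name: [[curves_by_loc[name][loc].response(p.name, s, tuning=c)
                    for s in range(4)] for c in range(4)]
            for name in probe_names
        }
    out["pc_tuning_curves"] = pc_curves

    # predictions compare against the tuning "before the rewarded phase",
    # i.e. the post-development probe (base single-location protocol only)
    if config.n_locations == 1 and all(
            k in recordings
            for k in ("post_dev_probe", "mid_probe", "post_probe")):
        report = analysis.predictions_report(
            recordings["post_dev_probe"], recordings["mid_probe"],
            recordings["post_probe"], pop_table, rewarded_id)
        out["predictions"] = report.as_dict()

    out["saturation"] = {name: rec.saturation
                         for name, rec in recordings.items()}
    out["connection_counts"] = circuit.connection_counts().to_dict("records")
    return out


def save_outputs(result: ProtocolResult, outdir) -> None:
    """Write rasters, weight series, schedules and the JSON summary."""
    import pathlib

    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pop_table = result.pop_table
    pop_table.to_csv(outdir / "populations.csv", index=False)
    for name, rec in result.recordings.items():
        rec.raster_frame(pop_table).to_csv(
            outdir / f"raster_{name}.csv", index=False)
        for li, sched in enumerate(rec.schedules):
            sched.to_csv(outdir / f"schedule_{name}_loc{li}.csv")
    for pw in result.circuit.pathways:
        series = pathway_group_series(result.circuit, result.recordings,
                                      pw.name)
        safe = pw.name.replace("->", "_to_")
        series.table.to_csv(outdir / f"weights_{safe}.csv", index=False)
    with open(outdir / "summary.json", "w") as fh:
        json.dump(result.summary, fh, indent=2, default=float)
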