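"""Pipeline orchestration: simulate -> preprocess -> behavior -> selectivity
-> reversal -> decoding as one configured, reproducible run.

The whole run is a pure function of (config, seed): re-running with the
same config file and seed reproduces every CSV/JSON output byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__, behavior, decoding, io, preprocess, reversal, selectivity, synthgen
from .task import NO_REWARD, REWARD, TaskSpec

STAGES = ("simulate", "preprocess", "behavior", "selectivity", "reversal", "decoding")


@dataclass
class RunConfig:
    """Everything a pipeline run needs, serializable to one YAML file."""

    out_dir: str = "run"
    seed: int = 0
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    # simulate
    stimuli: list[str] = field(default_factory=lambda: ["A", "B"])
    category_map: dict[str, str] = field(
        default_factory=lambda: {"A": REWARD, "B": NO_REWARD}
    )
    n_trials: int = 300
    n_days: int = 2
    reverse_daily: bool = True
    truth: dict = field(default_factory=dict)  # kwargs of GroundTruth.build
    agent: dict = field(default_factory=dict)  # kwargs of AgentParams
    noise: dict = field(default_factory=dict)  # kwargs of NoiseSpec
    # preprocess
    threshold_mode: str = "median+3iqr"
    drift_window: int = 900
    # selectivity
    n_shuffles: int = 1000
    # decoding
    decoder: dict = field(default_factory=dict)  # kwargs of DecoderSpec
    decode_frame_stride: int = 4

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in order; returns the run report."""
    bad = [s for s in config.stages if s not in STAGES]
    if bad:
        raise ValueError(f"unknown stage(s): {bad}")
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {"version": __version__, "seed": config.seed, "stages": []}
    state: dict = {}
    for stage in STAGES:
        if stage not in config.stages:
            continue
        t0 = time.time()
        try:
            outputs = _STAGE_FNS[stage](config, state, out_dir)
        except Exception as exc:  # noqa: BLE001 - report the failing stage
            report["failed_stage"] = stage
            report["error"] = str(exc)
            (out_dir / "run_report.json").write_text(json.dumps(report, indent=1))
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
        report["stages"].append(
            {"stage": stage, "outputs": outputs, "wall_s": round(time.time() - t0, 3)}
        )
    (out_dir / "run_report.json").write_text(json.dumps(report, indent=1))
    return report


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------
def _task(config: RunConfig) -> TaskSpec:
    return TaskSpec(stimuli=tuple(config.stimuli), category_map=dict(config.category_map))


def _stage_simulate(config: RunConfig, state: dict, out_dir: Path) -> dict:
    task = _task(config)
    truth = synthgen.GroundTruth.build(
        stimuli=tuple(config.stimuli), seed=config.seed, **config.truth
    )
    agent = synthgen.AgentParams(**config.agent)
    noise = synthgen.NoiseSpec(**config.noise)
    schedule = [
        dict(task.category_map) if (d % 2 == 0 or not config.reverse_daily)
        else task.reversed_map()
        for d in range(config.n_days)
    ]
    sessions, regmap = synthgen.generate_multiday(
        task, truth, config.n_days, schedule,
        seed=config.seed, agent=agent, noise=noise, n_trials=config.n_trials,
    )
    outputs = {}
    for s in sessions:
        outputs[f"day{s.day}"] = io.write_session(s, out_dir, stem=f"day{s.day}")
    io.write_registration(regmap, out_dir / "registration.json")
    io.write_truth(truth, out_dir / "ground_truth.json")
    outputs["registration"] = str(out_dir / "registration.json")
    outputs["ground_truth"] = str(out_dir / "ground_truth.json")
    state.update(sessions=sessions, regmap=regmap, task=task)
    return outputs


def _load_sessions(config: RunConfig, state: dict, out_dir: Path) -> list:
    if "sessions" not in state:
        sessions = []
        for d in range(config.n_days):
            sessions.append(
                io.read_session(out_dir / f"day{d}_trials.csv", out_dir / f"day{d}_fluorescence.h5")
            )
        state["sessions"] = sessions
        state["regmap"] = io.read_registration(out_dir / "registration.json")
    return state["sessions"]


def _stage_preprocess(config: RunConfig, state: dict, out_dir: Path) -> dict:
    outputs = {}
    state["events"] = []
    for s in _load_sessions(config, state, out_dir):
        ev = preprocess.preprocess_session(
            s, drift_window=config.drift_window, threshold_mode=config.threshold_mode
        )
        path = out_dir / f"day{s.day}_events.h5"
        io.write_events(ev, path)
        state["events"].append(ev)
        outputs[f"day{s.day}"] = str(path)
    return outputs


def _stage_behavior(config: RunConfig, state: dict, out_dir: Path) -> dict:
    outputs = {}
    state["perf"] = []
    state["masks"] = []
    for s in _load_sessions(config, state, out_dir):
        perf = behavior.find_high_performance(s.trials)
        state["perf"].append(perf)
        state["masks"].append(behavior.analysis_trial_mask(s.trials, perf))
        overall = behavior.compute_rates(s.trials, "all")
        path = out_dir / f"day{s.day}_performance.json"
        path.write_text(json.dumps({
            "hit_rate": float(overall.hit_rate[0]),
            "cr_rate": float(overall.cr_rate[0]),
            "correct_rate": float(overall.correct_rate[0]),
            "high_performance_trials": int(perf.high_performance_mask.sum()),
            "session_high_performance": bool(perf.session_high_performance),
        }, indent=1))
        outputs[f"day{s.day}"] = str(path)
    return outputs


def _stage_selectivity(config: RunConfig, state: dict, out_dir: Path) -> dict:
    outputs = {}
    state["selectivity"] = []
    sessions = _load_sessions(config, state, out_dir)
    for s, ev, mask in zip(sessions, state["events"], state["masks"]):
        table = selectivity.trial_type_selectivity(
            ev.events, s.trials, mask, s.epoch_frames,
            n_shuffles=config.n_shuffles, seed=config.seed,
        )
        profiles = [
            selectivity.response_profile(ev.events[n], s.trials, mask, s.epoch_frames)
            for n in range(s.n_neurons)
        ]
        table["go_code"] = [p.codes["Go"] for p in profiles]
        table["nogo_code"] = [p.codes["NoGo"] for p in profiles]
        table["response_score"] = [p.score for p in profiles]
        path = out_dir / f"day{s.day}_selectivity.csv"
        table.to_csv(path, index=False)
        state["selectivity"].append(table)
        outputs[f"day{s.day}"] = str(path)
    return outputs


def _stage_reversal(config: RunConfig, state: dict, out_dir: Path) -> dict:
    sessions = _load_sessions(config, state, out_dir)
    pairs = behavior.pair_reversed_sessions(sessions, max_gap_days=1)
    outputs = {}
    for i, j in pairs:
        cls = reversal.classify_across_reversal(
            state["selectivity"][i]["label"].to_numpy(),
            state["selectivity"][j]["label"].to_numpy(),
            state["regmap"], reversed_pair=True,
            day_i=sessions[i].day, day_j=sessions[j].day,
        )
        stem = f"reversal_day{sessions[i].day}_day{sessions[j].day}"
        cls.per_neuron.to_csv(out_dir / f"{stem}.csv", index=False)
        inf = cls.inference
        (out_dir / f"{stem}_inference.json").write_text(json.dumps({
            "table": inf.table.tolist(),
            "chi2": inf.chi2, "p": inf.p, "dof": inf.dof,
            "adjusted_residuals": inf.adjusted_residuals.tolist(),
            "planned_p": {str(k): v for k, v in inf.planned_p.items()},
            "class_counts": cls.class_counts,
        }, indent=1))
        outputs[stem] = str(out_dir / f"{stem}.csv")
    return outputs


def _stage_decoding(config: RunConfig, state: dict, out_dir: Path) -> dict:
    sessions = _load_sessions(config, state, out_dir)
    spec = decoding.DecoderSpec(seed=config.seed, **config.decoder)
    outputs = {}
    for s, ev, mask in zip(sessions, state["events"], state["masks"]):
        idx = np.flatnonzero(mask)
        labels = s.trials["category"].to_numpy()[idx]
        keep = idx[decoding.balance_trials(labels, seed=config.seed)]
        frames = np.arange(0, s.n_frames, config.decode_frame_stride)
        res = decoding.decode_timecourse(
            ev.events[:, :, keep], s.trials["category"].to_numpy()[keep], spec, frames
        )
        path = out_dir / f"day{s.day}_decoding.csv"
        out = np.column_stack([res.frames, res.frames / s.frame_rate_hz, res.accuracy])
        header = "frame,time_s,accuracy"
        np.savetxt(path, out, delimiter=",", header=header, comments="")
        outputs[f"day{s.day}"] = str(path)
    return outputs


_STAGE_FNS = {
    "simulate": _stage_simulate,
    "preprocess": _stage_preprocess,
    "behavior": _stage_behavior,
    "selectivity": _stage_selectivity,
    "reversal": _stage_reversal,
    "decoding": _stage_decoding,
}
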