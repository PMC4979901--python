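"""File formats, run configuration and the end-to-end pipeline.

Tables travel as plain CSV: spike events (`time_s,channel`), bursts
(`onset_s,offset_s,n_channels,n_spikes`), stimulus-response pairs and
per-trial session logs.  Summaries are JSON, stamped with the seed and a
hash of the configuration so a run can be reproduced exactly.

The pipeline mirrors one full in-silico experiment: simulate spontaneous
activity until enough inter-burst intervals are collected, detect bursts
offline, fit the lognormal IBI model, probe the network open-loop at
uniform latencies, fit the recovery model, build the predicted objective
with its 99% CI, run the closed-loop learning session, and evaluate the
learned policy against the model predictions.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import burst_detect, model_fit, phenomodel, session_eval, simulator

logger = logging.getLogger(__name__)


def read_spike_events(path) -> pd.DataFrame:
    """Read a `time_s,channel` CSV; sort (with a warning) if unordered."""
    df = pd.read_csv(path)
    missing = {"time_s", "channel"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    bad = df.index[~np.isfinite(df["time_s"]) | (df["time_s"] < 0)]
    if len(bad):
        # +2: header line plus 1-based numbering
        raise ValueError(f"{path}: invalid time at line {bad[0] + 2}")
    if not df["time_s"].is_monotonic_increasing:
        warnings.warn(f"{path}: spike times were unsorted; sorting", UserWarning)
        df = df.sort_values("time_s", kind="stable").reset_index(drop=True)
    df["channel"] = df["channel"].astype(int)
    return df


def write_spike_events(table: pd.DataFrame, path) -> None:
    table[["time_s", "channel"]].to_csv(path, index=False)


def write_bursts(events, path) -> None:
    pd.DataFrame(
        {
            "onset_s": [e.onset for e in events],
            "offset_s": [e.offset for e in events],
            "n_channels": [len(e.participating_channels) for e in events],
            "n_spikes": [e.spike_count for e in events],
        }
    ).to_csv(path, index=False)


@dataclass
class RunConfig:
    """Everything one pipeline run needs; loadable from YAML."""

    params: phenomodel.NetworkParams = field(
        default_factory=phenomodel.NetworkParams.canonical
    )
    seed: int = 0
    min_ibis: int = 200            # spontaneous phase runs until this many IBIs
    n_open_loop_probes: int = 100
    n_channels: int = 8
    state_width: float = 0.5
    n_states: int = 20
    neutral_reward: float = 0.0
    schedule: session_eval.SessionSchedule = field(
        default_factory=session_eval.SessionSchedule
    )
    out_dir: str = "neurostim_run"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        kw = dict(raw)
        if "params" in kw:
            p = kw["params"]
            req = {"A", "B", "lam", "mu", "sigma"}
            missing = req - set(p)
            if missing:
                raise ValueError(f"config params missing fields: {sorted(missing)}")
            kw["params"] = phenomodel.NetworkParams(**p)
        if "schedule" in kw:
            kw["schedule"] = session_eval.SessionSchedule(**kw["schedule"])
        return cls(**kw)

    def to_dict(self) -> dict:
        return {
            "params": dataclasses.asdict(self.params),
            "seed": self.seed,
            "min_ibis": self.min_ibis,
            "n_open_loop_probes": self.n_open_loop_probes,
            "n_channels": self.n_channels,
            "state_width": self.state_width,
            "n_states": self.n_states,
            "neutral_reward": self.neutral_reward,
            "schedule": dataclasses.asdict(self.schedule),
            "out_dir": self.out_dir,
        }

    def config_hash(self) -> str:
        # identifies the scientific configuration; where outputs land is
        # not part of what a re-run must match
        d = self.to_dict()
        d.pop("out_dir")
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def open_loop_probe(
    params: phenomodel.NetworkParams,
    n_probes: int,
    rng: np.random.Generator,
    t_max: float = 10.0,
    t_min: float = 0.01,
    until_responses: bool = False,
) -> pd.DataFrame:
    """Open-loop stimulus-response table at uniform random latencies.

    Each probe waits a latency drawn uniformly on [t_min, t_max] after a
    burst end; probes intercepted by the next spontaneous burst (interval
    shorter than the planned latency) yield no response row, as in the
    recorded experiments.  With ``until_responses`` the probing continues
    until ``n_probes`` responses have been collected instead of counting
    attempts.
    """
    lats, resps = [], []
    attempts = 0
    while True:
        if until_responses:
            if len(lats) >= n_probes:
                break
        elif attempts >= n_probes:
            break
        attempts += 1
        latency = rng.uniform(t_min, t_max)
        ibi = simulator.draw_ibi(params.mu, params.sigma, rng)
        if ibi <= latency:
            continue
        lats.append(latency)
        resps.append(simulator.evoke_response(latency, params, rng))
    return pd.DataFrame({"latency_s": lats, "response_spikes": resps})


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full in-silico experiment; returns the summary dict.

    Writes every intermediate table plus ``summary.json`` to
    ``config.out_dir``.  Any stage failure raises with the stage name.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    p = config.params
    stage = "simulate"
    try:
        # spontaneous phase: long enough for >= min_ibis intervals
        expected_ibi = float(np.exp(p.mu + 0.5 * p.sigma**2))
        duration = config.min_ibis * (expected_ibi + 1.0) * 1.3
        sim_cfg = simulator.SimConfig(params=p, n_channels=config.n_channels)
        spikes, truth = simulator.generate_spontaneous_recording(
            sim_cfg, duration, rng
        )
        write_spike_events(spikes, out / "spontaneous_spikes.csv")
        truth.to_csv(out / "ground_truth_bursts.csv", index=False)

        stage = "detect"
        events = burst_detect.detect_network_bursts(spikes)
        write_bursts(events, out / "detected_bursts.csv")
        ibis = burst_detect.ibis_from_bursts(events)

        stage = "fit-ibi"
        ibi_fit = model_fit.fit_ibi_lognormal(ibis)

        stage = "open-loop-probe"
        probes = open_loop_probe(p, config.n_open_loop_probes, rng)
        probes.to_csv(out / "open_loop_probes.csv", index=False)

        stage = "fit-recovery"
        rec_fit = model_fit.fit_recovery(probes, mode="per-trial")
        fit = model_fit.FitResult(recovery=rec_fit, ibi=ibi_fit)

        stage = "predict-objective"
        grid = phenomodel.LatencyGrid()
        curve, lower, upper = model_fit.predict_objective(
            fit, grid, rng=np.random.default_rng(config.seed + 1)
        )

        stage = "closed-loop-session"
        env = simulator.StimulationEnv(
            p,
            state_width=config.state_width,
            n_states=config.n_states,
            neutral_reward=config.neutral_reward,
            rng=np.random.default_rng(config.seed + 2),
        )
        log = session_eval.run_session(
            env, config.schedule, rng=np.random.default_rng(config.seed + 3)
        )
        session_eval.trials_to_frame(log).to_csv(out / "session_trials.csv",
                                                 index=False)

        stage = "evaluate"
        report = session_eval.evaluate_vs_model(
            log, fit, grid, rng=np.random.default_rng(config.seed + 4)
        )
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc

    summary = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "true_params": dataclasses.asdict(p),
        "n_detected_bursts": len(events),
        "n_ibis": int(len(ibis)),
        "fitted_params": dataclasses.asdict(fit.params),
        "predicted_t_star": curve.t_star,
        "predicted_f_star": curve.f_at_t_star,
        "learned_latency": log.learned_latency,
        "achieved_efficacy": report.achieved_efficacy,
        "inside_99ci": report.inside_ci,
        "baseline_efficacy": report.baseline_efficacy,
        "rounds": [dataclasses.asdict(m) for m in log.rounds],
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
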