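"""Run configuration and stage orchestration.

A run is a selection of stages over synthetic (or supplied) data:

    simulate -> idealize -> couple -> sparklets -> bleachsteps -> clusters
    -> kinetics

Each stage writes a flat table under the output directory; the run writes a
machine-readable summary (JSON) capturing seeds, parameters and package
version.  One master seed in the config drives every stage through
deterministically derived per-stage streams (numpy SeedSequence spawning),
so rerunning with the same config reproduces all numeric outputs exactly.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import ValidationError
from .idealize import all_points_histogram, compute_activity, fit_quantal_mixture, idealize_record
from .imaging import cluster_areas, count_bleach_steps, detect_sparklet_sites
from .kinetics import FacilitationModel, facilitation_curve, fit_boltzmann, fit_multiexp, t50
from .markov import estimate_kappa
from .synthetic import (
    DecaySpec,
    GatingParams,
    simulate_coupled_record,
    simulate_decay_trace,
    simulate_dose_response,
    simulate_photobleach_traces,
    simulate_sparklet_movie,
)
from . import io as cio

ALL_STAGES = ("simulate", "idealize", "couple", "sparklets", "bleachsteps", "kinetics")


@dataclass
class RunConfig:
    """All pipeline parameters in one namespace-per-stage structure."""

    stages: list[str] = field(default_factory=lambda: list(ALL_STAGES))
    out_dir: str = "results"
    seed: int = 1
    # gating simulation
    n_channels: int = 8
    p_co: float = 0.003
    p_oc: float = 0.007
    kappas: list[float] = field(default_factory=lambda: [0.0, 0.5, 1.0])
    amplitude: float = 0.5
    fs: float = 20_000.0
    duration: float = 2.0
    n_records: int = 5
    # idealization / coupling
    kappa_threshold: float = 0.1
    max_levels: int = 5
    # sparklets
    quantal_amplitude: float = 38.0
    detect_sd: float = 3.0
    min_event_frames: int = 3
    frame_rate: float = 100.0
    # photobleaching
    n_spots: int = 30
    step_count_mean: float = 8.0
    bleach_frames: int = 2000
    step_penalty: float = 80.0
    # kinetics
    decay_taus: list[float] = field(default_factory=lambda: [0.62, 2.19, 3.15])
    boltzmann_v50: float = 254.3
    boltzmann_slope: float = 30.0
    tau_recovery: float = 0.375
    tau_decoupling: float = 0.333
    # imaging constants
    bleedthrough: float = 0.16
    k_d: float = 570.0
    r_f: float = 100.0
    pixel_size: float = 200.0

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _stage_seed(master: int, stage: str) -> np.random.SeedSequence:
    idx = {name: i for i, name in enumerate(ALL_STAGES)}[stage]
    return np.random.SeedSequence(entropy=master, spawn_key=(idx,))


def run_pipeline(config: RunConfig) -> dict:
    """Execute the selected stages; returns the machine-readable summary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    unknown = [s for s in config.stages if s not in ALL_STAGES]
    if unknown:
        raise ValidationError(f"unknown stages: {unknown}; valid: {ALL_STAGES}")
    summary: dict = {
        "version": __version__,
        "seed": config.seed,
        "stages": list(config.stages),
        "parameters": dataclasses.asdict(config),
        "outputs": {},
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    if not config.stages:
        summary["message"] = "no stages selected; nothing to do"
        return summary

    records = {}
    for stage in ALL_STAGES:
        if stage not in config.stages:
            continue
        try:
            if stage == "simulate":
                records = _stage_simulate(config, out, summary)
            elif stage == "idealize":
                _stage_idealize(config, out, summary, records)
            elif stage == "couple":
                _stage_couple(config, out, summary, records)
            elif stage == "sparklets":
                _stage_sparklets(config, out, summary)
            elif stage == "bleachsteps":
                _stage_bleachsteps(config, out, summary)
            elif stage == "kinetics":
                _stage_kinetics(config, out, summary)
        except Exception as exc:
            raise RuntimeError(f"stage '{stage}' failed: {exc}") from exc

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=float)
    return summary


def _record_grid(config: RunConfig):
    seeds = _stage_seed(config.seed, "simulate").generate_state(
        len(config.kappas) * config.n_records
    )
    i = 0
    for kappa in config.kappas:
        for rep in range(config.n_records):
            yield kappa, rep, int(seeds[i] % (2**31)), i
            i += 1


def _stage_simulate(config: RunConfig, out: Path, summary: dict) -> dict:
    records = {}
    rows = []
    for kappa, rep, seed, i in _record_grid(config):
        params = GatingParams(
            n_channels=config.n_channels,
            p_co=config.p_co,
            p_oc=config.p_oc,
            kappa=kappa,
            amplitude=config.amplitude,
            fs=config.fs,
            duration=config.duration,
            seed=seed,
        )
        rec, levels = simulate_coupled_record(params)
        record_id = f"k{kappa:g}_r{rep}"
        records[record_id] = (rec, levels, kappa)
        path = out / f"trace_{record_id}.csv"
        cio.write_trace(path, rec.time, rec.values)
        cio.write_levels(out / f"levels_{record_id}.txt", levels)
        rows.append(
            {"record_id": record_id, "kappa_true": kappa, "seed": seed,
             "n_samples": rec.n_samples}
        )
    cio.write_table(out / "simulated_records.csv", pd.DataFrame(rows))
    summary["outputs"]["simulate"] = str(out / "simulated_records.csv")
    return records


def _stage_idealize(config: RunConfig, out: Path, summary: dict, records: dict) -> None:
    rows = []
    for record_id, (rec, true_levels, kappa) in records.items():
        fit = fit_quantal_mixture(rec, max_levels=config.max_levels)
        levels = idealize_record(rec, amplitude=rec.amplitude, baseline=0.0,
                                 n_max=config.n_channels)
        act = compute_activity(levels, fs=rec.fs)
        rows.append(
            {
                "record_id": record_id,
                "kappa_true": kappa,
                "q_hat": fit.q,
                "n_levels": fit.n_levels,
                "nPo": act.value,
                "idealization_accuracy": float(np.mean(levels == true_levels)),
            }
        )
    cio.write_table(out / "idealization.csv", pd.DataFrame(rows))
    summary["outputs"]["idealize"] = str(out / "idealization.csv")


def _stage_couple(config: RunConfig, out: Path, summary: dict, records: dict) -> None:
    rows = []
    for record_id, (rec, _true, kappa) in records.items():
        levels = idealize_record(rec, amplitude=rec.amplitude, baseline=0.0,
                                 n_max=config.n_channels, hysteresis=0.75)
        res = estimate_kappa(levels, n=config.n_channels,
                             threshold=config.kappa_threshold)
        rows.append(
            {
                "record_id": record_id,
                "kappa_true": kappa,
                "kappa_hat": res.kappa_hat,
                "p_co_hat": res.p_co_hat,
                "p_oc_hat": res.p_oc_hat,
                "loglik": res.loglik,
                "cooperative": res.cooperative,
            }
        )
    cio.write_table(out / "coupling.csv", pd.DataFrame(rows))
    summary["outputs"]["couple"] = str(out / "coupling.csv")


def _stage_sparklets(config: RunConfig, out: Path, summary: dict) -> None:
    ss = _stage_seed(config.seed, "sparklets").generate_state(4)
    site_params = GatingParams(
        n_channels=2,
        p_co=0.02,
        p_oc=0.05,
        kappa=0.3,
        amplitude=config.quantal_amplitude,
        noise_sd=0.0,
        fs=config.frame_rate,
        duration=5.0,
        seed=int(ss[0] % (2**31)),
    )
    movie, truths = simulate_sparklet_movie(
        sites=[((14.0, 14.0), site_params), ((30.0, 28.0), site_params)],
        frame_rate=config.frame_rate,
        noise_sd=config.quantal_amplitude / 5.0,
        pixel_size=config.pixel_size,
        seed=int(ss[1] % (2**31)),
    )
    sites = detect_sparklet_sites(
        movie,
        detect_sd=config.detect_sd,
        min_event_frames=config.min_event_frames,
        quantal_amplitude=config.quantal_amplitude,
    )
    rows = [
        {
            "site": i,
            "row": s.center[0],
            "col": s.center[1],
            "nPs": s.nps.value,
            "n_quantal_levels": s.n_quantal_levels,
        }
        for i, s in enumerate(sites)
    ]
    cio.write_table(out / "sparklet_sites.csv", pd.DataFrame(rows))
    summary["outputs"]["sparklets"] = str(out / "sparklet_sites.csv")
    summary["sparklet_sites_detected"] = len(sites)
    summary["sparklet_sites_planted"] = len(truths)


def _stage_bleachsteps(config: RunConfig, out: Path, summary: dict) -> None:
    seed = int(_stage_seed(config.seed, "bleachsteps").generate_state(1)[0] % (2**31))
    traces, truths = simulate_photobleach_traces(
        n_spots=config.n_spots,
        step_count_mean=config.step_count_mean,
        n_frames=config.bleach_frames,
        step_amplitude=100.0,
        noise_sd=100.0 / 6.0,
        seed=seed,
    )
    rows = []
    for i, (trace, truth) in enumerate(zip(traces, truths)):
        counted = count_bleach_steps(trace, penalty=config.step_penalty)
        rows.append(
            {"spot": i, "true_steps": truth.true_steps, "counted_steps": counted}
        )
    df = pd.DataFrame(rows)
    cio.write_table(out / "bleach_steps.csv", df)
    summary["outputs"]["bleachsteps"] = str(out / "bleach_steps.csv")
    summary["bleach_mean_true"] = float(df["true_steps"].mean())
    summary["bleach_mean_counted"] = float(df["counted_steps"].mean())


def _stage_kinetics(config: RunConfig, out: Path, summary: dict) -> None:
    rows = []
    spec = DecaySpec(
        amplitudes=[1.0] * len(config.decay_taus), taus=list(config.decay_taus)
    )
    t, y = simulate_decay_trace(spec)
    fit = fit_multiexp(t, y, n_components=len(config.decay_taus))
    for i, (a, tau) in enumerate(zip(fit.amplitudes, fit.taus)):
        rows.append({"analysis": "decay", "parameter": f"tau{i+1}_s", "estimate": tau})
        rows.append({"analysis": "decay", "parameter": f"amp{i+1}", "estimate": a})
    rows.append({"analysis": "decay", "parameter": "t50_s", "estimate": t50(t, y)})

    table = simulate_dose_response(v50=config.boltzmann_v50, slope=config.boltzmann_slope)
    bfit = fit_boltzmann(table["ca_nM"].values, table["response"].values)
    rows.append({"analysis": "boltzmann", "parameter": "v50_nM", "estimate": bfit.v50})
    rows.append({"analysis": "boltzmann", "parameter": "slope_nM", "estimate": bfit.slope})

    model = FacilitationModel(
        tau_recovery=config.tau_recovery, tau_decoupling=config.tau_decoupling,
    )
    intervals = np.arange(0.1, 1.61, 0.1)
    curve = facilitation_curve(model, intervals)
    cio.write_table(
        out / "facilitation_curve.csv",
        pd.DataFrame({"interval_s": curve[:, 0], "ratio": curve[:, 1]}),
    )
    peak_i = int(np.argmax(curve[:, 1]))
    rows.append(
        {"analysis": "facilitation", "parameter": "peak_interval_s",
         "estimate": curve[peak_i, 0]}
    )
    rows.append(
        {"analysis": "facilitation", "parameter": "peak_ratio",
         "estimate": curve[peak_i, 1]}
    )
    cio.write_table(out / "kinetics_fits.csv", pd.DataFrame(rows))
    summary["outputs"]["kinetics"] = str(out / "kinetics_fits.csv")
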