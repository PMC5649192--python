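"""End-to-end in-silico replay of the 80-min experiment.

``run_replay`` chains every stage: kinetic simulation of the reactor, the
no-chlorine-effect prediction, synthetic event-stream generation for both
staining modes, gating/binning/alignment, and the derived analyses (baseline,
onset, chlorination decline, washout fit, comparison to prediction). All
randomness derives from one seed; outputs are byte-identical across reruns
with the same (config, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .analysis import (BaselineStats, ComparisonReport, LinearFit, WashoutFit,
                       baseline_stats, compare_to_prediction, detect_onset,
                       fit_linear_rate, fit_washout, percent_reduction)
from .config import RunConfig
from .gating import BinnedSeries, process_stream
from .instrument import generate_event_stream
from .io import (RunManifest, write_binned_series, write_config,
                 write_event_stream, write_trajectory)
from .reactor import Trajectory, predict_series, simulate_experiment

__all__ = ["ReplayResult", "run_replay", "chlorination_exclusion_window"]


def chlorination_exclusion_window(config: RunConfig) -> tuple[float, float]:
    """Reactor-minute window excluded when comparing to the pure prediction.

    The prediction assumes no chlorine effect on counts, so the comparison
    excludes the span where chlorination influences the measurement: from the
    start of dosing until three volume changes into flow-through, after which
    any chlorine-induced excess has decayed below ~5% of its initial size.
    """
    exp = config.experiment
    d = exp.nominal_dilution_rate
    return (exp.chlorination_start, exp.flowthrough_start + 3.0 / d)


@dataclass
class ReplayResult:
    manifest: RunManifest
    trajectory: Trajectory
    prediction: Trajectory
    tcc_series: BinnedSeries
    icc_series: BinnedSeries
    baseline_tcc: BaselineStats
    baseline_icc: BaselineStats
    onset_tcc_min: float | None
    onset_icc_min: float | None
    chlorination_fit: LinearFit
    washout_fit: WashoutFit
    comparison: ComparisonReport
    icc_reduction_pct: float
    icc_postchlorination_mean: float
    report: dict


def run_replay(config: RunConfig | None = None, seed: int = 0,
               out_dir: str | Path | None = None, *,
               sim_step: float = 0.01) -> ReplayResult:
    """Run the full pipeline; optionally write all outputs under ``out_dir``."""
    cfg = config if config is not None else RunConfig()
    exp = cfg.experiment
    manifest = RunManifest(seed=seed)
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    stage = "simulate"

    def _finish_stage(name: str) -> None:
        manifest.completed_stages.append(name)

    try:
        trajectory = simulate_experiment(exp, cfg.kinetics, step=sim_step)
        prediction = predict_series(exp)
        _finish_stage("simulate")
        stage = "generate"

        ss = np.random.SeedSequence(seed)
        seeds = ss.generate_state(2)
        streams = {}
        for mode, s in zip(("SG", "SG+PI"), seeds):
            streams[mode] = generate_event_stream(
                trajectory, cfg.instrument, cfg.populations, mode, int(s))
        _finish_stage("generate")
        stage = "bin"

        duration = exp.total_duration + cfg.instrument.staining_delay_min
        n_bins = int(round(duration))  # 1-min bins over the acquisition
        series = {}
        for mode, stream in streams.items():
            s = process_stream(stream, cfg.gates, cfg.instrument,
                               bin_width_s=60.0, n_bins=n_bins)
            # drop bins aligned to before the experiment started
            series[mode] = s.window(0.0, exp.total_duration)
        tcc_series, icc_series = series["SG"], series["SG+PI"]
        _finish_stage("bin")
        stage = "analyze"

        base_window = (0.0, exp.contamination_start)
        baseline_tcc = baseline_stats(tcc_series, base_window)
        baseline_icc = baseline_stats(icc_series, base_window)
        onset_tcc = detect_onset(tcc_series, baseline_tcc)
        onset_icc = detect_onset(icc_series, baseline_icc)

        # linear-decline fit runs from one bin after dosing starts to the
        # flow-through switch: a bin straddling the regime change would bias
        # the slope
        chlor_window = (exp.chlorination_start + 1.0, exp.flowthrough_start)
        chlorination_fit = fit_linear_rate(tcc_series, chlor_window)

        wash_window = (exp.flowthrough_start + 1.0, exp.total_duration)
        washout_fit = fit_washout(tcc_series, wash_window, floor=exp.tap_tcc)

        plateau = icc_series.window(exp.chlorination_start - 7.0,
                                    exp.chlorination_start)
        post = icc_series.window(exp.chlorination_start + 5.0,
                                 exp.flowthrough_start)
        icc_before = float(np.mean(plateau.concentration))
        icc_after = float(np.mean(post.concentration))
        icc_reduction = percent_reduction(icc_before, icc_after)
        _finish_stage("analyze")
        stage = "compare"

        comparison = compare_to_prediction(
            tcc_series, prediction, column="tcc",
            exclude_window=chlorination_exclusion_window(cfg))
        _finish_stage("compare")
    except Exception:
        manifest.failed_stage = stage
        if out is not None:
            manifest.write(out / "manifest.json")
        raise

    report = {
        "seed": seed,
        "baseline_tcc": {"mean": baseline_tcc.mean, "sd": baseline_tcc.sd,
                         "n": baseline_tcc.n},
        "baseline_icc": {"mean": baseline_icc.mean, "sd": baseline_icc.sd,
                         "n": baseline_icc.n},
        "onset_tcc_min": onset_tcc,
        "onset_icc_min": onset_icc,
        "chlorination_slope": chlorination_fit.slope,
        "washout_rate": washout_fit.rate if washout_fit.ok else None,
        "washout_asymptote": washout_fit.asymptote if washout_fit.ok else None,
        "icc_plateau_mean": icc_before,
        "icc_postchlorination_mean": icc_after,
        "icc_reduction_pct": icc_reduction,
        "comparison_rmse": comparison.rmse,
        "comparison_lag_min": comparison.lag_min,
    }

    if out is not None:
        write_config(cfg, out / "config.yaml")
        manifest.config_path = str(out / "config.yaml")
        write_trajectory(trajectory, out / "trajectory.csv")
        write_trajectory(prediction, out / "prediction.csv")
        write_event_stream(streams["SG"], out / "events_sg.csv")
        write_event_stream(streams["SG+PI"], out / "events_sgpi.csv")
        write_binned_series(tcc_series, out / "binned_tcc.csv")
        write_binned_series(icc_series, out / "binned_icc.csv")
        (out / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True) + "\n")
        for role, name in [("config", "config.yaml"),
                           ("trajectory", "trajectory.csv"),
                           ("prediction", "prediction.csv"),
                           ("events_sg", "events_sg.csv"),
                           ("events_sg_meta", "events_sg.csv.meta.json"),
                           ("events_sgpi", "events_sgpi.csv"),
                           ("events_sgpi_meta", "events_sgpi.csv.meta.json"),
                           ("binned_tcc", "binned_tcc.csv"),
                           ("binned_icc", "binned_icc.csv"),
                           ("report", "report.json")]:
            manifest.add_file(role, out / name)
        manifest.write(out / "manifest.json")

    return ReplayResult(
        manifest=manifest, trajectory=trajectory, prediction=prediction,
        tcc_series=tcc_series, icc_series=icc_series,
        baseline_tcc=baseline_tcc, baseline_icc=baseline_icc,
        onset_tcc_min=onset_tcc, onset_icc_min=onset_icc,
        chlorination_fit=chlorination_fit, washout_fit=washout_fit,
        comparison=comparison, icc_reduction_pct=icc_reduction,
        icc_postchlorination_mean=icc_after, report=report)
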