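"""End-to-end orchestration of the three synthetic studies.

Each pipeline composes the module stages in acquisition order and
returns a machine-readable results bundle; with an output directory it
also writes CSV/JSON artifacts and a provenance record (config, seed).
All randomness derives from the single config seed, so reruns are
bit-identical.

- caffeine: connective movies -> (optional) motion correction ->
  illumination correction -> dF/F -> connective-mean traces ->
  pre-feeding normalization -> per-bin maximum activity -> one-sided
  Mann-Whitney tests -> wave peak-time map;
- arena: trajectory -> Savitzky-Golay signed velocity -> per-epoch
  backward-walking metrics vs. generator truth;
- degradation: daily series -> alignment -> ROI means -> day-1
  normalization -> per-day two-sided Mann-Whitney tests -> decay-rate
  recovery.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import arena as arena_mod
from . import degradation as deg_mod
from . import photometry, waves
from .datatypes import SampledTrace
from .registration import OpticFlowParams, correct_two_channel
from .synthetic import (
    ArenaTrajectorySpec,
    ConnectiveMovieSpec,
    DegradationSeriesSpec,
    WaveSpec,
    generate_arena_trajectory,
    generate_connective_movie,
    generate_degradation_series,
)

__all__ = [
    "PipelineConfig",
    "run_caffeine_pipeline",
    "run_arena_pipeline",
    "run_degradation_pipeline",
]

CONDITIONS = ("sucrose", "low_caffeine", "high_caffeine")
#: post-feeding time bins (upper edges in minutes), as reported per fly
AFTER_BINS = (9, 19, 29, 38)
#: minutes-after-feeding of the trial representing each bin
AFTER_TRIAL_MINUTES = (8, 18, 28, 37)


@dataclass
class PipelineConfig:
    """Single configuration object driving all three pipelines.

    Numeric defaults mirror the acquisition and analysis parameters of
    the long-term imaging studies (smoothness weight 800, median kernel
    (71, 91), stationarity threshold 0.01 rot/s, 75% context fraction,
    three 3 s stimulations after 30 s, etc.). Movie sizes default to a
    reduced desk scale so a full synthetic study runs in seconds.
    """

    seed: int = 0
    # caffeine study
    n_flies_per_condition: int = 3
    movie_height: int = 64
    movie_width: int = 96
    trial_n_frames: int = 96
    frame_rate: float = 16.0
    n_axons: int = 8
    motion_amplitude: float = 0.0
    nonrigid_amplitude: float = 0.0
    illumination_slope: float = 0.001
    movie_noise_sd: float = 1.0
    fluctuation_amplitude: float = 0.25
    wave_amplitude: float = 4.0
    wave_onset_s: float = 3.0
    wave_lag_s: float = 0.4
    wave_duration_s: float = 2.0
    lambda_smooth: float = 800.0
    # arena study
    n_arena_flies: int = 3
    arena_noise_sd: float = 0.0
    savgol_window: int = 9
    # degradation study
    n_days: int = 15
    n_flies_per_group: int = 5
    bleach_rate: float = 0.02
    amputation_decay_rate: float = 0.25
    degradation_noise_sd: float = 0.5
    degradation_jitter: float = 2.0

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _write_report(out_dir: str | Path | None, name: str, payload: dict) -> None:
    if out_dir is None:
        return
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / name).write_text(json.dumps(payload, indent=2, default=_json_default))


# ---------------------------------------------------------------------------
# Caffeine study
# ---------------------------------------------------------------------------

def _trial_plan() -> list[tuple[str, float | None, str]]:
    """(phase, minutes_after_feeding, bin label) for one fly's session:
    two pre-feeding trials, one during, four after at increasing delays."""
    plan = [("before", None, "before"), ("before", None, "before"),
            ("during", None, "during")]
    for minutes, edge in zip(AFTER_TRIAL_MINUTES, AFTER_BINS):
        plan.append(("after", float(minutes), f"<{edge}min"))
    return plan


def _simulate_fly(
    config: PipelineConfig, condition: str, fly_seeds: np.random.SeedSequence
) -> dict:
    """Generate and analyze all trials of one fly; returns traces,
    per-bin maximum normalized activity, and the wave trial if any."""
    child_seeds = fly_seeds.generate_state(len(_trial_plan()) + 1)
    layout_seed = int(child_seeds[0] % (2**31))

    flow_params = OpticFlowParams(lambda_smooth=config.lambda_smooth)
    trials = []
    for i, (phase, minutes, bin_label) in enumerate(_trial_plan()):
        has_wave = (
            condition == "high_caffeine"
            and phase == "after"
            and minutes is not None
            and minutes > 29
        )
        wave = (
            WaveSpec(
                onset_time=config.wave_onset_s,
                inter_region_lag=config.wave_lag_s,
                amplitude=config.wave_amplitude,
                duration=config.wave_duration_s,
            )
            if has_wave
            else None
        )
        spec = ConnectiveMovieSpec(
            n_frames=config.trial_n_frames,
            frame_rate=config.frame_rate,
            height=config.movie_height,
            width=config.movie_width,
            n_axons=config.n_axons,
            motion_amplitude=config.motion_amplitude,
            nonrigid_amplitude=config.nonrigid_amplitude,
            illumination_slope=config.illumination_slope,
            noise_sd=config.movie_noise_sd,
            fluctuation_amplitude=config.fluctuation_amplitude,
            wave=wave,
            seed=int(child_seeds[i + 1] % (2**31)),
            layout_seed=layout_seed,
        )
        red, green, truth = generate_connective_movie(spec)
        if config.motion_amplitude > 0 or config.nonrigid_amplitude > 0:
            red, green, _ = correct_two_channel(red, green, params=flow_params)
        trials.append(
            {"phase": phase, "minutes": minutes, "bin": bin_label,
             "green": green, "truth": truth, "has_wave": has_wave}
        )

    # illumination correction (fit on the first trial's temporal mean)
    phot = photometry.PhotometryParams(
        median_kernel=(31, 31), central_width=min(64, config.movie_width - 1)
    )
    profile = photometry.fit_illumination_profile(
        trials[0]["green"].data.mean(axis=0), phot
    )
    for trial in trials:
        trial["green"] = photometry.apply_illumination_correction(
            trial["green"], profile
        )

    # dF/F with the baseline taken as the minimum across all trials
    baseline = photometry.compute_baseline([t["green"] for t in trials], phot)
    mask = trials[0]["truth"].roi_masks > 0
    for trial in trials:
        dff = photometry.compute_dff(trial["green"], baseline)
        trial["trace"] = waves.connective_mean_trace(dff, mask)

    norm = waves.compute_normalization(
        [t["trace"] for t in trials if t["phase"] == "before"]
    )
    pooled_before = SampledTrace(
        np.concatenate([t["trace"].values for t in trials if t["phase"] == "before"]),
        config.frame_rate,
    )
    activity = {"before": waves.max_normalized_activity(pooled_before, norm)}
    for trial in trials:
        if trial["phase"] != "before":
            activity[trial["bin"]] = waves.max_normalized_activity(trial["trace"], norm)

    wave_trial = next((t for t in trials if t["has_wave"]), None)
    return {"activity": activity, "wave_trial": wave_trial}


def run_caffeine_pipeline(
    config: PipelineConfig | None = None, out_dir: str | Path | None = None
) -> dict:
    """Run the full synthetic caffeine-ingestion study.

    Three conditions (sucrose, low caffeine, high caffeine), three flies
    each; activity waves occur only in high-caffeine trials recorded
    more than 29 min after feeding. Returns per-fly maximum normalized
    activities, per-bin one-sided Mann-Whitney p-values of high caffeine
    against each control condition, and the wave peak-time analysis of
    one high-caffeine fly.
    """
    config = config or PipelineConfig()
    root = np.random.SeedSequence(config.seed)
    fly_sequences = root.spawn(len(CONDITIONS) * config.n_flies_per_condition)

    per_fly = []
    rows = []
    idx = 0
    for condition in CONDITIONS:
        for f in range(config.n_flies_per_condition):
            result = _simulate_fly(config, condition, fly_sequences[idx])
            idx += 1
            fly_id = f"{condition}_{f}"
            per_fly.append({"fly_id": fly_id, "condition": condition, **result})
            for bin_label, value in result["activity"].items():
                rows.append(
                    {"fly_id": fly_id, "condition": condition,
                     "bin": bin_label, "max_normalized_activity": value}
                )
    table = pd.DataFrame(rows)

    bins = ["during"] + [f"<{e}min" for e in AFTER_BINS]
    pvalues = {}
    for bin_label in bins:
        sub = table[table["bin"] == bin_label]
        high = sub.loc[sub["condition"] == "high_caffeine",
                       "max_normalized_activity"].to_numpy()
        pvalues[bin_label] = {
            "vs_sucrose": waves.mann_whitney_u(
                high,
                sub.loc[sub["condition"] == "sucrose",
                        "max_normalized_activity"].to_numpy(),
                sides="one", method="normal_cc",
            ),
            "vs_low_caffeine": waves.mann_whitney_u(
                high,
                sub.loc[sub["condition"] == "low_caffeine",
                        "max_normalized_activity"].to_numpy(),
                sides="one", method="normal_cc",
            ),
        }

    # wave timing on the first high-caffeine fly's wave trial
    wave_report = None
    wave_fly = next(
        (f for f in per_fly if f["condition"] == "high_caffeine" and f["wave_trial"]),
        None,
    )
    if wave_fly is not None:
        trial = wave_fly["wave_trial"]
        trace = trial["trace"]
        t_peak = waves.global_peak_time(trace)
        peak_map = waves.pixel_peak_time_map(trial["green"], t_peak)
        truth = trial["truth"]
        roi_peaks = {}
        for label in np.unique(truth.roi_masks):
            if label == 0:
                continue
            roi_peaks[int(label)] = float(
                np.median(peak_map[truth.roi_masks == label])
            )
        from scipy import stats as sp_stats

        common = sorted(truth.wave_peak_times)
        rho = sp_stats.spearmanr(
            [truth.wave_peak_times[k] for k in common],
            [roi_peaks[k] for k in common],
        ).statistic
        wave_report = {
            "t_peak_s": t_peak,
            "roi_peak_times_s": roi_peaks,
            "true_peak_times_s": {int(k): v for k, v in truth.wave_peak_times.items()},
            "spearman_rho": float(rho),
        }

    results = {
        "seed": config.seed,
        "activity_table": table,
        "pvalues": pvalues,
        "wave_timing": wave_report,
    }
    report = {k: v for k, v in results.items() if k != "activity_table"}
    report["activity"] = rows
    _write_report(out_dir, "caffeine_report.json", report)
    if out_dir is not None:
        table.to_csv(Path(out_dir) / "caffeine_activity.csv", index=False)
    return results


# ---------------------------------------------------------------------------
# Arena study
# ---------------------------------------------------------------------------

def run_arena_pipeline(
    config: PipelineConfig | None = None, out_dir: str | Path | None = None
) -> dict:
    """Synthetic optogenetic backward-walking study.

    Generates one session per fly under the stimulation protocol,
    recomputes the signed translational velocity from the centroid track
    and extracts the three per-epoch metrics, reporting recovery error
    against the generator's analytic truth.
    """
    config = config or PipelineConfig()
    root = np.random.SeedSequence(config.seed)
    seeds = root.generate_state(config.n_arena_flies)

    epochs, total = arena_mod.session_schedule()
    rows = []
    for f in range(config.n_arena_flies):
        spec = ArenaTrajectorySpec(
            noise_sd=config.arena_noise_sd, seed=int(seeds[f] % (2**31))
        )
        traj, truth = generate_arena_trajectory(spec)
        vel = arena_mod.translational_velocity(traj, config.savgol_window)
        metrics = arena_mod.compute_epoch_metrics(vel, traj, truth.extras["epochs"])
        for m, tm in zip(metrics, truth.true_metrics):
            rows.append(
                {
                    "fly_id": f"fly_{f}",
                    "epoch": m.epoch_index,
                    "slope_mm_s2": m.response_slope,
                    "distance_mm": m.backward_distance,
                    "max_neg_vel_mm_s": m.max_negative_velocity,
                    "true_slope_mm_s2": tm.response_slope,
                    "true_distance_mm": tm.backward_distance,
                    "true_max_neg_vel_mm_s": tm.max_negative_velocity,
                    "excluded": m.excluded,
                }
            )
    table = pd.DataFrame(rows)
    rel_err = {
        "slope": float(
            np.abs(table["slope_mm_s2"] / table["true_slope_mm_s2"] - 1).max()
        ),
        "distance": float(
            np.abs(table["distance_mm"] / table["true_distance_mm"] - 1).max()
        ),
        "max_neg_vel": float(
            np.abs(table["max_neg_vel_mm_s"] / table["true_max_neg_vel_mm_s"] - 1).max()
        ),
    }
    results = {
        "seed": config.seed,
        "session_length_s": total,
        "stim_onsets_s": [e.onset for e in epochs],
        "metrics_table": table,
        "max_relative_error": rel_err,
    }
    _write_report(
        out_dir,
        "arena_report.json",
        {k: v for k, v in results.items() if k != "metrics_table"},
    )
    if out_dir is not None:
        table.to_csv(Path(out_dir) / "arena_metrics.csv", index=False)
    return results


# ---------------------------------------------------------------------------
# Degradation study
# ---------------------------------------------------------------------------

def run_degradation_pipeline(
    config: PipelineConfig | None = None, out_dir: str | Path | None = None
) -> dict:
    """Synthetic longitudinal degradation study.

    Intact and amputated groups are imaged daily; series are aligned to
    day 1, ROI means extracted, normalized to 1 dpi, groups compared per
    day (two-sided exact Mann-Whitney) and the amputation decay rate
    re-estimated from the normalized curves.
    """
    config = config or PipelineConfig()
    spec = DegradationSeriesSpec(
        n_days=config.n_days,
        n_flies_per_group=config.n_flies_per_group,
        bleach_rate=config.bleach_rate,
        amputation_decay_rate=config.amputation_decay_rate,
        jitter=config.degradation_jitter,
        noise_sd=config.degradation_noise_sd,
        seed=config.seed,
    )
    series_list, truth = generate_degradation_series(spec)
    tables = []
    for series in series_list:
        aligned, _ = deg_mod.align_series(series)
        tables.append(deg_mod.roi_mean_by_day(aligned, truth.roi_masks))
    table = deg_mod.normalize_to_first_day(pd.concat(tables, ignore_index=True))

    target_roi = spec.amputated_rois[0]
    pvals = deg_mod.compare_groups_by_day(table, roi_id=target_roi)

    # decay-rate recovery, averaged over amputated flies
    rates = [
        deg_mod.fit_decay_rate(table, f"amputated_{f}", target_roi, start_day=2)
        for f in range(config.n_flies_per_group)
    ]
    true_rate = truth.true_decay_rates[("amputated", target_roi)]
    results = {
        "seed": config.seed,
        "table": table,
        "pvalues_by_day": pvals,
        "estimated_decay_rate_per_day": float(np.mean(rates)),
        "true_decay_rate_per_day": float(true_rate),
        "decay_rate_relative_error": float(abs(np.mean(rates) / true_rate - 1)),
    }
    _write_report(
        out_dir,
        "degradation_report.json",
        {
            "seed": config.seed,
            "pvalues_by_day": pvals.to_dict(),
            "estimated_decay_rate_per_day": results["estimated_decay_rate_per_day"],
            "true_decay_rate_per_day": results["true_decay_rate_per_day"],
        },
    )
    if out_dir is not None:
        table.to_csv(Path(out_dir) / "degradation_table.csv", index=False)
    return results
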