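"""End-to-end pipeline: preprocess -> events -> MoS -> stratify -> stats.

`run_cohort_pipeline` operates in memory on a simulated cohort (or one
supplied by the caller) and returns a result bundle;
:func:`run_pipeline` additionally writes every table as TSV plus a
machine-readable summary and a run log with seeds and versions.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig
from .gait_events import detect_events, segment_steps
from .preprocessing import MarkerTrajectory, fill_gaps, smooth_trajectory
from .recording import TrialRecording
from .risk_stratification import analyze_mos_table, assign_tertiles
from .stability import compute_step_mos, detect_fall_events, mos_records_to_frame
from .stats_report import build_step_pairs, condition_regression, paired_wilcoxon, summarize_steps
from .synthetic_data import generate_cohort

logger = logging.getLogger("mostrip")

__all__ = ["preprocess_recording", "process_trial", "run_cohort_pipeline", "run_pipeline", "PipelineResult"]


def preprocess_recording(
    recording: TrialRecording, max_gap: int = 20, smoothing: str | float = "gcv"
) -> TrialRecording:
    """Gap-fill and smooth every marker channel of a recording."""
    out = recording.copy()
    for name, pos in out.markers.items():
        traj = MarkerTrajectory.from_array(name, pos, out.sampling_rate)
        traj, _ = fill_gaps(traj, max_gap=max_gap)
        if smoothing != "none":
            mode = "gcv" if smoothing == "gcv" else float(smoothing)
            traj = smooth_trajectory(traj, predicted_mse=mode)
        filled = traj.positions.copy()
        filled[traj.missing] = np.nan
        out.markers[name] = filled
    return out


def process_trial(
    recording: TrialRecording,
    schedule,
    perturbation_frames,
    config: PipelineConfig,
    preprocess: bool = True,
) -> tuple[pd.DataFrame, list, list]:
    """One trial through preprocess -> events -> steps -> MoS -> falls.

    Returns the tidy MoS table (with perturbation ``window_id``), the
    fall episodes, and the detected events.
    """

    rec = (
        preprocess_recording(recording, config.max_gap, config.smoothing)
        if preprocess
        else recording
    )
    events = detect_events(rec)
    steps = segment_steps(
        events,
        schedule,
        perturbation_frames,
        condition=recording.meta.get("condition"),
    )
    records = compute_step_mos(
        rec, steps, events, boundary=config.boundary, g=config.g, belt_mode=config.belt_mode
    )
    table = mos_records_to_frame(records)
    window = {}
    for s in steps:
        if s.label == "perturbed" and s.perturbation_id is not None:
            for j in range(-1, 4):
                window[s.ordinal + j] = s.perturbation_id
    table["window_id"] = table["ordinal"].map(window).astype("Int64")
    table["participant_id"] = recording.meta.get("participant_id", "P?")
    table["condition"] = recording.meta.get("condition", "unknown")
    falls = detect_fall_events(rec.harness_load, threshold=config.fall_threshold)
    return table, falls, events


@dataclass
class PipelineResult:
    participants: pd.DataFrame
    profiles: list
    mos: pd.DataFrame
    auc: pd.DataFrame
    step_summary: pd.DataFrame
    summary_by_condition_tertile: pd.DataFrame
    wilcoxon: pd.DataFrame
    regression: pd.DataFrame
    fall_episodes: pd.DataFrame
    n_trials: int
    n_failed: int


_PAIRED_COMPARISONS = (
    ("preperturbation", "perturbed"),
    ("preperturbation", "recovery1"),
    ("preperturbation", "recovery2"),
    ("preperturbation", "recovery3"),
)


def run_cohort_pipeline(config: PipelineConfig, cohort=None) -> PipelineResult:
    """Run the full analysis over a cohort (simulated unless supplied)."""
    if cohort is None:
        cohort = generate_cohort(config.simulation)
    mos_tables = []
    fall_rows = []
    n_failed = 0
    for participant_id, condition, recording, truth in cohort.trials:
        try:
            table, falls, _ = process_trial(
                recording, truth.schedule, truth.perturbation_frames, config
            )
        except Exception:
            logger.exception("trial %s/%s failed; skipped", participant_id, condition.name)
            n_failed += 1
            continue
        mos_tables.append(table)
        for ep in falls:
            fall_rows.append(
                {
                    "participant_id": participant_id,
                    "condition": condition.name,
                    "start_frame": ep.start_frame,
                    "end_frame": ep.end_frame,
                    "peak_load": ep.peak_load,
                }
            )
    if not mos_tables:
        raise RuntimeError("all trials failed; nothing to analyse")
    mos = pd.concat(mos_tables, ignore_index=True)

    profiles = assign_tertiles(cohort.participants)
    tert = {p.participant_id: p.tertile for p in profiles}
    auc = analyze_mos_table(mos, profiles, pooling=config.roc_pooling)
    step_summary = summarize_steps(mos, group_by=("label",))
    by_ct = summarize_steps(
        mos.assign(tertile=mos["participant_id"].map(tert)),
        group_by=("condition", "label", "tertile"),
    )

    unit = "perturbation" if config.pairing_unit == "perturbation" else "participant"
    test_rows = []
    for a, b in _PAIRED_COMPARISONS:
        pairs = build_step_pairs(mos, a, b, unit=unit)
        if len(pairs) == 0:
            continue
        res = paired_wilcoxon(pairs, a, b)
        test_rows.append(dataclasses.asdict(res))
    base_pairs = build_step_pairs(mos, "baseline", "preperturbation", unit="participant")
    if len(base_pairs) > 0:
        res = paired_wilcoxon(base_pairs, "baseline", "preperturbation")
        test_rows.append(dataclasses.asdict(res))
    wilcoxon = pd.DataFrame(test_rows)

    regression = condition_regression(mos, profiles)

    return PipelineResult(
        participants=cohort.participants,
        profiles=profiles,
        mos=mos,
        auc=auc,
        step_summary=step_summary,
        summary_by_condition_tertile=by_ct,
        wilcoxon=wilcoxon,
        regression=regression,
        fall_episodes=pd.DataFrame(
            fall_rows, columns=["participant_id", "condition", "start_frame", "end_frame", "peak_load"]
        ),
        n_trials=len(cohort.trials),
        n_failed=n_failed,
    )


def run_pipeline(config: PipelineConfig, cohort=None) -> PipelineResult:
    """Run the cohort analysis and write all outputs under ``out_dir``."""
    result = run_cohort_pipeline(config, cohort=cohort)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tables = {
        "participants.tsv": result.participants,
        "mos.tsv": result.mos,
        "auc.tsv": result.auc,
        "step_summary.tsv": result.step_summary,
        "step_summary_by_condition_tertile.tsv": result.summary_by_condition_tertile,
        "wilcoxon.tsv": result.wilcoxon,
        "regression.tsv": result.regression,
        "fall_episodes.tsv": result.fall_episodes,
    }
    for name, table in tables.items():
        table.to_csv(out / name, sep="\t", index=False, float_format="%.9g")
    summary = {
        "n_trials": result.n_trials,
        "n_failed": result.n_failed,
        "n_participants": int(len(result.participants)),
        "conditions": sorted(result.mos["condition"].unique().tolist()),
        "step_labels": sorted(result.mos["label"].unique().tolist()),
        "n_fall_episodes": int(len(result.fall_episodes)),
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    log = {
        "mostrip_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": config.seed,
        "config": json.loads(json.dumps(config.to_dict(), default=str)),
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=2))
    return result
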