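"""TSV interchange formats.

TSV with SI units is the canonical interchange: one wide table per
trial (frame, time_s, then x/y/z per marker, belt_speed_mps,
harness_load_pctbw), an events table (frame, time_s, kind, side,
source), and a cohort manifest (participant_id, condition, risk_score,
file paths).  Frames are 0-based and ``time_s = frame / rate``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .gait_events import GaitEvent
from .recording import REQUIRED_MARKERS, TrialRecording

__all__ = [
    "write_trial",
    "read_trial",
    "write_events",
    "read_events",
    "write_manifest",
    "read_manifest",
]

_AXES = ("x", "y", "z")


def write_trial(recording: TrialRecording, path: str | Path) -> Path:
    """Write one trial as a wide TSV table."""
    path = Path(path)
    n = recording.n_frames
    data: dict[str, np.ndarray] = {
        "frame": np.arange(n),
        "time_s": recording.times,
    }
    for name in sorted(recording.markers):
        for ax_i, ax in enumerate(_AXES):
            data[f"{name}_{ax}"] = recording.markers[name][:, ax_i]
    data["belt_speed_mps"] = recording.belt_speed
    data["harness_load_pctbw"] = recording.harness_load
    pd.DataFrame(data).to_csv(path, sep="\t", index=False, float_format="%.9g")
    return path


def read_trial(
    path: str | Path,
    format: str = "tsv",
    sampling_rate: float | None = None,
    marker_map: dict[str, str] | None = None,
    required: tuple[str, ...] = REQUIRED_MARKERS,
) -> TrialRecording:
    """Read a trial table back into a :class:`TrialRecording`.

    ``marker_map`` renames file marker labels to the package's canonical
    names.  The sampling rate is inferred from the time column and
    checked against ``sampling_rate`` when given (mismatch is an error).
    """

    if format == "c3d":
        raise ValueError(
            "C3D input is not supported by this build; export the trial as the "
            "canonical TSV (see write_trial) instead"
        )
    if format != "tsv":
        raise ValueError(f"unknown trial format {format!r}")
    path = Path(path)
    try:
        table = pd.read_csv(path, sep="\t")
    except pd.errors.ParserError as exc:  # malformed/truncated file
        raise ValueError(f"cannot parse {path}: {exc}") from exc
    for col in ("frame", "time_s", "belt_speed_mps", "harness_load_pctbw"):
        if col not in table.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    if len(table) < 2:
        raise ValueError(f"{path}: trial table needs at least 2 frames")
    dt = np.diff(table["time_s"].to_numpy())
    if not np.allclose(dt, dt[0], rtol=0, atol=1e-9):
        raise ValueError(f"{path}: time column is not uniformly sampled")
    rate = 1.0 / dt[0]
    if sampling_rate is not None and not np.isclose(rate, sampling_rate, rtol=1e-6):
        raise ValueError(
            f"{path}: sampling rate {rate:.6g} Hz does not match the stated "
            f"{sampling_rate:.6g} Hz"
        )

    marker_map = marker_map or {}
    stems = sorted(
        {c[:-2] for c in table.columns if c.endswith(("_x", "_y", "_z"))}
    )
    markers = {}
    for stem in stems:
        name = marker_map.get(stem, stem)
        markers[name] = table[[f"{stem}_{ax}" for ax in _AXES]].to_numpy(dtype=float)
    missing = [m for m in required if m not in markers]
    if missing:
        raise ValueError(
            f"{path}: missing marker(s) {missing}; file provides {stems} "
            f"(marker_map={marker_map})"
        )
    return TrialRecording(
        markers=markers,
        belt_speed=table["belt_speed_mps"].to_numpy(dtype=float),
        harness_load=table["harness_load_pctbw"].to_numpy(dtype=float),
        sampling_rate=float(round(rate, 9)),
        meta={"source": str(path)},
    )


def write_events(events: list[GaitEvent], path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {
            "frame": [e.frame for e in events],
            "time_s": [e.time for e in events],
            "kind": [e.kind for e in events],
            "side": [e.side for e in events],
            "source": [e.source for e in events],
        }
    ).to_csv(path, sep="\t", index=False)
    return path


def read_events(path: str | Path) -> list[GaitEvent]:
    table = pd.read_csv(path, sep="\t")
    return [
        GaitEvent(int(r.frame), float(r.time_s), str(r.kind), str(r.side), str(r.source))
        for r in table.itertuples(index=False)
    ]


def write_manifest(manifest: pd.DataFrame, path: str | Path) -> Path:
    required = {"participant_id", "condition", "risk_score", "trial_path"}
    missing = required - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest lacks column(s) {sorted(missing)}")
    manifest.to_csv(path, sep="\t", index=False)
    return Path(path)


def read_manifest(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    if table.empty:
        raise ValueError(f"{path}: manifest is empty")
    required = {"participant_id", "condition", "risk_score", "trial_path"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"{path}: manifest lacks column(s) {sorted(missing)}")
    return table
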